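"""Transmit sequences: plane-wave, mono-focus and wide-beam (diverging)
delay laws, and steered-compounding sequences.

A wide-beam event is modelled as a virtual point source behind the
aperture at depth z_v; the default z_v is chosen so the geometric
divergence cone covers the steered sector: z_v = (A/2)/tan(span/2) for
aperture width A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import SequenceError
from .geometry import ArrayGeometry, SOUND_SPEED

#: The wearable imager's compounding sequence: 97 angles spanning ±37.5°.
DEFAULT_SPAN_DEG = 75.0
DEFAULT_N_ANGLES = 97
DEFAULT_FOCAL_DEPTH = 60e-3


@dataclass(frozen=True)
class Pulse:
    """Gaussian-enveloped transmit pulse.

    centre_frequency in Hz; fractional_bandwidth is the −6 dB fractional
    bandwidth of the amplitude spectrum (0.55 for the wearable imager).
    """

    centre_frequency: float = 3.0e6
    fractional_bandwidth: float = 0.55

    def __post_init__(self) -> None:
        if self.centre_frequency <= 0:
            raise SequenceError("pulse centre frequency must be positive")
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise SequenceError("fractional bandwidth must be in (0, 2)")

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation in seconds (−6 dB spectral width)."""
        sigma_f = self.fractional_bandwidth * self.centre_frequency / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return 1.0 / (2.0 * math.pi * sigma_f)

    @property
    def duration(self) -> float:
        """Effective support (±4σ of the envelope), seconds."""
        return 8.0 * self.sigma_t


@dataclass(frozen=True)
class TransmitEvent:
    """One firing: per-element delays (min = 0) and apodization weights."""

    kind: Literal["plane", "focus", "widebeam"]
    delays: np.ndarray
    apodization: np.ndarray
    steer_angle_deg: float | None = None
    focal_point: np.ndarray | None = None
    virtual_source: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        a = np.asarray(self.apodization, dtype=float)
        if d.ndim != 1 or a.shape != d.shape:
            raise SequenceError("delays and apodization must be matching 1-D arrays")
        if not np.all(np.isfinite(d)):
            raise SequenceError("delays must be finite")
        if abs(float(d.min())) > 1e-15:
            raise SequenceError("delays must be normalized to min = 0")
        if np.any((a < 0) | (a > 1)):
            raise SequenceError("apodization weights must lie in [0, 1]")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "apodization", a)

    @property
    def n_elements(self) -> int:
        return self.delays.size


@dataclass(frozen=True)
class TransmitSequence:
    """Ordered set of transmit events sharing one array and pulse."""

    events: tuple[TransmitEvent, ...]
    pulse: Pulse = field(default_factory=Pulse)

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise SequenceError("a transmit sequence must contain at least one event")
        n = self.events[0].n_elements
        if any(ev.n_elements != n for ev in self.events):
            raise SequenceError("all events must reference the same array size")
        object.__setattr__(self, "events", tuple(self.events))

    def __len__(self) -> int:
        return len(self.events)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([ev.steer_angle_deg if ev.steer_angle_deg is not None else np.nan
                         for ev in self.events])


def angle_set(min_deg: float, max_deg: float, n: int) -> np.ndarray:
    """n equally spaced steering angles, both endpoints inclusive.

    (−37.5, 37.5, 97) reproduces the imager's compounding set with an
    exact step of 0.78125° (printed as 0.78°).
    """
    if n < 1:
        raise SequenceError("need at least one angle")
    if min_deg > max_deg:
        raise SequenceError("min_deg must not exceed max_deg")
    if n == 1:
        return np.array([0.5 * (min_deg + max_deg)])
    return np.linspace(min_deg, max_deg, n)


def _normalize(delays: np.ndarray) -> np.ndarray:
    return delays - delays.min()


def plane_delays(array: ArrayGeometry, angle_deg: float, c: float = SOUND_SPEED) -> TransmitEvent:
    """Plane-wave delay law steered at `angle_deg` in the imaging plane.

    delay_i = (x_i·sinθ + z_i·cosθ)/c, shifted to min 0.  Curved arrays
    use their true element positions.
    """
    if abs(angle_deg) >= 90.0:
        raise SequenceError("plane-wave steering angle must satisfy |θ| < 90°")
    th = math.radians(angle_deg)
    pos = array.element_positions
    d = (pos[:, 0] * math.sin(th) + pos[:, 2] * math.cos(th)) / c
    return TransmitEvent(kind="plane", delays=_normalize(d),
                         apodization=np.ones(array.n_elements),
                         steer_angle_deg=float(angle_deg))


def focus_delays(array: ArrayGeometry, focus, c: float = SOUND_SPEED) -> TransmitEvent:
    """Mono-focus delay law: wavefront coincides at the focal point.

    delay_i = (max_j d_j − d_i)/c with d_i the element-to-focus distance.
    """
    f = np.asarray(focus, dtype=float).reshape(3)
    if f[2] <= 0:
        raise SequenceError("focal point must be at positive depth")
    dist = np.linalg.norm(array.element_positions - f[None, :], axis=1)
    if np.any(dist < 1e-12):
        raise SequenceError("focal point coincides with an element")
    d = (dist.max() - dist) / c
    return TransmitEvent(kind="focus", delays=_normalize(d),
                         apodization=np.ones(array.n_elements),
                         focal_point=f)


def widebeam_delays(array: ArrayGeometry, angle_deg: float, virtual_depth: float,
                    c: float = SOUND_SPEED) -> TransmitEvent:
    """Diverging-wave delay law from a virtual source behind the aperture.

    The virtual source sits at v = centroid + (−z_v·sinθ, 0, −z_v·cosθ)
    (anchored to the aperture so the law is translation-invariant);
    delay_i = (|r_i − v| − min_j |r_j − v|)/c.
    """
    if virtual_depth <= 0:
        raise SequenceError("virtual source depth must be positive")
    th = math.radians(angle_deg)
    v = (array.element_positions.mean(axis=0)
         + np.array([-virtual_depth * math.sin(th), 0.0, -virtual_depth * math.cos(th)]))
    dist = np.linalg.norm(array.element_positions - v[None, :], axis=1)
    d = (dist - dist.min()) / c
    return TransmitEvent(kind="widebeam", delays=_normalize(d),
                         apodization=np.ones(array.n_elements),
                         steer_angle_deg=float(angle_deg), virtual_source=v)


def default_virtual_depth(array: ArrayGeometry, span_deg: float = DEFAULT_SPAN_DEG) -> float:
    """Virtual-source depth whose divergence cone covers ±span/2."""
    if span_deg <= 0:
        raise SequenceError("span must be positive")
    return (array.aperture_width / 2.0) / math.tan(math.radians(span_deg / 2.0))


def make_compounding_sequence(
    array: ArrayGeometry,
    span_deg: float = DEFAULT_SPAN_DEG,
    n_angles: int = DEFAULT_N_ANGLES,
    virtual_depth: float | None = None,
    pulse: Pulse | None = None,
) -> TransmitSequence:
    """Wide-beam compounding sequence: one diverging event per angle.

    Defaults reproduce the imager's 97 angles over ±37.5°.
    """
    if virtual_depth is None:
        virtual_depth = default_virtual_depth(array, span_deg) if span_deg > 0 else 8.08e-3
    if pulse is None:
        pulse = Pulse(array.centre_frequency, array.fractional_bandwidth)
    angles = angle_set(-span_deg / 2.0, span_deg / 2.0, n_angles)
    events = tuple(widebeam_delays(array, a, virtual_depth) for a in angles)
    return TransmitSequence(events=events, pulse=pulse)


def make_plane_sequence(array: ArrayGeometry, angles_deg=(0.0,), pulse: Pulse | None = None) -> TransmitSequence:
    """Plane-wave sequence at the given steering angles."""
    if pulse is None:
        pulse = Pulse(array.centre_frequency, array.fractional_bandwidth)
    return TransmitSequence(events=tuple(plane_delays(array, a) for a in angles_deg), pulse=pulse)


def make_focus_sequence(array: ArrayGeometry, focal_depth: float = DEFAULT_FOCAL_DEPTH,
                        pulse: Pulse | None = None) -> TransmitSequence:
    """Single mono-focus event on axis at the given focal depth."""
    if pulse is None:
        pulse = Pulse(array.centre_frequency, array.fractional_bandwidth)
    return TransmitSequence(events=(focus_delays(array, (0.0, 0.0, focal_depth)),), pulse=pulse)
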