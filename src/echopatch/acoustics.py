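"""Forward acoustic simulation.

Single-scattering (Born) pulse-echo model: each scatterer re-radiates a
delayed, amplitude-scaled replica of the transmit pulse.  Transmitted
fields are evaluated in the time domain and reported as the root mean
square of the pressure at each grid point; channel data are synthesized
by depositing per-scatterer impulses (linear interpolation in time) on
each element's trace and convolving once with the pulse kernel.

The transmit arrival time at a point p is the first arrival of the fired
wavefront, min over elements of (delay_e + |p − r_e|/c), which is valid
for plane, focused and diverging laws on flat or curved apertures alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import gausspulse, oaconvolve

from .errors import SimulationError
from .geometry import ArrayGeometry, SOUND_SPEED
from .transmit import Pulse, TransmitEvent, TransmitSequence

DEFAULT_FS = 20.0e6


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Phantom:
    """Collection of point scatterers, with optional labelled regions used
    as metrics ground truth."""

    positions: np.ndarray          # (S, 3) metres
    reflectivity: np.ndarray       # (S,) dimensionless amplitude
    regions: tuple = ()            # optional (label, shape-dict) pairs
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        refl = np.atleast_1d(np.asarray(self.reflectivity, dtype=float))
        if pos.shape[1] != 3 or refl.shape[0] != pos.shape[0]:
            raise SimulationError("positions (S,3) and reflectivity (S,) must match")
        if not np.all(np.isfinite(refl)):
            raise SimulationError("reflectivities must be finite")
        if pos.shape[0] and np.any(pos[:, 2] <= 0):
            raise SimulationError("scatterers must lie at positive depth")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "reflectivity", refl)

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def union(self, other: "Phantom") -> "Phantom":
        return Phantom(
            positions=np.vstack([self.positions, other.positions]),
            reflectivity=np.concatenate([self.reflectivity, other.reflectivity]),
            regions=self.regions + other.regions,
        )


@dataclass(frozen=True)
class FieldMap:
    """RMS transmitted-pressure map on a regular lateral × axial grid."""

    x: np.ndarray                  # lateral coordinates (m)
    z: np.ndarray                  # axial coordinates (m)
    rms_pressure: np.ndarray       # (len(z), len(x)), >= 0, linear units

    def __post_init__(self) -> None:
        p = np.asarray(self.rms_pressure, dtype=float)
        if p.shape != (len(self.z), len(self.x)):
            raise SimulationError("rms_pressure shape must be (n_z, n_x)")
        if np.any(p < 0):
            raise SimulationError("RMS pressure must be non-negative")
        object.__setattr__(self, "rms_pressure", p)


@dataclass(frozen=True)
class ChannelData:
    """RF samples indexed event × element × time."""

    samples: np.ndarray            # (n_events, n_elements, n_t)
    fs: float
    t0: float
    c: float
    array: ArrayGeometry = field(repr=False)
    sequence: TransmitSequence = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 3:
            raise SimulationError("samples must be (events, elements, time)")
        fc = self.sequence.pulse.centre_frequency
        if self.fs < 4.0 * fc:
            raise SimulationError("sampling rate must be at least 4x the centre frequency")
        if not np.all(np.isfinite(s)):
            raise SimulationError("samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_events(self) -> int:
        return self.samples.shape[0]

    @property
    def n_elements(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# primitives

def rms(samples: Sequence[float] | np.ndarray) -> float:
    """Root mean square, sqrt((1/n)·Σ x_i²)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise SimulationError("RMS of an empty sample set is undefined")
    return float(np.sqrt(np.mean(x * x)))


def pulse_kernel(pulse: Pulse, fs: float) -> tuple[np.ndarray, int]:
    """Sampled Gaussian-modulated sinusoid and the index of its t=0 centre."""
    half = int(np.ceil(0.5 * pulse.duration * fs))
    t = np.arange(-half, half + 1) / fs
    k = gausspulse(t, fc=pulse.centre_frequency, bw=pulse.fractional_bandwidth)
    return k, half


def _lateral_tangents(array: ArrayGeometry) -> np.ndarray:
    """Per-element unit lateral axis (normal rotated −90° in the xz plane)."""
    n = array.element_normals
    return np.column_stack([n[:, 2], np.zeros(array.n_elements), -n[:, 0]])


def element_directivity(array: ArrayGeometry, unit_dirs: np.ndarray,
                        tangents: np.ndarray | None = None,
                        wavelength: float | None = None) -> np.ndarray:
    """Far-field rectangular-aperture directivity for each (element, dir).

    unit_dirs: (..., E, 3) unit vectors from element to field point.
    Width sets the lateral factor, element length the elevational one:
    D = sinc(w·sinθ_lat/λ)·sinc(L·sinθ_el/λ)   (sinc(u) = sin(πu)/(πu)).
    """
    lam = wavelength if wavelength is not None else array.wavelength
    if tangents is None:
        tangents = _lateral_tangents(array)
    sin_lat = np.einsum("...ek,ek->...e", unit_dirs, tangents)
    sin_el = unit_dirs[..., 1]
    return np.sinc(array.element_width * sin_lat / lam) * np.sinc(array.element_length * sin_el / lam)


def transmit_arrival(array: ArrayGeometry, event: TransmitEvent, points: np.ndarray,
                     c: float = SOUND_SPEED) -> tuple[np.ndarray, np.ndarray]:
    """First-arrival transmit time at each point, and the index of the
    element that launches it.

    Returns (t_tx, e_idx), each of shape (P,).
    """
    p = np.atleast_2d(points)
    diff = p[:, None, :] - array.element_positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)                     # (P, E)
    t = event.delays[None, :] + dist / c
    e_idx = np.argmin(t, axis=1)
    return t[np.arange(p.shape[0]), e_idx], e_idx


# ---------------------------------------------------------------------------
# transmitted-field simulation

def simulate_field(
    array: ArrayGeometry,
    transmit: TransmitEvent | TransmitSequence,
    x: np.ndarray,
    z: np.ndarray,
    pulse: Pulse | None = None,
    c: float = SOUND_SPEED,
    fs: float = DEFAULT_FS,
    chunk: int = 2048,
) -> FieldMap:
    """RMS transmitted-pressure field on the y=0 grid x × z.

    Per point the per-element pulse replicas (1/r spreading, far-field
    directivity, transmit apodization) are superposed in the time domain
    and reduced to their RMS; for a sequence the per-event RMS maps are
    combined as sqrt of the sum of squares.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise SimulationError("field grid must lie at positive depth")
    if isinstance(transmit, TransmitSequence):
        events = transmit.events
        pulse = transmit.pulse if pulse is None else pulse
    else:
        events = (transmit,)
        pulse = pulse if pulse is not None else Pulse(array.centre_frequency, array.fractional_bandwidth)

    X, Z = np.meshgrid(x, z)
    pts = np.column_stack([X.ravel(), np.zeros(X.size), Z.ravel()])
    tangents = _lateral_tangents(array)
    lam = c / pulse.centre_frequency

    total_sq = np.zeros(pts.shape[0])
    for event in events:
        # constant analysis-window length per event keeps the RMS
        # denominator n identical across grid points
        t_win = event.delays.max() + array.aperture_width / c + pulse.duration
        n_t = int(np.ceil(t_win * fs)) + 1
        offsets = np.arange(n_t) / fs
        sum_sq = np.empty(pts.shape[0])
        for lo in range(0, pts.shape[0], chunk):
            p = pts[lo:lo + chunk]
            diff = p[:, None, :] - array.element_positions[None, :, :]
            dist = np.linalg.norm(diff, axis=2)             # (P, E)
            tau = event.delays[None, :] + dist / c
            u = diff / dist[:, :, None]
            amp = event.apodization[None, :] * element_directivity(array, u, tangents, lam) / dist
            t0p = tau.min(axis=1)
            # (P, E, T) evaluation of the pulse replicas
            targ = (t0p[:, None, None] + offsets[None, None, :]) - tau[:, :, None]
            wave = np.einsum("pe,pet->pt", amp,
                             gausspulse(targ, fc=pulse.centre_frequency,
                                        bw=pulse.fractional_bandwidth))
            sum_sq[lo:lo + chunk] = np.sum(wave * wave, axis=1)
        total_sq += sum_sq / n_t
    return FieldMap(x=x, z=z, rms_pressure=np.sqrt(total_sq).reshape(len(z), len(x)))


# ---------------------------------------------------------------------------
# channel-data simulation

def simulate_channel_data(
    phantom: Phantom,
    array: ArrayGeometry,
    sequence: TransmitSequence,
    fs: float = DEFAULT_FS,
    noise_rms: float = 0.0,
    seed: int | None = None,
    c: float = SOUND_SPEED,
    max_depth: float | None = None,
) -> ChannelData:
    """Synthesize RF channel data for a phantom and transmit sequence.

    For each event/element/scatterer the echo arrives at
    t = t_tx(scatterer) + |scatterer − r_e|/c with amplitude
    reflectivity × directivity_tx·directivity_rx / (r_tx·r_rx); optional
    additive white Gaussian noise of the given RMS is seeded explicitly.
    """
    if fs < 4.0 * sequence.pulse.centre_frequency:
        raise SimulationError("fs must be at least 4x the pulse centre frequency")
    if noise_rms < 0:
        raise SimulationError("noise_rms must be non-negative")

    pulse = sequence.pulse
    kernel, k0 = pulse_kernel(pulse, fs)
    tangents = _lateral_tangents(array)
    lam = c / pulse.centre_frequency
    E = array.n_elements
    pos_e = array.element_positions

    if phantom.n_scatterers:
        depth_guess = float(np.max(np.linalg.norm(phantom.positions, axis=1)))
    else:
        depth_guess = max_depth if max_depth is not None else 0.14
    if max_depth is not None:
        depth_guess = max(depth_guess, max_depth)
    max_delay = max(float(ev.delays.max()) for ev in sequence.events)
    t_max = max_delay + 2.0 * (depth_guess + array.aperture_width) / c + pulse.duration
    n_t = int(np.ceil(t_max * fs)) + 1
    t0 = 0.0

    rf = np.zeros((len(sequence), E, n_t))
    if phantom.n_scatterers:
        diff_rx = phantom.positions[:, None, :] - pos_e[None, :, :]   # (S, E, 3)
        dist_rx = np.linalg.norm(diff_rx, axis=2)                     # (S, E)
        u_rx = diff_rx / dist_rx[:, :, None]
        dir_rx = element_directivity(array, u_rx, tangents, lam)      # (S, E)
        for i, event in enumerate(sequence.events):
            t_arr = event.delays[:, None] + dist_rx.T / c             # (E, S)
            e_first = np.argmin(t_arr, axis=0)                        # (S,)
            s_idx = np.arange(phantom.n_scatterers)
            t_tx = t_arr[e_first, s_idx]
            r_tx = dist_rx[s_idx, e_first]
            a_tx = (event.apodization[e_first]
                    * dir_rx[s_idx, e_first] / r_tx)                  # reciprocity: same geometry
            tau = t_tx[:, None] + dist_rx / c                         # (S, E)
            amp = (phantom.reflectivity[:, None] * a_tx[:, None]
                   * dir_rx / dist_rx)                                # (S, E)
            # deposit 2-tap linear-interpolated impulses per element trace
            pos_f = (tau - t0) * fs
            i_lo = np.floor(pos_f).astype(np.int64)
            frac = pos_f - i_lo
            valid = (i_lo >= 0) & (i_lo + 1 < n_t)
            e_grid = np.broadcast_to(np.arange(E)[None, :], tau.shape)
            flat = rf[i]
            np.add.at(flat, (e_grid[valid], i_lo[valid]), (amp * (1 - frac))[valid])
            np.add.at(flat, (e_grid[valid], i_lo[valid] + 1), (amp * frac)[valid])
        rf = oaconvolve(rf, kernel[None, None, :], axes=2)[:, :, k0:k0 + n_t]

    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        rf = rf + rng.normal(0.0, noise_rms, size=rf.shape)

    return ChannelData(samples=rf, fs=fs, t0=t0, c=c, array=array, sequence=sequence)
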