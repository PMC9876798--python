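"""Image formation: delay-and-sum receive beamforming with dynamic
focusing, coherent compounding, envelope detection and log compression,
sector scan conversion, and B-mode/M-mode assembly.

Beamforming runs directly on a Cartesian pixel grid (the sector
beamform-then-scan-convert path is provided separately through
``scan_convert``).  Element positions default to the ones stored with
the channel data; passing explicit positions enables curvature-corrected
versus flat-assumption comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .acoustics import ChannelData
from .errors import ImagingError

DEFAULT_F_NUMBER = 1.5
DEFAULT_FLOOR_DB = -60.0


@dataclass(frozen=True)
class PixelGrid:
    """Regular imaging grid.

    Pixel spacings follow the display convention
    Δy = imaging_depth/(N_vertical − 1), Δx = imaging_width/(N_lateral − 1).
    The grid spans x ∈ x_centre ± width/2 and z ∈ [z_start, z_start + depth].
    """

    imaging_depth: float
    imaging_width: float
    n_vertical: int
    n_lateral: int
    x_centre: float = 0.0
    z_start: float = 0.0

    def __post_init__(self) -> None:
        if self.n_vertical < 2 or self.n_lateral < 2:
            raise ImagingError("need at least 2 pixels per axis")
        if self.imaging_depth <= 0 or self.imaging_width <= 0:
            raise ImagingError("imaging depth and width must be positive")

    @property
    def dy(self) -> float:
        return self.imaging_depth / (self.n_vertical - 1)

    @property
    def dx(self) -> float:
        return self.imaging_width / (self.n_lateral - 1)

    @property
    def x(self) -> np.ndarray:
        return self.x_centre + np.linspace(-self.imaging_width / 2,
                                           self.imaging_width / 2, self.n_lateral)

    @property
    def z(self) -> np.ndarray:
        return self.z_start + np.linspace(0.0, self.imaging_depth, self.n_vertical)


def pixel_spacing(depth: float, width: float, n_v: int, n_l: int) -> tuple[float, float]:
    """Pixel spacings (Δy, Δx) = (depth/(N_v−1), width/(N_l−1))."""
    if n_v < 2 or n_l < 2:
        raise ImagingError("pixel counts must be at least 2")
    if depth <= 0 or width <= 0:
        raise ImagingError("depth and width must be positive")
    return depth / (n_v - 1), width / (n_l - 1)


@dataclass(frozen=True)
class BeamformedFrame:
    """Pre-compression beamformed frame (complex analytic values)."""

    grid: PixelGrid
    values: np.ndarray                      # (n_vertical, n_lateral) complex
    coverage: np.ndarray = None             # bool mask: pixel inside record
    n_events: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (self.grid.n_vertical, self.grid.n_lateral):
            raise ImagingError("frame shape must match grid")
        if not np.all(np.isfinite(v)):
            raise ImagingError("frame values must be finite")
        cov = self.coverage
        if cov is None:
            cov = np.ones(v.shape, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "coverage", np.asarray(cov, dtype=bool))


@dataclass(frozen=True)
class BModeImage:
    """Envelope-detected, log-compressed image, normalized so max = 0 dB."""

    grid: PixelGrid
    intensity_db: np.ndarray
    floor_db: float = DEFAULT_FLOOR_DB

    def __post_init__(self) -> None:
        v = np.asarray(self.intensity_db, dtype=float)
        if v.shape != (self.grid.n_vertical, self.grid.n_lateral):
            raise ImagingError("image shape must match grid")
        if abs(float(v.max())) > 1e-9:
            raise ImagingError("log-compressed image must be normalized to 0 dB max")
        if np.any(v < self.floor_db - 1e-9):
            raise ImagingError("image values must not fall below the display floor")
        object.__setattr__(self, "intensity_db", v)

    @property
    def linear(self) -> np.ndarray:
        """Linear-scale envelope (max 1), inverse of the log compression."""
        return 10.0 ** (self.intensity_db / 20.0)


@dataclass(frozen=True)
class MModeImage:
    """One scanline's depth profile stacked over time."""

    z: np.ndarray                  # depth axis (m)
    times: np.ndarray              # frame times (s)
    intensity_db: np.ndarray       # (n_z, n_frames)
    scanline_x: float
    floor_db: float = DEFAULT_FLOOR_DB

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ImagingError("frame times must be strictly increasing (>= 2 frames)")
        v = np.asarray(self.intensity_db, dtype=float)
        if v.shape != (len(self.z), t.size):
            raise ImagingError("M-mode shape must be (n_z, n_frames)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity_db", v)

    @property
    def frame_interval(self) -> float:
        return float(np.mean(np.diff(self.times)))

    @property
    def linear(self) -> np.ndarray:
        return 10.0 ** (self.intensity_db / 20.0)


# ---------------------------------------------------------------------------
# delay-and-sum

def das_beamform(
    channel: ChannelData,
    grid: PixelGrid,
    event_index: int = 0,
    f_number: float = DEFAULT_F_NUMBER,
    window: str = "hann",
    element_positions: np.ndarray | None = None,
) -> BeamformedFrame:
    """Delay-and-sum beamform one transmit event onto a Cartesian grid.

    Pixel value = Σ_e w_e(p)·s_e(t_tx(p) + |p − r_e|/c) on the analytic
    (Hilbert) channel signals, with dynamic receive aperture of the given
    f-number and Hann (or uniform) apodization.  ``element_positions``
    overrides the stored array geometry for both the transmit-arrival
    model and the receive delays (curvature correction A/B testing).
    """
    if not (0 <= event_index < channel.n_events):
        raise ImagingError("event index out of range")
    if f_number <= 0:
        raise ImagingError("f-number must be positive")
    pos = (np.asarray(element_positions, dtype=float)
           if element_positions is not None else channel.array.element_positions)
    if pos.shape != (channel.n_elements, 3):
        raise ImagingError("element positions must be (n_elements, 3)")

    event = channel.sequence.events[event_index]
    c = channel.c
    rf = channel.samples[event_index]
    analytic = hilbert(rf, axis=-1)
    t_axis0, dt = channel.t0, 1.0 / channel.fs
    n_t = channel.n_samples
    t_end = t_axis0 + (n_t - 1) * dt

    X, Z = np.meshgrid(grid.x, grid.z)
    px, pz = X.ravel(), Z.ravel()
    P = px.size

    # first-arrival transmit time per pixel
    t_tx = np.full(P, np.inf)
    for e in range(channel.n_elements):
        d = np.sqrt((px - pos[e, 0]) ** 2 + pos[e, 1] ** 2 + (pz - pos[e, 2]) ** 2)
        np.minimum(t_tx, event.delays[e] + d / c, out=t_tx)

    out = np.zeros(P, dtype=complex)
    covered = np.zeros(P, dtype=bool)
    half_ap = np.maximum(pz / (2.0 * f_number), 1e-6)
    # sector imaging with a small phased aperture: centre the dynamic
    # aperture on the pixel's lateral position clamped to the array, so
    # pixels steered beyond the aperture edge still use edge elements
    x_lo, x_hi = pos[:, 0].min(), pos[:, 0].max()
    x_c = np.clip(px, x_lo, x_hi)
    sample_t = np.arange(n_t) * dt + t_axis0
    for e in range(channel.n_elements):
        u = (pos[e, 0] - x_c) / half_ap
        inside = np.abs(u) <= 1.0
        if not np.any(inside):
            continue
        if window == "hann":
            w = np.where(inside, 0.5 + 0.5 * np.cos(np.pi * np.clip(u, -1, 1)), 0.0)
        elif window == "uniform":
            w = inside.astype(float)
        else:
            raise ImagingError(f"unknown apodization window: {window!r}")
        d_rx = np.sqrt((px - pos[e, 0]) ** 2 + pos[e, 1] ** 2 + (pz - pos[e, 2]) ** 2)
        t = t_tx + d_rx / c
        ok = inside & (t >= t_axis0) & (t <= t_end)
        covered |= ok
        re = np.interp(t, sample_t, analytic.real[e], left=0.0, right=0.0)
        im = np.interp(t, sample_t, analytic.imag[e], left=0.0, right=0.0)
        out += np.where(ok, w * (re + 1j * im), 0.0)

    return BeamformedFrame(grid=grid, values=out.reshape(X.shape),
                           coverage=covered.reshape(X.shape), n_events=1)


def compound(frames: Sequence[BeamformedFrame], weights: Sequence[float] | None = None) -> BeamformedFrame:
    """Coherent (pre-envelope) weighted sum of beamformed frames."""
    if len(frames) == 0:
        raise ImagingError("nothing to compound")
    g0 = frames[0].grid
    if any(f.grid != g0 for f in frames):
        raise ImagingError("all frames must share the same grid")
    if weights is None:
        weights = np.ones(len(frames))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(frames),):
        raise ImagingError("one weight per frame required")
    acc = np.zeros_like(frames[0].values, dtype=complex)
    cov = np.zeros(acc.shape, dtype=bool)
    for w, f in zip(weights, frames):
        acc += w * f.values
        cov |= f.coverage
    return BeamformedFrame(grid=g0, values=acc, coverage=cov,
                           n_events=sum(f.n_events for f in frames))


def beamform_sequence(channel: ChannelData, grid: PixelGrid,
                      f_number: float = DEFAULT_F_NUMBER,
                      element_positions: np.ndarray | None = None) -> BeamformedFrame:
    """Beamform every event and coherently compound them (uniform weights)."""
    frames = [das_beamform(channel, grid, i, f_number=f_number,
                           element_positions=element_positions)
              for i in range(channel.n_events)]
    return compound(frames)


# ---------------------------------------------------------------------------
# envelope + compression

def envelope_logcompress(frame: BeamformedFrame, floor_db: float = DEFAULT_FLOOR_DB) -> BModeImage:
    """Envelope detection and log compression I_new = 20·log10(I_old).

    The envelope is normalized to its maximum before compression, so the
    image maximum is 0 dB; values are clipped at the display floor.
    """
    if floor_db >= 0:
        raise ImagingError("display floor must be negative dB")
    env = np.abs(frame.values)
    peak = env.max()
    if peak == 0:
        raise ImagingError("cannot normalize an all-zero frame")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    db = np.clip(db, floor_db, 0.0)
    return BModeImage(grid=frame.grid, intensity_db=db, floor_db=floor_db)


# ---------------------------------------------------------------------------
# sector scan conversion

def scan_convert(
    sector_db: np.ndarray,
    beam_angles_deg: np.ndarray,
    r0: float,
    dr: float,
    upsample: int = 5,
    floor_db: float = DEFAULT_FLOOR_DB,
) -> tuple[np.ndarray, PixelGrid, np.ndarray]:
    """Polar (beam × range) to Cartesian conversion with upsampling.

    Bilinear interpolation onto a Cartesian grid upsampled by the given
    factor (default 5) in both directions; pixels outside the sector are
    set to the floor and masked out.  Returns (image_db, grid, mask).
    """
    sec = np.asarray(sector_db, dtype=float)
    ang = np.radians(np.asarray(beam_angles_deg, dtype=float))
    if sec.ndim != 2 or sec.shape[0] != ang.size:
        raise ImagingError("sector data must be (n_beams, n_range)")
    if upsample < 1:
        raise ImagingError("upsample factor must be >= 1")
    n_beams, n_range = sec.shape
    r = r0 + dr * np.arange(n_range)

    if n_beams == 1:
        # degenerate sector: a single scanline maps to a straight column
        th = float(ang[0])
        z = r * np.cos(th)
        x_c = float(np.mean(r * np.sin(th)))
        grid = PixelGrid(imaging_depth=float(z[-1] - z[0]), imaging_width=max(dr, 1e-6),
                         n_vertical=n_range, n_lateral=2,
                         x_centre=x_c, z_start=float(z[0]))
        img = np.repeat(sec[0][:, None], 2, axis=1)
        return img, grid, np.ones_like(img, dtype=bool)

    dth = np.diff(ang)
    if np.any(dth <= 0):
        raise ImagingError("beam angles must be strictly increasing")
    if np.max(np.abs(dth - dth[0])) > 1e-9:
        raise ImagingError("beam angles must be uniformly spaced")

    xs = np.outer(r, np.sin(ang))
    zs = np.outer(r, np.cos(ang))
    x_lo, x_hi = xs.min(), xs.max()
    z_lo, z_hi = zs.min(), zs.max()
    n_l = max(2, upsample * n_beams)
    n_v = max(2, upsample * n_range)
    grid = PixelGrid(imaging_depth=float(z_hi - z_lo), imaging_width=float(x_hi - x_lo),
                     n_vertical=n_v, n_lateral=n_l,
                     x_centre=float(0.5 * (x_lo + x_hi)), z_start=float(z_lo))
    X, Z = np.meshgrid(grid.x, grid.z)
    rr = np.hypot(X, Z)
    th = np.arctan2(X, Z)
    i_th = (th - ang[0]) / dth[0]
    i_r = (rr - r0) / dr
    mask = (i_th >= 0) & (i_th <= n_beams - 1) & (i_r >= 0) & (i_r <= n_range - 1)
    img = map_coordinates(sec, [i_th.ravel(), i_r.ravel()], order=1,
                          mode="constant", cval=floor_db).reshape(X.shape)
    img = np.where(mask, img, floor_db)
    return img, grid, mask


# ---------------------------------------------------------------------------
# M-mode

def extract_mmode(frames: Sequence[BModeImage], x_position: float,
                  frame_times: Sequence[float]) -> MModeImage:
    """Stack the axial profile at the nearest grid column across frames."""
    if len(frames) < 2:
        raise ImagingError("M-mode extraction needs at least two frames")
    g0 = frames[0].grid
    if any(f.grid != g0 for f in frames):
        raise ImagingError("all frames must share the same grid")
    x = g0.x
    if x_position < x.min() - g0.dx / 2 or x_position > x.max() + g0.dx / 2:
        raise ImagingError("scanline position outside the image grid")
    col = int(np.argmin(np.abs(x - x_position)))
    data = np.column_stack([f.intensity_db[:, col] for f in frames])
    return MModeImage(z=g0.z, times=np.asarray(frame_times, dtype=float),
                      intensity_db=data, scanline_x=float(x[col]),
                      floor_db=frames[0].floor_db)
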