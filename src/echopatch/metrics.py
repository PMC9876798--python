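"""Image-quality characterization: FWHM resolutions, location accuracy,
dynamic range, CNR, SNR versus depth, penetration depth, fractional
bandwidth, insertion loss and the relative-resistance utility.

Conventions: PSF widths are measured on linear-scale (pre-dB) envelope
profiles with sub-sample half-maximum crossings by linear interpolation;
CNR is computed on linear intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import Phantom, rms
from .errors import MetricError
from .imaging import BModeImage


@dataclass
class QualityReport:
    """Tidy collection of metric rows (name, value, units, depth, offset)."""

    rows: list = field(default_factory=list)

    def add(self, name: str, value: float, units: str = "",
            depth_mm: float = np.nan, offset_mm: float = np.nan) -> None:
        self.rows.append({"name": name, "value": float(value), "units": units,
                          "depth_mm": depth_mm, "offset_mm": offset_mm})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["name", "value", "units", "depth_mm", "offset_mm"])


# ---------------------------------------------------------------------------
# FWHM

def fwhm(profile: np.ndarray, spacing: float) -> float:
    """Full width at half maximum of a sampled unimodal profile.

    The half-maximum crossings are located by linear interpolation
    between the straddling samples (ties broken toward the peak).
    Rejected when the peak sits on the boundary, when no half-maximum
    crossing exists on either side, or when equal global maxima occur at
    non-contiguous positions (ambiguous main lobe).
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise MetricError("profile must be 1-D with at least 3 samples")
    if spacing <= 0:
        raise MetricError("sample spacing must be positive")
    peak = y.max()
    if peak <= 0:
        raise MetricError("profile has no positive peak")
    at_max = np.flatnonzero(y >= peak * (1.0 - 1e-12))
    if np.any(np.diff(at_max) > 1):
        raise MetricError("multiple separated equal peaks; main lobe ambiguous")
    i_lo, i_hi = at_max[0], at_max[-1]
    if i_lo == 0 or i_hi == y.size - 1:
        raise MetricError("peak at the profile boundary")
    half = 0.5 * peak

    # walk outward from the peak plateau to the first crossing
    left = None
    for i in range(i_lo, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = (i - 1) + (half - y[i - 1]) / (y[i] - y[i - 1])
            break
    right = None
    for i in range(i_hi, y.size - 1):
        if y[i + 1] < half <= y[i]:
            right = i + (y[i] - half) / (y[i] - y[i + 1])
            break
    if left is None or right is None:
        raise MetricError("no half-maximum crossing on one side of the peak")
    return float((right - left) * spacing)


# ---------------------------------------------------------------------------
# PSF resolutions on wire images

def _peak_near(bmode: BModeImage, x0: float, z0: float, tol: float = 2e-3):
    """Index of the image maximum within ±tol of (x0, z0); None when the
    maximum rides the search-window boundary (wire not detected)."""
    x, z = bmode.grid.x, bmode.grid.z
    ix = np.flatnonzero(np.abs(x - x0) <= tol)
    iz = np.flatnonzero(np.abs(z - z0) <= tol)
    if ix.size == 0 or iz.size == 0:
        return None
    sub = bmode.linear[np.ix_(iz, ix)]
    r, c = np.unravel_index(np.argmax(sub), sub.shape)
    on_edge = ((r == 0 and iz[0] > 0) or (r == sub.shape[0] - 1 and iz[-1] < z.size - 1)
               or (c == 0 and ix[0] > 0) or (c == sub.shape[1] - 1 and ix[-1] < x.size - 1))
    if on_edge:
        return None
    return iz[r], ix[c]


def _beam_profile(bmode: BModeImage, peak_rc, direction, spacing: float) -> np.ndarray:
    """Linear-envelope profile through a peak along a unit direction
    (x, z), sampled by bilinear interpolation; outside the grid → 0."""
    from scipy.ndimage import map_coordinates
    grid = bmode.grid
    r, c = peak_rc
    x0, z0 = grid.x[c], grid.z[r]
    half_x = grid.imaging_width / 2.0
    half_z = grid.imaging_depth / 2.0
    extent = np.hypot(half_x, half_z)
    k = np.arange(-int(extent / spacing), int(extent / spacing) + 1)
    xs = x0 + k * spacing * direction[0]
    zs = z0 + k * spacing * direction[1]
    i_r = (zs - grid.z[0]) / grid.dy
    i_c = (xs - grid.x[0]) / grid.dx
    return map_coordinates(bmode.linear, [i_r, i_c], order=1,
                           mode="constant", cval=0.0)


def resolution_set(bmode: BModeImage, truth: Phantom, search_tol: float = 2e-3) -> pd.DataFrame:
    """Axial and lateral FWHM of the linear-scale PSF for each wire.

    Per wire the image peak within ±2 mm of the true position is found
    and the FWHM measured along the beam (range) direction and across it
    (cross-range).  For an on-axis wire these coincide with the vertical
    and horizontal image cuts; off-axis they follow the steered beam, so
    the widths are true axial/lateral resolutions rather than cuts
    through a rotated PSF.  Undetected wires are flagged with NaN widths.
    """
    grid = bmode.grid
    spacing = min(grid.dx, grid.dy)
    rows = []
    for (x0, _, z0) in truth.positions:
        entry = {"wire_x_mm": x0 * 1e3, "wire_z_mm": z0 * 1e3,
                 "axial_fwhm_mm": np.nan, "lateral_fwhm_mm": np.nan,
                 "detected": False}
        hit = _peak_near(bmode, x0, z0, search_tol)
        if hit is not None:
            rng = np.hypot(x0, z0)
            u_ax = (x0 / rng, z0 / rng)          # range (beam) direction
            u_lat = (u_ax[1], -u_ax[0])          # cross-range
            try:
                entry["axial_fwhm_mm"] = fwhm(_beam_profile(bmode, hit, u_ax, spacing),
                                              spacing) * 1e3
                entry["lateral_fwhm_mm"] = fwhm(_beam_profile(bmode, hit, u_lat, spacing),
                                                spacing) * 1e3
                entry["detected"] = True
            except MetricError:
                pass
        rows.append(entry)
    return pd.DataFrame(rows)


def elevational_profile(peak_amplitudes: np.ndarray, y_offsets: np.ndarray) -> float:
    """Elevational FWHM from peak image amplitude versus scatterer
    elevational offset (the y-sweep replacement for rotating the probe)."""
    y = np.asarray(y_offsets, dtype=float)
    if np.any(np.diff(y) <= 0):
        raise MetricError("y offsets must be strictly increasing")
    dy = np.diff(y)
    if np.max(np.abs(dy - dy[0])) > 1e-12:
        raise MetricError("y offsets must be uniformly spaced")
    return fwhm(np.asarray(peak_amplitudes, dtype=float), float(dy[0]))


# ---------------------------------------------------------------------------
# scalar metrics

def location_accuracy(computed_distance: float, ground_truth: float) -> float:
    """Accuracy = 1 − |computed/truth − 1|."""
    if ground_truth <= 0:
        raise MetricError("ground-truth distance must be positive")
    return 1.0 - abs(computed_distance / ground_truth - 1.0)


def dynamic_range(contrasts_db, mean_grey) -> tuple[float, tuple[float, float]]:
    """Dynamic range from a linear fit of mean grey value vs contrast.

    Fits grey = m·contrast + b by least squares and extrapolates to grey
    0 and 255; the dynamic range is the contrast span between the two,
    which equals 255/m.  Returns (span_db, (contrast_at_0, contrast_at_255)).
    """
    c = np.asarray(contrasts_db, dtype=float)
    g = np.asarray(mean_grey, dtype=float)
    if c.size != g.size or c.size < 2:
        raise MetricError("need >= 2 (contrast, grey) points")
    m, b = np.polyfit(c, g, 1)
    if m <= 0 or not np.isfinite(m):
        raise MetricError("grey value must increase with contrast")
    c_at_0 = (0.0 - b) / m
    c_at_255 = (255.0 - b) / m
    return float(c_at_255 - c_at_0), (float(c_at_0), float(c_at_255))


def cnr(image: np.ndarray, roi_in: np.ndarray, roi_out: np.ndarray) -> float:
    """Contrast-to-noise ratio |μ_in − μ_out|/sqrt(σ_in² + σ_out²) on
    linear-intensity pixels, with the ROIs given as boolean masks."""
    img = np.asarray(image, dtype=float)
    m_in = np.asarray(roi_in, dtype=bool)
    m_out = np.asarray(roi_out, dtype=bool)
    if not m_in.any() or not m_out.any():
        raise MetricError("both ROIs must be non-empty")
    if np.any(m_in & m_out):
        raise MetricError("ROIs must be disjoint")
    a, b = img[m_in], img[m_out]
    denom = np.sqrt(a.var() + b.var())
    if denom == 0:
        raise MetricError("zero joint variance; CNR undefined")
    return float(abs(a.mean() - b.mean()) / denom)


def grey_level(bmode: BModeImage) -> np.ndarray:
    """Linear dB→[0, 255] display mapping over [floor, 0] (uint8 scale)."""
    return 255.0 * (bmode.intensity_db - bmode.floor_db) / (0.0 - bmode.floor_db)


def snr_depth(bmode: BModeImage, signal_points, noise_roi: np.ndarray,
              search_tol: float = 2e-3) -> pd.DataFrame:
    """SNR = 20·log10(peak linear amplitude / RMS of the noise ROI) for
    each (x, z) signal point."""
    mask = np.asarray(noise_roi, dtype=bool)
    if not mask.any():
        raise MetricError("noise ROI is empty")
    noise = rms(bmode.linear[mask])
    if noise == 0:
        raise MetricError("noise ROI has zero RMS")
    rows = []
    for (x0, z0) in signal_points:
        hit = _peak_near(bmode, x0, z0, search_tol)
        if hit is None:
            rows.append({"x_mm": x0 * 1e3, "depth_mm": z0 * 1e3, "snr_db": np.nan})
            continue
        peak = bmode.linear[hit]
        rows.append({"x_mm": x0 * 1e3, "depth_mm": z0 * 1e3,
                     "snr_db": 20.0 * np.log10(peak / noise)})
    return pd.DataFrame(rows)


def penetration_depth(bmode: BModeImage, wire_positions, margin_db: float = 6.0,
                      search_tol: float = 2e-3, exclusion: float = 4e-3) -> float:
    """Depth of the deepest wire whose image peak exceeds the local
    background by at least ``margin_db`` (the 6-dB differentiability
    rule).  Returns 0.0 when no wire qualifies."""
    wires = sorted(wire_positions, key=lambda w: w[1])
    x, z = bmode.grid.x, bmode.grid.z
    deepest = 0.0
    for (x0, z0) in wires:
        hit = _peak_near(bmode, x0, z0, search_tol)
        if hit is None:
            continue
        peak_db = bmode.intensity_db[hit]
        iz = np.flatnonzero(np.abs(z - z0) <= search_tol)
        bg_cols = np.ones(x.size, dtype=bool)
        for (xw, _) in wires:
            bg_cols &= np.abs(x - xw) > exclusion
        if not bg_cols.any():
            raise MetricError("no background columns left outside the wires")
        background_db = float(np.mean(bmode.intensity_db[np.ix_(iz, np.flatnonzero(bg_cols))]))
        if peak_db >= background_db + margin_db:
            deepest = max(deepest, float(z0))
    return deepest


def fractional_bandwidth(waveform: np.ndarray, fs: float) -> float:
    """−6 dB fractional bandwidth of an echo waveform.

    The magnitude spectrum's full width at half maximum is divided by
    the centre frequency, taken as the midpoint of the two half-maximum
    crossings.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise MetricError("waveform must be 1-D with at least 8 samples")
    n_fft = max(4096, 4 * x.size)
    spec = np.abs(np.fft.rfft(x, n_fft))
    f = np.fft.rfftfreq(n_fft, 1.0 / fs)
    peak = spec.max()
    if peak == 0:
        raise MetricError("empty spectrum")
    i_pk = int(np.argmax(spec))
    half = 0.5 * peak
    lo = None
    for i in range(i_pk, 0, -1):
        if spec[i - 1] < half <= spec[i]:
            lo = f[i - 1] + (half - spec[i - 1]) / (spec[i] - spec[i - 1]) * (f[i] - f[i - 1])
            break
    hi = None
    for i in range(i_pk, spec.size - 1):
        if spec[i + 1] < half <= spec[i]:
            hi = f[i] + (spec[i] - half) / (spec[i] - spec[i + 1]) * (f[i + 1] - f[i])
            break
    if lo is None or hi is None:
        raise MetricError("no half-maximum crossings in the spectrum")
    centre = 0.5 * (lo + hi)
    if centre <= 0:
        raise MetricError("degenerate spectral centre")
    return float((hi - lo) / centre)


def insertion_loss(vr: float, vt: float, d_mm: float, fr_mhz: float) -> float:
    """Insertion loss |20·log10(Vr/Vt) + 1.9 + 2.2e−4 · 2d · fr²| in dB.

    The 1.9 dB term is the transmission loss into the quartz-crystal
    reflector and 2.2e−4 dB/(mm·MHz²) the water attenuation over the
    round trip 2d; d in mm, fr in MHz.
    """
    if vr <= 0 or vt <= 0:
        raise MetricError("voltages must be positive")
    return float(abs(20.0 * np.log10(vr / vt) + 1.9 + 2.2e-4 * 2.0 * d_mm * fr_mhz**2))


def relative_resistance(r: float, r0: float) -> float:
    """Relative resistance R/R0 (stretchable-electrode characterization)."""
    if r0 <= 0:
        raise MetricError("reference resistance must be positive")
    return r / r0
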