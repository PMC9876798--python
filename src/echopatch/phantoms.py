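"""Seeded test-object generators: wire grids, speckle phantoms with
cylindrical contrast inclusions, and a beating-left-ventricle generator
producing segmentation-mask stacks with exact ground-truth volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .acoustics import Phantom
from .errors import SimulationError, CardiacError

# Default contrast set for the six-object greyscale phantom; the extremes
# and the lowest pair are the documented ones, the middle pair is chosen
# symmetric.
DEFAULT_CONTRASTS_DB = (-15.0, -6.0, -3.0, 3.0, 6.0, 15.0)

#: Nominal resolution-cell area (axial 0.5 mm × lateral 1.0 mm) used to
#: convert "scatterers per resolution cell" into a scatterer count.
DEFAULT_CELL_AREA = 0.5e-3 * 1.0e-3


# ---------------------------------------------------------------------------
# wires

@dataclass(frozen=True)
class WireLayout:
    """Point-wire positions in the imaging (y = 0) plane."""

    positions: np.ndarray          # (n, 2): x, z in metres
    reflectivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if p.size == 0:
            p = p.reshape(0, 2)
        if p.shape[1] != 2:
            raise SimulationError("wire positions must be (n, 2) = (x, z)")
        if p.shape[0] and np.any(p[:, 1] <= 0):
            raise SimulationError("wires must lie at positive depth")
        if p.shape[0] != len(np.unique(p, axis=0)):
            raise SimulationError("wire positions must be unique")
        r = self.reflectivity
        r = np.ones(p.shape[0]) if r is None else np.atleast_1d(np.asarray(r, float))
        if r.shape[0] != p.shape[0]:
            raise SimulationError("one reflectivity per wire required")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "reflectivity", r)


#: Nine laterally distributed wires at 0, ±1, ±2, ±3, ±4 cm from the
#: centre, all at 50 mm depth (the lateral characterization row).
LATERAL_ROW_X = np.array([-40, -30, -20, -10, 0, 10, 20, 30, 40]) * 1e-3
LATERAL_ROW_DEPTH = 50e-3


def wire_layout_preset(name: str) -> WireLayout:
    """Named wire layouts: 'lateral-row' (nine wires at ±4…0 cm, 50 mm
    deep) and 'axial-stack' (on-axis wires every 10 mm from 10–140 mm)."""
    if name == "lateral-row":
        pos = np.column_stack([LATERAL_ROW_X, np.full(9, LATERAL_ROW_DEPTH)])
    elif name == "axial-stack":
        z = np.arange(10, 141, 10) * 1e-3
        pos = np.column_stack([np.zeros_like(z), z])
    else:
        raise SimulationError(f"unknown wire layout preset: {name!r}")
    return WireLayout(positions=pos)


def wire_phantom(layout: WireLayout | str) -> Phantom:
    """One unit-reflectivity point scatterer per wire (wires are far below
    the resolution limit and modelled as ideal points)."""
    if isinstance(layout, str):
        layout = wire_layout_preset(layout)
    n = layout.positions.shape[0]
    pos3 = np.column_stack([layout.positions[:, 0], np.zeros(n), layout.positions[:, 1]])
    return Phantom(positions=pos3, reflectivity=layout.reflectivity)


# ---------------------------------------------------------------------------
# contrast inclusions

@dataclass(frozen=True)
class InclusionSpec:
    """Cylindrical inclusion: centre (x, z) m, radius m, contrast in dB
    relative to the speckle background."""

    centre: tuple[float, float]
    radius: float
    contrast_db: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SimulationError("inclusion radius must be positive")


def inclusion_phantom(
    specs: Sequence[InclusionSpec],
    x_range: tuple[float, float],
    z_range: tuple[float, float],
    density: float = 20.0,
    seed: int = 0,
    cell_area: float = DEFAULT_CELL_AREA,
) -> Phantom:
    """Speckle phantom with cylindrical contrast inclusions.

    Scatterer positions are uniform over the field (seeded); amplitudes
    are zero-mean Gaussian draws scaled by 10^(contrast/20) inside each
    inclusion.  ``density`` is scatterers per resolution cell; >= 10
    gives fully developed speckle.
    """
    if density <= 0:
        raise SimulationError("density must be positive")
    x0, x1 = x_range
    z0, z1 = z_range
    if x1 <= x0 or z1 <= z0 or z0 <= 0:
        raise SimulationError("invalid field extent")
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = math.hypot(a.centre[0] - b.centre[0], a.centre[1] - b.centre[1])
            if d < a.radius + b.radius:
                raise SimulationError("inclusions must not overlap")

    area = (x1 - x0) * (z1 - z0)
    n = max(1, int(round(density * area / cell_area)))
    rng = np.random.default_rng(seed)
    x = rng.uniform(x0, x1, n)
    z = rng.uniform(z0, z1, n)
    amp = rng.normal(0.0, 1.0, n)
    scale = np.ones(n)
    for spec in specs:
        inside = (x - spec.centre[0]) ** 2 + (z - spec.centre[1]) ** 2 <= spec.radius ** 2
        scale[inside] = 10.0 ** (spec.contrast_db / 20.0)
    regions = tuple(("inclusion", {"centre": s.centre, "radius": s.radius,
                                   "contrast_db": s.contrast_db}) for s in specs)
    return Phantom(positions=np.column_stack([x, np.zeros(n), z]),
                   reflectivity=amp * scale, regions=regions, seed=seed)


# ---------------------------------------------------------------------------
# beating left ventricle

@dataclass(frozen=True)
class BeatingLVSpec:
    """Prolate-spheroid left ventricle beating between EDV and ESV.

    The long-to-short axis ratio is fixed (default 2, a typical healthy
    LV shape), so the cavity's apical-long-axis section is an ellipse
    whose spheroid volume follows a smooth periodic waveform with a
    systolic contraction phase, rapid filling, diastasis and an atrial
    kick.  Only EDV, ESV and heart rate are treated as recoverable truth.
    """

    edv_ml: float = 120.0
    esv_ml: float = 50.0
    heart_rate_bpm: float = 75.0
    frame_rate_hz: float = 30.0
    n_cycles: float = 4.0
    axis_ratio: float = 2.0
    pixel_size_m: float = 0.25e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.esv_ml < self.edv_ml):
            raise CardiacError("require 0 < ESV < EDV")
        if self.heart_rate_bpm <= 0 or self.n_cycles <= 0:
            raise CardiacError("heart rate and cycle count must be positive")
        if self.frame_rate_hz < 2.0 * self.heart_rate_bpm / 60.0:
            raise CardiacError("frame rate below twice the heart rate (temporal aliasing)")
        if self.axis_ratio <= 1.0:
            raise CardiacError("long axis must exceed the short axis")


def _cycle_shape(phase: np.ndarray) -> np.ndarray:
    """Normalized volume over one cycle: 1 at end diastole, 0 at end
    systole, with plateaus at both extremes, rapid filling, diastasis and
    an atrial kick.  Piecewise-cosine, C0-smooth."""
    p = np.mod(phase, 1.0)
    s = np.empty_like(p)

    def ramp(t, lo, hi, a, b):
        u = (t - lo) / (hi - lo)
        return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * u))

    seg = p < 0.05
    s[seg] = 1.0                                       # end-diastolic plateau
    seg = (p >= 0.05) & (p < 0.30)
    s[seg] = ramp(p[seg], 0.05, 0.30, 1.0, 0.0)        # systolic contraction
    seg = (p >= 0.30) & (p < 0.40)
    s[seg] = 0.0                                       # end-systolic plateau
    seg = (p >= 0.40) & (p < 0.70)
    s[seg] = ramp(p[seg], 0.40, 0.70, 0.0, 0.85)       # rapid filling
    seg = (p >= 0.70) & (p < 0.85)
    s[seg] = 0.85                                      # diastasis
    seg = (p >= 0.85) & (p < 0.95)
    s[seg] = ramp(p[seg], 0.85, 0.95, 0.85, 1.0)       # atrial kick
    s[p >= 0.95] = 1.0
    return s


@dataclass(frozen=True)
class LVSequence:
    """Output of the beating-LV generator."""

    masks: np.ndarray              # (n_frames, rows, cols) uint8
    truth_volume_ml: np.ndarray    # exact spheroid volume per frame
    times: np.ndarray              # frame times (s)
    pixel_size_m: float
    spec: BeatingLVSpec

    @property
    def frame_dt(self) -> float:
        return float(np.mean(np.diff(self.times)))


def beating_lv(spec: BeatingLVSpec) -> LVSequence:
    """Render the beating-LV mask stack and its exact volume waveform.

    Masks are 1 inside the cavity section, 0 outside; the long axis runs
    along image rows.  Identical specs (same seed) give identical stacks.
    """
    period = 60.0 / spec.heart_rate_bpm
    n_frames = int(round(spec.n_cycles * period * spec.frame_rate_hz))
    t = np.arange(n_frames) / spec.frame_rate_hz
    phase = t / period
    vol_ml = spec.esv_ml + (spec.edv_ml - spec.esv_ml) * _cycle_shape(phase)

    k = spec.axis_ratio
    vol_m3 = vol_ml * 1e-6
    b = np.cbrt(3.0 * vol_m3 / (4.0 * math.pi * k))    # short semi-axis (m)
    a = k * b                                          # long semi-axis (m)

    px = spec.pixel_size_m
    a_max, b_max = a.max(), b.max()
    rows = int(np.ceil(2 * (a_max + 2e-3) / px))
    cols = int(np.ceil(2 * (b_max + 2e-3) / px))
    r = (np.arange(rows) - (rows - 1) / 2.0) * px
    cgrid = (np.arange(cols) - (cols - 1) / 2.0) * px

    masks = np.empty((n_frames, rows, cols), dtype=np.uint8)
    R2 = r[:, None] ** 2
    C2 = cgrid[None, :] ** 2
    for i in range(n_frames):
        masks[i] = (R2 / a[i] ** 2 + C2 / b[i] ** 2 <= 1.0).astype(np.uint8)
    return LVSequence(masks=masks, truth_volume_ml=vol_ml, times=t,
                      pixel_size_m=px, spec=spec)
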