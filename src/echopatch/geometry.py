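"""Transducer-array geometry: flat linear arrays, orthogonal (Mills-cross)
configurations, and mapping of nominal element positions onto a measured
body-surface profile.

Coordinate convention (used everywhere in the package): x lateral,
y elevational, z axial positive into tissue, origin at the aperture
centroid.  SI units internally (metres, seconds, Hz); mm only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import GeometryError

#: Default speed of sound in soft tissue (m/s).
SOUND_SPEED = 1540.0

# Default transducer parameters of the wearable imager: 3 MHz centre
# frequency, 32 elements, 0.4 mm pitch, 0.3 mm element width, 2.3 mm
# element length, 55% fractional bandwidth (-6 dB).
DEFAULT_FC = 3.0e6
DEFAULT_N_ELEMENTS = 32
DEFAULT_PITCH = 0.4e-3
DEFAULT_WIDTH = 0.3e-3
DEFAULT_LENGTH = 2.3e-3
DEFAULT_BANDWIDTH = 0.55


@dataclass(frozen=True)
class ArrayGeometry:
    """A (possibly curved) 1-D transducer array.

    Attributes
    ----------
    n_elements : int
        Number of elements.
    pitch : float
        Centre-to-centre element spacing measured along the aperture
        surface (arc length for curved arrays), in metres.
    element_width : float
        Element size in the lateral direction (m).
    element_length : float
        Element size in the elevational direction (m).
    centre_frequency : float
        Nominal centre frequency (Hz).
    fractional_bandwidth : float
        −6 dB fractional bandwidth (dimensionless).
    element_positions : (n, 3) ndarray
        Element centres in metres, ordered along the aperture.
    element_normals : (n, 3) ndarray
        Unit normals pointing into tissue (+z for a flat array).
    """

    n_elements: int
    pitch: float
    element_width: float
    element_length: float
    centre_frequency: float
    fractional_bandwidth: float
    element_positions: np.ndarray = field(repr=False)
    element_normals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise GeometryError("n_elements must be >= 1")
        if not (self.pitch > self.element_width > 0):
            raise GeometryError("require pitch > element_width > 0")
        if self.element_length <= 0:
            raise GeometryError("element_length must be positive")
        if self.centre_frequency <= 0:
            raise GeometryError("centre_frequency must be positive")
        pos = np.asarray(self.element_positions, dtype=float)
        nrm = np.asarray(self.element_normals, dtype=float)
        if pos.shape != (self.n_elements, 3) or nrm.shape != (self.n_elements, 3):
            raise GeometryError("positions/normals must have shape (n_elements, 3)")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("element positions must be finite")
        norms = np.linalg.norm(nrm, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise GeometryError("element normals must be unit vectors")
        object.__setattr__(self, "element_positions", pos)
        object.__setattr__(self, "element_normals", nrm)

    @property
    def aperture_width(self) -> float:
        """Aperture extent along the array, (n−1)·pitch in metres."""
        return (self.n_elements - 1) * self.pitch

    @property
    def is_flat(self) -> bool:
        """True when all elements lie in the z = 0 plane on a regular pitch."""
        pos = self.element_positions
        if np.any(np.abs(pos[:, 2]) > 1e-12):
            return False
        if self.n_elements > 1:
            dx = np.diff(pos[:, 0])
            if np.any(np.abs(dx - self.pitch) > 1e-12):
                return False
        return True

    @property
    def wavelength(self) -> float:
        return SOUND_SPEED / self.centre_frequency

    def with_positions(self, positions: np.ndarray, normals: np.ndarray) -> "ArrayGeometry":
        return replace(self, element_positions=np.asarray(positions, float),
                       element_normals=np.asarray(normals, float))


@dataclass(frozen=True)
class OrthogonalArray:
    """Two linear apertures sharing a centre, rotated 90° about z
    (a Mills-cross layout giving two perpendicular imaging planes)."""

    axis_a: ArrayGeometry
    axis_b: ArrayGeometry

    def __post_init__(self) -> None:
        da = _axis_direction(self.axis_a)
        db = _axis_direction(self.axis_b)
        if abs(float(np.dot(da, db))) > 1e-9:
            raise GeometryError("aperture axes must be orthogonal")

    @property
    def n_elements_total(self) -> int:
        return self.axis_a.n_elements + self.axis_b.n_elements


def _axis_direction(array: ArrayGeometry) -> np.ndarray:
    """Unit vector along the aperture (first → last element)."""
    if array.n_elements == 1:
        return np.array([1.0, 0.0, 0.0])
    d = array.element_positions[-1] - array.element_positions[0]
    return d / np.linalg.norm(d)


@dataclass(frozen=True)
class SurfaceProfile:
    """Out-of-plane shape of the skin surface the array conforms to.

    kind 'flat' — identity; 'cylinder' — convex cylinder of given radius
    (elements wrap toward the tissue); 'sampled' — measured
    (arc-length, displacement) pairs, displacement positive into tissue;
    'explicit' — measured per-element 3-vector positions.
    """

    kind: Literal["flat", "cylinder", "sampled", "explicit"]
    radius: float | None = None
    samples: np.ndarray | None = None  # (m, 2) s/h pairs or (n, 3) positions

    def __post_init__(self) -> None:
        if self.kind == "cylinder":
            if self.radius is None or self.radius <= 0:
                raise GeometryError("cylinder profile requires a positive radius")
        elif self.kind == "sampled":
            s = np.asarray(self.samples, dtype=float)
            if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
                raise GeometryError("sampled profile needs (m, 2) samples, m >= 2")
            if np.any(np.diff(s[:, 0]) <= 0):
                raise GeometryError("arc length must be strictly increasing")
            object.__setattr__(self, "samples", s)
        elif self.kind == "explicit":
            p = np.asarray(self.samples, dtype=float)
            if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
                raise GeometryError("explicit profile needs (n, 3) element positions")
            object.__setattr__(self, "samples", p)

    @classmethod
    def flat(cls) -> "SurfaceProfile":
        return cls(kind="flat")

    @classmethod
    def cylinder(cls, radius: float) -> "SurfaceProfile":
        return cls(kind="cylinder", radius=radius)

    @classmethod
    def sampled(cls, s: Sequence[float], h: Sequence[float]) -> "SurfaceProfile":
        return cls(kind="sampled", samples=np.column_stack([s, h]))

    @classmethod
    def explicit(cls, positions: np.ndarray) -> "SurfaceProfile":
        return cls(kind="explicit", samples=np.asarray(positions, dtype=float))


def make_linear_array(
    n: int = DEFAULT_N_ELEMENTS,
    pitch: float = DEFAULT_PITCH,
    width: float = DEFAULT_WIDTH,
    length: float = DEFAULT_LENGTH,
    fc: float = DEFAULT_FC,
    bw: float = DEFAULT_BANDWIDTH,
) -> ArrayGeometry:
    """Build a flat linear array centred on the x-axis.

    Element i sits at x_i = (i − (n−1)/2)·pitch, giving an aperture width
    of (n−1)·pitch.  Defaults are the wearable imager's parameters.
    """
    if n < 1:
        raise GeometryError("n must be >= 1")
    if not (pitch > width > 0) or length <= 0 or fc <= 0:
        raise GeometryError("non-positive or inconsistent array dimensions")
    idx = np.arange(n, dtype=float)
    x = (idx - (n - 1) / 2.0) * pitch
    positions = np.column_stack([x, np.zeros(n), np.zeros(n)])
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return ArrayGeometry(
        n_elements=n, pitch=pitch, element_width=width, element_length=length,
        centre_frequency=fc, fractional_bandwidth=bw,
        element_positions=positions, element_normals=normals,
    )


def pitch_in_wavelengths(pitch: float, fc: float, c: float = SOUND_SPEED) -> float:
    """Element pitch expressed in ultrasonic wavelengths, pitch·fc/c."""
    if pitch <= 0 or fc <= 0 or c <= 0:
        raise GeometryError("pitch, fc and c must all be positive")
    return pitch * fc / c


def make_orthogonal_array(base: ArrayGeometry) -> OrthogonalArray:
    """Pair a flat array with its 90°-about-z rotated copy (shared centre)."""
    if not base.is_flat:
        raise GeometryError("orthogonal configuration requires a flat base array")
    pos = base.element_positions
    rot = np.column_stack([-pos[:, 1], pos[:, 0], pos[:, 2]])
    nrm = base.element_normals
    rot_n = np.column_stack([-nrm[:, 1], nrm[:, 0], nrm[:, 2]])
    axis_b = base.with_positions(rot, rot_n)
    return OrthogonalArray(axis_a=base, axis_b=axis_b)


def apply_surface(array: ArrayGeometry, profile: SurfaceProfile) -> ArrayGeometry:
    """Map nominal element positions onto a surface profile.

    Elements keep their arc-length spacing (= pitch) along the surface;
    normals follow the local surface normal; the aperture centroid is
    re-centred at the origin.  A flat profile returns the input unchanged.
    """
    if profile.kind == "flat":
        return array

    n = array.n_elements
    s_el = (np.arange(n, dtype=float) - (n - 1) / 2.0) * array.pitch

    if profile.kind == "explicit":
        positions = np.asarray(profile.samples, dtype=float)
        if positions.shape[0] != n:
            raise GeometryError("explicit profile must list one position per element")
        # normals from the local tangent in the xz plane
        t = np.gradient(positions, axis=0)
        t_norm = np.hypot(t[:, 0], t[:, 2])
        normals = np.column_stack([-t[:, 2] / t_norm, np.zeros(n), t[:, 0] / t_norm])
        positions = positions - positions.mean(axis=0, keepdims=True)
        return array.with_positions(positions, normals)

    if profile.kind == "cylinder":
        R = float(profile.radius)
        if R <= array.aperture_width / 2.0:
            raise GeometryError("cylinder radius must exceed the aperture half-width")
        phi = s_el / R
        x = R * np.sin(phi)
        z = R * (1.0 - np.cos(phi))  # convex chest: edges wrap toward tissue
        positions = np.column_stack([x, np.zeros(n), z])
        # normal into tissue = toward the cylinder axis at (0, ., R)
        normals = np.column_stack([-np.sin(phi), np.zeros(n), np.cos(phi)])
    else:  # sampled
        s_raw, h_raw = profile.samples[:, 0], profile.samples[:, 1]
        half = array.aperture_width / 2.0
        if s_raw[0] > -half or s_raw[-1] < half:
            raise GeometryError("surface profile does not span the aperture arc length")
        h_of_s = PchipInterpolator(s_raw, h_raw)
        # integrate dx = sqrt(ds^2 - dz^2) on a fine arc-length grid
        s_fine = np.linspace(s_raw[0], s_raw[-1], max(2001, 20 * len(s_raw)))
        z_fine = h_of_s(s_fine)
        ds = np.diff(s_fine)
        dz = np.diff(z_fine)
        dx2 = ds**2 - dz**2
        if np.any(dx2 < -1e-18):
            raise GeometryError("profile slope exceeds 45°-per-arc-length; not a valid arc-length parameterization")
        dx = np.sqrt(np.clip(dx2, 0.0, None))
        x_fine = np.concatenate([[0.0], np.cumsum(dx)])
        x_fine -= np.interp(0.0, s_fine, x_fine)  # x(0) = 0
        x = np.interp(s_el, s_fine, x_fine)
        z = h_of_s(s_el)
        positions = np.column_stack([x, np.zeros(n), z])
        # tangent from the fine curve, normal = tangent rotated +90° in xz
        tx = np.gradient(x_fine, s_fine)
        tz = np.gradient(z_fine, s_fine)
        txi = np.interp(s_el, s_fine, tx)
        tzi = np.interp(s_el, s_fine, tz)
        t_norm = np.hypot(txi, tzi)
        normals = np.column_stack([-tzi / t_norm, np.zeros(n), txi / t_norm])

    positions = positions - positions.mean(axis=0, keepdims=True)
    return array.with_positions(positions, normals)
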