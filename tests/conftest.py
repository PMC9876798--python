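"""Shared fixtures: simulated channel data and images reused across the
suite.  All randomness is explicitly seeded; the heavier simulations are
session-scoped so each runs once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import echopatch as ep

settings.register_profile("echopatch", deadline=None, derandomize=True)
settings.load_profile("echopatch")

SEED = 11
NOISE_RMS = 2e-5          # per-channel additive noise, ~35-40 dB below a wire echo
AXIAL_DEPTHS = np.arange(30, 101, 10) * 1e-3


@pytest.fixture(scope="session")
def array():
    return ep.make_linear_array()


@pytest.fixture(scope="session")
def axial_wire_phantom():
    return ep.Phantom(positions=[[0.0, 0.0, z] for z in AXIAL_DEPTHS],
                      reflectivity=np.ones(len(AXIAL_DEPTHS)))


@pytest.fixture(scope="session")
def compound_axial_channel(array, axial_wire_phantom):
    """97-angle wide-beam compounding data for the on-axis wire stack."""
    seq = ep.make_compounding_sequence(array)
    return ep.simulate_channel_data(axial_wire_phantom, array, seq,
                                    noise_rms=NOISE_RMS, seed=SEED)


@pytest.fixture(scope="session")
def plane_axial_channel(array, axial_wire_phantom):
    """Single 0° plane-wave data for the same phantom and noise seed."""
    seq = ep.make_plane_sequence(array, [0.0])
    return ep.simulate_channel_data(axial_wire_phantom, array, seq,
                                    noise_rms=NOISE_RMS, seed=SEED)


def wire_patch_bmode(channel, x0, z0, *, width=10e-3, depth=5e-3,
                     n_v=101, n_l=101):
    """Beamform + compound + log-compress a patch around one wire."""
    grid = ep.PixelGrid(imaging_depth=depth, imaging_width=width,
                        n_vertical=n_v, n_lateral=n_l,
                        x_centre=x0, z_start=z0 - depth / 2)
    frame = ep.beamform_sequence(channel, grid)
    return ep.envelope_logcompress(frame)


def wire_resolution(channel, x0, z0, **kw):
    bmode = wire_patch_bmode(channel, x0, z0, **kw)
    truth = ep.Phantom(positions=[[x0, 0.0, z0]], reflectivity=[1.0])
    return ep.resolution_set(bmode, truth).iloc[0]


@pytest.fixture(scope="session")
def axial_psf_table(compound_axial_channel):
    """Axial/lateral FWHM vs depth for the 97-angle compound."""
    rows = [wire_resolution(compound_axial_channel, 0.0, z) for z in AXIAL_DEPTHS]
    import pandas as pd
    return pd.DataFrame([dict(r) for r in rows])


@pytest.fixture(scope="session")
def lateral_row_channel(array):
    """97-angle compounding data for the nine-wire 50 mm lateral row."""
    ph = ep.wire_phantom("lateral-row")
    seq = ep.make_compounding_sequence(array)
    return ep.simulate_channel_data(ph, array, seq, seed=SEED)


@pytest.fixture(scope="session")
def lateral_row_results(lateral_row_channel):
    """Per-wire (x_mm, lateral FWHM mm, axial FWHM mm, peak x m)."""
    from echopatch.phantoms import LATERAL_ROW_X, LATERAL_ROW_DEPTH
    out = []
    for x0 in LATERAL_ROW_X:
        bmode = wire_patch_bmode(lateral_row_channel, x0, LATERAL_ROW_DEPTH,
                                 width=16e-3, depth=8e-3, n_v=121, n_l=129)
        truth = ep.Phantom(positions=[[x0, 0.0, LATERAL_ROW_DEPTH]], reflectivity=[1.0])
        res = ep.resolution_set(bmode, truth).iloc[0]
        lin = bmode.linear
        i = np.unravel_index(np.argmax(lin), lin.shape)
        out.append({"x_mm": x0 * 1e3, "lateral_fwhm_mm": res.lateral_fwhm_mm,
                    "axial_fwhm_mm": res.axial_fwhm_mm,
                    "detected": res.detected,
                    "peak_x_m": bmode.grid.x[i[1]], "peak_z_m": bmode.grid.z[i[0]]})
    import pandas as pd
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def cnr_by_contrast(array):
    """CNR per contrast on mirrored-ROI speckle simulations.

    One inclusion per simulation, identical background speckle
    realization (same seed), inside ROI on the inclusion and background
    ROI at its mirror position so both see identical imaging gain.
    """
    seq = ep.make_compounding_sequence(array, n_angles=21)
    centre = (-4.5e-3, 30e-3)
    values = {}
    for cdb in (-15.0, -6.0, -3.0, 3.0, 6.0, 15.0):
        spec = ep.InclusionSpec(centre=centre, radius=3.5e-3, contrast_db=cdb)
        ph = ep.inclusion_phantom([spec], x_range=(-11e-3, 11e-3),
                                  z_range=(22e-3, 38e-3), density=15, seed=42)
        ch = ep.simulate_channel_data(ph, array, seq)
        grid = ep.PixelGrid(imaging_depth=12e-3, imaging_width=18e-3,
                            n_vertical=121, n_lateral=121, z_start=24e-3)
        env = np.abs(ep.beamform_sequence(ch, grid).values)
        X, Z = np.meshgrid(grid.x, grid.z)
        roi_in = (X - centre[0]) ** 2 + (Z - centre[1]) ** 2 <= (3e-3) ** 2
        roi_out = (X + centre[0]) ** 2 + (Z - centre[1]) ** 2 <= (3e-3) ** 2
        values[cdb] = ep.cnr(env, roi_in, roi_out)
    return values


@pytest.fixture(scope="session")
def lv_sequence():
    spec = ep.BeatingLVSpec(edv_ml=120.0, esv_ml=50.0, heart_rate_bpm=75.0,
                            frame_rate_hz=30.0, n_cycles=4.0, seed=0)
    return ep.beating_lv(spec)
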