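"""Readers and writers: HDF5 containers for channel data, images,
phantoms and mask stacks; PNG display export; CSV reports and surface
profiles; TOML array configuration.

Every container carries a `/format_version` field; mismatched versions
are refused on read.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .acoustics import ChannelData, Phantom
from .errors import EchoPatchError
from .geometry import ArrayGeometry, SurfaceProfile, make_linear_array
from .imaging import BModeImage, PixelGrid
from .phantoms import LVSequence
from .transmit import Pulse, TransmitEvent, TransmitSequence

FORMAT_VERSION = 1


def _check_version(f: h5py.File, path: str) -> None:
    v = int(f["format_version"][()]) if "format_version" in f else None
    if v != FORMAT_VERSION:
        raise EchoPatchError(f"{path}: container format version {v!r} != {FORMAT_VERSION}")


# ---------------------------------------------------------------------------
# arrays and sequences inside HDF5

def _write_array(g: h5py.Group, array: ArrayGeometry) -> None:
    g.create_dataset("positions", data=array.element_positions)
    g.create_dataset("normals", data=array.element_normals)
    for k in ("pitch", "element_width", "element_length",
              "centre_frequency", "fractional_bandwidth"):
        g.attrs[k] = getattr(array, k)


def _read_array(g: h5py.Group) -> ArrayGeometry:
    pos = g["positions"][()]
    return ArrayGeometry(
        n_elements=pos.shape[0], pitch=float(g.attrs["pitch"]),
        element_width=float(g.attrs["element_width"]),
        element_length=float(g.attrs["element_length"]),
        centre_frequency=float(g.attrs["centre_frequency"]),
        fractional_bandwidth=float(g.attrs["fractional_bandwidth"]),
        element_positions=pos, element_normals=g["normals"][()])


def _write_sequence(g: h5py.Group, seq: TransmitSequence) -> None:
    g.create_dataset("delays_s", data=np.stack([ev.delays for ev in seq.events]))
    g.create_dataset("apod", data=np.stack([ev.apodization for ev in seq.events]))
    g.create_dataset("angles_deg", data=seq.angles_deg)
    g.create_dataset("kinds", data=np.array([ev.kind for ev in seq.events], dtype="S"))
    g.attrs["pulse_fc"] = seq.pulse.centre_frequency
    g.attrs["pulse_bw"] = seq.pulse.fractional_bandwidth


def _read_sequence(g: h5py.Group) -> TransmitSequence:
    delays = g["delays_s"][()]
    apod = g["apod"][()]
    angles = g["angles_deg"][()]
    kinds = [k.decode() for k in g["kinds"][()]]
    events = []
    for i in range(delays.shape[0]):
        ang = None if np.isnan(angles[i]) else float(angles[i])
        events.append(TransmitEvent(kind=kinds[i], delays=delays[i] - delays[i].min(),
                                    apodization=apod[i], steer_angle_deg=ang))
    pulse = Pulse(float(g.attrs["pulse_fc"]), float(g.attrs["pulse_bw"]))
    return TransmitSequence(events=tuple(events), pulse=pulse)


# ---------------------------------------------------------------------------
# channel data

def write_channel_data(path, channel: ChannelData, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("format_version", data=FORMAT_VERSION)
        f.create_dataset("rf", data=channel.samples.astype(np.float32))
        f.create_dataset("fs", data=channel.fs)
        f.create_dataset("t0", data=channel.t0)
        f.create_dataset("c", data=channel.c)
        _write_array(f.create_group("array"), channel.array)
        _write_sequence(f.create_group("sequence"), channel.sequence)
        for k, v in attrs.items():
            f.attrs[k] = v


def read_channel_data(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        return ChannelData(samples=f["rf"][()].astype(np.float64),
                           fs=float(f["fs"][()]), t0=float(f["t0"][()]),
                           c=float(f["c"][()]),
                           array=_read_array(f["array"]),
                           sequence=_read_sequence(f["sequence"]))


# ---------------------------------------------------------------------------
# images

def write_bmode(path, bmode: BModeImage, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("format_version", data=FORMAT_VERSION)
        f.create_dataset("img_db", data=bmode.intensity_db.astype(np.float32))
        g = f.create_group("grid")
        g.attrs["imaging_depth"] = bmode.grid.imaging_depth
        g.attrs["imaging_width"] = bmode.grid.imaging_width
        g.attrs["n_vertical"] = bmode.grid.n_vertical
        g.attrs["n_lateral"] = bmode.grid.n_lateral
        g.attrs["x_centre"] = bmode.grid.x_centre
        g.attrs["z_start"] = bmode.grid.z_start
        f.attrs["floor_db"] = bmode.floor_db
        for k, v in attrs.items():
            f.attrs[k] = v


def read_bmode(path) -> BModeImage:
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        g = f["grid"]
        grid = PixelGrid(imaging_depth=float(g.attrs["imaging_depth"]),
                         imaging_width=float(g.attrs["imaging_width"]),
                         n_vertical=int(g.attrs["n_vertical"]),
                         n_lateral=int(g.attrs["n_lateral"]),
                         x_centre=float(g.attrs["x_centre"]),
                         z_start=float(g.attrs["z_start"]))
        img = f["img_db"][()].astype(np.float64)
        img = img - img.max()  # float32 round trip can nudge the 0 dB max
        return BModeImage(grid=grid, intensity_db=np.clip(img, float(f.attrs["floor_db"]), 0.0),
                          floor_db=float(f.attrs["floor_db"]))


def bmode_to_png(path, bmode: BModeImage) -> None:
    """8-bit PNG with the linear dB→[0, 255] mapping over [floor, 0]."""
    grey = 255.0 * (bmode.intensity_db - bmode.floor_db) / (0.0 - bmode.floor_db)
    Image.fromarray(np.clip(np.round(grey), 0, 255).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# phantoms and mask stacks

def write_phantom(path, phantom: Phantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("format_version", data=FORMAT_VERSION)
        f.create_dataset("scatterers",
                         data=np.column_stack([phantom.positions, phantom.reflectivity]))
        if phantom.seed is not None:
            f.attrs["seed"] = phantom.seed


def read_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        data = f["scatterers"][()]
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return Phantom(positions=data[:, :3], reflectivity=data[:, 3], seed=seed)


def write_masks(path, lv: LVSequence) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("format_version", data=FORMAT_VERSION)
        f.create_dataset("masks", data=lv.masks, compression="gzip")
        f.create_dataset("truth_volume_ml", data=lv.truth_volume_ml)
        f.create_dataset("frame_dt_s", data=lv.frame_dt)
        f.create_dataset("pixel_mm", data=lv.pixel_size_m * 1e3)


def read_masks(path) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Returns (masks, truth_volume_ml, frame_dt_s, pixel_size_m)."""
    with h5py.File(path, "r") as f:
        _check_version(f, str(path))
        return (f["masks"][()], f["truth_volume_ml"][()],
                float(f["frame_dt_s"][()]), float(f["pixel_mm"][()]) * 1e-3)


# ---------------------------------------------------------------------------
# CSV / TOML

def write_report(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_surface_profile(path) -> SurfaceProfile:
    """2-column CSV (s_mm, h_mm) → sampled profile; 3-column per-element
    CSV (x_mm, y_mm, z_mm) → explicit element positions."""
    tbl = pd.read_csv(path)
    vals = tbl.to_numpy(dtype=float)
    if vals.shape[1] == 2:
        return SurfaceProfile.sampled(vals[:, 0] * 1e-3, vals[:, 1] * 1e-3)
    if vals.shape[1] == 3:
        return SurfaceProfile.explicit(vals * 1e-3)
    raise EchoPatchError("surface profile CSV must have 2 or 3 columns")


def write_surface_profile(path, profile: SurfaceProfile) -> None:
    if profile.kind != "sampled":
        raise EchoPatchError("only sampled profiles are written to CSV")
    pd.DataFrame({"s_mm": profile.samples[:, 0] * 1e3,
                  "h_mm": profile.samples[:, 1] * 1e3}).to_csv(path, index=False)


def read_array_config(path) -> ArrayGeometry:
    """TOML array block: [array] n, pitch_mm, width_mm, length_mm,
    fc_mhz, bandwidth."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    a = cfg.get("array", {})
    return make_linear_array(
        n=int(a.get("n", 32)),
        pitch=float(a.get("pitch_mm", 0.4)) * 1e-3,
        width=float(a.get("width_mm", 0.3)) * 1e-3,
        length=float(a.get("length_mm", 2.3)) * 1e-3,
        fc=float(a.get("fc_mhz", 3.0)) * 1e6,
        bw=float(a.get("bandwidth", 0.55)))


def mask_stack_to_pngs(directory, lv: LVSequence) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(lv.masks.shape[0]):
        Image.fromarray(lv.masks[i] * np.uint8(255)).save(directory / f"frame_{i:04d}.png")
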