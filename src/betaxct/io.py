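"""File formats: HDF5 tilt-series/volumes, TIFF stacks, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .beamline import Radiograph, TiltSeries
from .physics import BeamlineGeometry


def save_tilt_series(path, series: TiltSeries) -> None:
    """Write a tilt series to one HDF5 file (/images, /angles, /metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=series.images(), compression="gzip")
        f.create_dataset("angles_deg", data=series.angles_deg)
        f.create_dataset("shot_index",
                         data=np.array([r.shot_index for r in series]))
        f.create_dataset("true_shift_um",
                         data=np.array([r.true_shift_um for r in series]))
        f.create_dataset("flux_factor",
                         data=np.array([r.flux_factor for r in series]))
        f.create_dataset("photon_total",
                         data=np.array([r.photon_total or 0.0 for r in series]))
        f.create_dataset("degenerate",
                         data=np.array([r.degenerate for r in series]))
        flat = series[0].flat_reference
        if flat is not None:
            f.create_dataset("flat", data=flat)
        f.attrs["pixel_pitch_um"] = series[0].pixel_pitch_um
        f.attrs["n_projections"] = series.n_projections
        f.attrs["shots_per_projection"] = series.shots_per_projection
        f.attrs["geometry_l_m"] = series.geometry.l
        f.attrs["geometry_d_m"] = series.geometry.d
        if series.rng_seed is not None:
            f.attrs["rng_seed"] = series.rng_seed


def load_tilt_series(path) -> TiltSeries:
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        angles = f["angles_deg"][...]
        shots = f["shot_index"][...]
        shifts = f["true_shift_um"][...]
        flux = f["flux_factor"][...]
        totals = f["photon_total"][...]
        degen = f["degenerate"][...]
        flat = f["flat"][...] if "flat" in f else None
        pitch = float(f.attrs["pixel_pitch_um"])
        geometry = BeamlineGeometry(float(f.attrs["geometry_l_m"]),
                                    float(f.attrs["geometry_d_m"]))
        n_proj = int(f.attrs["n_projections"])
        per = int(f.attrs["shots_per_projection"])
        seed = int(f.attrs["rng_seed"]) if "rng_seed" in f.attrs else None
    rads = [Radiograph(pixels=images[i], pixel_pitch_um=pitch,
                       angle_deg=float(angles[i]), shot_index=int(shots[i]),
                       true_shift_um=tuple(shifts[i]), flat_reference=flat,
                       photon_total=float(totals[i]), flux_factor=float(flux[i]),
                       degenerate=bool(degen[i]))
            for i in range(len(images))]
    return TiltSeries(rads, n_proj, per, geometry, rng_seed=seed)


def save_tiff_stack(directory, series: TiltSeries, prefix: str = "shot") -> list:
    """One 32-bit TIFF per shot plus a CSV metadata table; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths, rows = [], []
    for r in series:
        p = directory / f"{prefix}_{r.shot_index:05d}.tif"
        tifffile.imwrite(p, np.asarray(r.pixels, np.float32))
        paths.append(p)
        rows.append({"shot_index": r.shot_index, "angle_deg": r.angle_deg,
                     "true_shift_dy_um": r.true_shift_um[0],
                     "true_shift_dx_um": r.true_shift_um[1],
                     "flux_factor": r.flux_factor,
                     "photon_total": r.photon_total,
                     "degenerate": r.degenerate})
    pd.DataFrame(rows).to_csv(directory / f"{prefix}_metadata.csv", index=False)
    return paths


def save_volume(path, volume: np.ndarray, voxel_size_um: float,
                units: str = "cm^-3") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume", data=np.asarray(volume, np.float32),
                         compression="gzip")
        f.attrs["voxel_size_um"] = voxel_size_um
        f.attrs["units"] = units


def load_volume(path):
    with h5py.File(path, "r") as f:
        return f["volume"][...], float(f.attrs["voxel_size_um"])


def save_map_tiff(path, image: np.ndarray, **metadata) -> None:
    """32-bit float TIFF with units carried in the image description tag."""
    tifffile.imwrite(path, np.asarray(image, np.float32),
                     description=json.dumps(metadata))


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
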