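"""Voxelized single-material test objects and their projected thickness.

Axis convention: volumes are indexed (z, y, x) with z the vertical
tomography axis; the beam travels along x, so a projection is an integral
over x producing a (z, y) image (row = vertical, column = horizontal).
Occupancy voxels are material volume fractions in [0, 1] with linear edge
anti-aliasing, so projected thicknesses are smooth at the voxel scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .materials import MaterialOptics


@dataclass(frozen=True)
class Phantom:
    voxels: np.ndarray            # (z, y, x) fractions in [0, 1]
    voxel_size_um: float
    material: MaterialOptics

    def __post_init__(self):
        v = np.asarray(self.voxels, np.float32)
        if v.ndim != 3:
            raise ValueError("phantom voxels must be 3D")
        if v.min() < 0 or v.max() > 1 + 1e-6:
            raise ValueError("occupancy fractions must lie in [0, 1]")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "voxels", np.clip(v, 0.0, 1.0))

    @property
    def shape(self):
        return self.voxels.shape

    def material_volume_um3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_size_um ** 3


def _grids(shape, voxel):
    # voxel-center coordinates (μm), origin at the volume centre
    return [(np.arange(n) - (n - 1) / 2.0) * voxel for n in shape]


def _soft_ball(zz, yy, xx, center, semi, voxel):
    """Anti-aliased ellipsoid occupancy via the normalized radial excess."""
    r = np.sqrt(((zz - center[0]) / semi[0]) ** 2 +
                ((yy - center[1]) / semi[1]) ** 2 +
                ((xx - center[2]) / semi[2]) ** 2)
    # distance from the surface in μm, approximated with the smallest semi-axis
    edge = (1.0 - r) * min(semi)
    return np.clip(edge / voxel + 0.5, 0.0, 1.0)


def make_phantom(kind: str, shape, voxel_size_um: float,
                 material: MaterialOptics, **params) -> Phantom:
    """Build a test object.

    kinds
    -----
    ``cylinder``   axis-aligned uniform cylinder (params: ``radius_um``,
                   ``axis`` in {"z","y"}, ``length_fraction``).
    ``wire``       opaque vertical rod (param: ``diameter_um``, default 100),
                   e.g. a tungsten source-size wire.
    ``insect_like`` union of ellipsoidal body segments and a thin shell,
                   with internal ellipsoidal voids — a stand-in for a dried
                   insect (single material, internal air pockets).
    """
    shape = tuple(int(n) for n in shape)
    z, y, x = _grids(shape, voxel_size_um)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    half = [n * voxel_size_um / 2.0 for n in shape]

    if kind == "cylinder":
        radius = float(params.get("radius_um", shape[1] * voxel_size_um / 4))
        axis = params.get("axis", "z")
        length_fraction = float(params.get("length_fraction", 0.9))
        if radius > min(half[1], half[2]):
            raise ValueError("cylinder radius exceeds the voxel grid")
        if axis == "z":
            r = np.sqrt(yy ** 2 + xx ** 2)
            along = np.abs(zz)
            extent = half[0] * length_fraction
        elif axis == "y":
            r = np.sqrt(zz ** 2 + xx ** 2)
            along = np.abs(yy)
            extent = half[1] * length_fraction
        else:
            raise ValueError("cylinder axis must be 'z' or 'y'")
        occ = np.clip((radius - r) / voxel_size_um + 0.5, 0, 1)
        occ *= along <= extent
        return Phantom(occ, voxel_size_um, material)

    if kind == "wire":
        diameter = float(params.get("diameter_um", 100.0))
        radius = diameter / 2.0
        if radius > min(half[1], half[2]):
            raise ValueError("wire exceeds the voxel grid")
        r = np.sqrt(yy ** 2 + xx ** 2)
        occ = np.clip((radius - r) / voxel_size_um + 0.5, 0, 1)
        return Phantom(occ, voxel_size_um, material)

    if kind == "insect_like":
        # keep the body inside ~3/4 of the field so reconstruction and
        # background estimation have clear void around the sample
        scale = min(half) * float(params.get("scale", 0.75))
        body = np.zeros(shape, np.float32)
        # three overlapping body segments (head/thorax/abdomen along y);
        # kept plump so every projection stays wide against the phase
        # retrieval kernel, as the real specimen is at full scale
        segments = [((0.0, -0.60 * scale, 0.0), (0.30, 0.28, 0.30)),
                    ((0.0, -0.10 * scale, 0.0), (0.50, 0.40, 0.50)),
                    ((0.0, 0.52 * scale, 0.0), (0.42, 0.40, 0.42))]
        for center, semi in segments:
            semi_um = tuple(s * scale for s in semi)
            body = np.maximum(body, _soft_ball(zz, yy, xx, center, semi_um,
                                               voxel_size_um))
        # internal voids (tracheae/air pockets) carved out of the solid
        voids = [((0.06 * scale, -0.10 * scale, 0.04 * scale),
                  (0.24, 0.22, 0.24)),
                 ((-0.10 * scale, 0.52 * scale, -0.06 * scale),
                  (0.22, 0.20, 0.22))]
        for center, semi in voids:
            semi_um = tuple(s * scale for s in semi)
            body = np.minimum(body, 1.0 - _soft_ball(zz, yy, xx, center,
                                                     semi_um, voxel_size_um))
        return Phantom(body, voxel_size_um, material)

    raise ValueError(f"unknown phantom kind {kind!r}")


def project(phantom: Phantom, angle_deg: float = 0.0) -> np.ndarray:
    """Projected material thickness (μm) at tomographic angle ``angle_deg``.

    The volume is rotated about the vertical (z) axis with linear
    interpolation, then integrated along the beam (x) axis; parallel-beam
    geometry, adequate for the small cone angles of a metre-scale arm.
    """
    vol = phantom.voxels
    if angle_deg % 360.0 != 0.0:
        vol = ndimage.rotate(vol, angle_deg, axes=(2, 1), reshape=False,
                             order=1, prefilter=False)
        vol = np.clip(vol, 0.0, 1.0)
    return vol.sum(axis=2) * phantom.voxel_size_um


def cylinder_chord(x_um, radius_um: float) -> np.ndarray:
    """Analytic projected thickness 2·sqrt(r²−x²) of a cylinder (oracle)."""
    x = np.asarray(x_um, float)
    return 2.0 * np.sqrt(np.maximum(radius_um ** 2 - x ** 2, 0.0))
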