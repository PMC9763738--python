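"""Voxelised realisations of the benchmark geometries.

These build :class:`~impedyn.em_core.VoxelDielectricMap` instances plus
Dirichlet data for the analytic benchmark configurations, so the voxel
solver can be cross-checked against closed forms.  Electrode/boundary
values are imposed on background voxels adjacent to the domain, i.e. at
the shared face, half a voxel from the first interior center.
"""

from __future__ import annotations

import numpy as np

from .benchmarks import (
    ConcentricCylinderSpec,
    ConcentricSphereSpec,
    OffsetCylinderSpec,
    SlabSpec,
)
from .em_core import ElectrodePair, VoxelDielectricMap

__all__ = ["voxelize_slab", "voxelize_disc", "voxelize_sphere"]


def voxelize_slab(spec: SlabSpec, n: int, n_cross: int = 2):
    """Slab on an (n+2, n_cross, n_cross) grid with electrode layers at both ends.

    The first/last layers along x are pinned background voxels, so the
    Dirichlet planes sit exactly at x = 0 and x = L.  A voxel whose center
    lies at the interface is assigned to region 1.
    """
    h = spec.length / n
    hc = np.sqrt(spec.area) / n_cross
    labels = np.zeros((n + 2, n_cross, n_cross), dtype=np.int16)
    x = (np.arange(n) + 0.5) * h
    labels[1:-1] = np.where(x <= spec.p * spec.length, 1, 2)[:, None, None]
    vmap = VoxelDielectricMap(
        labels=labels,
        spacing=(h, hc, hc),
        materials={1: spec.eps1, 2: spec.eps2},
        origin=(-h, 0.0, 0.0),
    )
    patch_b = np.zeros_like(labels, dtype=bool)
    patch_b[0] = True  # grounded, adjacent to region 1
    patch_a = np.zeros_like(labels, dtype=bool)
    patch_a[-1] = True  # driven at v0
    electrodes = ElectrodePair(
        patch_a=patch_a, patch_b=patch_b, v0=spec.v0, frequency=spec.eps1.frequency
    )
    return vmap, electrodes


def _disc_labels_and_pins(n, b, box, center, r_iface, boundary_potential, v0,
                          inner_radius=None, inner_value=0.0):
    h = box / n
    coords = (np.arange(n) + 0.5) * h - box / 2
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    R = np.hypot(X, Y)
    Rc = np.hypot(X - center, Y)
    labels = np.zeros((n, n, 1), dtype=np.int16)
    inside = R <= b
    labels[..., 0][inside & (Rc <= r_iface)] = 1
    labels[..., 0][inside & (Rc > r_iface)] = 2
    pin = np.zeros((n, n, 1), dtype=bool)
    pin[..., 0] = ~inside
    values = np.zeros((n, n, 1), dtype=complex)
    values[..., 0][~inside] = boundary_potential(np.arctan2(Y, X)[~inside])
    if inner_radius is not None:
        core = R <= inner_radius
        labels[..., 0][core] = 0
        pin[..., 0][core] = True
        values[..., 0][core] = inner_value
    return labels, pin, values, h


def voxelize_disc(spec: ConcentricCylinderSpec | OffsetCylinderSpec, n: int, box_factor=1.1):
    """2D disc-in-circle geometry on an (n, n, 1) grid with unit axial depth.

    Returns ``(vmap, pin, values)``; pinned voxels are the background outside
    the circular boundary carrying the Fourier boundary data (and an inner
    electrode core if the spec has one).  Use
    :func:`impedyn.em_core.boundary_charge` to extract the weighted charge.
    """
    b = spec.r_outer
    box = 2 * b * box_factor
    if isinstance(spec, OffsetCylinderSpec):
        center, r_iface = spec.offset, spec.r_cylinder
        inner_radius, inner_value = None, 0.0
    else:
        center, r_iface = 0.0, spec.r_interface
        inner_radius = spec.inner_radius
        inner_value = complex(np.atleast_1d((spec.inner_coeffs or {}).get(0, (0, 0)))[0])

    def boundary_potential(theta):
        out = np.zeros_like(theta, dtype=complex)
        for m, cs in spec.outer_coeffs.items():
            ac, as_ = np.atleast_1d(cs)[0], np.atleast_1d(cs)[-1] if np.size(cs) > 1 else 0.0
            out += ac * np.cos(m * theta) + as_ * np.sin(m * theta)
        return out

    labels, pin, values, h = _disc_labels_and_pins(
        n, b, box, center, r_iface, boundary_potential, spec.v0, inner_radius, inner_value
    )
    vmap = VoxelDielectricMap(
        labels=labels,
        spacing=(h, h, 1.0),
        materials={1: spec.eps_in, 2: spec.eps_out},
        origin=(-box / 2, -box / 2, 0.0),
    )
    return vmap, pin, values


def voxelize_sphere(spec: ConcentricSphereSpec, n: int, box_factor=1.1):
    """Concentric-sphere geometry on an (n, n, n) grid; z is the polar axis."""
    b = spec.r_outer
    box = 2 * b * box_factor
    h = box / n
    coords = (np.arange(n) + 0.5) * h - box / 2
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    labels = np.zeros((n, n, n), dtype=np.int16)
    inside = R <= b
    labels[inside & (R <= spec.r_interface)] = 1
    labels[inside & (R > spec.r_interface)] = 2
    pin = ~inside
    with np.errstate(invalid="ignore"):
        costh = np.where(R > 0, Z / np.maximum(R, 1e-300), 1.0)
    values = np.zeros((n, n, n), dtype=complex)
    from scipy.special import eval_legendre

    vb = np.zeros_like(costh, dtype=complex)
    for l, c in spec.outer_coeffs.items():
        vb += c * eval_legendre(l, costh)
    values[pin] = vb[pin]
    if spec.inner_radius is not None:
        core = R <= spec.inner_radius
        labels[core] = 0
        pin = pin | core
        values[core] = complex((spec.inner_coeffs or {}).get(0, 0.0))
    vmap = VoxelDielectricMap(
        labels=labels,
        spacing=(h, h, h),
        materials={1: spec.eps_in, 2: spec.eps_out},
        origin=(-box / 2, -box / 2, -box / 2),
    )
    return vmap, pin, values
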