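"""File formats: NIfTI volumes, triangulated surfaces, HDF5 artifacts, YAML config.

Unit conventions at the I/O boundary: everything in memory is SI (meters);
NIfTI affines and surface meshes on disk are in millimeters (the common
neuroimaging/mesh convention) and are converted on read/write.  Voxel
indices are 0-based; world coordinates come from the NIfTI affine.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import trimesh
import yaml

from .em_core import ComplexDielectric, PotentialField, VoxelDielectricMap, make_dielectric
from .deformation import DeformationSeries, SurfaceDisplacementSeries
from .perturbation import SensitivityMap, TriSurface

__all__ = [
    "read_voxel_volume",
    "write_voxel_volume",
    "read_displacement_series",
    "write_displacement_series",
    "read_surface",
    "write_surface",
    "read_materials",
    "write_materials",
    "read_voxel_map",
    "write_potential_field",
    "write_sensitivity_map",
    "read_sensitivity_map",
    "write_surface_series",
    "read_surface_series",
    "config_hash",
]

MM = 1e-3


def read_voxel_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine) with the affine in meters."""
    img = nib.load(str(path))
    affine = img.affine.copy()
    affine[:3] *= MM
    return np.asanyarray(img.dataobj), affine

def write_voxel_volume(path, data: np.ndarray, affine_m: np.ndarray | None = None,
                       spacing=None, origin=None):
    """Write a NIfTI volume; affine given in meters (or built from spacing/origin)."""
    if affine_m is None:
        affine_m = np.eye(4)
        if spacing is not None:
            affine_m[:3, :3] = np.diag(spacing)
        if origin is not None:
            # NIfTI origin refers to the center of voxel (0,0,0)
            affine_m[:3, 3] = np.asarray(origin) + 0.5 * np.asarray(
                spacing if spacing is not None else (1.0, 1.0, 1.0)
            )
    affine = affine_m.copy()
    affine[:3] /= MM
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def _grid_from_affine(affine_m: np.ndarray):
    lin = affine_m[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin))):
        raise ValueError("only axis-aligned affines are supported")
    spacing = tuple(np.diag(lin))
    if any(s <= 0 for s in spacing):
        raise ValueError("affine must have positive, axis-aligned spacing")
    origin = tuple(affine_m[:3, 3] - 0.5 * np.asarray(spacing))
    return spacing, origin


def read_displacement_series(path_or_paths, mask=None) -> DeformationSeries:
    """Displacement series from one 5D/4D NIfTI or a list of per-phase NIfTIs.

    On-disk values are in mm; a 5D file is (nx, ny, nz, n_phases, 3), a list
    holds per-phase (nx, ny, nz, 3) volumes.  All files must share one affine.
    """
    if isinstance(path_or_paths, (str, Path)):
        data, affine = read_voxel_volume(path_or_paths)
        if data.ndim != 5 or data.shape[-1] != 3:
            raise ValueError("expected a 5D NIfTI (x, y, z, phase, component)")
        disp = np.moveaxis(data, 3, 0)
    else:
        vols, affine = [], None
        for p in path_or_paths:
            d, a = read_voxel_volume(p)
            if d.ndim != 4 or d.shape[-1] != 3:
                raise ValueError("per-phase volumes must be (x, y, z, 3)")
            if affine is None:
                affine = a
            elif not np.allclose(a, affine):
                raise ValueError("mismatched affines across phase volumes")
            vols.append(d)
        disp = np.stack(vols)
    spacing, origin = _grid_from_affine(affine)
    return DeformationSeries(
        disp=disp * MM, spacing=spacing, origin=origin, mask=mask
    )


def write_displacement_series(path, series: DeformationSeries):
    data = np.moveaxis(series.disp, 0, 3) / MM
    write_voxel_volume(path, data, spacing=series.spacing, origin=series.origin)


def read_surface(path, region1_inside: bool = True) -> TriSurface:
    """Load an STL/PLY/OFF surface (mm on disk), oriented and in meters.

    Degenerate faces are dropped; if the mesh is closed, the orientation is
    corrected so normals point out of the enclosed region (region 1) — pass
    ``region1_inside=False`` to flip (e.g. a ventricular cavity seen from the
    brain side).  Non-watertight input triggers a warning with a hole count.
    """
    mesh = trimesh.load_mesh(str(path), process=True)  # merge duplicate vertices
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.apply_scale(MM)
    if mesh.is_watertight:
        if mesh.volume < 0:
            mesh.invert()
        if not region1_inside:
            mesh.invert()
    else:
        warnings.warn(
            f"surface {path} is not watertight "
            f"({len(trimesh.repair.broken_faces(mesh))} broken faces)",
            stacklevel=2,
        )
    return TriSurface.from_trimesh(mesh)


def write_surface(path, surface: TriSurface):
    mesh = surface.to_trimesh()
    mesh.apply_scale(1.0 / MM)
    mesh.export(str(path))


def read_materials(path, frequency: float) -> dict:
    """YAML tissue table {name_or_id: {eps_r, sigma}} -> ComplexDielectric map."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    return {
        key: make_dielectric(entry["eps_r"], entry["sigma"], frequency)
        for key, entry in table.items()
    }


def write_materials(path, materials: dict):
    table = {
        key: {"eps_r": float(m.eps_r), "sigma": float(m.sigma)}
        for key, m in materials.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(table, fh)


def read_voxel_map(labels_path, materials_path, frequency: float) -> VoxelDielectricMap:
    labels, affine = read_voxel_volume(labels_path)
    spacing, origin = _grid_from_affine(affine)
    materials = read_materials(materials_path, frequency)
    materials = {int(k): v for k, v in materials.items()}
    return VoxelDielectricMap(
        labels=labels.astype(np.int32), spacing=spacing, materials=materials,
        origin=origin,
    )


def write_potential_field(path, field: PotentialField, vmap: VoxelDielectricMap):
    """Potential to HDF5 (and the grid metadata needed to re-sample it)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("phi_real", data=field.phi.real, compression="gzip")
        fh.create_dataset("phi_imag", data=field.phi.imag, compression="gzip")
        fh.create_dataset("free", data=field.free)
        fh.create_dataset("pin", data=field.pin)
        fh.attrs["residual"] = field.residual
        fh.attrs["spacing"] = vmap.spacing
        fh.attrs["origin"] = vmap.origin


def write_sensitivity_map(path, smap: SensitivityMap):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("vertices", data=smap.surface.vertices)
        fh.create_dataset("faces", data=smap.surface.faces)
        fh.create_dataset("geometry", data=smap.geometry)
        fh.attrs["perfusion_per_volume"] = smap.perfusion_per_volume
        fh.attrs["v0"] = smap.v0
        fh.attrs["omega"] = smap.omega
        if smap.y_base is not None:
            fh.attrs["y_base"] = smap.y_base


def read_sensitivity_map(path) -> SensitivityMap:
    with h5py.File(path, "r") as fh:
        surface = TriSurface(fh["vertices"][...], fh["faces"][...])
        return SensitivityMap(
            surface=surface,
            geometry=fh["geometry"][...],
            perfusion_per_volume=complex(fh.attrs["perfusion_per_volume"]),
            v0=float(fh.attrs["v0"]),
            omega=float(fh.attrs["omega"]),
            y_base=complex(fh.attrs["y_base"]) if "y_base" in fh.attrs else None,
        )


def write_surface_series(path, sds: SurfaceDisplacementSeries):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("vertices", data=sds.surface.vertices)
        fh.create_dataset("faces", data=sds.surface.faces)
        fh.create_dataset("disp", data=sds.disp, compression="gzip")
        fh.attrs["method"] = sds.method


def read_surface_series(path) -> SurfaceDisplacementSeries:
    with h5py.File(path, "r") as fh:
        surface = TriSurface(fh["vertices"][...], fh["faces"][...])
        return SurfaceDisplacementSeries(
            surface=surface, disp=fh["disp"][...], method=str(fh.attrs["method"])
        )


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration, for logging/reproducibility."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
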