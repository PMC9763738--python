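"""Processing of DENSE-like voxel displacement series into surface motion.

A displacement-encoded MRI acquisition yields, per cardiac phase, a voxel
field of tissue displacement for two opposite encoding-gradient polarities.
The pipeline implemented here mirrors the standard processing chain:

1. background-error removal by polarity subtraction, (pos - neg)/2;
2. masking to GM/WM (probability maps), eroded 3 voxels to stay clear of
   CSF-adjacent voxels with poor data quality;
3. k-nearest-neighbour smoothing (k = 150) of the masked vectors;
4. extrapolation of the masked data onto triangulated brain surfaces, by
   nearest-neighbour lookup or by an unstructured Fourier (least-squares
   "FFT") fit with SVD regularisation that makes no zero-outside-domain
   assumption;
5. extraction of scalar pulsation features per phase: CSF volume change
   dVCSF, surface-averaged translation TS and rotation RS.

Sign convention: surface normals point out of the brain into CSF, and
dVCSF = -sum(d.n A): brain expansion displaces CSF out of the cranium
(Monro-Kellie coupling), so the perfusion-driving blood volume change is
dv_total = -dVCSF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .perturbation import TriSurface

__all__ = [
    "DeformationSeries",
    "SurfaceDisplacementSeries",
    "PulsationFeatures",
    "remove_background",
    "build_mask",
    "erode",
    "knn_smooth",
    "nn_extrapolate",
    "fft_extrapolate",
    "FourierExtrapolator",
    "extract_features",
    "subinterval_motion",
]

WARN_DISPLACEMENT = 1e-3  # m; physiological brain pulsation is well below 1 mm
REJECT_DISPLACEMENT = 1e-2  # m; clearly non-physiological input
SURFACE_REJECT_DEFAULT = 300e-6  # m; reconstructed surface motion >> 100 um is rejected


@dataclass
class DeformationSeries:
    """Voxel displacement vector fields over the cardiac cycle.

    ``disp`` has shape (n_phases, nx, ny, nz, 3) in meters; ``mask`` flags
    the voxels considered valid.  ``spacing``/``origin`` place voxel centers
    in world coordinates (meters).
    """

    disp: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 5 or self.disp.shape[-1] != 3:
            raise ValueError("disp must have shape (n_phases, nx, ny, nz, 3)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask shape does not match the voxel grid")
        peak = np.abs(self.disp).max()
        if peak > REJECT_DISPLACEMENT:
            raise ValueError(
                f"displacement magnitude {peak:.2e} m is not physiological"
            )
        if peak > WARN_DISPLACEMENT:
            warnings.warn(
                f"displacement magnitude {peak:.2e} m exceeds 1 mm", stacklevel=2
            )

    @property
    def n_phases(self) -> int:
        return self.disp.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.disp.shape[1:4]

    def masked_coordinates(self) -> np.ndarray:
        """World coordinates (n_mask, 3) of the masked voxel centers."""
        if self.mask is None:
            raise ValueError("series has no validity mask")
        idx = np.argwhere(self.mask)
        return (idx + 0.5) * np.asarray(self.spacing) + np.asarray(self.origin)

    def masked_values(self) -> np.ndarray:
        """Masked displacement values, shape (n_phases, n_mask, 3)."""
        return self.disp[:, self.mask, :]


def remove_background(pos: DeformationSeries, neg: DeformationSeries) -> DeformationSeries:
    """Cancel the shared background error of a gradient-polarity pair.

    The two polarities encode opposite motion on top of a common background
    field, so (pos - neg)/2 recovers the motion and cancels the background
    exactly; validity masks are intersected.
    """
    if pos.disp.shape != neg.disp.shape:
        raise ValueError("polarity pair shapes differ")
    if pos.spacing != neg.spacing or not np.allclose(pos.origin, neg.origin):
        raise ValueError("polarity pair grids differ")
    mask = None
    if pos.mask is not None or neg.mask is not None:
        mask = np.ones(pos.grid_shape, dtype=bool)
        if pos.mask is not None:
            mask &= pos.mask
        if neg.mask is not None:
            mask &= neg.mask
    return DeformationSeries(
        disp=(pos.disp - neg.disp) / 2.0,
        spacing=pos.spacing,
        mask=mask,
        origin=pos.origin,
    )


def build_mask(prob_gm, prob_wm, prob_csf, threshold: float = 0.5) -> np.ndarray:
    """Brain-tissue validity mask: GM+WM posterior wins over CSF at threshold."""
    gm = np.asarray(prob_gm, dtype=float)
    wm = np.asarray(prob_wm, dtype=float)
    csf = np.asarray(prob_csf, dtype=float)
    if gm.max() <= 0 and wm.max() <= 0:
        raise ValueError("empty tissue probability maps")
    tissue = gm + wm
    return (tissue >= threshold) & (tissue > csf)


def erode(mask: np.ndarray, n: int = 3) -> np.ndarray:
    """6-connectivity morphological erosion by n voxels; must stay non-empty."""
    structure = generate_binary_structure(3, 1)
    out = binary_erosion(mask, structure=structure, iterations=n)
    if not out.any():
        raise ValueError(f"mask empty after {n}-voxel erosion")
    return out


def knn_smooth(series: DeformationSeries, k: int = 150) -> DeformationSeries:
    """Replace each masked vector by the mean over its k nearest masked voxels.

    Neighbourhoods are Euclidean in physical units and shared across phases
    and components; voxels outside the mask are left untouched.
    """
    if series.mask is None:
        raise ValueError("knn_smooth requires a validity mask")
    coords = series.masked_coordinates()
    n_mask = len(coords)
    k_eff = min(k, n_mask)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_eff, workers=-1)
    idx = np.atleast_2d(idx)
    vals = series.masked_values()  # (n_phases, n_mask, 3)
    smoothed = np.empty_like(vals)
    for ph in range(series.n_phases):
        smoothed[ph] = vals[ph][idx].mean(axis=1)
    out = series.disp.copy()
    out[:, series.mask, :] = smoothed
    return replace(series, disp=out)


@dataclass
class SurfaceDisplacementSeries:
    """Per-face surface displacement vectors over the cardiac cycle."""

    surface: TriSurface
    disp: np.ndarray  # (n_phases, n_faces, 3), meters
    method: str = ""

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 3 or self.disp.shape[-1] != 3:
            raise ValueError("disp must have shape (n_phases, n_faces, 3)")
        if self.disp.shape[1] != self.surface.n_faces:
            raise ValueError("face count mismatch")

    @property
    def n_phases(self) -> int:
        return self.disp.shape[0]

    def validate(self, cap: float = SURFACE_REJECT_DEFAULT):
        """Reject reconstructions with non-physiological surface motion (>> 100 um)."""
        peak = np.linalg.norm(self.disp, axis=-1).max()
        if peak > cap:
            raise ValueError(
                f"reconstructed surface displacement {peak * 1e6:.0f} um exceeds the "
                f"{cap * 1e6:.0f} um rejection cap ({self.method or 'unknown'} method)"
            )
        return self


def nn_extrapolate(
    series: DeformationSeries,
    surface: TriSurface,
    cap: float = SURFACE_REJECT_DEFAULT,
) -> SurfaceDisplacementSeries:
    """Assign to each face the displacement of its nearest masked voxel."""
    if series.mask is None or not series.mask.any():
        raise ValueError("nn_extrapolate requires a non-empty mask")
    coords = series.masked_coordinates()
    tree = cKDTree(coords)
    _, nearest = tree.query(surface.face_centroids, workers=-1)
    vals = series.masked_values()[:, nearest, :]
    return SurfaceDisplacementSeries(surface=surface, disp=vals, method="nn").validate(cap)


class FourierExtrapolator:
    """Least-squares truncated Fourier fit of scattered voxel samples.

    The basis is the tensor product of 1, cos and sin up to ``n_harmonics``
    per axis on the mask bounding box padded by ``pad`` — a genuinely
    unstructured fit: nothing is assumed about the field outside the mask.
    The normal-equations-free solve uses an SVD with a relative singular
    value cutoff to control the conditioning of the scattered-data problem.

    Building the design matrix and its SVD depends only on the mask, so one
    extrapolator can be reused across phases, components and subjects that
    share a grid and mask.
    """

    def __init__(
        self,
        coords: np.ndarray,
        n_harmonics: int = 4,
        pad: float = 0.25,
        svd_rel_cutoff: float = 1e-3,
        max_samples: int = 20000,
        rng: np.random.Generator | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if rng is None:
            rng = np.random.default_rng(0)
        if len(coords) > max_samples:
            self.sample_idx = np.sort(
                rng.choice(len(coords), size=max_samples, replace=False)
            )
        else:
            self.sample_idx = np.arange(len(coords))
        pts = coords[self.sample_idx]
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        span = hi - lo
        span = np.where(span > 0, span, max(span.max(), 1.0))  # degenerate axes
        self.box_lo = lo - pad * span / 2
        self.box_len = span * (1 + pad)
        self.n_harmonics = n_harmonics
        self.svd_rel_cutoff = svd_rel_cutoff
        A = self._design(pts)
        if A.shape[0] < A.shape[1]:
            raise ValueError(
                f"{A.shape[0]} masked samples cannot constrain {A.shape[1]} basis functions"
            )
        u, s, vt = np.linalg.svd(A, full_matrices=False)
        keep = s >= self.svd_rel_cutoff * s[0]
        if keep.sum() < 0.1 * len(s):
            raise RuntimeError(
                f"rank collapse: {keep.sum()}/{len(s)} singular values above the "
                f"{self.svd_rel_cutoff:g} relative cutoff; the mask geometry cannot "
                "support this basis"
            )
        self.rank = int(keep.sum())
        self._pinv = (vt[keep].T / s[keep]) @ u[:, keep].T

    def _axis_basis(self, x: np.ndarray, axis: int) -> np.ndarray:
        t = 2 * np.pi * (x - self.box_lo[axis]) / self.box_len[axis]
        cols = [np.ones_like(t)]
        for k in range(1, self.n_harmonics + 1):
            cols.append(np.cos(k * t))
            cols.append(np.sin(k * t))
        return np.stack(cols, axis=1)

    def _design(self, pts: np.ndarray) -> np.ndarray:
        bx = self._axis_basis(pts[:, 0], 0)
        by = self._axis_basis(pts[:, 1], 1)
        bz = self._axis_basis(pts[:, 2], 2)
        A = np.einsum("ni,nj,nk->nijk", bx, by, bz)
        return A.reshape(len(pts), -1)

    def fit(self, values: np.ndarray) -> np.ndarray:
        """Coefficients for one or more sample vectors (..., n_samples)."""
        v = np.asarray(values)[..., self.sample_idx]
        return v @ self._pinv.T

    def evaluate(self, coeffs: np.ndarray, points: np.ndarray) -> np.ndarray:
        return coeffs @ self._design(np.asarray(points, dtype=float)).T


def fft_extrapolate(
    series: DeformationSeries,
    surface: TriSurface,
    n_harmonics: int = 4,
    svd_rel_cutoff: float = 1e-3,
    cap: float = SURFACE_REJECT_DEFAULT,
    extrapolator: FourierExtrapolator | None = None,
) -> SurfaceDisplacementSeries:
    """Unstructured-Fourier extrapolation of the masked data onto a surface."""
    if series.mask is None or not series.mask.any():
        raise ValueError("fft_extrapolate requires a non-empty mask")
    if extrapolator is None:
        extrapolator = FourierExtrapolator(
            series.masked_coordinates(),
            n_harmonics=n_harmonics,
            svd_rel_cutoff=svd_rel_cutoff,
        )
    vals = series.masked_values()  # (n_phases, n_mask, 3)
    stacked = np.moveaxis(vals, 1, 2)  # (n_phases, 3, n_mask)
    coeffs = extrapolator.fit(stacked)
    out = extrapolator.evaluate(coeffs, surface.face_centroids)  # (n_phases, 3, n_faces)
    disp = np.moveaxis(out, 1, 2)
    return SurfaceDisplacementSeries(surface=surface, disp=disp, method="fft").validate(cap)


@dataclass
class PulsationFeatures:
    """Scalar pulsation features per cardiac phase.

    ``dvcsf`` in m^3 (negative of the brain-surface swept volume), ``ts`` the
    area-weighted mean displacement vector in m, and ``rs`` the
    least-squares infinitesimal rigid rotation vector in rad.
    """

    dvcsf: np.ndarray  # (n_phases,)
    ts: np.ndarray  # (n_phases, 3)
    rs: np.ndarray  # (n_phases, 3)

    @property
    def ts_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.ts, axis=-1)

    @property
    def rs_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.rs, axis=-1)

    def as_matrix(self) -> np.ndarray:
        """(n_phases, 3) feature curves: dVCSF, |TS|, |RS|."""
        return np.stack([self.dvcsf, self.ts_magnitude, self.rs_magnitude], axis=1)

    def curves(self, components=("dvcsf", "ts_z", "rs_x")) -> np.ndarray:
        """(n_components, n_phases) selected feature curves.

        Components: ``dvcsf``, ``ts_x|y|z``, ``rs_x|y|z`` (signed anatomical
        projections, e.g. cranio-caudal translation, nodding rotation) or
        ``ts_mag``/``rs_mag``.  Signed projections keep the curves linear in
        the underlying motion and are the natural inputs for inference.
        """
        axis = {"x": 0, "y": 1, "z": 2}
        rows = []
        for comp in components:
            if comp == "dvcsf":
                rows.append(self.dvcsf)
            elif comp == "ts_mag":
                rows.append(self.ts_magnitude)
            elif comp == "rs_mag":
                rows.append(self.rs_magnitude)
            elif comp.startswith("ts_"):
                rows.append(self.ts[:, axis[comp[3:]]])
            elif comp.startswith("rs_"):
                rows.append(self.rs[:, axis[comp[3:]]])
            else:
                raise ValueError(f"unknown feature component {comp!r}")
        return np.stack(rows)


def extract_features(sds: SurfaceDisplacementSeries) -> PulsationFeatures:
    """dVCSF, TS and RS from a reconstructed surface displacement series.

    The rigid part (t, theta) per phase minimises the area-weighted misfit
    sum_f A_f |d_f - t - theta x (c_f - c0)|^2 about the area centroid c0;
    TS is reported as the area-weighted mean displacement and RS as the
    fitted rotation vector.
    """
    surf = sds.surface
    a = surf.face_areas
    n = surf.face_normals
    c = surf.face_centroids
    total_area = a.sum()
    c0 = (a[:, None] * c).sum(axis=0) / total_area
    r = c - c0

    dvcsf = -np.einsum("pfj,fj,f->p", sds.disp, n, a)
    ts = np.einsum("pfj,f->pj", sds.disp, a) / total_area

    # least-squares rigid fit: block normal equations for (t, theta)
    def cross_mat(v):
        out = np.zeros((len(v), 3, 3))
        out[:, 0, 1] = -v[:, 2]
        out[:, 0, 2] = v[:, 1]
        out[:, 1, 0] = v[:, 2]
        out[:, 1, 2] = -v[:, 0]
        out[:, 2, 0] = -v[:, 1]
        out[:, 2, 1] = v[:, 0]
        return out

    rx = cross_mat(r)  # theta x r = -r x theta = -rx @ theta -> d ~ t + (-rx) theta
    B = -rx
    att = total_area * np.eye(3)
    atb = np.einsum("f,fij->ij", a, B)
    abb = np.einsum("f,fki,fkj->ij", a, B, B)
    M = np.block([[att, atb], [atb.T, abb]])
    rhs_t = np.einsum("pfj,f->pj", sds.disp, a)
    rhs_b = np.einsum("pfk,f,fkj->pj", sds.disp, a, B)
    rhs = np.concatenate([rhs_t, rhs_b], axis=1)
    sol = np.linalg.solve(M, rhs.T).T
    rs = sol[:, 3:]
    return PulsationFeatures(dvcsf=dvcsf, ts=ts, rs=rs)


def subinterval_motion(sds: SurfaceDisplacementSeries, n_intervals: int = 6) -> np.ndarray:
    """End-minus-start per-face displacement over n sub-intervals of the cycle.

    Interval boundaries are evenly spaced phase indices from the first to the
    last phase, so the intervals tile the covered cycle and their sum equals
    the last-minus-first displacement.
    """
    bounds = np.linspace(0, sds.n_phases - 1, n_intervals + 1).round().astype(int)
    return np.stack(
        [sds.disp[bounds[i + 1]] - sds.disp[bounds[i]] for i in range(n_intervals)]
    )
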