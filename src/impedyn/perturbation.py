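"""Reciprocity-theorem perturbation of charge/admittance for dynamic interfaces.

Given a single base solve, the charge change dQ caused by (i) a small
displacement of a dielectric interface, (ii) a small change of the inner
region's complex permittivity, or (iii) both, is evaluated from field
quantities on the *original* interface location only:

    V0*dQ_geom = -sum_f [ (eps2^2/eps1 - eps2)*En+^2
                          + (eps2 - eps1)*Et.Et ] * (d.n) * A_f
    V0*dQ_diel = d_eps1 * sum_f phi(r1) * dphi/dn|- * A_f

with unconjugated complex products, so that dQ is genuinely complex and
yields both a capacitance and a resistance change.  The per-face geometry
kernel divided by V0 is the sensitivity map S(r): the functional derivative
of dQ with respect to locally swept interface volume.

Normal convention: face normals point from region 1 (inner, e.g. brain)
into region 2 (outer, e.g. CSF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .em_core import ComplexDielectric, PotentialField, VoxelDielectricMap

__all__ = [
    "TriSurface",
    "InterfaceFieldState",
    "SurfaceDisplacement",
    "BilayerDensities",
    "PerturbResult",
    "SensitivityMap",
    "extract_interface_fields",
    "bilayer_densities",
    "dq_geometry",
    "dq_dielectric",
    "dq_combined",
    "sensitivity_map",
    "dq_from_sensitivity",
]


class GeometryError(ValueError):
    pass


@dataclass
class TriSurface:
    """Triangulated interface surface with consistent outward-from-region-1 normals."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        v = self.vertices
        tri = v[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1)
        if np.any(norms <= 0):
            raise ValueError("degenerate faces with zero area")
        self.face_areas = 0.5 * norms
        self.face_normals = cross / norms[:, None]
        self.face_centroids = tri.mean(axis=1)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def signed_volume(self) -> float:
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def check_orientation(self) -> bool:
        """True if every shared edge is traversed once per direction."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        fwd = set(map(tuple, edges))
        return all((b, a) in fwd for a, b in fwd if (a, b) in fwd) and len(fwd) == len(edges)

    @classmethod
    def from_trimesh(cls, mesh) -> "TriSurface":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class SurfaceDisplacement:
    """Per-face displacement vectors r2 - r1 (meters), optionally per phase."""

    vectors: np.ndarray  # (n_faces, 3) or (n_phases, n_faces, 3)
    warn_fraction: float = 0.10

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[-1] != 3:
            raise ValueError("displacement vectors must have 3 components")

    def check_small(self, feature_size: float):
        mags = np.linalg.norm(self.vectors, axis=-1)
        if mags.max(initial=0.0) > self.warn_fraction * feature_size:
            warnings.warn(
                "interface displacement exceeds "
                f"{self.warn_fraction:.0%} of the local feature size; the "
                "first-order perturbation may degrade",
                stacklevel=2,
            )


@dataclass
class InterfaceFieldState:
    """Complex field/potential quantities on the original interface location.

    ``en_plus`` is the normal E on the region-2 side, ``et`` the tangential E
    vector (continuous across the interface), ``phi_r1`` the potential, and
    ``dphidn_minus``/``dphidn_plus`` the one-sided normal derivatives of phi.
    Flux continuity eps1*dphidn_minus == eps2*dphidn_plus holds up to the
    sampling tolerance reported by :func:`extract_interface_fields`.
    """

    surface: TriSurface
    en_plus: np.ndarray
    et: np.ndarray
    phi_r1: np.ndarray
    dphidn_minus: np.ndarray
    dphidn_plus: np.ndarray
    eps1: ComplexDielectric
    eps2: ComplexDielectric
    v0: float
    flux_continuity_error: float = 0.0

    @property
    def omega(self) -> float:
        return self.eps1.omega

    def flux_mismatch(self) -> np.ndarray:
        e1, e2 = self.eps1.value, self.eps2.value
        num = np.abs(e1 * self.dphidn_minus - e2 * self.dphidn_plus)
        den = np.maximum(np.abs(e1 * self.dphidn_minus), np.abs(e2 * self.dphidn_plus))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(den > 0, num / den, 0.0)
        return rel


@dataclass
class BilayerDensities:
    """Equivalent surface charge bi-layer at the old/new interface locations."""

    rho_s1: np.ndarray
    rho_s2: np.ndarray


@dataclass
class PerturbResult:
    """First-order complex charge change and derived signal quantities.

    ``dr`` uses the first-order parallel-equivalent linearisation
    ``dR = -Re(dY)/Re(Y)^2`` and therefore requires the base admittance.
    """

    dq: complex
    dy: complex
    dc: float
    dr: float | None
    v0: float
    omega: float
    split: dict = field(default_factory=dict)

    @classmethod
    def from_dq(cls, dq, v0, omega, y_base=None, split=None) -> "PerturbResult":
        dy = 1j * omega * dq / v0
        dc = dy.imag / omega
        dr = None
        if y_base is not None and y_base.real != 0:
            dr = -dy.real / y_base.real**2
        return cls(dq=complex(dq), dy=dy, dc=dc, dr=dr, v0=v0, omega=omega, split=split or {})


def _geometry_kernel(state: InterfaceFieldState, conjugate: bool = False) -> np.ndarray:
    """Per-face integrand of the moving-interface formula (without d.n A)."""
    e1, e2 = state.eps1.value, state.eps2.value
    en = state.en_plus
    et = state.et
    if conjugate:
        en2 = np.abs(en) ** 2
        et2 = np.einsum("fj,fj->f", et, np.conj(et)).real
    else:
        en2 = en * en
        et2 = np.einsum("fj,fj->f", et, et)
    return -((e2**2 / e1 - e2) * en2 + (e2 - e1) * et2)


def extract_interface_fields(
    field_: PotentialField,
    vmap: VoxelDielectricMap,
    surface: TriSurface,
    eps1: ComplexDielectric,
    eps2: ComplexDielectric,
    v0: float,
    h_frac: float = 0.5,
) -> InterfaceFieldState:
    """Sample the solved potential on a triangulated interface.

    phi is interpolated trilinearly at face centroids offset along the normal
    by h and 2h per side (h = ``h_frac`` voxels); two-point one-sided stencils
    keep both samples of each slope clear of the interpolation cell that
    straddles the material interface, where trilinear interpolation smears
    the kink in phi.  phi(r1) is extrapolated to the interface from the
    region-1 side and the tangential E comes from the in-plane gradient on
    that side.  The interface must stay inside the solved domain.
    """
    spacing = np.asarray(vmap.spacing)
    origin = np.asarray(vmap.origin)
    h = h_frac * float(spacing.min())

    def sample(points: np.ndarray) -> np.ndarray:
        idx = ((points - origin) / spacing - 0.5).T
        if (idx < -0.5).any() or (idx.T > np.asarray(vmap.shape) - 0.5).any():
            raise GeometryError("surface exits the solved voxel domain")
        re = map_coordinates(field_.phi.real, idx, order=1, mode="nearest")
        im = map_coordinates(field_.phi.imag, idx, order=1, mode="nearest")
        return re + 1j * im

    c = surface.face_centroids
    n = surface.face_normals
    phi_m1 = sample(c - h * n)
    phi_m2 = sample(c - 2 * h * n)
    phi_p1 = sample(c + h * n)
    phi_p2 = sample(c + 2 * h * n)
    dphidn_minus = (phi_m1 - phi_m2) / h
    dphidn_plus = (phi_p2 - phi_p1) / h
    phi_r1 = phi_m1 + h * dphidn_minus

    # tangential E from the in-plane gradient sampled on the region-1 side
    base = c - h * n
    grad = np.empty((surface.n_faces, 3), dtype=complex)
    for axis in range(3):
        off = np.zeros(3)
        off[axis] = h
        grad[:, axis] = (sample(base + off) - sample(base - off)) / (2 * h)
    e_vec = -grad
    en_c = np.einsum("fj,fj->f", e_vec, n)
    et = e_vec - en_c[:, None] * n

    state = InterfaceFieldState(
        surface=surface,
        en_plus=-dphidn_plus,
        et=et,
        phi_r1=phi_r1,
        dphidn_minus=dphidn_minus,
        dphidn_plus=dphidn_plus,
        eps1=eps1,
        eps2=eps2,
        v0=v0,
    )
    state.flux_continuity_error = float(np.median(state.flux_mismatch()))
    return state


def bilayer_densities(state: InterfaceFieldState, eps1_star: ComplexDielectric) -> BilayerDensities:
    """Equivalent bi-layer charge densities for a perturbed configuration.

    rho_s1 = (eps2*eps1*/eps1 - eps1*) * dphi/dn|+  at the original interface,
    rho_s2 = -(eps2 - eps1*) * dphi/dn|+            at the shifted interface,
    both evaluated with base fields under the small-shift approximation.
    """
    e1, e2 = state.eps1.value, state.eps2.value
    e1s = eps1_star.value
    if e1 == 0:
        raise ZeroDivisionError("eps1 must be nonzero")
    rho_s1 = (e2 * e1s / e1 - e1s) * state.dphidn_plus
    rho_s2 = -(e2 - e1s) * state.dphidn_plus
    return BilayerDensities(rho_s1=rho_s1, rho_s2=rho_s2)


def dq_geometry(
    state: InterfaceFieldState,
    disp: SurfaceDisplacement | np.ndarray,
    y_base: complex | None = None,
    conjugate: bool = False,
) -> PerturbResult:
    """Charge change from a small interface displacement at fixed properties."""
    vec = disp.vectors if isinstance(disp, SurfaceDisplacement) else np.asarray(disp, float)
    if vec.shape != (state.surface.n_faces, 3):
        raise ValueError(
            f"displacement shape {vec.shape} does not match {state.surface.n_faces} faces"
        )
    dn = np.einsum("fj,fj->f", vec, state.surface.face_normals)
    kern = _geometry_kernel(state, conjugate=conjugate)
    dq = np.sum(kern * dn * state.surface.face_areas) / state.v0
    return PerturbResult.from_dq(
        dq, state.v0, state.omega, y_base, split={"geometry": complex(dq), "dielectric": 0j}
    )


def dq_dielectric(
    state: InterfaceFieldState,
    d_eps1: complex,
    y_base: complex | None = None,
) -> PerturbResult:
    """Charge change from a small change d_eps1 of the region-1 permittivity."""
    dq = (
        d_eps1
        * np.sum(state.phi_r1 * state.dphidn_minus * state.surface.face_areas)
        / state.v0
    )
    return PerturbResult.from_dq(
        dq, state.v0, state.omega, y_base, split={"geometry": 0j, "dielectric": complex(dq)}
    )


def dq_combined(
    state: InterfaceFieldState,
    disp: SurfaceDisplacement | np.ndarray,
    d_eps1: complex,
    y_base: complex | None = None,
    conjugate: bool = False,
) -> PerturbResult:
    """First-order superposition of the geometry and dielectric changes."""
    g = dq_geometry(state, disp, conjugate=conjugate)
    d = dq_dielectric(state, d_eps1)
    dq = g.dq + d.dq
    return PerturbResult.from_dq(
        dq,
        state.v0,
        state.omega,
        y_base,
        split={"geometry": g.dq, "dielectric": d.dq},
    )


@dataclass
class SensitivityMap:
    """Functional derivative of dQ w.r.t. locally swept interface volume.

    ``geometry`` is the per-face kernel (C/m^3 per unit swept volume,
    including the 1/V0 normalisation so that integrating it against d.n dS
    reproduces dQ exactly); ``perfusion_per_volume`` is the uniform
    perfusion term per unit total swept volume (homogeneous blood
    distribution assumption).
    """

    surface: TriSurface
    geometry: np.ndarray
    perfusion_per_volume: complex
    v0: float
    omega: float
    y_base: complex | None = None

    @property
    def total(self) -> np.ndarray:
        return self.geometry + self.perfusion_per_volume


def sensitivity_map(
    state: InterfaceFieldState,
    perfusion=None,
    y_base: complex | None = None,
    conjugate: bool = False,
) -> SensitivityMap:
    """Build the sensitivity map; ``perfusion`` is a mixing_rules.PerfusionModel."""
    geom = _geometry_kernel(state, conjugate=conjugate) / state.v0
    perf = 0j
    if perfusion is not None:
        if perfusion.v_tissue <= 0:
            raise ValueError("perfusion model requires positive tissue volume")
        et, eb = perfusion.eps_tissue.value, perfusion.eps_blood.value
        integral = np.sum(state.phi_r1 * state.dphidn_minus * state.surface.face_areas)
        perf = et / (perfusion.v_tissue * state.v0) * np.log(eb / et) * integral
    return SensitivityMap(
        surface=state.surface,
        geometry=geom,
        perfusion_per_volume=complex(perf),
        v0=state.v0,
        omega=state.omega,
        y_base=y_base,
    )


def dq_from_sensitivity(
    smap: SensitivityMap,
    disp: SurfaceDisplacement | np.ndarray,
    swept_volume: float | None = None,
) -> PerturbResult:
    """Integrate the sensitivity map against a displacement field.

    ``swept_volume`` lets the perfusion term be driven by a total swept
    volume other than this surface's own (e.g. the union of cortical and
    ventricular interfaces); it defaults to this surface's swept volume.
    """
    vec = disp.vectors if isinstance(disp, SurfaceDisplacement) else np.asarray(disp, float)
    if vec.shape != (smap.surface.n_faces, 3):
        raise ValueError("face count mismatch between map and displacement")
    dn_area = np.einsum("fj,fj->f", vec, smap.surface.face_normals) * smap.surface.face_areas
    swept = float(dn_area.sum()) if swept_volume is None else swept_volume
    dq_geom = np.sum(smap.geometry * dn_area)
    dq_perf = smap.perfusion_per_volume * swept
    return PerturbResult.from_dq(
        dq_geom + dq_perf,
        smap.v0,
        smap.omega,
        smap.y_base,
        split={"geometry": complex(dq_geom), "dielectric": complex(dq_perf)},
    )
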