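"""Self-contained synthetic test data: head phantom, pulsation fields, cohorts.

The phantom is a four-layer spherical head (brain, CSF, skull, scalp) with
an ellipsoidal ventricle cavity, triangulated cortical and ventricular
surfaces and three scalp electrode pairs, standing in for an image-based
anatomical model.  The pulsation generator emulates the characteristics of
displacement-encoded (DENSE-like) MRI: smooth sub-100-um brain motion over
20 cardiac phases, two gradient-polarity copies sharing a background error
field, additive voxel noise, and GM/WM probability maps whose eroded mask
excludes CSF-adjacent voxels.

The ground-truth motion is a closed-form field

    d(x,t) = a(t) g(r) r_hat  +  T(t)  +  rot(t) g(r) (e x r_hat)  +  swirl

(radial pulsation, rigid translation, a rotation component, and a
divergence-free off-center vortex nuisance), so the pulsation features of
the generated subject are known exactly.  The radial and rotational terms
are windowed with a plateau envelope g(r) that is constant in the outer
brain shell: brain-surface motion amplitudes do not keep growing linearly
into the parenchyma the way a solid-body field would, and the plateau makes
the surface features well-defined independently of how far inside the
validity mask ends.  Per-subject amplitude and phase-lag heterogeneity
produces the hysteretic signal/feature 'loops' the inference protocol is
tested on.  Everything regenerates bit-identically from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import binary_dilation, generate_binary_structure

from .deformation import (
    DeformationSeries,
    SurfaceDisplacementSeries,
    build_mask,
    erode,
    extract_features,
)
from .em_core import ElectrodePair, VoxelDielectricMap, make_dielectric
from .perturbation import TriSurface

__all__ = [
    "PhantomSpec",
    "Phantom",
    "DeformationGridSpec",
    "SubjectParams",
    "CohortSpec",
    "make_phantom",
    "make_pulsation",
    "make_cohort",
    "subject_parameters",
    "DEFAULT_TISSUES",
]

# Representative head-tissue dielectric parameters at 1 MHz (eps_r, sigma S/m)
DEFAULT_TISSUES = {
    "brain": (900.0, 0.25),
    "csf": (109.0, 2.0),
    "skull": (145.0, 0.021),
    "scalp": (1830.0, 0.22),
    "blood": (3030.0, 0.70),
}

_LABELS = {"brain": 1, "csf": 2, "skull": 3, "scalp": 4}


@dataclass
class PhantomSpec:
    """Layered spherical head phantom for the EM solves."""

    grid_n: int = 48
    box_size: float = 0.2  # m
    r_brain: float = 0.070
    r_csf: float = 0.076
    r_skull: float = 0.082
    r_scalp: float = 0.088
    # common anisotropy of all head layers (anterior-posterior elongated,
    # cranio-caudally flattened); a rotating ellipsoidal brain sweeps volume,
    # so rotation is visible in the impedance signal, unlike for a sphere
    aspect: tuple[float, float, float] = (1.10, 1.0, 0.84)
    ventricle_semiaxes: tuple[float, float, float] = (0.022, 0.016, 0.011)
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    frequency: float = 1e6
    v0: float = 1.0
    patch_edge: float = 0.016
    cortex_subdivisions: int = 3
    ventricle_subdivisions: int = 2

    def __post_init__(self):
        radii = (self.r_brain, self.r_csf, self.r_skull, self.r_scalp)
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing")
        if max(self.ventricle_semiaxes) >= self.r_brain:
            raise ValueError("ventricle must lie strictly inside the brain")


@dataclass
class Phantom:
    spec: PhantomSpec
    vmap: VoxelDielectricMap
    surfaces: dict  # name -> TriSurface (normals out of the brain into CSF)
    electrodes: dict  # 1..3 -> ElectrodePair
    center: np.ndarray
    v_tissue: float  # brain parenchyma volume, m^3
    materials: dict  # name -> ComplexDielectric


def _voxel_centers(n: int, box: float):
    c = (np.arange(n) + 0.5) * (box / n) - box / 2
    return np.meshgrid(c, c, c, indexing="ij")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelise the layered head and build surfaces and electrode pairs.

    The phantom is centered in the grid; world coordinates have their origin
    at the head center.  Electrode patches are background voxels adjacent to
    the scalp within ~16 mm caps along six canonical directions, paired as
    front/back, left/right and front/left (mixed).
    """
    n, box = spec.grid_n, spec.box_size
    X, Y, Z = _voxel_centers(n, box)
    ax, ay, az = spec.aspect
    R = np.sqrt((X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2)
    a, b, c = spec.ventricle_semiaxes
    in_vent = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[R <= spec.r_scalp] = _LABELS["scalp"]
    labels[R <= spec.r_skull] = _LABELS["skull"]
    labels[R <= spec.r_csf] = _LABELS["csf"]
    labels[R <= spec.r_brain] = _LABELS["brain"]
    labels[in_vent] = _LABELS["csf"]

    materials = {
        name: make_dielectric(er, sg, spec.frequency)
        for name, (er, sg) in spec.tissues.items()
    }
    vmap = VoxelDielectricMap(
        labels=labels,
        spacing=(box / n,) * 3,
        materials={lab: materials[name] for name, lab in _LABELS.items()},
        origin=(-box / 2,) * 3,
    )

    # surfaces: cortex outward; ventricle normals flipped to point from brain
    # (region 1, outside the cavity) into the ventricular CSF
    cortex = trimesh.creation.icosphere(
        subdivisions=spec.cortex_subdivisions, radius=spec.r_brain
    )
    cortex.apply_scale(spec.aspect)
    vent = trimesh.creation.icosphere(subdivisions=spec.ventricle_subdivisions, radius=1.0)
    vent.apply_scale(spec.ventricle_semiaxes)
    vent.invert()
    surfaces = {
        "cortex": TriSurface.from_trimesh(cortex),
        "ventricles": TriSurface.from_trimesh(vent),
    }

    active = labels > 0
    struct = generate_binary_structure(3, 1)
    rim = binary_dilation(active, structure=struct) & ~active
    # three mutually asymmetric pairs: an opposed pair is insensitive to
    # rigid translation/rotation by symmetry, so the set mixes opposed and
    # 90-degree placements to give the configurations complementary
    # sensitivity to the different pulsation features
    s2 = 1.0 / np.sqrt(2.0)
    dirs = {
        "front": np.array([0.0, 1.0, 0.0]),
        "back": np.array([0.0, -1.0, 0.0]),
        "left": np.array([1.0, 0.0, 0.0]),
        "top": np.array([0.0, 0.0, 1.0]),
        "topfront": np.array([0.0, s2, s2]),
    }
    half_angle = np.arcsin(0.57 * spec.patch_edge / spec.r_scalp)
    pts = np.stack([X, Y, Z], axis=-1)
    true_r = np.sqrt(X**2 + Y**2 + Z**2)
    unit = pts / np.maximum(true_r, 1e-12)[..., None]
    patches = {}
    for name, d in dirs.items():
        ang = np.arccos(np.clip(unit @ d, -1, 1))
        patch = rim & (ang <= half_angle)
        if not patch.any():
            # coarse grids: fall back to the rim voxel closest to the axis
            ang_rim = np.where(rim, ang, np.inf)
            patch = ang_rim == ang_rim.min()
        patches[name] = patch
    pairs = {1: ("front", "back"), 2: ("topfront", "back"), 3: ("left", "top")}
    electrodes = {
        k: ElectrodePair(
            patch_a=patches[pa],
            patch_b=patches[pb],
            v0=spec.v0,
            frequency=spec.frequency,
            patch_edge=spec.patch_edge,
        )
        for k, (pa, pb) in pairs.items()
    }

    vent_volume = 4.0 / 3.0 * np.pi * a * b * c
    v_tissue = 4.0 / 3.0 * np.pi * spec.r_brain**3 - vent_volume
    return Phantom(
        spec=spec,
        vmap=vmap,
        surfaces=surfaces,
        electrodes=electrodes,
        center=np.zeros(3),
        v_tissue=v_tissue,
        materials=materials,
    )


# ---------------------------------------------------------------------------
# DENSE-like pulsation fields
# ---------------------------------------------------------------------------


@dataclass
class DeformationGridSpec:
    """Voxel grid of the displacement acquisition (independent of the EM grid)."""

    grid_n: int = 64
    box_size: float = 0.2

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.box_size / self.grid_n,) * 3

    @property
    def origin(self) -> tuple[float, float, float]:
        return (-self.box_size / 2,) * 3


@dataclass
class SubjectParams:
    """Per-subject ground-truth motion parameters (amplitudes in meters)."""

    radial_amp: float = 30e-6
    trans_amp: float = 15e-6
    rot_amp: float = 40e-6  # tangential surface amplitude; RS ~ rot_amp/r_brain
    swirl_amp: float = 3e-6
    vent_amp: float = 8e-6
    # anatomically consistent preferred directions (cranio-caudal shift,
    # nodding rotation about the left-right axis); subjects jitter around them
    trans_dir: tuple[float, float, float] = (0.1, 0.25, 0.96)
    rot_axis: tuple[float, float, float] = (1.0, 0.1, 0.1)
    shape2: float = 0.35  # second-harmonic fraction of the waveform
    shape2_phase: float = 0.6
    lag_ts: float = 0.06  # cycle-fraction lag of TS behind dVCSF
    lag_rs: float = -0.08
    lag_swirl: float = 0.1


@dataclass
class CohortSpec:
    """Synthetic multi-subject study conditions."""

    n_subjects: int = 8
    n_phases: int = 20
    noise_std: float = 10e-6  # m, per-voxel per-polarity
    background_amp: float = 50e-6  # m, shared polarity background error
    amp_heterogeneity: float = 0.35  # relative spread of subject amplitudes
    lag_heterogeneity: float = 0.08  # cycle-fraction spread of phase lags
    seed: int = 0


def _waveform(n_phases: int, lag: float, shape2: float, shape2_phase: float) -> np.ndarray:
    u = np.arange(n_phases) / n_phases
    return np.sin(2 * np.pi * (u - lag)) + shape2 * np.sin(
        4 * np.pi * (u - lag) + shape2_phase
    )


def _smoothstep(r, r0, r1):
    t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _ground_truth_field(points: np.ndarray, params: SubjectParams, phantom_spec: PhantomSpec,
                        n_phases: int) -> np.ndarray:
    """Closed-form displacement (n_phases, n_points, 3) at arbitrary points."""
    p = np.asarray(points, dtype=float)
    r_true = np.linalg.norm(p, axis=-1)
    rhat = p / np.maximum(r_true, 1e-12)[:, None]
    # envelopes are keyed on the layer-scaled radius so the plateaus follow
    # the (ellipsoidal) anatomical surfaces
    r = np.linalg.norm(p / np.asarray(phantom_spec.aspect), axis=-1)

    # envelopes (scaled to the brain radius): the cortical terms are zero in
    # the deep brain and plateau across the outer shell, the ventricular term
    # plateaus around the cavity and vanishes by mid-brain — each surface and
    # its masked neighbourhood sees a locally uniform amplitude
    rb = phantom_spec.r_brain
    g = _smoothstep(r, 0.57 * rb, 0.79 * rb)
    gv = 1.0 - _smoothstep(r, 0.50 * rb, 0.71 * rb)
    # divergence-free vortex nuisance: curl of an off-center Gaussian stream
    # function (0, 0, psi), unit peak magnitude, buried mid-parenchyma so its
    # footprint on both surfaces is negligible
    sig = 0.12 * rb
    vortex_center = (rb / 0.07) * np.array([0.030, -0.024, 0.018])
    dp = p - vortex_center
    rho = np.linalg.norm(dp, axis=-1)
    psi = np.exp(-(rho**2) / (2 * sig**2))
    swirl = np.stack([dp[:, 1], -dp[:, 0], np.zeros(len(p))], axis=1) * (
        np.e**0.5 * psi / sig
    )[:, None]

    # cortical and ventricular pulsation share one waveform: both are driven
    # by the same cerebral blood volume change (Monro-Kellie coupling)
    a_t = params.radial_amp * _waveform(n_phases, 0.0, params.shape2, params.shape2_phase)
    av_t = params.vent_amp * _waveform(n_phases, 0.0, params.shape2, params.shape2_phase)
    t_t = params.trans_amp * _waveform(n_phases, params.lag_ts, params.shape2, params.shape2_phase)
    th_t = params.rot_amp * _waveform(n_phases, params.lag_rs, params.shape2, params.shape2_phase)
    sw_t = params.swirl_amp * _waveform(
        n_phases, params.lag_swirl, params.shape2, params.shape2_phase
    )

    e_t = np.asarray(params.trans_dir, float)
    e_t = e_t / np.linalg.norm(e_t)
    e_r = np.asarray(params.rot_axis, float)
    e_r = e_r / np.linalg.norm(e_r)
    # windowed rotation about the craniocervical pivot below the brain: the
    # tangential part has a plateau magnitude over both surfaces (each surface
    # moves like a rigid rotation of tangential amplitude rot_amp) and the
    # off-center pivot adds the rotation-locked uniform shift Theta x (-p)
    rot_field = np.cross(e_r[None, :], rhat) * np.minimum(g + gv, 1.0)[:, None]
    pivot = np.array([0.0, 0.0, -0.81 * rb])
    rot_field = rot_field + np.cross(e_r, -pivot)[None, :] / rb

    out = (
        a_t[:, None, None] * (g[:, None] * rhat)[None]
        + av_t[:, None, None] * (gv[:, None] * rhat)[None]
        + t_t[:, None, None] * e_t[None, None, :]
        + th_t[:, None, None] * rot_field[None]
        + sw_t[:, None, None] * swirl[None]
    )
    return out


def _probability_maps(dgrid: DeformationGridSpec, spec: PhantomSpec):
    n, box = dgrid.grid_n, dgrid.box_size
    X, Y, Z = _voxel_centers(n, box)
    ax, ay, az = spec.aspect
    R = np.sqrt((X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2)
    a, b, c = spec.ventricle_semiaxes
    in_vent = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    brain = (R <= spec.r_brain) & ~in_vent
    gm = (brain & (R > 0.045)).astype(float)
    wm = (brain & (R <= 0.045)).astype(float)
    csf = (((R > spec.r_brain) & (R <= spec.r_csf)) | in_vent).astype(float)
    return gm, wm, csf


def make_pulsation(
    phantom_spec: PhantomSpec,
    params: SubjectParams,
    cohort: CohortSpec,
    rng: np.random.Generator,
    dgrid: DeformationGridSpec | None = None,
    surfaces: dict | None = None,
    noise_free: bool = False,
) -> dict:
    """One subject's DENSE-like polarity pair plus exact ground truth.

    Returns a dict with ``pos``/``neg`` DeformationSeries (masked with the
    eroded GM/WM mask), the probability maps, the exact surface displacement
    series and the ground-truth features per surface.
    """
    if dgrid is None:
        dgrid = DeformationGridSpec()
    n = dgrid.grid_n
    X, Y, Z = _voxel_centers(n, dgrid.box_size)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    truth = _ground_truth_field(pts, params, phantom_spec, cohort.n_phases)
    truth = truth.reshape(cohort.n_phases, n, n, n, 3)

    gm, wm, csf = _probability_maps(dgrid, phantom_spec)
    mask = erode(build_mask(gm, wm, csf), 3)

    shape = truth.shape
    if noise_free:
        background = np.zeros(shape)
        noise_pos = np.zeros(shape)
        noise_neg = np.zeros(shape)
    else:
        background = _smooth_background(rng, dgrid, cohort.background_amp, cohort.n_phases)
        noise_pos = rng.normal(0.0, cohort.noise_std, size=shape)
        noise_neg = rng.normal(0.0, cohort.noise_std, size=shape)

    common = dict(spacing=dgrid.spacing, origin=dgrid.origin, mask=mask)
    pos = DeformationSeries(disp=truth + background + noise_pos, **common)
    neg = DeformationSeries(disp=-truth + background + noise_neg, **common)

    gt_surface = {}
    gt_features = {}
    if surfaces:
        for name, surf in surfaces.items():
            d = _ground_truth_field(
                surf.face_centroids, params, phantom_spec, cohort.n_phases
            )
            sds = SurfaceDisplacementSeries(surface=surf, disp=d, method="ground-truth")
            gt_surface[name] = sds
            gt_features[name] = extract_features(sds)

    return {
        "pos": pos,
        "neg": neg,
        "prob_maps": (gm, wm, csf),
        "mask": mask,
        "truth": truth,
        "gt_surface": gt_surface,
        "gt_features": gt_features,
        "params": params,
    }


def _smooth_background(rng, dgrid: DeformationGridSpec, amp: float, n_phases: int):
    """Low-order smooth background field shared by the two polarities."""
    n = dgrid.grid_n
    X, Y, Z = _voxel_centers(n, dgrid.box_size)
    u = np.stack([X, Y, Z], axis=-1) / (dgrid.box_size / 2)
    out = np.zeros((n_phases, n, n, n, 3))
    for comp in range(3):
        coef = rng.normal(size=4)
        fieldc = coef[0] + coef[1] * u[..., 0] + coef[2] * u[..., 1] + coef[3] * u[..., 2]
        out[..., comp] = amp * fieldc[None] / np.sqrt(4.0)
    return out


def subject_parameters(cohort: CohortSpec) -> list[SubjectParams]:
    """Heterogeneous per-subject motion parameters, reproducible from the seed."""
    rng = np.random.default_rng(cohort.seed)
    base = SubjectParams()
    out = []
    for _ in range(cohort.n_subjects):
        h = cohort.amp_heterogeneity
        lh = cohort.lag_heterogeneity

        def amp(x):
            return float(x * (1.0 + h * rng.uniform(-1, 1)))

        def jittered(direction):
            v = np.asarray(direction, float) + 0.08 * rng.normal(size=3)
            return tuple(v / np.linalg.norm(v))

        out.append(
            SubjectParams(
                radial_amp=(ra := amp(base.radial_amp)),
                trans_amp=amp(base.trans_amp),
                rot_amp=amp(base.rot_amp),
                swirl_amp=amp(base.swirl_amp),
                # ventricular amplitude tied to the cortical one: both surfaces
                # respond to the same blood volume change
                vent_amp=ra * base.vent_amp / base.radial_amp,
                trans_dir=jittered(base.trans_dir),
                rot_axis=jittered(base.rot_axis),
                # waveform-family constants (harmonic phase, nuisance lag) are
                # population properties; subjects differ in amplitudes, lags
                # and directions
                shape2=float(np.clip(base.shape2 + 0.3 * h * rng.uniform(-1, 1), 0.05, 0.8)),
                shape2_phase=base.shape2_phase,
                lag_ts=float(base.lag_ts + lh * rng.uniform(-1, 1)),
                lag_rs=float(base.lag_rs + lh * rng.uniform(-1, 1)),
                lag_swirl=base.lag_swirl,
            )
        )
    return out


def make_cohort(
    cohort: CohortSpec,
    phantom_spec: PhantomSpec | None = None,
    dgrid: DeformationGridSpec | None = None,
    surfaces: dict | None = None,
    noise_free: bool = False,
):
    """Generator yielding (params, subject-data dict) per synthetic subject."""
    if phantom_spec is None:
        phantom_spec = PhantomSpec()
    seeds = np.random.SeedSequence(cohort.seed).spawn(cohort.n_subjects)
    for params, ss in zip(subject_parameters(cohort), seeds):
        rng = np.random.default_rng(ss)
        yield params, make_pulsation(
            phantom_spec, params, cohort, rng, dgrid=dgrid, surfaces=surfaces,
            noise_free=noise_free,
        )
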