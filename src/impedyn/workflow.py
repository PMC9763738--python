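"""End-to-end drivers tying the solver, perturbation and pipeline together.

These are thin orchestration helpers: solve the phantom once per electrode
configuration, extract interface field states on the cortical and
ventricular surfaces, build sensitivity maps (geometry + perfusion), run
the deformation pipeline per subject and synthesise the transient dC/dR
signals and pulsation features for a whole synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import deformation as dfm
from .em_core import solve_quasistatic, total_charge
from .mixing_rules import PerfusionModel
from .perturbation import extract_interface_fields, sensitivity_map
from .signal_analysis import ImpedanceSignalSet, transient_signals
from .synthetic import CohortSpec, DeformationGridSpec, Phantom, make_cohort

__all__ = [
    "compute_sensitivity_maps",
    "process_subject",
    "run_cohort_study",
    "CohortStudy",
]


def compute_sensitivity_maps(phantom: Phantom, configs=None, tol: float = 1e-10) -> dict:
    """Solve the phantom per electrode configuration and map sensitivities.

    Returns ``{config: {"cortex": SensitivityMap, "ventricles": ...}}``; each
    map carries the base admittance (for dR) and the uniform perfusion term
    (Lichtenecker-linearised brain/blood mixing, homogeneous perfusion).
    """
    if configs is None:
        configs = sorted(phantom.electrodes)
    eps_brain = phantom.materials["brain"]
    eps_csf = phantom.materials["csf"]
    eps_blood = phantom.materials["blood"]
    perfusion = PerfusionModel(
        eps_tissue=eps_brain, eps_blood=eps_blood, dv_total=0.0, v_tissue=phantom.v_tissue
    )
    out = {}
    for config in configs:
        electrodes = phantom.electrodes[config]
        field = solve_quasistatic(phantom.vmap, electrodes, tol=tol)
        base = total_charge(field, phantom.vmap, electrodes)
        per_iface = {}
        for name, surface in phantom.surfaces.items():
            state = extract_interface_fields(
                field, phantom.vmap, surface, eps1=eps_brain, eps2=eps_csf,
                v0=electrodes.v0,
            )
            per_iface[name] = sensitivity_map(state, perfusion=perfusion, y_base=base.y)
        out[config] = {"maps": per_iface, "base": base}
    return out


@dataclass
class SharedPipeline:
    """Mask-dependent objects reused across subjects sharing one grid/mask."""

    knn_indices: np.ndarray | None = None
    extrapolator: dfm.FourierExtrapolator | None = None


def process_subject(
    subject: dict,
    surfaces: dict,
    method: str = "nn",
    knn_k: int | None = 150,
    shared: SharedPipeline | None = None,
    fft_harmonics: int = 5,
    fft_pad: float = 1.0,
) -> dict:
    """Polarity subtraction, smoothing and surface reconstruction for one subject.

    ``subject`` is a dict from :func:`impedyn.synthetic.make_pulsation`.
    Returns the reconstructed SurfaceDisplacementSeries and extracted
    PulsationFeatures per surface.
    """
    field = dfm.remove_background(subject["pos"], subject["neg"])
    if knn_k:
        field = dfm.knn_smooth(field, k=knn_k)
    sds = {}
    feats = {}
    extrap = shared.extrapolator if shared is not None else None
    for name, surf in surfaces.items():
        if method == "nn":
            s = dfm.nn_extrapolate(field, surf)
        elif method == "fft":
            if extrap is None:
                extrap = dfm.FourierExtrapolator(
                    field.masked_coordinates(), n_harmonics=fft_harmonics, pad=fft_pad
                )
                if shared is not None:
                    shared.extrapolator = extrap
            s = dfm.fft_extrapolate(field, surf, extrapolator=extrap)
        else:
            raise ValueError(f"unknown reconstruction method {method!r}")
        sds[name] = s
        feats[name] = dfm.extract_features(s)
    return {"field": field, "sds": sds, "features": feats}


@dataclass
class CohortStudy:
    """Signals, features and ground truth for a synthetic cohort."""

    signals: list  # per subject: ImpedanceSignalSet
    features: list  # per subject: {interface: PulsationFeatures}
    gt_features: list
    params: list

    def signal_array(self) -> np.ndarray:
        """(n_subjects, n_signals, n_phases) total dC/dR stacks."""
        return np.stack([s.signal_matrix() for s in self.signals])

    def feature_array(
        self,
        interface: str = "cortex",
        source: str = "pipeline",
        components=("dvcsf", "ts_z", "rs_x"),
    ) -> np.ndarray:
        """(n_subjects, n_components, n_phases) feature curves.

        Defaults to the signed curves used for inference: CSF volume change,
        cranio-caudal translation and nodding rotation.
        """
        feats = self.features if source == "pipeline" else self.gt_features
        return np.stack([f[interface].curves(components) for f in feats])


def run_cohort_study(
    phantom: Phantom,
    cohort: CohortSpec,
    smaps: dict | None = None,
    dgrid: DeformationGridSpec | None = None,
    method: str = "nn",
    knn_k: int | None = 150,
    noise_free: bool = False,
) -> CohortStudy:
    """Generate a cohort, run the pipeline and synthesise signals per subject."""
    if smaps is None:
        smaps = compute_sensitivity_maps(phantom)
    maps_only = {cfg: d["maps"] for cfg, d in smaps.items()}
    signals, features, gt_features, params_list = [], [], [], []
    for params, subject in make_cohort(
        cohort, phantom.spec, dgrid=dgrid, surfaces=phantom.surfaces,
        noise_free=noise_free,
    ):
        proc = process_subject(subject, phantom.surfaces, method=method, knn_k=knn_k)
        signals.append(transient_signals(maps_only, proc["sds"]))
        features.append(proc["features"])
        gt_features.append(subject["gt_features"])
        params_list.append(params)
    return CohortStudy(
        signals=signals, features=features, gt_features=gt_features, params=params_list
    )
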