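"""From sensitivity maps and surface motion to impedance signals and inference.

``transient_signals`` combines per-electrode-configuration sensitivity maps
with reconstructed surface displacement series into transient capacitance
and resistance changes dC_k(t), dR_k(t), split by interface (cortex /
ventricles) and mechanism (geometry / perfusion); the perfusion drive is
the Monro-Kellie coupled blood volume change dv_total(t) = -dVCSF(t).
Signals are referenced to a fixed cardiac phase (the third snapshot).

``pca_ridge_fit``/``predict_features`` implement subject-specific inference
of pulsation features from measurable signals: per-subject concatenated
(signals + features) vectors are decomposed by PCA, the components are
projected to the measurement and feature sub-spaces and renormalised, and
ridge regression maps measurement-subspace coordinates to feature-subspace
coordinates.  ``compare_baselines`` runs the Shapiro-Wilk / Wilcoxon
protocol against non-personalised baselines.

The uncertainty budget combines log-normal dielectric-property
uncertainties via sensitivity coefficients in dB/dB and a root sum of
squares, plus a grid-convergence estimate of the numerical uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .deformation import SurfaceDisplacementSeries
from .perturbation import SensitivityMap

__all__ = [
    "ImpedanceSignalSet",
    "ScalingFit",
    "PCAInferenceModel",
    "UncertaintyBudget",
    "transient_signals",
    "fit_scale_offset",
    "pca_ridge_fit",
    "predict_features",
    "deviation_metric",
    "compare_baselines",
    "sensitivity_coefficients",
    "combine_uncertainty",
    "gridconv_extrapolate",
    "to_db",
]

REFERENCE_PHASE = 2  # third snapshot of the cardiac cycle


@dataclass
class ImpedanceSignalSet:
    """Transient dC (F) and dR (Ohm) per (config, interface, mechanism).

    ``dc``/``dr`` map keys ``(config, interface, mechanism)`` with mechanism
    in {"geometry", "perfusion"} to arrays over cardiac phases; splits sum
    to the total signal exactly.
    """

    dc: dict
    dr: dict
    n_phases: int
    reference_phase: int = REFERENCE_PHASE

    def total(self, config, which: str = "dc", interface=None) -> np.ndarray:
        src = self.dc if which == "dc" else self.dr
        out = np.zeros(self.n_phases)
        for (cfg, iface, mech), series in src.items():
            if cfg == config and (interface is None or iface == interface):
                out = out + series
        return out

    def configs(self):
        return sorted({k[0] for k in self.dc})

    def signal_matrix(self, which=("dc", "dr")) -> np.ndarray:
        """(n_signals, n_phases) stack of total signals, configs x {dC, dR}."""
        rows = [self.total(cfg, w) for cfg in self.configs() for w in which]
        return np.stack(rows)


def transient_signals(
    smaps: dict,
    sds: dict,
    reference_phase: int = REFERENCE_PHASE,
) -> ImpedanceSignalSet:
    """Per-phase dC/dR from sensitivity maps x surface displacement.

    ``smaps[config][interface]`` are :class:`SensitivityMap` (with base
    admittance for the dR linearisation), ``sds[interface]`` the
    reconstructed surface series.  The perfusion term of every interface is
    driven by the global swept volume over all interfaces (homogeneous
    perfusion of the whole parenchyma).
    """
    interfaces = sorted(sds)
    any_sds = sds[interfaces[0]]
    n_phases = any_sds.n_phases

    dn_area = {
        name: np.einsum(
            "pfj,fj,f->pf",
            sds[name].disp,
            sds[name].surface.face_normals,
            sds[name].surface.face_areas,
        )
        for name in interfaces
    }
    swept_total = sum(dn_area[name].sum(axis=1) for name in interfaces)

    dc: dict = {}
    dr: dict = {}
    for config, per_iface in smaps.items():
        for name in interfaces:
            smap: SensitivityMap = per_iface[name]
            if smap.surface.n_faces != sds[name].surface.n_faces:
                raise ValueError(f"face count mismatch for interface {name!r}")
            dq_geom = dn_area[name] @ smap.geometry
            dq_perf = smap.perfusion_per_volume * swept_total
            for mech, dq in (("geometry", dq_geom), ("perfusion", dq_perf)):
                dy = 1j * smap.omega * dq / smap.v0
                c_series = dy.imag / smap.omega
                if smap.y_base is None or smap.y_base.real == 0:
                    r_series = np.full(n_phases, np.nan)
                else:
                    r_series = -dy.real / smap.y_base.real**2
                dc[(config, name, mech)] = c_series - c_series[reference_phase]
                dr[(config, name, mech)] = r_series - r_series[reference_phase]
    return ImpedanceSignalSet(dc=dc, dr=dr, n_phases=n_phases, reference_phase=reference_phase)


# ---------------------------------------------------------------------------
# cohort amplitude/shape variability
# ---------------------------------------------------------------------------


@dataclass
class ScalingFit:
    """Least-squares scale/offset of each subject's signal onto the mean curve."""

    scale: np.ndarray  # f_i
    offset: np.ndarray  # g_i
    fitted: np.ndarray  # d*_i(t) = f_i d_i(t) + g_i
    reference: np.ndarray
    scale_std: float
    shape_dev_mean: float
    shape_dev_std: float


def fit_scale_offset(signals: np.ndarray, reference: np.ndarray | None = None) -> ScalingFit:
    """Fit d*_i = f_i d_i + g_i to the reference (default: cohort mean) curve."""
    signals = np.asarray(signals, dtype=float)
    if reference is None:
        reference = signals.mean(axis=0)
    scale = np.empty(len(signals))
    offset = np.empty(len(signals))
    for i, d in enumerate(signals):
        A = np.stack([d, np.ones_like(d)], axis=1)
        (scale[i], offset[i]), *_ = np.linalg.lstsq(A, reference, rcond=None)
    fitted = scale[:, None] * signals + offset[:, None]
    ref_norm = np.linalg.norm(reference)
    devs = np.linalg.norm(fitted - reference, axis=1) / ref_norm
    return ScalingFit(
        scale=scale,
        offset=offset,
        fitted=fitted,
        reference=reference,
        scale_std=float(scale.std(ddof=1)) if len(signals) > 1 else 0.0,
        shape_dev_mean=float(devs.mean()),
        shape_dev_std=float(devs.std(ddof=1)) if len(signals) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# PCA + ridge feature inference
# ---------------------------------------------------------------------------


@dataclass
class PCAInferenceModel:
    """PCA of concatenated (signals, features) vectors + ridge subspace map."""

    mean: np.ndarray
    components_meas: np.ndarray  # (n_comp, Dm), rows renormalised
    components_feat: np.ndarray  # (n_comp, Df)
    ridge_matrix: np.ndarray  # maps measurement coords -> feature coords
    ridge_alpha: float
    n_meas: int
    n_feat: int
    norm_mean: np.ndarray
    norm_std: np.ndarray
    block_slices_meas: list
    block_slices_feat: list

    def _meas_coords(self, z_meas: np.ndarray) -> np.ndarray:
        a, *_ = np.linalg.lstsq(self.components_meas.T, z_meas - self.mean[: self.n_meas],
                                rcond=None)
        return a


def _normalize_blocks(X: np.ndarray, n_blocks: int):
    """Z-score each equal-length sub-series block across the whole cohort."""
    n, D = X.shape
    L = D // n_blocks
    mean = np.empty(D)
    std = np.empty(D)
    for b in range(n_blocks):
        sl = slice(b * L, (b + 1) * L)
        mu = X[:, sl].mean()
        sd = X[:, sl].std()
        mean[sl] = mu
        std[sl] = sd if sd > 0 else 1.0
    return (X - mean) / std, mean, std


def pca_ridge_fit(
    signals: np.ndarray,
    features: np.ndarray,
    n_components: int | None = None,
    ridge_alpha: float | None = None,
) -> PCAInferenceModel:
    """Fit the PCA + ridge inference model on a cohort.

    ``signals`` is (n_subjects, n_signals, n_phases) and ``features``
    (n_subjects, n_features, n_phases).  Each sub-series is z-scored across
    the cohort before concatenation.  The ridge penalty defaults to
    leave-one-out cross-validation over a log grid.
    """
    signals = np.asarray(signals, dtype=float)
    features = np.asarray(features, dtype=float)
    n_sub, ns, nt = signals.shape
    nf = features.shape[1]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_components is None:
        n_components = n_sub - 1
    if n_components > n_sub - 1:
        raise ValueError(f"n_components must be <= n_subjects-1 = {n_sub - 1}")

    Xm = signals.reshape(n_sub, ns * nt)
    Xf = features.reshape(n_sub, nf * nt)
    X = np.concatenate([Xm, Xf], axis=1)
    Z, norm_mean, norm_std = _normalize_blocks(X, ns + nf)
    Dm = ns * nt

    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components)
    pca.fit(Z)
    W = pca.components_
    mean = pca.mean_

    def renorm(rows):
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return rows / norms

    Wm = renorm(W[:, :Dm])
    Wf = renorm(W[:, Dm:])

    # training coordinates in the two renormalised sub-spaces
    A = np.linalg.lstsq(Wm.T, (Z[:, :Dm] - mean[:Dm]).T, rcond=None)[0].T
    Bc = np.linalg.lstsq(Wf.T, (Z[:, Dm:] - mean[Dm:]).T, rcond=None)[0].T

    from sklearn.linear_model import Ridge, RidgeCV

    if ridge_alpha is None:
        rcv = RidgeCV(alphas=np.logspace(-4, 2, 13), fit_intercept=False)
        rcv.fit(A, Bc)
        ridge_alpha = float(rcv.alpha_)
        R = rcv.coef_.T
    else:
        rr = Ridge(alpha=ridge_alpha, fit_intercept=False)
        rr.fit(A, Bc)
        R = rr.coef_.T

    return PCAInferenceModel(
        mean=mean,
        components_meas=Wm,
        components_feat=Wf,
        ridge_matrix=R,
        ridge_alpha=ridge_alpha,
        n_meas=Dm,
        n_feat=nf * nt,
        norm_mean=norm_mean,
        norm_std=norm_std,
        block_slices_meas=[slice(i * nt, (i + 1) * nt) for i in range(ns)],
        block_slices_feat=[slice(i * nt, (i + 1) * nt) for i in range(nf)],
    )


def predict_features(model: PCAInferenceModel, subject_signals: np.ndarray) -> np.ndarray:
    """Infer a subject's feature curves from its signals.

    ``subject_signals`` is (n_signals, n_phases); returns (n_features,
    n_phases) on the physical scale of the training features.
    """
    flat = np.asarray(subject_signals, dtype=float).reshape(-1)
    zm = (flat - model.norm_mean[: model.n_meas]) / model.norm_std[: model.n_meas]
    a = model._meas_coords(zm)
    b = a @ model.ridge_matrix
    zf = model.mean[model.n_meas :] + b @ model.components_feat
    xf = zf * model.norm_std[model.n_meas :] + model.norm_mean[model.n_meas :]
    nt = model.block_slices_feat[0].stop - model.block_slices_feat[0].start
    return xf.reshape(-1, nt)


def deviation_metric(x: np.ndarray, x_hat: np.ndarray,
                     normalization: str = "geometric") -> float:
    """Normalised mismatch |x - x_hat| / sqrt(|x| * |x_hat|) (L2 norms).

    The default geometric-mean normalisation is symmetric in the two curves;
    it is 0 for perfect agreement and 2 for x_hat = -x at equal norms.
    ``normalization="reference"`` divides by |x| instead.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if normalization == "geometric":
        denom = np.sqrt(np.linalg.norm(x) * np.linalg.norm(x_hat))
    elif normalization == "reference":
        denom = np.linalg.norm(x)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        return 0.0 if np.allclose(x, x_hat) else np.inf
    return float(np.linalg.norm(x - x_hat) / denom)


def _paired_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Shapiro-Wilk on the differences, then one-sided Wilcoxon (a < b)."""
    d = np.asarray(a) - np.asarray(b)
    if np.allclose(d, 0):
        return {"shapiro_p": 1.0, "wilcoxon_p": 1.0, "significant_5": False,
                "significant_1": False}
    sw = stats.shapiro(d).pvalue if len(d) >= 3 else np.nan
    w = stats.wilcoxon(a, b, alternative="less").pvalue
    return {
        "shapiro_p": float(sw),
        "wilcoxon_p": float(w),
        "significant_5": bool(w < 0.05),
        "significant_1": bool(w < 0.01),
    }


def compare_baselines(
    deviations_pred: np.ndarray,
    deviations_mean: np.ndarray,
    deviations_between: np.ndarray,
) -> dict:
    """Statistical comparison of personalised predictions against baselines.

    Inputs are per-subject deviation values: of the prediction from the true
    curve, of the true curve from the cohort mean, and the inter-subject
    variability (mean deviation from the other subjects).  Returns the
    Shapiro-Wilk and paired one-sided Wilcoxon results for prediction vs
    each baseline.
    """
    return {
        "pred_vs_mean": _paired_test(deviations_pred, deviations_mean),
        "pred_vs_between": _paired_test(deviations_pred, deviations_between),
    }


def loo_predictions(
    signals: np.ndarray,
    features: np.ndarray,
    n_components: int | None = None,
    ridge_alpha: float | None = None,
) -> np.ndarray:
    """Leave-one-out feature predictions for every subject, (n_sub, nf, nt)."""
    signals = np.asarray(signals, dtype=float)
    features = np.asarray(features, dtype=float)
    n_sub = len(signals)
    out = np.empty_like(features)
    for i in range(n_sub):
        keep = np.arange(n_sub) != i
        model = pca_ridge_fit(
            signals[keep], features[keep], n_components=n_components,
            ridge_alpha=ridge_alpha,
        )
        out[i] = predict_features(model, signals[i])
    return out


# ---------------------------------------------------------------------------
# uncertainty budget
# ---------------------------------------------------------------------------


def to_db(x: float) -> float:
    """Amplitude ratio in dB (20 log10)."""
    return 20.0 * np.log10(x)


def sensitivity_coefficients(
    runner,
    tissues,
    properties=("sigma", "eps_r"),
    perturbation: float = 0.20,
) -> dict:
    """Sensitivity s = d(QoI in dB)/d(input in dB) per tissue and property.

    ``runner(tissue, prop, factor)`` re-evaluates the quantities of interest
    (a dict of positive scalars, e.g. peak-to-peak dC and dR) with one tissue
    property scaled by ``factor``; coefficients use the central difference
    between the +perturbation and -perturbation runs.
    """
    din = to_db(1 + perturbation) - to_db(1 - perturbation)
    table: dict = {}
    for tissue in tissues:
        for prop in properties:
            hi = runner(tissue, prop, 1 + perturbation)
            lo = runner(tissue, prop, 1 - perturbation)
            table[(tissue, prop)] = {
                q: (to_db(hi[q]) - to_db(lo[q])) / din for q in hi
            }
    return table


@dataclass
class UncertaintyBudget:
    """Root-sum-of-squares combination of dB uncertainty contributions."""

    contributions: dict  # (tissue, prop) -> dB
    numerical: float  # dB
    per_property: dict = field(default_factory=dict)
    combined: float = 0.0

    @classmethod
    def combine(cls, contributions: dict, numerical: float) -> "UncertaintyBudget":
        props = sorted({p for (_, p) in contributions})
        per_property = {
            p: float(np.sqrt(sum(v**2 for (t, pp), v in contributions.items() if pp == p)))
            for p in props
        }
        combined = float(np.sqrt(sum(v**2 for v in contributions.values()) + numerical**2))
        return cls(
            contributions=dict(contributions),
            numerical=float(numerical),
            per_property=per_property,
            combined=combined,
        )


def combine_uncertainty(
    contributions: dict,
    numerical_db: float,
    input_db: float | None = None,
    s_table: dict | None = None,
    qoi: str | None = None,
) -> UncertaintyBudget:
    """Combined uncertainty u = sqrt(sum (s*u_in)^2 + u_num^2) in dB.

    Either pass per-(tissue, property) dB contributions directly, or a
    sensitivity table from :func:`sensitivity_coefficients` together with
    the per-property input uncertainty ``input_db`` and the QoI name.
    """
    if s_table is not None:
        if input_db is None or qoi is None:
            raise ValueError("s_table requires input_db and qoi")
        contributions = {
            key: abs(vals[qoi]) * input_db for key, vals in s_table.items()
        }
    return UncertaintyBudget.combine(contributions, numerical_db)


def gridconv_extrapolate(h: np.ndarray, values: np.ndarray) -> dict:
    """Power-law grid-convergence extrapolation q(h) = q* + C h^p.

    Returns the extrapolated value, observed order p, the R^2 of the log-log
    error fit, and the deviation of the finest-grid value from the
    extrapolation in dB (the numerical uncertainty).  Requires at least 3
    resolutions; a constant sequence yields zero uncertainty.
    """
    h = np.asarray(h, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(h) < 3:
        raise ValueError("need at least 3 resolutions")
    order = np.argsort(h)
    h, values = h[order], values[order]
    if np.ptp(values) == 0:
        return {"limit": float(values[0]), "order": np.inf, "r2": 1.0,
                "uncertainty_db": 0.0}

    def model(hh, qstar, c, p):
        return qstar + c * hh**p

    # Richardson-style initial guess from the three coarsest/finest points
    q1, q2, q3 = values[2], values[1], values[0]
    r = h[1] / h[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.log(abs((q1 - q2) / max(abs(q2 - q3), 1e-300))) / np.log(h[2] / h[1])
    p0 = float(np.clip(np.nan_to_num(p0, nan=1.0), 0.2, 6.0))
    q0 = q3 + (q3 - q2) / (r**p0 - 1) if r**p0 != 1 else q3
    try:
        popt, _ = optimize.curve_fit(
            model, h, values, p0=[q0, (values[-1] - q0) / h[-1] ** p0, p0], maxfev=20000
        )
    except RuntimeError:
        popt = [q0, (values[-1] - q0) / h[-1] ** p0, p0]
    qstar, c, p = popt
    err = np.abs(values - qstar)
    good = err > 0
    r2 = 1.0
    if good.sum() >= 2:
        le, lh = np.log(err[good]), np.log(h[good])
        fit = np.polyfit(lh, le, 1)
        resid = le - np.polyval(fit, lh)
        denom = np.sum((le - le.mean()) ** 2)
        r2 = float(1 - np.sum(resid**2) / denom) if denom > 0 else 1.0
    unc = abs(to_db(abs(values[0] / qstar))) if qstar != 0 else np.inf
    return {"limit": float(qstar), "order": float(p), "r2": r2,
            "uncertainty_db": float(unc)}
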