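"""Transient signals, cohort scaling, PCA+ridge inference and uncertainty."""

import numpy as np
import pytest

from impedyn import signal_analysis as sa
from impedyn.deformation import SurfaceDisplacementSeries
from impedyn.signal_analysis import (
    combine_uncertainty,
    compare_baselines,
    deviation_metric,
    fit_scale_offset,
    gridconv_extrapolate,
    loo_predictions,
    pca_ridge_fit,
    predict_features,
    sensitivity_coefficients,
    to_db,
    transient_signals,
)


class TestTransientSignals:
    def test_zero_motion_gives_zero_signals(self, smaps, phantom):
        maps_only = {cfg: d["maps"] for cfg, d in smaps.items()}
        sds = {
            name: SurfaceDisplacementSeries(surf, np.zeros((5, surf.n_faces, 3)))
            for name, surf in phantom.surfaces.items()
        }
        sig = transient_signals(maps_only, sds)
        for series in sig.dc.values():
            assert not series.any()

    def test_splits_sum_to_total(self, smaps, phantom):
        rng = np.random.default_rng(0)
        maps_only = {cfg: d["maps"] for cfg, d in smaps.items()}
        sds = {
            name: SurfaceDisplacementSeries(
                surf, rng.normal(scale=2e-5, size=(5, surf.n_faces, 3))
            )
            for name, surf in phantom.surfaces.items()
        }
        sig = transient_signals(maps_only, sds)
        total = sig.total(1, "dc")
        manual = sum(
            sig.dc[k] for k in sig.dc if k[0] == 1
        )
        assert np.allclose(total, manual)
        # reference phase is exactly zero
        assert total[sig.reference_phase] == 0

    def test_signals_scale_linearly_with_displacement(self, smaps, phantom):
        rng = np.random.default_rng(1)
        maps_only = {cfg: d["maps"] for cfg, d in smaps.items()}
        base = {
            name: rng.normal(scale=2e-5, size=(5, surf.n_faces, 3))
            for name, surf in phantom.surfaces.items()
        }

        def run(alpha):
            sds = {
                name: SurfaceDisplacementSeries(phantom.surfaces[name], alpha * d)
                for name, d in base.items()
            }
            return transient_signals(maps_only, sds).signal_matrix()

        assert np.allclose(run(3.0), 3.0 * run(1.0), rtol=1e-12)

    def test_cortex_dominates_ventricles_and_perfusion(self, cohort_study):
        sig = cohort_study.signals[0]
        for cfg in sig.configs():
            cortex = np.ptp(sig.total(cfg, "dc", interface="cortex"))
            vent = np.ptp(sig.total(cfg, "dc", interface="ventricles"))
            perf = np.ptp(
                sum(s for k, s in sig.dc.items() if k[0] == cfg and k[2] == "perfusion")
            )
            assert cortex > vent
            assert cortex > perf

    def test_dc_dr_strongly_correlated(self, cohort_study):
        for sig in cohort_study.signals[:3]:
            dc = sig.total(1, "dc")
            dr = sig.total(1, "dr")
            r = np.corrcoef(dc, dr)[0, 1]
            assert abs(r) > 0.9


class TestScalingFit:
    def test_identical_curves_unit_scale(self):
        curves = np.tile(np.sin(np.linspace(0, 2 * np.pi, 20)), (5, 1))
        fit = fit_scale_offset(curves)
        assert np.allclose(fit.scale, 1.0, atol=1e-12)
        assert np.allclose(fit.offset, 0.0, atol=1e-12)
        assert fit.scale_std == pytest.approx(0.0, abs=1e-12)
        assert fit.shape_dev_mean == pytest.approx(0.0, abs=1e-12)

    def test_affine_cohort_recovered_exactly(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 20))
        a = np.array([0.5, 1.0, 2.0, 4.0])
        b = np.array([0.1, -0.2, 0.0, 0.3])
        curves = a[:, None] * base + b[:, None]
        fit = fit_scale_offset(curves, reference=base)
        assert np.allclose(fit.scale, 1 / a, rtol=1e-10)
        assert fit.shape_dev_mean < 1e-12

    def test_scale_spread_grows_with_heterogeneity(self):
        rng = np.random.default_rng(0)
        base = np.sin(np.linspace(0, 2 * np.pi, 20))
        stds = []
        for spread in (0.1, 0.5):
            a = 1 + spread * rng.standard_normal(8)
            fit = fit_scale_offset(a[:, None] * base)
            stds.append(fit.scale_std)
        assert stds[1] > stds[0]


class TestDeviationMetric:
    def test_perfect_agreement(self):
        x = np.linspace(-1, 1, 20)
        assert deviation_metric(x, x) == 0

    def test_sign_flip_is_maximal(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 20))
        assert deviation_metric(x, -x) == pytest.approx(2.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 20))
        assert deviation_metric(x, y) == pytest.approx(deviation_metric(y, x))


class TestInference:
    def test_exact_linear_cohort_recovered(self):
        rng = np.random.default_rng(3)
        lat = rng.normal(size=(8, 4))
        bs = rng.normal(size=(4, 6 * 20))
        bf = rng.normal(size=(4, 3 * 20))
        sig = (lat @ bs).reshape(8, 6, 20)
        feat = (lat @ bf).reshape(8, 3, 20)
        preds = loo_predictions(sig, feat)
        devs = [deviation_metric(feat[i], preds[i]) for i in range(8)]
        # residual is the cross-validated ridge shrinkage, orders below any baseline
        assert max(devs) < 1e-3

    def test_permuted_cohort_no_better_than_mean(self):
        # negative control: shuffled signal-feature pairing carries no signal
        rng = np.random.default_rng(4)
        lat = rng.normal(size=(8, 3))
        sig = (lat @ rng.normal(size=(3, 6 * 20))).reshape(8, 6, 20)
        feat = (rng.normal(size=(8, 3)) @ rng.normal(size=(3, 3 * 20))).reshape(8, 3, 20)
        preds = loo_predictions(sig, feat)
        dev_pred = np.array([deviation_metric(feat[i], preds[i]) for i in range(8)])
        mean_curve = feat.mean(axis=0)
        dev_mean = np.array([deviation_metric(feat[i], mean_curve) for i in range(8)])
        from scipy import stats

        p = stats.wilcoxon(dev_pred, dev_mean, alternative="less").pvalue
        assert p > 0.05

    def test_component_cap_enforced(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(5, 2, 10))
        feat = rng.normal(size=(5, 2, 10))
        with pytest.raises(ValueError):
            pca_ridge_fit(sig, feat, n_components=5)
        with pytest.raises(ValueError):
            pca_ridge_fit(sig[:2], feat[:2])

    def test_prediction_output_shape(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(6, 4, 15))
        feat = rng.normal(size=(6, 2, 15))
        model = pca_ridge_fit(sig, feat)
        pred = predict_features(model, sig[0])
        assert pred.shape == (2, 15)


class TestCompareBaselines:
    def test_identical_samples_not_significant(self):
        d = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        rep = compare_baselines(d, d, d)
        assert rep["pred_vs_mean"]["wilcoxon_p"] == 1.0
        assert not rep["pred_vs_mean"]["significant_5"]

    def test_strict_domination_minimal_p(self):
        # n=8 one-sided signed-rank: smallest attainable p is 2^-8
        a = np.linspace(0.1, 0.2, 8)
        b = a + 0.5
        rep = compare_baselines(a, b, b)
        assert rep["pred_vs_mean"]["wilcoxon_p"] == pytest.approx(1 / 256)
        assert rep["pred_vs_mean"]["significant_1"]


class TestUncertainty:
    def test_sensitivity_definitional_cases(self):
        def runner(tissue, prop, factor):
            return {"flat": 5.0, "proportional": 5.0 * factor}

        table = sensitivity_coefficients(runner, ["brain"], properties=("sigma",))
        s = table[("brain", "sigma")]
        assert s["flat"] == pytest.approx(0.0, abs=1e-12)
        assert s["proportional"] == pytest.approx(1.0, rel=1e-12)

    def test_combination_trivial_cases(self):
        assert combine_uncertainty({}, 0.0).combined == 0.0
        single = combine_uncertainty({("csf", "sigma"): 0.7}, 0.0)
        assert single.combined == pytest.approx(0.7)

    def test_combination_monotone_and_permutation_invariant(self):
        a = {("t1", "sigma"): 0.3, ("t2", "eps"): 0.4}
        b = {("t2", "eps"): 0.4, ("t1", "sigma"): 0.3}
        assert combine_uncertainty(a, 0.1).combined == combine_uncertainty(b, 0.1).combined
        bigger = {("t1", "sigma"): 0.5, ("t2", "eps"): 0.4}
        assert combine_uncertainty(bigger, 0.1).combined > combine_uncertainty(a, 0.1).combined

    def test_input_db_path_matches_manual(self):
        table = {("t", "sigma"): {"q": 0.5}}
        u_in = to_db(1.1)
        budget = combine_uncertainty({}, 0.2, input_db=u_in, s_table=table, qoi="q")
        assert budget.combined == pytest.approx(np.hypot(0.5 * u_in, 0.2))


class TestGridConvergence:
    def test_exact_quadratic_sequence(self):
        h = np.array([0.4, 0.2, 0.1, 0.05])
        q = 3.0 + 5.0 * h**2
        res = gridconv_extrapolate(h, q)
        assert res["limit"] == pytest.approx(3.0, rel=1e-6)
        assert res["order"] == pytest.approx(2.0, rel=1e-3)
        assert res["r2"] > 0.999

    def test_constant_sequence_zero_uncertainty(self):
        res = gridconv_extrapolate([0.4, 0.2, 0.1], [2.0, 2.0, 2.0])
        assert res["uncertainty_db"] == 0.0
        assert res["limit"] == 2.0

    def test_slab_capacitance_extrapolates_to_closed_form(self):
        from impedyn import benchmarks as bm
        from impedyn import voxelize
        from impedyn.em_core import solve_quasistatic, total_charge

        spec = bm.SlabSpec()
        exact = abs(bm.slab_solution(spec).charge())
        hs, qs = [], []
        for n in (9, 27, 81):
            vmap, el = voxelize.voxelize_slab(spec, n)
            res = total_charge(solve_quasistatic(vmap, el), vmap, el)
            hs.append(spec.length / n)
            qs.append(abs(res.q))
        out = gridconv_extrapolate(hs, qs)
        assert out["limit"] == pytest.approx(exact, rel=0.005)
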