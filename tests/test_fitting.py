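"""Two-stage fitting: normalization, open-loop initialization, sinusoid
regression, closed-loop fine-tuning, visual fitting, and the cancellation
re-fit."""

import numpy as np
import pytest

from vorloop.circuit import frequency_response_dark, loop_gain
from vorloop.fitting import (
    RegularizationSpec,
    denormalize_traces,
    finetune_nonvisual,
    finetune_visual,
    fit_sine,
    normalize_signals,
    normalize_traces,
    openloop_init,
    openloop_learning_init,
    refit_kPT_post,
    sweep_feedback,
    vor_gain_phase,
)
from vorloop.fitting import _DarkCost, _lit_response

DT = 5e-4


class TestNormalization:
    def test_constants_match_pooled_sd_oracle(self, dataset_noiseless):
        sd = normalize_signals(dataset_noiseless)
        pools = {"head": [], "eye": [], "purkinje": []}
        for c in dataset_noiseless.battery:
            pools["head"].append(c.H)
            pools["eye"].append(dataset_noiseless.eye[c.name])
            pools["purkinje"].append(dataset_noiseless.purkinje[c.name])
        for k, chunks in pools.items():
            assert abs(sd[k] - np.std(np.concatenate(chunks))) < 1e-12

    def test_round_trip_identity(self, dataset_noiseless):
        normalized, sd = normalize_traces(dataset_noiseless)
        restored = denormalize_traces(normalized, sd)
        for name in dataset_noiseless.eye:
            np.testing.assert_allclose(
                restored[name]["eye"], dataset_noiseless.eye[name],
                rtol=1e-12)
            np.testing.assert_allclose(
                restored[name]["purkinje"],
                dataset_noiseless.purkinje[name], rtol=1e-12)

    def test_scaling_equivariance(self, dataset_noiseless):
        import copy

        sd = normalize_signals(dataset_noiseless)
        doubled = copy.copy(dataset_noiseless)
        doubled.eye = {k: 2 * v for k, v in dataset_noiseless.eye.items()}
        sd2 = normalize_signals(doubled)
        assert abs(sd2["eye"] - 2 * sd["eye"]) < 1e-9
        assert sd2["head"] == sd["head"]


class TestFitSine:
    def test_pure_sine_gain_one_phase_zero(self):
        t = np.arange(8000) * DT
        fr = fit_sine(np.sin(2 * np.pi * 0.5 * t), 0.5, DT)
        assert abs(fr.gain - 1.0) < 1e-9
        assert abs(fr.phase_deg) < 1e-6

    def test_cosine_leads_by_90_degrees(self):
        t = np.arange(8000) * DT
        fr = fit_sine(np.cos(2 * np.pi * 0.5 * t), 0.5, DT)
        assert abs(fr.phase_deg - 90.0) < 1e-6

    def test_requires_one_full_cycle(self):
        with pytest.raises(ValueError):
            fit_sine(np.zeros(100), 0.5, DT)

    def test_noisy_estimate_unbiased_within_mc_bands(self):
        rng = np.random.default_rng(8)
        t = np.arange(40000) * DT
        gains = []
        for _ in range(20):
            x = 2.0 * np.sin(2 * np.pi * 1.0 * t) + rng.standard_normal(
                t.size)
            gains.append(fit_sine(x, 1.0, DT).gain)
        # SE of the mean amplitude ~ sqrt(2/n)/sqrt(trials) ~ 0.003
        assert abs(np.mean(gains) - 2.0) < 0.01

    def test_vor_phase_convention_zero_means_eye_opposite_head(self):
        t = np.arange(8000) * DT
        H = 10 * np.sin(2 * np.pi * 0.5 * t)
        gain, phase = vor_gain_phase(-0.8 * H, 0.5, DT, 10.0)
        assert abs(gain - 0.8) < 1e-9
        assert abs(phase) < 1e-6


class TestOpenLoopInit:
    def test_noiseless_recovery_in_weak_regularization_limit(
            self, dataset_noiseless):
        """Noiseless data generated in the same basis: the regression
        recovers the generative weights as regularization -> 0."""
        reg = RegularizationSpec(scale=1e-8)
        p = openloop_init(dataset_noiseless, reg, g=0.2)
        truth = dataset_noiseless.params_true["pre"]
        for f in ("EH", "EP", "PH", "PR"):
            w_fit = getattr(p, f"k_{f}").weights
            w_true = getattr(truth, f"k_{f}").weights
            assert np.max(np.abs(w_fit - w_true)) < 1e-5

    def test_default_regularization_recovers_areas_and_kernels(
            self, dataset_noiseless):
        reg = RegularizationSpec()
        p = openloop_init(dataset_noiseless, reg, g=0.2)
        truth = dataset_noiseless.params_true["pre"]
        for f in ("EH", "EP"):
            kt = getattr(truth, f"k_{f}")
            kf = getattr(p, f"k_{f}")
            assert abs(kf.area() - kt.area()) < 0.02 * abs(kt.area())

    def test_infinite_regularization_shrinks_weights_to_zero(
            self, dataset_noiseless):
        reg = RegularizationSpec(scale=1e9)
        p = openloop_init(dataset_noiseless, reg, g=0.0)
        assert np.max(np.abs(p.k_EH.weights)) < 1e-4
        assert np.max(np.abs(p.k_PH.weights)) < 1e-4

    def test_penalty_ladder_shrinks_weight_norm_monotonically(
            self, dataset_noiseless):
        norms = []
        for scale in (0.1, 1.0, 10.0, 100.0, 1000.0):
            p = openloop_init(dataset_noiseless,
                              RegularizationSpec(scale=scale), g=0.0)
            norms.append(np.linalg.norm(np.concatenate(
                [p.k_EH.weights, p.k_PH.weights, p.k_PR.weights])))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_declared_loop_gain_enforced(self, dataset_noiseless):
        p = openloop_init(dataset_noiseless, RegularizationSpec(), g=0.4)
        assert abs(loop_gain(p) - 0.4) < 1e-9


class TestLearningInit:
    def test_identical_pre_post_data_gives_zero_deltas(
            self, dataset_noiseless):
        import copy

        ds = copy.copy(dataset_noiseless)
        ds.dataset2 = dataset_noiseless.dataset2.copy()
        for col in ("gain", "phase"):
            ds.dataset2[f"{col}_post_increase"] = ds.dataset2[f"{col}_pre"]
        pre = dataset_noiseless.post_targets["pre"]
        ds.post_targets = dict(dataset_noiseless.post_targets)
        ds.post_targets["increase"] = {
            "P_ss": pre["P_ss"], "E_ss": pre["E_ss"],
            "P_trans": pre["P_trans"], "dP_gain_05": 0j,
            "behavior_change_frac": 0.6}
        params = openloop_init(ds, RegularizationSpec(), g=0.2)
        dPH, dEH = openloop_learning_init(ds, params,
                                          RegularizationSpec(), "increase")
        # negligible against the ~3e-2 scale of the pre-learning weights
        assert np.max(np.abs(dPH)) < 1e-4
        assert np.max(np.abs(dEH)) < 1e-4
        assert abs(dPH.sum()) < 1e-9 and abs(dEH.sum()) < 1e-9

    def test_recovers_known_changes(self, dataset_noiseless):
        """Net area changes recovered against the generative truth."""
        params = openloop_init(dataset_noiseless, RegularizationSpec(),
                               g=0.2)
        dPH, dEH = openloop_learning_init(dataset_noiseless, params,
                                          RegularizationSpec(), "increase")
        truth = dataset_noiseless.params_true
        true_dPH = truth["post_increase"].k_PH.area() \
            - truth["pre"].k_PH.area()
        true_dEH = truth["post_increase"].k_EH.area() \
            - truth["pre"].k_EH.area()
        assert abs(dPH.sum() - true_dPH) < 0.02 * abs(true_dPH)
        assert abs(dEH.sum() - true_dEH) < 0.02 * abs(true_dEH)


class TestFinetuneNonvisual:
    def test_truth_is_a_near_stationary_point(self, dataset_noiseless):
        """Initialized at the generative optimum of noiseless data at the
        generative g, the cost is already tiny and the optimizer stays."""
        truth = dataset_noiseless.params_true
        cost = _DarkCost(dataset_noiseless, 0.2, RegularizationSpec(),
                         ("increase",))
        d_true = {"increase": (
            truth["post_increase"].k_PH.weights - truth["pre"].k_PH.weights,
            truth["post_increase"].k_EH.weights - truth["pre"].k_EH.weights)}
        x0 = cost.pack(truth["pre"], d_true)
        assert cost(x0, truth["pre"]) < 1e-3
        fit = finetune_nonvisual(truth["pre"], dataset_noiseless, 0.2,
                                 deltas_init=d_true,
                                 directions=("increase",), maxiter=5)
        assert fit.total_cost < 1e-3

    def test_cost_breakdown_sums_to_total(self, fit_g0):
        assert abs(fit_g0.total_cost
                   - sum(fit_g0.cost_terms.values())) < 1e-12

    def test_declared_g_matches_recomputed_loop_gain(self, fit_g0):
        assert abs(loop_gain(fit_g0.params_pre) - fit_g0.g) < 1e-9

    def test_both_learning_directions(self, dataset_noiseless):
        """Joint fit of both directions achieves the decrease-learning
        targets too (+1.04 normalized Purkinje change, VOR gain 0.4)."""
        from vorloop.synth import measure_step_response

        p0 = openloop_init(dataset_noiseless, RegularizationSpec(), g=0.2)
        fit = finetune_nonvisual(p0, dataset_noiseless, 0.2,
                                 directions=("increase", "decrease"),
                                 maxiter=60)
        pre = measure_step_response(fit.params_pre)
        post = measure_step_response(fit.params_post["decrease"])
        d_norm = (post["P_ss"] - pre["P_ss"]) / 0.6
        assert abs(d_norm - 1.04) < 0.03
        gain = abs(frequency_response_dark(
            fit.params_post["decrease"], 0.5)["E_over_H"][0])
        assert abs(gain - 0.4) < 0.02


class TestFinetuneVisual:
    def test_all_dark_dataset_is_noop(self, dataset_noiseless):
        import copy

        ds = copy.copy(dataset_noiseless)
        ds.battery = [c for c in dataset_noiseless.battery if not c.lights]
        p0 = openloop_init(dataset_noiseless, RegularizationSpec(), g=0.2)
        out = finetune_visual(p0, ds, maxfev=50)
        np.testing.assert_array_equal(out.k_PR.kernel, p0.k_PR.kernel)

    def test_descent_reduces_lit_condition_residual(self, dataset_noiseless):
        rng = np.random.default_rng(9)
        p0 = openloop_init(dataset_noiseless, RegularizationSpec(), g=0.2)
        perturbed = p0.copy()
        perturbed.k_PR.weights = p0.k_PR.weights * (
            1 + 0.3 * rng.standard_normal(12))
        perturbed.k_PR.kernel = perturbed.k_PR.weights @ \
            p0.k_PR.basis.vectors
        out = finetune_visual(perturbed, dataset_noiseless, maxfev=400)
        truth = dataset_noiseless.params_true["pre"]

        def resid(p):
            return np.linalg.norm(p.k_PR.kernel - truth.k_PR.kernel)

        assert resid(out) < resid(perturbed)


class TestRefitCancellation:
    def test_post_cancellation_eye_matches_pre(self, fit_g0,
                                               dataset_noiseless):
        """After the re-fit, 0.5 Hz cancellation eye velocity is unchanged
        by learning (normalized residual < 1%)."""
        post = refit_kPT_post(fit_g0, dataset_noiseless, "increase")
        cond = dataset_noiseless.condition("x0_sine_0.5")
        E_pre, _ = _lit_response(fit_g0.params_pre, cond)
        fitted = fit_g0.params_post["increase"].copy()
        fitted.k_PT = post.k_PT
        E_post, _ = _lit_response(fitted, cond)
        assert abs(E_post - E_pre) < 0.01 * max(abs(E_pre), 0.05)

    def test_identity_when_post_equals_pre(self, fit_g0, dataset_noiseless):
        import copy

        fit = copy.copy(fit_g0)
        fit.params_post = {"increase": fit_g0.params_pre.copy()}
        post = refit_kPT_post(fit, dataset_noiseless, "increase")
        c_pre = fit_g0.params_pre.k_PT.sine_gain[0.5]
        assert abs(post.k_PT.sine_gain[0.5] - c_pre) < 1e-9


class TestSweep:
    def test_singleton_sweep_equals_direct_call(self, dataset_noiseless):
        reg = RegularizationSpec()
        sweep = sweep_feedback(dataset_noiseless, g_values=[0.2], reg=reg,
                               directions=("increase",), maxiter=10,
                               refit_cancellation=False)
        p0 = openloop_init(dataset_noiseless, reg, g=0.2)
        deltas = {"increase": openloop_learning_init(
            dataset_noiseless, p0, reg, "increase")}
        direct = finetune_nonvisual(p0, dataset_noiseless, 0.2, reg,
                                    directions=("increase",),
                                    deltas_init=deltas, maxiter=10)
        np.testing.assert_allclose(sweep[0].params_pre.k_PH.weights,
                                   direct.params_pre.k_PH.weights,
                                   atol=1e-12)

    def test_fit_quality_similar_across_feedback_gains(self, dataset_noisy):
        """Pre-learning fit error is nearly indistinguishable across
        feedback gains (fit-quality degeneracy): with measurement noise
        present every model fits down to the same noise floor.  A coarse
        three-gain sweep suffices to check the property."""
        sweep = sweep_feedback(dataset_noisy, g_values=[0.0, 0.5, 1.0],
                               directions=("increase",), maxiter=40,
                               refit_cancellation=False)
        errs = [fit.cost_terms["pre_trace_E"] + fit.cost_terms["pre_trace_P"]
                for fit in sweep]
        n_tot = sum(c.n for c in dataset_noisy.battery if not c.lights)
        nrmse = np.sqrt(np.array(errs) / n_tot)
        assert nrmse.max() - nrmse.min() < 0.1 * nrmse.mean()
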