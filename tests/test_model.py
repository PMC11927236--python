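"""MAP estimation: objective arithmetic, recovery, priors, bootstrap, holdout."""

import numpy as np
import pandas as pd
import pytest

import doxopkpd as dx
from doxopkpd.model import PriorSpec, default_priors
from doxopkpd.synthetic import DesignSpec, NoiseSpec

from ._oracles import logistic_closed_form
from .conftest import TRUTH


def _truth_params(arms):
    p = dict(TRUTH)
    p.update({f"n0_{a:g}": dx.DEFAULT_N0[a] for a in arms})
    return p


def _control_records(counts_by_time, arm=0.0):
    rows = [
        (arm, t, f"r{i}", c)
        for t, counts in counts_by_time.items()
        for i, c in enumerate(counts)
    ]
    return pd.DataFrame(rows, columns=["arm_nM", "time_h", "replicate", "count"])


class TestMapCost:
    def test_zero_at_truth_with_centered_priors(self, clean_dataset):
        model = dx.DoxoPKPDModel(clean_dataset)
        p = _truth_params(model.arms)
        centered = PriorSpec(mu=p, sd={k: abs(v) * 0.1 for k, v in p.items()})
        model_c = dx.DoxoPKPDModel(clean_dataset, priors=centered)
        at_truth = model_c.map_cost(p)
        assert at_truth < 0.1
        perturbed = dict(p, k_p=p["k_p"] * 1.1)
        assert model_c.map_cost(perturbed) > 100 * max(at_truth, 1e-6)

    def test_flat_priors_reduce_to_weighted_ssr(self, noisy_dataset, pk, pd_params):
        flat = PriorSpec(mu={}, sd={})
        model = dx.DoxoPKPDModel(noisy_dataset, priors=flat)
        p = _truth_params(model.arms)
        # independent accumulation of the weighted sum of squares
        expected = 0.0
        for arm in model.arms:
            obs = model._obs[arm]
            yhat = dx.predict_arm_counts(
                pk.with_gamma(p["gamma"]), pd_params, arm, obs["times"], n0=p[f"n0_{arm:g}"]
            )
            w = 3.0 if arm == 0.0 else 1.0
            expected += np.sum(w * (obs["y"] - yhat) ** 2 / obs["var"])
        assert model.map_cost(p) == pytest.approx(expected, rel=1e-6)

    def test_toy_dataset_hand_arithmetic(self):
        # control arm, two times, two replicates each; one prior on k_p
        records = _control_records({0.0: [9000.0, 11000.0], 240.0: [90000.0, 110000.0]})
        priors = PriorSpec(mu={"k_p": 0.028}, sd={"k_p": 0.014})
        model = dx.DoxoPKPDModel(records, priors=priors, control_weight=3.0)
        p = {"k_p": 0.02, "theta": 2.5e5, "kd_max": 0.05, "xb_hs": 50.0, "gamma": 0.005,
             "n0_0": 10000.0}
        # spreadsheet-style expectation with the analytic logistic solution;
        # sample sd of {x-d, x+d} is d*sqrt(2), so sem^2 = (d*sqrt(2))^2/2 = d^2
        yhat = logistic_closed_form(np.array([0.0, 240.0]), 10000.0, 0.02, 2.5e5)
        y = np.array([10000.0, 100000.0])
        sem2 = np.array([1000.0**2, 10000.0**2])
        expected = np.sum(3.0 * (y - yhat) ** 2 / sem2) + ((0.02 - 0.028) / 0.014) ** 2
        # the model evaluates the growth law by quadrature, the oracle
        # analytically; they agree to the quadrature error
        assert model.map_cost(p) == pytest.approx(expected, rel=1e-3)


class TestFit:
    def test_noise_free_recovery_within_1pct(self, clean_dataset):
        res = dx.DoxoPKPDModel(clean_dataset).fit(n_starts=1)
        assert res.converged
        for name, value in TRUTH.items():
            assert res.params[name] == pytest.approx(value, rel=0.01), name

    def test_control_only_data_fixes_drug_parameters(self, clean_dataset):
        ctrl = clean_dataset[clean_dataset["arm_nM"] == 0.0]
        res = dx.DoxoPKPDModel(ctrl).fit(n_starts=1)
        assert set(res.fixed) == {"kd_max", "xb_hs", "gamma"}
        assert res.params["k_p"] == pytest.approx(TRUTH["k_p"], rel=0.02)
        assert res.params["theta"] == pytest.approx(TRUTH["theta"], rel=0.05)

    def test_noisy_estimates_within_3_bootstrap_sd(self, fitted_noisy, bootstrapped_noisy):
        for name, value in TRUTH.items():
            err = abs(fitted_noisy.params[name] - value)
            assert err < 3 * bootstrapped_noisy.sd[name], name

    def test_median_bias_small_over_20_datasets(self, recovery_estimates):
        ests = pd.DataFrame(recovery_estimates)
        for name, value in TRUTH.items():
            bias = np.median(np.abs(ests[name] - value) / value)
            limit = 0.15 if name == "theta" else 0.10
            assert bias < limit, f"{name}: median |bias| {bias:.3f}"

    def test_prior_pull_monotone_on_kp(self, noisy_dataset):
        estimates = []
        for rel_sd in (0.5, 0.15, 0.05):
            priors = default_priors(
                dx.DoxoPKPDModel(noisy_dataset).averaged, kp_rel_sd=rel_sd
            )
            res = dx.DoxoPKPDModel(noisy_dataset, priors=priors).fit(n_starts=1)
            estimates.append(res.params["k_p"])
        # data pull kp below the 0.028 prior mean; tightening the prior must
        # move the estimate monotonically toward it
        assert estimates[0] < estimates[1] < estimates[2] < 0.028

    def test_control_weighting_stable_on_clean_data(self, clean_dataset, bootstrapped_noisy):
        res1 = dx.DoxoPKPDModel(clean_dataset, control_weight=1.0).fit(n_starts=1)
        res3 = dx.DoxoPKPDModel(clean_dataset, control_weight=3.0).fit(n_starts=1)
        assert abs(res1.params["k_p"] - res3.params["k_p"]) < bootstrapped_noisy.sd["k_p"]
        assert abs(res1.params["theta"] - res3.params["theta"]) < bootstrapped_noisy.sd["theta"]

    def test_summary_lists_all_parameters(self, fitted_noisy):
        text = fitted_noisy.summary()
        for name in fitted_noisy.params.index:
            assert name in text


class TestBootstrap:
    def test_seeding_contract(self, clean_dataset):
        res = dx.DoxoPKPDModel(clean_dataset).fit(n_starts=1)
        b1 = res.bootstrap(B=2, seed=13)
        b2 = res.bootstrap(B=2, seed=13)
        assert b1.n_replicates == 2
        pd.testing.assert_frame_equal(b1.replicates, b2.replicates)

    def test_noise_free_data_gives_zero_sd(self, clean_dataset):
        res = dx.DoxoPKPDModel(clean_dataset).fit(n_starts=1)
        boot = res.bootstrap(B=3, seed=0)
        assert float(boot.sd.max()) == pytest.approx(0.0, abs=1e-8)

    def test_bands_ordered_and_cv_plausible(self, fitted_noisy, bootstrapped_noisy):
        boot = bootstrapped_noisy
        for arm, band in boot.bands.items():
            assert (band["lo"] <= band["hi"] + 1e-9).all()
        # precision comparable to the experimental study: CVs of a few
        # percent to a few tens of percent
        assert 0.5 < boot.cv["k_p"] < 40.0
        assert boot.n_failed == 0

    def test_rejects_tiny_b(self, fitted_noisy):
        with pytest.raises(ValueError):
            fitted_noisy.bootstrap(B=1)


class TestHoldout:
    def test_reduced_fit_consistent_with_full_within_3sd(
        self, noisy_dataset, fitted_noisy, bootstrapped_noisy
    ):
        res = dx.validate_holdout(noisy_dataset, n_starts=2, seed=0)
        for name in TRUTH:
            gap = abs(res.train_result.params[name] - fitted_noisy.params[name])
            assert gap < 3 * bootstrapped_noisy.sd[name], name

    def test_heldout_rmse_within_2x_train(self, noisy_dataset):
        res = dx.validate_holdout(noisy_dataset, n_starts=2, seed=0)
        pooled = np.sqrt(
            np.mean(
                np.concatenate(
                    [(p["observed"] - p["predicted"]) ** 2 for p in res.predictions.values()]
                )
            )
        )
        assert pooled < 2.0 * res.rmse_train
        assert set(res.rmse) == {10.0, 40.0, 450.0}

    def test_full_vs_reduced_trajectories_close(self, noisy_dataset):
        res = dx.validate_holdout(noisy_dataset, n_starts=2, seed=0, compare_full=True)
        assert res.full_comparison is not None
        for arm, gap in res.full_comparison.items():
            assert gap < 0.25, f"arm {arm}: max relative gap {gap:.3f}"

    def test_overlapping_arms_rejected(self, noisy_dataset):
        with pytest.raises(ValueError, match="disjoint"):
            dx.validate_holdout(noisy_dataset, train_arms=(0.0, 20.0), test_arms=(20.0,))

    def test_absent_test_arm_skipped_with_warning(self, noisy_dataset):
        with pytest.warns(UserWarning, match="skipped"):
            res = dx.validate_holdout(
                noisy_dataset,
                train_arms=(0.0, 20.0, 50.0, 200.0, 900.0),
                test_arms=(10.0, 123.0),
                n_starts=1,
            )
        assert res.skipped == [123.0]
        assert 10.0 in res.rmse


class TestNoiseSensitivity:
    def test_bootstrap_sd_increases_with_noise(self):
        design = DesignSpec(arms=(0.0, 50.0, 900.0), missing=frozenset())
        sds = []
        for cv in (0.05, 0.2, 0.4):
            df = dx.generate_dataset(
                design=design, noise=NoiseSpec(cv=cv, first_sample_factor=1.0), seed=6
            )
            res = dx.DoxoPKPDModel(df).fit(n_starts=1)
            boot = res.bootstrap(B=16, seed=6)
            sds.append(float(boot.sd["k_p"]))
        assert sds[0] < sds[1] < sds[2]
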