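import numpy as np
import pandas as pd
import pytest

from arbrl.dataset import BehavioralDataset
from arbrl.inference import (
    bms,
    evidence_matrix,
    fit_subject,
    model_recovery,
    parameter_recovery,
    recovery_report,
    sequence_likelihood,
)
from arbrl.model_space import ModelVariantSpec, instantiate
from arbrl.synthetic_data import CohortSpec, simulate_cohort

from _oracles import conjugate_bms_exceedance, naive_baseline_loglik

BASE_PARAMS = {"eta_mb": 0.3, "eta_mf": 0.25, "A_mf2mb": 0.4,
               "A_mb2mf": 0.6, "B": 3.0, "tau_base": 0.5}


class TestSequenceLikelihood:
    def test_uniform_limit_at_vanishing_temperature(self, model, smoke_dataset):
        dataset, _, _ = smoke_dataset
        params = dict(BASE_PARAMS, tau_base=1e-12)
        agent = instantiate("lee2014", params, model=model)
        logp = sequence_likelihood(agent, dataset)
        n_avail2 = dataset.df.sort_values(["subject", "session", "trial"])[
            "avail2"].str.count("\\|").to_numpy() + 1
        assert np.allclose(logp[:, 0], -np.log(2))
        assert np.allclose(logp[:, 1], -np.log(n_avail2))

    def test_replay_is_deterministic_and_side_effect_free(self, model, smoke_dataset):
        dataset, _, _ = smoke_dataset
        agent = instantiate("best", dict(BASE_PARAMS), model=model)
        a = sequence_likelihood(agent, dataset)
        b = sequence_likelihood(agent, dataset)
        assert np.array_equal(a, b)

    def test_matches_independent_trial_loop_oracle(self, model, smoke_dataset):
        dataset, _, _ = smoke_dataset
        toy = BehavioralDataset(dataset.df.head(5))
        agent = instantiate("lee2014", BASE_PARAMS, model=model)
        got = sequence_likelihood(agent, toy)
        want = naive_baseline_loglik(model, toy.df, BASE_PARAMS)
        assert np.allclose(got, want, atol=1e-12)


class TestFitSubject:
    @pytest.fixture(scope="class")
    def subject_400(self, config, model):
        cohort = CohortSpec(variant_id="best", n_subjects=1, n_sessions=5,
                            trials_per_session=80, master_seed=5)
        dataset, _, sidecar = simulate_cohort(cohort, config, model)
        return dataset, sidecar["subjects"]["sim000"]["params"]

    def test_fit_beats_generative_parameters(self, model, subject_400):
        dataset, true_params = subject_400
        fit = fit_subject("best", dataset, n_starts=20, rng=0, model=model)
        agent = instantiate("best", true_params, model=model)
        nll_truth = -sequence_likelihood(agent, dataset).sum()
        assert fit.nll <= nll_truth + 1e-6
        assert fit.converged

    def test_identical_seed_identical_result(self, model, subject_400):
        dataset, _ = subject_400
        a = fit_subject("lee2014", dataset, n_starts=3, rng=123, model=model)
        b = fit_subject("lee2014", dataset, n_starts=3, rng=123, model=model)
        assert a.params == b.params and a.nll == b.nll

    def test_one_free_parameter_matches_grid_search(self, model, subject_400):
        dataset, true_params = subject_400
        spec = ModelVariantSpec.from_id("best")
        fixed = {k: v for k, v in true_params.items() if k != "tau_base"}
        fit = fit_subject(spec, dataset, n_starts=4, rng=0, model=model,
                          fixed=fixed)
        grid = np.linspace(0.01, 10.0, 400)
        nlls = []
        for tau in grid:
            agent = instantiate(spec, {**fixed, "tau_base": tau}, model=model)
            nlls.append(-sequence_likelihood(agent, dataset).sum())
        best_grid = grid[int(np.argmin(nlls))]
        assert fit.params["tau_base"] == pytest.approx(
            best_grid, abs=(grid[1] - grid[0]))
        assert fit.nll <= min(nlls) + 1e-6

    def test_bic_convention(self, model, subject_400):
        dataset, _ = subject_400
        fit = fit_subject("lee2014", dataset, n_starts=1, rng=0, model=model)
        k = len(ModelVariantSpec.from_id("lee2014").param_names)
        assert fit.bic == pytest.approx(2 * fit.nll + k * np.log(fit.n_obs))
        assert fit.log_evidence == pytest.approx(-fit.bic / 2)


class TestBMS:
    def test_symmetry_for_identical_evidence(self):
        lme = np.tile([[-10.0, -10.0]], (8, 1))
        res = bms(lme, rng=0)
        assert np.allclose(res.exceedance, 0.5, atol=0.02)
        assert np.allclose(res.expected_freq, 0.5, atol=1e-6)

    def test_dominant_model_exceeds_099(self):
        rng = np.random.default_rng(0)
        lme = rng.normal(-200, 5, size=(20, 3))
        lme[:, 1] += 20.0  # better by >= 20 nats everywhere
        res = bms(lme, ["m0", "m1", "m2"], rng=1)
        assert res.exceedance[1] > 0.99

    def test_exceedance_sums_to_one(self):
        rng = np.random.default_rng(2)
        res = bms(rng.normal(-100, 3, size=(10, 4)), rng=3)
        assert res.exceedance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_evidence_rejected(self):
        lme = np.zeros((3, 2))
        lme[0, 0] = np.nan
        with pytest.raises(ValueError):
            bms(lme)

    @pytest.mark.parametrize("delta,tol", [
        # at the symmetric and dominance limits the variational posterior
        # coincides with the conjugate closed form (up to MC error); in the
        # intermediate-evidence regime it is a documented approximation
        (0.0, 0.01), (30.0, 0.01), (1.0, 0.07),
    ])
    def test_single_subject_two_models_matches_conjugate_form(self, delta, tol):
        lme = np.array([[0.0, -delta]])
        res = bms(lme, rng=0, n_samples=200_000)
        want = conjugate_bms_exceedance(lme[0])
        assert res.exceedance[0] == pytest.approx(want, abs=tol)


class TestRecovery:
    def test_low_noise_learning_rate_recovery(self, config, model):
        # near-deterministic choices: tau_base at the bound's top
        rng = np.random.default_rng(0)
        params_list = []
        for _ in range(8):
            p = {"eta_mb": rng.uniform(0.05, 0.8), "eta_mf": rng.uniform(0.05, 0.8),
                 "A_mf2mb": 0.3, "A_mb2mf": 0.3, "B": 3.0, "tau_base": 8.0}
            params_list.append(p)
        report, truth, fits = parameter_recovery(
            "lee2014", n_agents=8, trials_per_session=80, n_sessions=4,
            rng=1, n_starts=6, config=config, params_list=params_list)
        r_eta_mb = report.set_index("parameter").loc["eta_mb", "r"]
        assert r_eta_mb > 0.9

    def test_shuffled_pairing_destroys_correlation(self, config, model):
        rng = np.random.default_rng(3)
        n = 40
        truth = [{"x": float(rng.uniform(0, 1))} for _ in range(n)]

        class FakeFit:
            def __init__(self, v):
                self.params = {"x": v}

        fits = [FakeFit(t["x"] + rng.normal(0, 0.01)) for t in truth]
        paired = recovery_report(truth, fits, ["x"])
        assert paired.loc[0, "r"] > 0.95
        shuffled = list(rng.permutation(fits))
        broken = recovery_report(truth, shuffled, ["x"])
        assert abs(broken.loc[0, "r"]) < 0.4

    def test_report_covers_every_free_parameter(self, config):
        spec = ModelVariantSpec.from_id("3Q_int1_exc_bi_explore")
        report, truth, fits = parameter_recovery(
            spec, n_agents=3, trials_per_session=30, n_sessions=1,
            rng=2, n_starts=1, config=config)
        assert list(report["parameter"]) == list(spec.param_names)


class TestModelRecovery:
    def test_single_model_subset_is_trivial(self):
        out = model_recovery(["lee2014"], rng=0)
        vid = ModelVariantSpec.from_id("lee2014").variant_id
        assert out.iloc[0][vid] == 1.0

    def test_confusion_rows_sum_to_one(self, config):
        out = model_recovery(
            ["lee2014", "3Q_null_noexp"], rng=4, n_agents=4,
            trials_per_session=40, n_sessions=2, n_starts=2, config=config)
        cols = [c for c in out.columns if c != "generating"]
        assert np.allclose(out[cols].sum(axis=1), 1.0, atol=1e-9)


def test_evidence_matrix_pivot(model, smoke_dataset):
    dataset, _, _ = smoke_dataset
    fits = [fit_subject(v, dataset, n_starts=1, rng=0, model=model)
            for v in ("lee2014", "best")]
    mat = evidence_matrix(fits)
    assert mat.shape == (1, 2)
    assert np.isfinite(mat.to_numpy()).all()
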