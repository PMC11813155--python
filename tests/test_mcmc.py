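import numpy as np
import pytest

import txpred as tx
from oracles import blup_closed_form, enumeration_posterior
from txpred.mcmc import calibrate_priors

SHORT = tx.MCMCSchedule(30_000, 5_000, 10)  # 2,500 retained draws
TINY = tx.MCMCSchedule(3_000, 500, 5)


@pytest.fixture(scope="module")
def spike_instance():
    rng = np.random.default_rng(33)
    n, m = 40, 5
    X = rng.normal(size=(n, m))
    beta = np.array([1.0, 0.0, 0.0, -0.8, 0.0])
    y = X @ beta + rng.normal(size=n)
    return X, y


class TestSchedule:
    def test_default_schedules_retained_counts(self):
        assert tx.BAYESC_SCHEDULE.retained == 2000
        assert tx.TBLUP_SCHEDULE.retained == 1500

    @pytest.mark.parametrize("args", [(100, 200, 10), (100, 50, 0), (100, 30, 9)])
    def test_invalid_schedules_rejected(self, args):
        with pytest.raises(ValueError):
            tx.MCMCSchedule(*args)

    def test_retained_draws_match_formula(self, spike_instance):
        X, y = spike_instance
        fit = tx.fit_bayesc(X, y, sched=TINY, seed=1)
        assert fit.retained_draws == TINY.retained
        assert len(fit.variance_components["sigma_e2"]["draws"]) == TINY.retained


class TestCalibration:
    def test_residual_mode(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        y = (y - y.mean()) / y.std(ddof=1)  # Var(y) = 1
        cal = calibrate_priors(y, [{"kind": "kernel", "mean_diag": 1.0}],
                               tx.PriorCalibration(r2_target=0.8))
        df = 5.0
        assert cal["S_e"] * df / (df + 2) == pytest.approx(0.2)

    def test_equal_partition_weights(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=100)
        vy = np.var(y, ddof=1)
        cal = calibrate_priors(
            y,
            [{"kind": "kernel", "mean_diag": 1.0}, {"kind": "kernel", "mean_diag": 1.0}],
            tx.PriorCalibration(r2_target=0.8, partition_weights=(0.5, 0.5)),
        )
        df = 5.0
        for s in cal["scales"]:
            assert s * df / (df + 2) == pytest.approx(0.4 * vy)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=80)
        comps = [{"kind": "effects", "sum_var_x": 10.0, "pi": 0.3}]
        cal1 = calibrate_priors(y, comps, tx.PriorCalibration())
        cal2 = calibrate_priors(y * np.sqrt(2), comps, tx.PriorCalibration())
        assert cal2["S_e"] == pytest.approx(2 * cal1["S_e"])
        assert cal2["scales"][0] == pytest.approx(2 * cal1["scales"][0])

    def test_invalid_r2(self):
        with pytest.raises(ValueError):
            tx.PriorCalibration(r2_target=1.0)


class TestBayesC:
    def test_pips_match_enumeration(self, spike_instance):
        X, y = spike_instance
        pi, sb, se = 0.2, 0.5, 1.0
        Xc, yc = X - X.mean(0), y - y.mean()
        exact, _ = enumeration_posterior(Xc, yc, pi, sb, se)
        fit = tx.fit_bayesc(X, y, sched=SHORT,
                            fixed={"pi": pi, "sigma_beta2": sb, "sigma_e2": se},
                            seed=5)
        assert np.abs(exact - fit.pip).max() <= 0.05

    def test_null_mean_pip_matches_enumeration(self):
        rng = np.random.default_rng(44)
        n, m = 40, 5
        X = rng.normal(size=(n, m))
        y = rng.normal(size=n)  # independent of X
        Xc, yc = X - X.mean(0), y - y.mean()
        exact, _ = enumeration_posterior(Xc, yc, 0.1, 0.5, 1.0)
        fit = tx.fit_bayesc(X, y, sched=SHORT,
                            fixed={"pi": 0.1, "sigma_beta2": 0.5, "sigma_e2": 1.0},
                            seed=6)
        mc_se = fit.pip.std() / np.sqrt(5)
        assert abs(fit.pip.mean() - exact.mean()) <= max(3 * mc_se, 0.03)

    def test_column_permutation_permutes_pips(self, spike_instance):
        # checked through the enumeration oracle, not chain-path identity
        X, y = spike_instance
        perm = np.array([3, 0, 4, 1, 2])
        fixed = {"pi": 0.2, "sigma_beta2": 0.5, "sigma_e2": 1.0}
        fit_p = tx.fit_bayesc(X[:, perm], y, sched=SHORT, fixed=fixed, seed=7)
        Xc, yc = X - X.mean(0), y - y.mean()
        exact, _ = enumeration_posterior(Xc, yc, 0.2, 0.5, 1.0)
        assert np.abs(fit_p.pip - exact[perm]).max() <= 0.05

    def test_predictions_near_oracle(self, spike_instance):
        X, y = spike_instance
        Xc, yc = X - X.mean(0), y - y.mean()
        X_test = np.random.default_rng(8).normal(size=(10, 5))
        exact_pip, exact_pred = enumeration_posterior(
            Xc, yc, 0.2, 0.5, 1.0, X_test=X_test - X.mean(0))
        fit = tx.fit_bayesc(X, y, sched=SHORT, X_test=X_test,
                            fixed={"pi": 0.2, "sigma_beta2": 0.5, "sigma_e2": 1.0},
                            seed=9)
        tol = 0.05 * np.std(y)
        assert np.abs(fit.predictions - y.mean() - exact_pred).max() <= tol

    def test_free_hyperparameters_recover_signal(self, spike_instance):
        X, y = spike_instance
        fit = tx.fit_bayesc(X, y, sched=SHORT, seed=10)
        assert fit.pip[0] > 0.9 and fit.pip[3] > 0.9
        assert fit.pip[[1, 2, 4]].max() < 0.5


class TestGOBayesC:
    def test_universe_term_reduces_to_bayesc(self, spike_instance):
        X, y = spike_instance
        mask = np.ones(5, bool)
        a = tx.fit_go_bayesc(X, y, mask, sched=TINY, seed=11)
        b = tx.fit_bayesc(X, y, sched=TINY, seed=11)
        np.testing.assert_array_equal(a.pip, b.pip)

    def test_empty_block_rejected(self, spike_instance):
        X, y = spike_instance
        with pytest.raises(ValueError, match="empty GO block"):
            tx.fit_go_bayesc(X, y, np.zeros(5, bool), sched=TINY)

    def test_identical_groups_consistent_with_single_group(self, spike_instance):
        X, y = spike_instance
        rng = np.random.default_rng(12)
        X_test = rng.normal(size=(8, 5))
        fixed = {"pi": 0.2, "sigma_beta2": 0.5, "sigma_e2": 1.0}
        mask = np.array([True, True, False, False, False])
        go = tx.fit_go_bayesc(X, y, mask, sched=SHORT, X_test=X_test,
                              fixed=fixed, seed=13)
        single = tx.fit_bayesc(X, y, sched=SHORT, X_test=X_test, fixed=fixed,
                               seed=14)
        sd = np.maximum(go.pred_draws.std(axis=0), single.pred_draws.std(axis=0))
        mc_se = sd / np.sqrt(50)  # conservative effective draws
        assert np.all(np.abs(go.predictions - single.predictions) <= 3 * mc_se + 1e-8)

    def test_grouped_pips_match_grouped_enumeration(self):
        rng = np.random.default_rng(15)
        n, m = 40, 5
        X = rng.normal(size=(n, m))
        y = X[:, 0] * 1.2 + rng.normal(size=n)
        groups = np.array([0, 0, 1, 1, 1])
        pi_g = np.array([0.4, 0.1])
        sb_g = np.array([0.8, 0.3])
        Xc, yc = X - X.mean(0), y - y.mean()
        exact, _ = enumeration_posterior(Xc, yc, pi_g, sb_g, 1.0, groups=groups)
        fit = tx.fit_go_bayesc(
            X, y, groups == 0, sched=SHORT,
            fixed={"pi": pi_g, "sigma_beta2": sb_g, "sigma_e2": 1.0}, seed=16)
        assert np.abs(exact - fit.pip).max() <= 0.05

    def test_go_inclusion_exceeds_background_on_enriched_data(self, go_dataset):
        wins = 0
        members = set(go_dataset.genesets[go_dataset.config.causal_term])
        mask = np.array([g in members for g in go_dataset.expression.gene_ids])
        for rep in range(10):
            fit = tx.fit_go_bayesc(go_dataset.expression.values,
                                   go_dataset.phenotype.values, mask,
                                   sched=TINY, seed=100 + rep)
            wins += fit.pi_mean[0] > fit.pi_mean[1]
        assert wins >= 9


class TestTBLUP:
    @pytest.fixture(scope="class")
    def kernel_setup(self):
        rng = np.random.default_rng(17)
        cfg = tx.SimulationConfig(n_lines=60, n_genes=150, target_H2m=0.8, seed=18)
        ds = tx.simulate_dataset(cfg)
        W = tx.standardize(ds.expression)
        T = tx.build_trm(W)
        return T.values, ds.phenotype.values

    def test_fixed_variances_match_closed_form_blup(self, kernel_setup):
        T, y = kernel_setup
        tr, te = np.arange(48), np.arange(48, 60)
        st, se = 1.0, 0.5
        fit = tx.fit_tblup(T, y[tr], tr, te, sched=tx.MCMCSchedule(20_000, 2_000, 10),
                           fixed={"sigma_t2": st, "sigma_e2": se}, seed=19)
        t_hat, pred = blup_closed_form(T[np.ix_(tr, tr)], T[np.ix_(te, tr)],
                                       y[tr], st, se)
        mc_se = fit.pred_draws.std(axis=0) / np.sqrt(200)
        assert np.all(np.abs(fit.predictions - (pred + y[tr].mean())) <= 4 * mc_se)
        assert np.abs(fit.effect_means - t_hat).max() <= 0.05 * np.std(y)

    def test_zero_genetic_variance_predicts_training_mean(self, kernel_setup):
        T, y = kernel_setup
        tr, te = np.arange(48), np.arange(48, 60)
        fit = tx.fit_tblup(T, y[tr], tr, te, sched=TINY,
                           fixed={"sigma_t2": 0.0, "sigma_e2": 1.0}, seed=20)
        np.testing.assert_allclose(fit.predictions, y[tr].mean(), atol=1e-10)

    def test_accuracy_non_decreasing_in_heritability(self):
        # posterior-predictive accuracy tracks the simulated signal strength
        mean_rs = []
        for h2 in (0.2, 0.5, 0.8):
            rs = []
            for rep in range(6):
                cfg = tx.SimulationConfig(n_lines=80, n_genes=200, target_H2m=h2,
                                          seed=3000 + rep)
                ds = tx.simulate_dataset(cfg)
                W = tx.standardize(ds.expression)
                T = tx.build_trm(W).values
                tr, te = np.arange(64), np.arange(64, 80)
                fit = tx.fit_tblup(T, ds.phenotype.values[tr], tr, te,
                                   sched=TINY, seed=rep)
                rs.append(np.corrcoef(fit.predictions,
                                      ds.phenotype.values[te])[0, 1])
            mean_rs.append(np.mean(rs))
        assert mean_rs[0] < mean_rs[2]


class TestGOTBLUP:
    def test_whole_universe_contract(self):
        rng = np.random.default_rng(21)
        T = rng.normal(size=(10, 10))
        T = T @ T.T / 10
        with pytest.raises(ValueError, match="non-empty"):
            tx.fit_go_tblup(T, np.zeros_like(T), rng.normal(size=8),
                            np.arange(8), None, sched=TINY)

    def test_kernel_additivity_reduces_to_single_kernel(self):
        # paper-scaled kernels: T_GO + T_notGO = T, so equal fixed variances
        # reproduce the single-kernel model
        cfg = tx.SimulationConfig(n_lines=50, n_genes=120, target_H2m=0.8, seed=22)
        ds = tx.simulate_dataset(cfg)
        W = tx.standardize(ds.expression)
        Tg, Tn = tx.go_kernels(W, W.gene_ids[:40])
        T = tx.build_trm(W)
        np.testing.assert_allclose(Tg.values + Tn.values, T.values, atol=1e-10)
        y = ds.phenotype.values
        tr, te = np.arange(40), np.arange(40, 50)
        st, se = 0.8, 0.4
        sched = tx.MCMCSchedule(20_000, 2_000, 10)
        go = tx.fit_go_tblup(Tg.values, Tn.values, y[tr], tr, te, sched=sched,
                             fixed={"sigma_t2": (st, st), "sigma_e2": se}, seed=23)
        single = tx.fit_tblup(T.values, y[tr], tr, te, sched=sched,
                              fixed={"sigma_t2": st, "sigma_e2": se}, seed=24)
        mc_se = np.maximum(go.pred_draws.std(axis=0), single.pred_draws.std(axis=0))
        mc_se = mc_se / np.sqrt(200)
        assert np.all(np.abs(go.predictions - single.predictions) <= 4 * mc_se)

    def test_variance_share_recovers_enriched_term(self, go_dataset):
        members = go_dataset.genesets[go_dataset.config.causal_term]
        W = tx.standardize(go_dataset.expression)
        Tg, Tn = tx.go_kernels(W, members)
        wins = 0
        for rep in range(10):
            fit = tx.fit_go_tblup(Tg, Tn, go_dataset.phenotype.values,
                                  np.arange(go_dataset.expression.n_lines), None,
                                  sched=TINY, seed=400 + rep)
            wins += fit.go_variance_share >= 0.5
        assert wins >= 9


def test_short_chain_flags_diagnostics(spike_instance):
    X, y = spike_instance
    # 80 retained draws cannot reach the ESS >= 100 bar, so the flag must fire
    with pytest.warns(UserWarning, match="diagnostics"):
        fit = tx.fit_bayesc(X, y, sched=tx.MCMCSchedule(130, 50, 1), seed=25)
    assert fit.diagnostics_ok is False
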