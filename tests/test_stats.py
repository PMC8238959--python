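import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from ranevs.stats import (ModelError, bh_adjust, chisq_counts, fit_group_model,
                          mann_whitney, pairwise_contrasts, partial_pearson,
                          tukey_cell_contrasts)


def oracle_bh(p):
    """Step-up formula: p_(i) * m / i with a running cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_group_table(rng, n_per_group=12, effects=None, sd=1.0, repeats=1):
    effects = effects or {}
    rows = []
    for dx in ("control", "ASD"):
        for cu in ("US", "HK"):
            for k in range(n_per_group):
                pid = f"{cu}-{dx}-{k}"
                age = float(rng.normal(20, 5))
                sex = "M" if rng.random() < 0.5 else "F"
                iq = float(rng.normal(105, 12))
                mu = (10.0 + effects.get("diagnosis", 0.0) * (dx == "ASD")
                      + effects.get("culture", 0.0) * (cu == "HK")
                      + effects.get("interaction", 0.0)
                      * (dx == "ASD") * (cu == "HK")
                      + effects.get("age", 0.0) * age)
                for _ in range(repeats):
                    rows.append({"participant_id": pid, "diagnosis": dx,
                                 "culture": cu, "condition": "symbolic",
                                 "sex": sex, "age": age, "iq": iq,
                                 "y": float(rng.normal(mu, sd))})
    return pd.DataFrame(rows)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_known_example(self):
        # classic: p = (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=200)
    @given(p=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), oracle_bh(p))

    @settings(deadline=None, max_examples=100)
    @given(p=st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=12),
           seed=st.integers(0, 1000))
    def test_permutation_equivariant(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        base = bh_adjust(p)
        shuffled = bh_adjust(np.asarray(p)[perm])
        assert np.allclose(shuffled, base[perm])

    @settings(deadline=None, max_examples=100)
    @given(p=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_at_most_one(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    def test_complete_separation_small_n(self):
        u, p = mann_whitney([10, 11, 12, 13], [1, 2, 3, 4])
        assert u == 16.0
        # two-sided exact: 2 / C(8, 4)
        assert p == pytest.approx(2 / 70)

    def test_exact_matches_scipy_when_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(0.5, size=5)
            u, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(x=st.lists(st.integers(0, 5), min_size=2, max_size=6),
           y=st.lists(st.integers(0, 5), min_size=2, max_size=6))
    def test_u_statistics_are_complementary(self, x, y):
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_ties_handled_in_exact_enumeration(self):
        # heavily tied data: p must still be a valid probability and symmetric
        u, p = mann_whitney([1, 1, 2, 2], [1, 2, 2, 3])
        _, p2 = mann_whitney([1, 2, 2, 3], [1, 1, 2, 2])
        assert 0 < p <= 1
        assert p == pytest.approx(p2)

    def test_large_n_normal_close_to_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = rng.normal(0.7, size=25)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPartialPearson:
    def test_no_covariates_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r, p = partial_pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = partial_pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_residualize_then_correlate_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(50, 2))
        x = z @ [1.0, -0.5] + rng.normal(size=50)
        y = z @ [0.3, 0.8] + 0.4 * x + rng.normal(size=50)
        r, _ = partial_pearson(x, y, covariates=z)
        Z = np.column_stack([np.ones(50), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert r == pytest.approx(sps.pearsonr(rx, ry).statistic)

    def test_covariate_fully_explains_association(self):
        # x and y both equal z plus noise: partialling out z kills r
        rng = np.random.default_rng(9)
        z = rng.normal(size=500)
        x = z + rng.normal(scale=0.5, size=500)
        y = z + rng.normal(scale=0.5, size=500)
        r_raw, _ = partial_pearson(x, y)
        r_part, _ = partial_pearson(x, y, covariates=z[:, None])
        assert r_raw > 0.5
        assert abs(r_part) < 0.15

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson(np.zeros(10),
                            np.random.default_rng(0).normal(size=10))

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson([1.0, 2.0], [2.0, 1.0])


class TestChiSquared:
    def test_identical_rows_give_zero(self):
        stat, dof, p = chisq_counts([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # [[10, 90], [20, 80]]: chi2 = sum (O-E)^2/E with E from marginals
        obs = np.array([[10, 90], [20, 80]], dtype=float)
        expect = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = float(((obs - expect) ** 2 / expect).sum())
        stat, dof, p = chisq_counts(obs)
        assert stat == pytest.approx(by_hand)
        assert dof == 1
        assert p == pytest.approx(float(sps.chi2.sf(by_hand, 1)))

    def test_rejects_non_integer_and_zero_marginal(self):
        with pytest.raises(ValueError):
            chisq_counts([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            chisq_counts([[0, 0], [3, 4]])

    def test_three_by_two_dof(self):
        _, dof, _ = chisq_counts([[5, 6], [7, 8], [9, 10]])
        assert dof == 2


class TestGroupModel:
    def test_constant_response_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        t = make_group_table(rng, n_per_group=6)
        t["y"] = 7.0
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        for e in res.effects:
            assert e.estimate == 0.0 and e.p == 1.0

    def test_rank_deficiency_names_aliased_term(self):
        rng = np.random.default_rng(1)
        t = make_group_table(rng, n_per_group=6)
        t["age2"] = t["age"]  # perfect alias
        with pytest.raises(ModelError, match="age2"):
            fit_group_model(t, "y", "symbolic", covariates=["age", "age2"])

    def test_missing_factor_level_rejected(self):
        rng = np.random.default_rng(2)
        t = make_group_table(rng, n_per_group=6)
        t = t[t["diagnosis"] == "ASD"]
        with pytest.raises(ModelError):
            fit_group_model(t, "y", "symbolic", covariates=["age"])

    def test_matches_ols_closed_form(self):
        rng = np.random.default_rng(3)
        t = make_group_table(rng, n_per_group=10,
                             effects={"diagnosis": 2.0, "age": 0.1})
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        X = np.column_stack([
            np.ones(len(t)),
            (t["diagnosis"] == "ASD").astype(float),
            (t["culture"] == "HK").astype(float),
            ((t["diagnosis"] == "ASD") & (t["culture"] == "HK")).astype(float),
            t["age"].to_numpy()])
        beta = np.linalg.lstsq(X, t["y"].to_numpy(), rcond=None)[0]
        by_term = {e.term: e.estimate for e in res.effects}
        assert by_term["diagnosis"] == pytest.approx(beta[1])
        assert by_term["culture"] == pytest.approx(beta[2])
        assert by_term["interaction"] == pytest.approx(beta[3])

    def test_parameter_recovery_ci_coverage(self):
        # 200 replicate cohorts: the 95% CI for the diagnosis effect should
        # cover the true value in roughly 95% of replicates
        rng = np.random.default_rng(12)
        true = 1.5
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            t = make_group_table(rng, n_per_group=8,
                                 effects={"diagnosis": true}, sd=1.0)
            res = fit_group_model(t, "y", "symbolic", covariates=["age"])
            e = next(x for x in res.effects if x.term == "diagnosis")
            half = sps.t.ppf(0.975, res.df_resid) * e.se
            cover += (e.estimate - half <= true <= e.estimate + half)
        assert 0.90 <= cover / n_rep <= 0.99

    def test_repeated_measures_use_mixed_model(self):
        rng = np.random.default_rng(4)
        t = make_group_table(rng, n_per_group=8, repeats=2,
                             effects={"diagnosis": 2.0})
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        assert res.mixed
        e = next(x for x in res.effects if x.term == "diagnosis")
        assert e.estimate == pytest.approx(2.0, abs=1.0)

    def test_interaction_lr_detects_injected_interaction(self):
        rng = np.random.default_rng(6)
        with_int = make_group_table(rng, n_per_group=25,
                                    effects={"interaction": 2.5}, sd=1.0)
        without = make_group_table(rng, n_per_group=25, sd=1.0)
        lr1, p1 = fit_group_model(with_int, "y", "symbolic",
                                  covariates=["age"]).lr_interaction
        lr0, p0 = fit_group_model(without, "y", "symbolic",
                                  covariates=["age"]).lr_interaction
        assert p1 < 0.01 < p0

    def test_default_covariates_include_iq_for_naming_responses(self):
        rng = np.random.default_rng(8)
        t = make_group_table(rng, n_per_group=8)
        t["naming_time_s"] = t["y"]
        res = fit_group_model(t, "naming_time_s", "symbolic")
        assert "iq" in res.column_names
        res2 = fit_group_model(t.rename(columns={"y": "mean_evs_items"}),
                               "mean_evs_items", "symbolic")
        assert "iq" not in res2.column_names


class TestContrasts:
    def test_two_cells_reduce_to_t_test(self):
        means = {"a": 3.0, "b": 1.0}
        ses = {"a": 0.5, "b": 0.5}
        [c] = tukey_cell_contrasts(means, ses, df_resid=30)
        se = np.sqrt(0.5)
        t = 2.0 / se
        assert c.t == pytest.approx(t)
        assert c.p_tukey == pytest.approx(2 * sps.t.sf(t, 30), rel=1e-6)

    def test_zero_se_gives_p_one(self):
        [c] = tukey_cell_contrasts({"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 0.0},
                                   df_resid=10)
        assert c.p_tukey == 1.0

    def test_balanced_null_has_large_p(self):
        rng = np.random.default_rng(10)
        t = make_group_table(rng, n_per_group=15, sd=1.0)
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        cons = pairwise_contrasts(res)
        assert len(cons) == 6
        assert all(c.p_tukey > 0.01 for c in cons)

    def test_single_cell_shift_recovered(self):
        rng = np.random.default_rng(13)
        t = make_group_table(rng, n_per_group=20, sd=1.0,
                             effects={"diagnosis": 3.0, "interaction": -3.0})
        # net effect: ASD-US shifted +3, ASD-HK back at baseline
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        cons = {frozenset((c.cell_a, c.cell_b)): c
                for c in pairwise_contrasts(res)}
        hot = cons[frozenset(("ASD-US", "control-US"))]
        cold = cons[frozenset(("ASD-HK", "control-HK"))]
        assert abs(hot.estimate) == pytest.approx(3.0, abs=1.0)
        assert hot.p_tukey < 0.001
        assert cold.p_tukey > 0.05

    def test_contrast_estimates_are_antisymmetric_consistent(self):
        rng = np.random.default_rng(14)
        t = make_group_table(rng, n_per_group=10)
        res = fit_group_model(t, "y", "symbolic", covariates=["age"])
        cons = pairwise_contrasts(res)
        # cell mean differences must telescope: (a-b) + (b-c) == (a-c)
        d = {(c.cell_a, c.cell_b): c.estimate for c in cons}

        def diff(a, b):
            return d[(a, b)] if (a, b) in d else -d[(b, a)]

        cells = sorted({c.cell_a for c in cons} | {c.cell_b for c in cons})
        for a in cells:
            for b in cells:
                for c in cells:
                    if len({a, b, c}) == 3:
                        assert diff(a, b) + diff(b, c) == pytest.approx(
                            diff(a, c), abs=1e-9)
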