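"""Survivor-victim statistics: MANOVA, logistic AICc, contingency, BH."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from canidiv import synthgen
from canidiv.fossilrec import ValidationError
from canidiv.selectivity import (SelectivityConfig, _fit_one_logit,
                                 _rank_pseudo_f, akaike_weights, bh_adjust,
                                 canid_survivor_victim_table,
                                 fit_logistic_models, perm_manova,
                                 resampled_contingency, run_selectivity)


class TestPermManova:
    def test_identical_groups_give_zero_stat_p_one(self):
        X = np.tile(np.arange(8, dtype=float).reshape(4, 2), (2, 1))
        labels = np.array([True] * 4 + [False] * 4)
        f, p = perm_manova(X, labels, n_perm=99, seed=0)
        assert f == 0.0 and p == 1.0

    def test_disjoint_clusters_attain_minimum_p(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(8, 0.1, (10, 2))])
        labels = np.array([True] * 10 + [False] * 10)
        _, p = perm_manova(X, labels, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(18, 2))
        labels = rng.random(18) < 0.5
        labels[0], labels[1] = True, False  # both groups non-empty
        f1, p1 = perm_manova(X, labels, n_perm=499, seed=7)
        Y = X.copy()
        Y[:, 0] = np.exp(X[:, 0])      # strictly increasing
        Y[:, 1] = X[:, 1] ** 3
        f2, p2 = perm_manova(Y, labels, n_perm=499, seed=7)
        assert f1 == pytest.approx(f2) and p1 == p2

    def test_one_group_empty_raises(self, rng):
        with pytest.raises(ValidationError):
            perm_manova(rng.normal(size=(5, 2)), np.ones(5, bool), 99, 0)

    def test_matches_exhaustive_enumeration(self, rng):
        n, n1 = 9, 4
        X = rng.normal(size=(n, 2))
        labels = np.zeros(n, bool)
        labels[:n1] = True
        ranks = np.column_stack([rankdata(X[:, j]) for j in range(2)])
        obs = _rank_pseudo_f(np.vstack([ranks[labels], ranks[~labels]]), n1)
        stats = []
        for comb in combinations(range(n), n1):
            m = np.zeros(n, bool)
            m[list(comb)] = True
            stats.append(_rank_pseudo_f(np.vstack([ranks[m], ranks[~m]]), n1))
        p_exact = np.mean(np.array(stats) >= obs - 1e-12)
        _, p_mc = perm_manova(X, labels, n_perm=9999, seed=5)
        assert p_mc == pytest.approx(p_exact, abs=4 * math.sqrt(p_exact / 9999) + 1e-3)

    def test_bootstrap_null_variant_runs(self, rng):
        X = rng.normal(size=(16, 2))
        labels = np.array([True] * 8 + [False] * 8)
        _, p = perm_manova(X, labels, n_perm=199, seed=3, null="bootstrap")
        assert 0 < p <= 1


class TestLogisticModels:
    def test_intercept_only_mle_closed_form(self):
        y = np.array([1.0] * 3 + [0.0] * 7)
        fit = _fit_one_logit(np.ones((10, 1)), y, "intercept")
        assert fit.params[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)

    def test_intercept_mle_matches_grid_search(self):
        y = np.array([1.0] * 4 + [0.0] * 9)
        fit = _fit_one_logit(np.ones((13, 1)), y, "intercept")
        grid = np.linspace(-4, 4, 80001)
        ll = y.sum() * grid - 13 * np.logaddexp(0, grid)
        assert fit.params[0] == pytest.approx(grid[np.argmax(ll)], abs=1e-4)

    def test_aicc_formula(self):
        # AICc = -2l + 2k + 2k(k+1)/(n-k-1): with k=2, n=20, -2l=10 -> 14.7059
        k, n, m2l = 2, 20, 10.0
        assert m2l + 2 * k + 2 * k * (k + 1) / (n - k - 1) == pytest.approx(14.7059, abs=1e-4)

    def test_three_models_fit_and_aicc_finite(self, rng):
        n = 40
        mass = rng.normal(1, 0.4, n)
        m1bs = rng.uniform(0.05, 0.2, n)
        y = (rng.random(n) < 0.4).astype(float)
        y[0], y[1] = 1.0, 0.0
        fits = fit_logistic_models(mass, m1bs, y)
        assert set(fits) == {"carnivory", "mass", "interaction"}
        assert all(np.isfinite(f.aicc) for f in fits.values())
        assert fits["interaction"].k == 4

    def test_one_class_outcome_is_na(self, rng):
        fits = fit_logistic_models(rng.normal(size=5), rng.normal(size=5),
                                   np.ones(5))
        assert all(f.na_reason == "one-class outcome" for f in fits.values())

    def test_complete_separation_flagged_with_fallback(self):
        x = np.linspace(-2, 2, 20)
        y = (x > 0).astype(float)
        fits = fit_logistic_models(x, np.zeros(20) + 0.1 * x, y)
        f = fits["mass"]
        assert f.na_reason is not None and "separation" in f.na_reason
        assert np.isfinite(f.aicc)


class TestAkaikeWeights:
    def test_equal_aicc_symmetric(self):
        assert akaike_weights([5.0, 5.0, 5.0]) == pytest.approx([1 / 3] * 3)

    def test_delta_two_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_shift_invariance_and_bruteforce(self, rng):
        a = rng.uniform(10, 40, size=6)
        w1 = akaike_weights(a)
        w2 = akaike_weights(a + 123.4)
        assert w1 == pytest.approx(w2, abs=1e-12)
        brute = np.exp(-a / 2) / np.exp(-a / 2).sum()
        assert w1 == pytest.approx(brute, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            akaike_weights([])


class TestContingency:
    def test_perfect_independence(self):
        lh = np.array([True] * 10 + [False] * 10)
        ext = np.array(([True] * 5 + [False] * 5) * 2)
        chi2, p = resampled_contingency(lh, ext, n_reps=999, seed=0)
        assert chi2 == 0.0 and p == 1.0

    def test_no_large_hypercarnivores_raises(self):
        with pytest.raises(ValidationError, match="constant"):
            resampled_contingency(np.zeros(10, bool),
                                  np.array([True] * 5 + [False] * 5), 99, 0)

    def test_perfect_association_small_p(self):
        v = np.array([True] * 8 + [False] * 8)
        chi2, p = resampled_contingency(v, v, n_reps=999, seed=2)
        assert chi2 == pytest.approx(16.0)
        assert p <= 0.01

    def test_matches_exhaustive_enumeration_small_n(self, rng):
        lh = np.array([True, True, True, False, False, False, False, False])
        ext = np.array([True, True, False, True, False, False, False, True])
        chi2_obs, p_mc = resampled_contingency(lh, ext, n_reps=20_000, seed=9)
        # enumerate all distinct reassignments of lh against ext
        from itertools import permutations
        stats = []
        for perm in set(permutations(lh.tolist())):
            a = int(np.sum(np.array(perm) & ext))
            from canidiv.selectivity import _chi2_2x2
            stats.append(float(_chi2_2x2(np.array(a), lh.sum(), ext.sum(), len(lh))))
        # weight by multiplicity: permutations of identical flags are equally likely
        # -> equivalent to hypergeometric over the (1,1) cell
        from scipy.stats import hypergeom
        from canidiv.selectivity import _chi2_2x2
        support = np.arange(0, min(lh.sum(), ext.sum()) + 1)
        pmf = hypergeom.pmf(support, len(lh), lh.sum(), ext.sum())
        chis = _chi2_2x2(support, int(lh.sum()), int(ext.sum()), len(lh))
        p_exact = float(pmf[chis >= chi2_obs - 1e-12].sum())
        assert p_mc == pytest.approx(p_exact, abs=4 * math.sqrt(p_exact / 20_000) + 1e-3)


class TestBH:
    def test_published_manova_family_flags_only_end_pleistocene(self):
        t = canid_survivor_victim_table()
        flags = bh_adjust(t["P"].to_numpy(float), fdr=0.2)
        flagged = [s for s, f in zip(t["slice_ma"], flags) if f is True]
        assert flagged == [0.01]

    def test_published_contingency_family_flags_none(self):
        t = canid_survivor_victim_table()
        flags = bh_adjust(t["chi2_P"].to_numpy(float), fdr=0.2)
        assert not any(f is True for f in flags)
        assert t["chi2_P"].min() == pytest.approx(0.041)

    def test_all_na(self):
        out = bh_adjust([np.nan, np.nan], 0.2)
        assert all(isinstance(v, float) and np.isnan(v) for v in out)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0.001, 1.0, size=25)
        ours = bh_adjust(p, fdr=0.2)
        from statsmodels.stats.multitest import multipletests
        ref = multipletests(p, alpha=0.2, method="fdr_bh")[0]
        assert [bool(v) for v in ours] == ref.tolist()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_monotone_in_p(self, ps):
        flags = bh_adjust(ps, fdr=0.2)
        flagged_ps = [p for p, f in zip(ps, flags) if f is True]
        if flagged_ps:
            cut = max(flagged_ps)
            assert all(f is True for p, f in zip(ps, flags) if p <= cut)


class TestRunSelectivity:
    def test_report_shape_and_na_reasons(self):
        matrix, profiles = synthgen.simulate_selectivity_data(seed=0)
        rep = run_selectivity(matrix, profiles,
                              SelectivityConfig(n_resamples=199, seed=0))
        assert len(rep) == matrix.scale.n_intervals - 1
        assert set(rep.columns) >= {"slice_ma", "F", "P", "BH_sig", "w_carnivory",
                                    "w_mass", "w_interaction", "chi2", "chi2_P",
                                    "chi2_BH", "na_reason"}
        # weights sum to 1 wherever defined
        w = rep[["w_carnivory", "w_mass", "w_interaction"]].dropna()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_single_species_slice_is_na(self, simple_scale):
        from canidiv.fossilrec import PresenceMatrix
        mat = np.array([[True, True, False, False],
                        [False, False, True, True]])
        matrix = PresenceMatrix(taxa=["a", "b"], scale=simple_scale, matrix=mat)
        profiles = pd.DataFrame({"taxon": ["a", "b"], "log10_mass": [1.0, 0.5],
                                 "m1bs": [0.1, 0.08],
                                 "large_hypercarnivore": [True, False]})
        rep = run_selectivity(matrix, profiles,
                              SelectivityConfig(n_resamples=99, seed=0))
        assert np.isnan(rep["F"]).all()
        assert (rep["na_reason"].str.len() > 0).all()

    def test_null_false_discovery_is_controlled(self):
        flags = 0
        tests = 0
        for rep in range(8):
            matrix, profiles = synthgen.simulate_selectivity_data(
                seed=600 + rep, planted_final_slice=False)
            out = run_selectivity(matrix, profiles,
                                  SelectivityConfig(n_resamples=499, seed=rep))
            flags += sum(1 for v in out["BH_sig"] if v is True)
            tests += int(out["P"].notna().sum())
        # under the global null the expected flagged share is far below FDR
        assert flags / max(tests, 1) <= 0.2

    def test_planted_final_slice_is_detected(self):
        matrix, profiles = synthgen.simulate_selectivity_data(
            seed=3, planted_final_slice=True, p_early_death=0.0)
        rep = run_selectivity(matrix, profiles,
                              SelectivityConfig(n_resamples=999, seed=3))
        assert rep["BH_sig"].iloc[-1] is True
        assert rep["P"].iloc[-1] <= 0.01
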