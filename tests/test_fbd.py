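"""Fossil birth-death likelihoods, HPDs, RJMCMC and its extensions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import canidiv.fbd_mcmc as F
from canidiv.fbd_mcmc import (CovariateLink, FossilDataset, McmcConfig,
                              PiecewiseRateFunction, PreservationModel,
                              bd_loglik, covar_loglik, hpd_interval,
                              model_probabilities, run_covar, run_covariate,
                              run_rjmcmc, shift_histogram,
                              subset_extinction_report, summarize_rates,
                              tpp_loglik)
from canidiv.fossilrec import SpeciesRange, ValidationError


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

class TestBdLoglik:
    def test_constant_rate_closed_form(self):
        lam = PiecewiseRateFunction.constant(0.5)
        mu = PiecewiseRateFunction.constant(0.4)
        rr = [SpeciesRange("a", 5, 2), SpeciesRange("b", 4, 1)]
        expect = 2 * math.log(0.5) + 2 * math.log(0.4) - 0.9 * 6
        assert bd_loglik(rr, lam, mu) == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(-8.6189, abs=1e-4)

    def test_zero_extinction_with_deaths_is_neg_inf(self):
        lam = PiecewiseRateFunction.constant(0.5)
        mu = PiecewiseRateFunction.constant(0.0)
        assert bd_loglik([SpeciesRange("a", 5, 2)], lam, mu) == -np.inf

    def test_piecewise_equals_constant_when_segments_equal(self):
        rr = [SpeciesRange("a", 9, 2), SpeciesRange("b", 6, 0)]
        lam_c = PiecewiseRateFunction.constant(0.5)
        lam_p = PiecewiseRateFunction((7.0, 3.0), (0.5, 0.5, 0.5))
        mu = PiecewiseRateFunction.constant(0.3)
        assert bd_loglik(rr, lam_p, mu) == pytest.approx(
            bd_loglik(rr, lam_c, mu), abs=1e-12)

    def test_extant_species_contribute_no_death_term(self):
        lam = PiecewiseRateFunction.constant(0.5)
        mu = PiecewiseRateFunction.constant(0.4)
        ll = bd_loglik([SpeciesRange("a", 5, 0)], lam, mu)
        assert ll == pytest.approx(math.log(0.5) - 0.9 * 5)

    def test_matches_quadrature_on_random_piecewise(self, rng):
        for _ in range(25):
            k = int(rng.integers(0, 4))
            lam = PiecewiseRateFunction(
                tuple(sorted(rng.uniform(1, 19, k), reverse=True)),
                tuple(rng.uniform(0.05, 1.0, k + 1)))
            k2 = int(rng.integers(0, 4))
            mu = PiecewiseRateFunction(
                tuple(sorted(rng.uniform(1, 19, k2), reverse=True)),
                tuple(rng.uniform(0.05, 1.0, k2 + 1)))
            rr = []
            for i in range(5):
                a, b = np.sort(rng.uniform(0.1, 20, 2))
                rr.append(SpeciesRange(f"s{i}", ts=b, te=a))
            ll = bd_loglik(rr, lam, mu)
            num = 0.0
            for r in rr:
                num += math.log(float(lam.rate_at(r.ts)))
                num += math.log(float(mu.rate_at(r.te)))
                num -= integrate.quad(
                    lambda t: float(lam.rate_at(t)) + float(mu.rate_at(t)),
                    r.te, r.ts, limit=300,
                    points=[s for s in (*lam.shift_times, *mu.shift_times)
                            if r.te < s < r.ts])[0]
            assert ll == pytest.approx(num, abs=1e-8)


class TestTppLoglik:
    def test_constant_q_closed_form(self):
        pm = PreservationModel.constant(1.5, oldest=10.0)
        ll = tpp_loglik({"a": np.array([2.5, 3.0, 3.5])},
                        [SpeciesRange("a", 4, 2)], pm)
        expect = 3 * math.log(1.5) - 3.0 - math.log(1 - math.exp(-3.0))
        assert ll == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(-1.7325, abs=1e-4)

    def test_huge_gamma_shape_reduces_to_homogeneous(self):
        occ = {"a": np.array([2.5, 3.0, 3.5])}
        rr = [SpeciesRange("a", 4, 2)]
        hom = tpp_loglik(occ, rr, PreservationModel.constant(1.5, oldest=10.0))
        het = tpp_loglik(occ, rr, PreservationModel.constant(
            1.5, oldest=10.0, gamma_shape=1e6, n_categories=4))
        assert het == pytest.approx(hom, abs=1e-6)

    def test_heterogeneous_differs_from_homogeneous(self):
        occ = {"a": np.array([2.5, 3.0, 3.5])}
        rr = [SpeciesRange("a", 4, 2)]
        hom = tpp_loglik(occ, rr, PreservationModel.constant(1.5, oldest=10.0))
        het = tpp_loglik(occ, rr, PreservationModel.constant(
            1.5, oldest=10.0, gamma_shape=0.5, n_categories=8))
        assert het != pytest.approx(hom, abs=1e-6)

    def test_occurrence_outside_range_names_species(self):
        pm = PreservationModel.constant(1.0, oldest=10.0)
        with pytest.raises(ValidationError, match="badger"):
            tpp_loglik({"badger": np.array([5.0])},
                       [SpeciesRange("badger", 4, 2)], pm)

    def test_multibin_integral_matches_quadrature(self, rng):
        pm = PreservationModel(bin_edges=(12.0, 8.0, 3.0, 0.0), q=(0.5, 2.0, 1.1))
        for _ in range(20):
            a, b = np.sort(rng.uniform(0, 12, 2))
            exact = float(pm.integral(a, b))
            num = integrate.quad(lambda t: float(pm.rate_at(t)), a, b,
                                 points=[8.0, 3.0], limit=200)[0]
            assert exact == pytest.approx(num, abs=1e-10)


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------

class TestHpd:
    def test_uniform_1_to_100_window(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94.0  # 95 consecutive values

    def test_constant_samples(self):
        assert hpd_interval(np.full(50, 3.3)) == (3.3, 3.3)

    def test_matches_bruteforce_window_search(self, rng):
        x = np.sort(rng.gamma(2.0, 1.0, size=400))
        lo, hi = hpd_interval(x, 0.95)
        m = int(math.ceil(0.95 * len(x)))
        widths = [(x[i + m - 1] - x[i], x[i], x[i + m - 1])
                  for i in range(len(x) - m + 1)]
        bw, blo, bhi = min(widths)
        assert (lo, hi) == (blo, bhi)

    def test_matches_arviz(self, rng):
        import arviz as az
        x = rng.normal(size=2000)
        lo, hi = hpd_interval(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            hpd_interval(np.array([]))


# ---------------------------------------------------------------------------
# Sampler correctness
# ---------------------------------------------------------------------------

def _tiny_dataset(rng, n=25, q=3.0, lam=0.3, mu=0.25, root=25.0):
    from canidiv import synthgen
    cfg = synthgen.SimConfig(
        root_age=root,
        lam=PiecewiseRateFunction.constant(lam, "origination"),
        mu=PiecewiseRateFunction.constant(mu, "extinction"),
        preservation=PreservationModel.constant(q, oldest=root + 10),
        min_sampled_species=n, max_sampled_species=6 * n,
        seed=int(rng.integers(2 ** 31)))
    ds = synthgen.simulate_dataset(cfg)
    return ds


class TestRjmcmc:
    def test_conjugate_posterior_with_fixed_ranges(self, rng):
        """With ts/te and q fixed and no shifts, the lambda posterior is the
        analytic Gamma(a + B, b + S)."""
        ds = _tiny_dataset(rng)
        fd = ds.to_fossil_dataset()
        cfg = McmcConfig(iterations=60_000, burn_in=10_000, thinning=25,
                         seed=2, sample_ranges=False, sample_q=False, rj=False)
        s = run_rjmcmc(fd, cfg)
        # ranges were fixed at their initialized values
        ts = fd.max_occ + 0.2
        te = np.where(fd.extant, 0.0, fd.min_occ * 0.9)
        B, S = fd.n_species, float((ts - te).sum())
        a, b = cfg.rate_prior_shape, cfg.rate_prior_rate
        post_mean = (a + B) / (b + S)
        post_sd = math.sqrt(a + B) / (b + S)
        mid = s.lam_grid.shape[1] // 2
        draws = s.lam_grid[:, mid]
        ess = max(s.ess()["lambda_mid"], 10.0)
        assert draws.mean() == pytest.approx(post_mean,
                                             abs=3 * post_sd / math.sqrt(ess))

    def test_flat_likelihood_recovers_poisson_shift_prior(self, monkeypatch):
        """Detailed-balance smoke test: with the likelihood silenced, the
        sampled shift counts must match the Poisson prior."""
        monkeypatch.setattr(F, "_bd_ll", lambda *a, **k: 0.0)
        ds = FossilDataset(taxa=["a", "b"], occ=[[5.0, 3.0], [8.0, 2.0]],
                           extant=np.array([False, False]))
        cfg = McmcConfig(iterations=300_000, burn_in=20_000, thinning=150,
                         seed=5, sample_ranges=False, sample_q=False)
        s = run_rjmcmc(ds, cfg)
        k = np.concatenate([s.k_lam, s.k_mu])
        obs = np.bincount(k, minlength=8)[:8]
        expect = stats.poisson.pmf(np.arange(8), 1.0)
        expect[7] = 1 - stats.poisson.cdf(6, 1.0)
        obs_m = np.concatenate([obs[:4], [obs[4:].sum()]])
        exp_m = np.concatenate([expect[:4], [expect[4:].sum()]]) * obs.sum()
        _, p = stats.chisquare(obs_m, exp_m)
        assert p > 0.01

    def test_posterior_invariants(self, rng):
        ds = _tiny_dataset(rng)
        s = run_rjmcmc(ds.to_fossil_dataset(),
                       McmcConfig(iterations=8_000, burn_in=2_000, thinning=10,
                                  seed=3))
        assert (s.lam_grid > 0).all() and (s.mu_grid > 0).all()
        assert s.shift_count_table("lambda").sum() == pytest.approx(1.0)
        assert s.shift_count_table("mu").sum() == pytest.approx(1.0)
        assert np.isfinite(s.loglik).all()

    def test_needs_two_species(self):
        ds = FossilDataset(taxa=["a"], occ=[[3.0]], extant=np.array([False]))
        with pytest.raises(ValidationError):
            run_rjmcmc(ds)


# ---------------------------------------------------------------------------
# Posterior reports
# ---------------------------------------------------------------------------

def _fake_summary(k_counts, shifts, span=40.0, n_grid=5):
    n = len(k_counts)
    grid = np.linspace(span, 0, n_grid)
    ones = np.ones((n, n_grid))
    return F.PosteriorSummary(
        grid=grid, lam_grid=0.3 * ones, mu_grid=0.2 * ones,
        k_lam=np.asarray(k_counts), k_mu=np.asarray(k_counts),
        shifts_lam=[np.asarray(s, dtype=float) for s in shifts],
        shifts_mu=[np.asarray(s, dtype=float) for s in shifts],
        rates_lam=[np.r_[0.3, [0.3] * len(s)] for s in shifts],
        rates_mu=[np.r_[0.2, [0.2] * len(s)] for s in shifts],
        q=np.ones((n, 1)), loglik=np.zeros(n), logpost=np.zeros(n),
        span=span, shift_prior_mean=1.0, accept={})


class TestReports:
    def test_model_probabilities_argmax(self):
        counts = [0] * 6 + [1] * 3 + [2] * 1
        s = _fake_summary(counts, [[]] * 6 + [[10.0]] * 3 + [[10.0, 5.0]])
        mp = model_probabilities(s)
        assert mp["origination"].tolist() == pytest.approx([0.6, 0.3, 0.1])
        assert mp.loc[mp["origination_best"], "model"].iloc[0] == "1-rate"
        assert mp["origination"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_shift_histogram_zero_logbf_when_posterior_equals_prior(self):
        span, width = 40.0, 1.0
        prior_occ = 1 - math.exp(-1.0 * width / span)
        n = 10_000
        k = int(round(prior_occ * n))
        shifts = [[0.5]] * k + [[]] * (n - k)
        s = _fake_summary([len(x) for x in shifts], shifts, span=span)
        h = shift_histogram(s, "lambda", bin_width=width)
        assert h["logBF"].iloc[0] == pytest.approx(0.0, abs=0.02)

    def test_concentrated_shifts_exceed_strong_threshold(self):
        shifts = [[10.5]] * 400
        s = _fake_summary([1] * 400, shifts)
        h = shift_histogram(s, "lambda")
        row = h[(h["bin_young_ma"] <= 10.5) & (h["bin_old_ma"] > 10.5)].iloc[0]
        assert row["logBF"] > 6 and row["strong"] and row["positive"]

    def test_strong_implies_positive(self):
        shifts = [[10.5]] * 300 + [[]] * 100
        s = _fake_summary([1] * 300 + [0] * 100, shifts)
        h = shift_histogram(s, "lambda")
        assert not (h["strong"] & ~h["positive"]).any()

    def test_summarize_rates_ordering(self, rng):
        n = 300
        grid = np.linspace(40, 0, 9)
        lam = rng.gamma(9, 1 / 30, size=(n, 9))
        mu = rng.gamma(4, 1 / 20, size=(n, 9))
        s = _fake_summary([0] * n, [[]] * n, n_grid=9)
        s.lam_grid, s.mu_grid = lam, mu
        out = summarize_rates(s)
        assert (out["lambda_hpd_lo"] <= out["lambda_mean"]).all()
        assert (out["lambda_mean"] <= out["lambda_hpd_hi"]).all()
        assert out["net_mean"].to_numpy() == pytest.approx(
            (lam - mu).mean(axis=0))

    def test_subset_report_exposes_mu_only(self):
        s = _fake_summary([0] * 200, [[]] * 200)
        out = subset_extinction_report(s, subset_run=True)
        assert [c for c in out.columns if c.startswith("lambda")] == []
        assert {"mu_mean", "mu_hpd_lo", "mu_hpd_hi"} <= set(out.columns)
        assert "note" in out.attrs
        full = subset_extinction_report(s, subset_run=False)
        assert "lambda_mean" in full.columns

    def test_two_subset_reports_share_grid(self):
        s1 = _fake_summary([0] * 200, [[]] * 200)
        s2 = _fake_summary([0] * 150, [[]] * 150)
        g = np.linspace(40, 0, 21)
        r1 = subset_extinction_report(s1, grid=g)
        r2 = subset_extinction_report(s2, grid=g)
        assert np.array_equal(r1["age_ma"], r2["age_ma"])


# ---------------------------------------------------------------------------
# Trait and covariate extensions
# ---------------------------------------------------------------------------

class TestCovar:
    def test_alpha_zero_reduces_to_constant_rate_bd(self, rng):
        n = 12
        ts = rng.uniform(5, 20, n)
        te = ts - rng.uniform(0.5, 4, n)
        te[te < 0] = 0
        ext = te > 0
        x = rng.normal(size=n)
        ll = covar_loglik(ts, te, ext, x, np.ones(n), np.ones(n),
                          0.3, 0.2, 0.0, 0.0)
        rr = [SpeciesRange(f"s{i}", float(a), float(b))
              for i, (a, b) in enumerate(zip(ts, te))]
        ref = bd_loglik(rr, PiecewiseRateFunction.constant(0.3),
                        PiecewiseRateFunction.constant(0.2))
        assert ll == pytest.approx(ref, abs=1e-9)

    def test_constant_trait_warns_and_posterior_matches_prior(self, rng):
        ds = _tiny_dataset(rng)
        fd = ds.to_fossil_dataset()
        traits = pd.DataFrame({"taxon": fd.taxa,
                               "log10_mass": np.ones(fd.n_species),
                               "carnivory_class": ["meso"] * fd.n_species})
        cfg = McmcConfig(iterations=20_000, burn_in=4_000, thinning=10, seed=4)
        with pytest.warns(UserWarning, match="unidentifiable"):
            post = run_covar(fd, traits, cfg)
        # alpha posterior should look like its Normal(0,1) prior
        assert abs(post.alpha_mu.samples.mean()) < 0.25
        assert 0.6 < post.alpha_mu.samples.std() < 1.4

    def test_missing_traits_error(self, rng):
        ds = _tiny_dataset(rng)
        fd = ds.to_fossil_dataset()
        traits = pd.DataFrame({"taxon": fd.taxa[:2],
                               "log10_mass": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="missing"):
            run_covar(fd, traits, McmcConfig(iterations=100, burn_in=10))


class TestCovariate:
    def test_gamma_zero_matches_constant_rate_loglik(self):
        # with a flat (centered) covariate the exponential link is exactly
        # the constant-rate model whatever gamma does; check z interpolation
        link = CovariateLink(ages=(50.0, 0.0), values=(0.7, 0.7))
        assert float(link.z(np.array([25.0]))[0]) == pytest.approx(0.7)

    def test_flat_curve_warns_unidentifiable(self, rng):
        ds = _tiny_dataset(rng)
        link = CovariateLink(ages=(60.0, 0.0), values=(0.5, 0.5))
        cfg = McmcConfig(iterations=15_000, burn_in=3_000, thinning=10, seed=6)
        with pytest.warns(UserWarning, match="unidentifiable"):
            post = run_covariate(ds.to_fossil_dataset(), link, cfg)
        assert abs(post.gamma_mu.samples.mean()) < 0.3

    def test_linear_link_rejects_negative_rates(self, rng):
        ds = _tiny_dataset(rng)
        curve = pd.DataFrame({"age_ma": np.linspace(60, 0, 50),
                              "d18O": np.linspace(-2, 2, 50)})
        link = CovariateLink.from_frame(curve, link="linear")
        cfg = McmcConfig(iterations=10_000, burn_in=2_000, thinning=10, seed=7,
                         walk_sd=0.5)
        fd = ds.to_fossil_dataset()
        post = run_covariate(fd, link, cfg)
        # every retained gamma must keep 1 + gamma * z(t) positive over the
        # clade span (z centered by its time-average over the span)
        span_grid = np.linspace(0, fd.span, 400)
        zc = link.z(span_grid) - np.trapezoid(link.z(span_grid), span_grid) / fd.span
        for g in np.concatenate([post.gamma_lambda.samples,
                                 post.gamma_mu.samples]):
            assert np.min(1 + g * zc) > 0

    def test_curve_must_span_clade(self, rng):
        ds = _tiny_dataset(rng)
        link = CovariateLink(ages=(5.0, 0.0), values=(0.1, 0.2))
        with pytest.raises(ValidationError, match="span"):
            run_covariate(ds.to_fossil_dataset(), link,
                          McmcConfig(iterations=100, burn_in=10))
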