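"""Quantile-exponential trade-off fits against independent oracles, plus the
environmental, resampling and sampling-bias diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from ringlife import ring_io
from ringlife import synthetic_data as sd
from ringlife import tradeoff as trd
from ringlife.types import summaries_to_frame, TreeSummary


def brute_force_quantile_line(x, y, q):
    """Independent oracle: score every line through a pair of points by total
    pinball loss; lowest loss wins, ties broken by smallest |slope|."""
    best = None
    n = len(x)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            b = (y[j] - y[i]) / (x[j] - x[i])
            a = y[i] - b * x[i]
            r = y - (a + b * x)
            loss = float(np.sum(np.where(r >= 0, q * r, (q - 1.0) * r)))
            key = (loss, abs(b))
            if best is None or key < best[0]:
                best = (key, a, b)
    return best[1], best[2]


def frame(x, y):
    return pd.DataFrame({"early_growth": np.asarray(x, float), "age": np.asarray(y, float)})


class TestQuantileFit:
    def test_matches_exhaustive_oracle_on_small_samples(self):
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            x = rng.uniform(0.2, 3.2, n)
            y = np.exp(rng.normal(4.5, 0.8, n))
            fit = trd.fit_quantile_exponential(frame(x, y), n_boot=0, min_n=2)
            a_o, b_o = brute_force_quantile_line(x, np.log(y), 0.95)
            assert fit.decay == pytest.approx(b_o, abs=1e-9)
            assert fit.intercept == pytest.approx(a_o, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 5.0), st.floats(1.1, 500.0)),
                    min_size=4, max_size=10, unique_by=lambda t: round(t[0], 6)))
    def test_oracle_equivalence_property(self, pts):
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        fit = trd.fit_quantile_exponential(frame(x, y), n_boot=0, min_n=2)
        a_o, b_o = brute_force_quantile_line(x, np.log(y), 0.95)
        loss_fit = trd.pinball_loss(np.log(y) - (fit.intercept + fit.decay * x), 0.95)
        loss_o = trd.pinball_loss(np.log(y) - (a_o + b_o * x), 0.95)
        assert loss_fit <= loss_o + 1e-9

    def test_flat_ages_give_zero_slope(self):
        x = np.linspace(0.5, 3.0, 30)
        fit = trd.fit_quantile_exponential(frame(x, np.full(30, 100.0)), n_boot=0)
        assert fit.decay == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(100.0), abs=1e-12)

    def test_no_growth_variance_rejected(self):
        with pytest.raises(ValueError, match="no growth variance"):
            trd.fit_quantile_exponential(frame(np.ones(30), np.arange(1, 31)), n_boot=0)

    def test_agrees_with_statsmodels_quantreg(self, known_sample_10k):
        """Independent cross-check: the IRLS solver in statsmodels lands on
        the same coefficients for a well-conditioned large sample."""
        _, df = known_sample_10k
        sub = df.iloc[:2000]
        fit = trd.fit_quantile_exponential(sub, n_boot=0)
        X = sm.add_constant(sub["early_growth"].to_numpy())
        res = sm.QuantReg(np.log(sub["age"].to_numpy()), X).fit(q=0.95)
        assert fit.intercept == pytest.approx(res.params[0], abs=0.02)
        assert fit.decay == pytest.approx(res.params[1], abs=0.02)

    def test_quantile_coverage(self, known_sample_10k):
        """About q*n points lie below the fitted curve."""
        _, df = known_sample_10k
        sub = df.iloc[:1000]
        fit = trd.fit_quantile_exponential(sub, n_boot=0)
        below = np.sum(
            np.log(sub["age"].to_numpy())
            < fit.intercept + fit.decay * sub["early_growth"].to_numpy()
        )
        assert abs(below - 0.95 * len(sub)) <= 2

    def test_bootstrap_pvalue_detects_real_slope(self):
        cfg = sd.KnownTradeoffConfig(b_true=-0.5, n=400, seed=6)
        df = sd.generate_known_tradeoff_sample(cfg)
        fit = trd.fit_quantile_exponential(df, n_boot=200, random_state=0)
        assert fit.p_value < 0.05

    def test_slope_error_at_field_sample_size(self):
        """Monte-Carlo: the mean absolute relative slope error of 300-tree
        refits stays well under 25%. (The log-uniform residual of the
        known-quantile generator is dense near its upper quantile, so the
        error here is much smaller than for field age data.)"""
        errs = []
        for rep in range(120):
            df = sd.generate_known_tradeoff_sample(
                sd.KnownTradeoffConfig(b_true=-0.5, n=300, seed=1000 + rep)
            )
            f = trd.fit_quantile_exponential(df, n_boot=0)
            errs.append(abs(f.decay - (-0.5)) / 0.5)
        mare = float(np.mean(errs))
        assert 0.0 < mare < 0.25


class TestNormalizeAndPool:
    def test_species_maxima_scale_to_one(self):
        rows = [
            TreeSummary("a", 1.0, 100, 40.0, species="X"),
            TreeSummary("b", 2.0, 50, 40.0, species="X"),
        ]
        rel = trd.normalize_relative(summaries_to_frame(rows))
        assert sorted(zip(rel["early_growth"], rel["age"])) == [(0.5, 1.0), (1.0, 0.5)]

    def test_singleton_species_dropped_and_empty_rejected(self):
        rows = [
            TreeSummary("a", 1.0, 100, 40.0, species="X"),
            TreeSummary("b", 2.0, 50, 40.0, species="X"),
            TreeSummary("c", 1.5, 60, 40.0, species="Y"),
        ]
        rel = trd.normalize_relative(summaries_to_frame(rows))
        assert set(rel["species"]) == {"X"}
        with pytest.raises(ValueError):
            trd.normalize_relative(summaries_to_frame([]))

    def test_weighted_mean_decay(self):
        mk = lambda b, n: trd.TradeoffFit(5.0, b, 0.95, n)
        # cube-root weights: n=8 -> 2, n=27 -> 3
        mean, n_neg = trd.weighted_mean_decay([mk(-0.2, 8), mk(-0.6, 27)])
        assert mean == pytest.approx((2 * -0.2 + 3 * -0.6) / 5)
        assert n_neg == 2
        mean_eq, _ = trd.weighted_mean_decay([mk(-0.1, 50), mk(-0.5, 50)])
        assert mean_eq == pytest.approx(-0.3)
        single, _ = trd.weighted_mean_decay([mk(-0.42, 10)])
        assert single == pytest.approx(-0.42)

    def test_weighted_mean_invariant_to_order(self):
        fits = [trd.TradeoffFit(5.0, b, 0.95, n) for b, n in [(-0.2, 8), (-0.6, 27), (0.1, 64)]]
        m1, _ = trd.weighted_mean_decay(fits)
        m2, _ = trd.weighted_mean_decay(fits[::-1])
        assert m1 == pytest.approx(m2)


class TestBinnedCheck:
    def test_single_bin_is_overall_percentile(self, known_sample_10k):
        _, df = known_sample_10k
        table, _ = trd.binned_quantile_check(df, n_bins=1)
        assert table.loc[0, "empirical_quantile_age"] == pytest.approx(
            np.percentile(df["age"], 95)
        )

    def test_deviation_small_on_generated_quantile_curve(self, known_sample_10k):
        _, df = known_sample_10k
        table, max_dev = trd.binned_quantile_check(df, n_bins=10)
        assert max_dev < 0.10


class TestMajorAxis:
    def test_exact_line(self):
        x = np.linspace(0, 5, 10)
        fit = trd.fit_major_axis(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_symmetric_cloud_gives_unit_slope(self):
        rng = np.random.default_rng(3)
        z1 = rng.normal(0, 1, 4000)
        z2 = rng.normal(0, 1, 4000)
        x, y = z1 + 0.5 * z2, z1 - 0.5 * z2 + 0.0
        # rotate so var(x)=var(y) and cov>0 by construction: use exchangeable pair
        x, y = z1 + 0.3 * z2, 0.3 * z2 + z1 * 0.999 + rng.normal(0, 0.04, 4000)
        fit = trd.fit_major_axis(x, y)
        assert fit.slope == pytest.approx(1.0, abs=0.05)

    def test_matches_eigen_decomposition_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.5, 4.0])
        y = np.array([1.0, 0.5, 2.5, 3.0, 5.0])
        cov = np.cov(x, y, ddof=1)
        w, v = np.linalg.eigh(cov)
        vec = v[:, np.argmax(w)]
        fit = trd.fit_major_axis(x, y)
        assert fit.slope == pytest.approx(vec[1] / vec[0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            trd.fit_major_axis(np.ones(5), np.arange(5.0))


@pytest.fixture(scope="module")
def env_population():
    """Population where temperature affects growth only (trade-off is direct)."""
    series, sites = sd.generate_population(
        sd.SynthConfig(n_trees=4000, n_sites=30, temp_growth_slope=0.12, seed=31)
    )
    summaries, _ = ring_io.summarize_trees(series)
    return summaries, sites


class TestStratified:
    def test_tradeoff_survives_temperature_control(self, env_population):
        summaries, sites = env_population
        fits = trd.stratified_tradeoff(summaries, sites, "temperature", n_boot=0)
        assert len(fits) >= 2
        big = [f for f in fits if f.n >= 200]
        assert all(f.decay < 0 for f in big)

    def test_temperature_effect_vanishes_at_fixed_growth(self, env_population):
        summaries, sites = env_population
        fits = trd.stratified_tradeoff(summaries, sites, "growth_band", n_boot=0)
        slopes = np.array([f.decay for f in fits])
        # temperature slopes within growth bands hover around zero
        assert np.max(np.abs(slopes)) < 0.25
        assert abs(np.mean(slopes)) < 0.1

    def test_single_stratum_reduces_to_plain_fit(self, env_population):
        summaries, sites = env_population
        site_df = trd.sites_to_frame(sites) if not isinstance(sites, pd.DataFrame) else sites
        fits = trd.stratified_tradeoff(summaries, sites, "temperature",
                                       temp_class_width=100.0, n_boot=0)
        assert len(fits) == 1
        plain = trd.fit_quantile_exponential(summaries, n_boot=0)
        assert fits[0].decay == pytest.approx(plain.decay, abs=1e-9)

    def test_small_strata_skipped(self, env_population):
        summaries, sites = env_population
        fits = trd.stratified_tradeoff(summaries.head(10), sites, "temperature", n_boot=0)
        assert fits == []


class TestSitePooling:
    def _mk(self, site_counts, coords):
        rows = []
        sites = []
        from ringlife.types import SiteRecord

        for (site, n), (lat, lon) in zip(site_counts.items(), coords):
            sites.append(SiteRecord(site_id=site, lat=lat, lon=lon, mat=0.0, map_mm=600.0))
            for i in range(n):
                rows.append(TreeSummary(f"{site}_{i}", 1.0, 50 + i, 40.0, site_id=site, species="SP"))
        return summaries_to_frame(rows), sites

    def test_large_sites_unchanged(self):
        df, sites = self._mk({"A": 35, "B": 40}, [(50, -70), (55, -75)])
        pooled = trd.site_level_aggregate(df, sites)
        assert len(pooled) == 2
        assert sorted(pooled["n"]) == [35, 40]

    def test_two_small_neighbours_pool(self):
        df, sites = self._mk({"A": 15, "B": 15}, [(50.0, -70.0), (50.01, -70.0)])
        pooled = trd.site_level_aggregate(df, sites)
        assert len(pooled) == 1 and pooled.loc[0, "n"] == 30

    def test_isolated_small_site_merges_with_nearest(self):
        df, sites = self._mk(
            {"A": 35, "B": 5, "C": 40}, [(50, -70), (50.1, -70), (58, -60)]
        )
        pooled = trd.site_level_aggregate(df, sites)
        assert len(pooled) == 2
        merged = pooled[pooled["site_ids"].str.contains("B")].iloc[0]
        assert "A" in merged["site_ids"] and merged["n"] == 40


class TestResampling:
    def test_full_sample_always_contains_maximum(self):
        ages = np.random.default_rng(0).uniform(20, 300, 200)
        out = trd.resample_max_age(ages, sizes=[200], reps=50, seed=1)
        assert out.loc[0, "frac_above_p95"] == 1.0

    def test_single_draw_probability(self):
        ages = np.random.default_rng(2).uniform(20, 300, 5000)
        out = trd.resample_max_age(ages, sizes=[1], reps=4000, seed=3)
        assert out.loc[0, "frac_above_p95"] == pytest.approx(0.05, abs=0.015)

    def test_hundred_tree_closed_form(self):
        """Tie-free ages: P(max of 100 > p95) ~ 1 - 0.95^100 ~ 0.994."""
        ages = np.random.default_rng(4).uniform(20.0, 300.0, 12_000)
        out = trd.resample_max_age(ages, sizes=[100], reps=500, seed=5)
        p = 1.0 - 0.95**100
        se = np.sqrt(p * (1 - p) / 500)
        assert abs(out.loc[0, "frac_above_p95"] - p) <= 3 * se + 1e-9

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            trd.resample_max_age(np.arange(10.0), sizes=[11], reps=5, seed=0)

    def test_error_curve_zero_at_full_size_and_decreasing(self):
        df = sd.generate_known_tradeoff_sample(sd.KnownTradeoffConfig(b_true=-0.5, n=800, seed=9))
        out = trd.sample_size_error_curve(df, sizes=[50, 200, 800], reps=40, seed=10)
        assert out.loc[2, "mean_abs_rel_error"] == pytest.approx(0.0, abs=1e-12)
        errs = out["mean_abs_rel_error"].to_numpy()
        assert errs[0] > errs[1] > errs[2]


@pytest.fixture(scope="module")
def bias_trajectories():
    series, _ = sd.generate_population(sd.SynthConfig(n_trees=1500, seed=13))
    return [s for s in series if s.age >= 10]


class TestBigTreeBias:
    def test_self_consistent_frequency_recovers_population_fit(self, bias_trajectories):
        sizes = np.array([t.max_diameter for t in bias_trajectories])
        edges = np.arange(0.0, sizes.max() + 20.0, 20.0)
        counts, _ = np.histogram(sizes, bins=edges)
        freq = pd.DataFrame({"bin_low_mm": edges[:-1], "count": counts})
        res = trd.big_tree_bias_experiment(bias_trajectories, freq, seed=1)
        assert res["all"]["ratio_to_all"] == 1.0
        assert res["all"]["fit"].decay < 0

    def test_threshold_sampling_weakens_tradeoff(self, bias_trajectories):
        """Under a field-realistic (steeply declining) stand size structure,
        coring only trees above the protocol threshold slightly weakens the
        apparent trade-off."""
        edges = np.arange(0.0, 360.0, 20.0)
        counts = (3000 * np.exp(-edges[:-1] / 80.0)).astype(int)
        freq = pd.DataFrame({"bin_low_mm": edges[:-1], "count": counts})
        res = trd.big_tree_bias_experiment(bias_trajectories, freq, seed=2)
        b_all = res["all"]["fit"].decay
        b_thr = res["threshold"]["fit"].decay
        b_top = res["top10pct"]["fit"].decay
        assert b_all < 0 and b_thr < 0 and b_top < 0
        assert abs(b_thr) <= abs(b_all)


class TestLambdaEstimate:
    def test_published_constants_evaluate_as_stated(self):
        lam = trd.PUBLISHED_LAMBDA
        assert lam(0.0) == pytest.approx(0.229)
        assert lam(100.0) == pytest.approx(0.0000132 * 1e4 - 0.00291 * 100 + 0.229)
        assert lam(100.0) == pytest.approx(0.070, abs=1e-6)
        assert lam(135.0) == pytest.approx(0.07)
        assert lam(400.0) == pytest.approx(0.07)

    def test_recovers_known_sensitivity(self):
        """Trees whose widths respond as exp(lam_true(A) * MAT) recover the
        band sensitivities within 10%."""
        rng = np.random.default_rng(17)
        from ringlife.types import RingSeries, SiteRecord

        lam_true = trd.PUBLISHED_LAMBDA
        sites = [
            SiteRecord(site_id=f"S{i}", lat=50, lon=-70, mat=float(t), map_mm=600.0)
            for i, t in enumerate(np.linspace(-4, 4, 9))
        ]
        series = []
        ages = np.arange(1, 161)
        for i in range(2000):
            site = sites[i % len(sites)]
            base = 1.2 * np.exp(-0.004 * ages)
            noise = np.exp(rng.normal(0.0, 0.1, ages.size))
            w = base * np.exp(lam_true(ages) * site.mat) * noise
            series.append(RingSeries(tree_id=f"T{i}", widths=w, site_id=site.site_id))
        fit = trd.estimate_lambda(series, sites)
        centers = 0.5 * (fit.band_edges[:-1] + fit.band_edges[1:])
        ok = np.isfinite(fit.band_lambdas)
        np.testing.assert_allclose(fit.band_lambdas[ok], lam_true(centers)[ok], rtol=0.10)
        assert fit.plateau == pytest.approx(0.07, rel=0.1)

    def test_insufficient_gradient_rejected(self):
        from ringlife.types import RingSeries, SiteRecord

        sites = [SiteRecord(site_id="S0", lat=50, lon=-70, mat=1.0, map_mm=600.0)]
        series = [RingSeries(tree_id="T0", widths=np.ones(50), site_id="S0")]
        with pytest.raises(ValueError, match="MAT spans"):
            trd.estimate_lambda(series, sites)
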