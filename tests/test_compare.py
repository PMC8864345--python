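"""Cross-phenomenon comparison: correlation, summary statistics, the full
report."""

import numpy as np
import pytest

from metacompare import (
    AnalysisConfig,
    MetaDataset,
    PhenomenonPair,
    SuiteTemplate,
    correlate_estimates,
    fit_random_effects,
    run_full_comparison,
    sensitivity_summary,
    simulate_phenomenon_suite,
    worst_case_estimate,
)
from metacompare.calibrate import bca_ci_for_proportion
from metacompare.compare import correlation_p_value, fisher_ci


def pairs_from_values(ma_values, mlr_values):
    """Build degenerate one-study pairs whose naive fit equals ma_values."""
    pairs, fits = [], []
    for i, (ma, mlr) in enumerate(zip(ma_values, mlr_values)):
        d = MetaDataset.from_arrays([ma], [0.01], phenomenon_id=f"p{i}")
        pairs.append(PhenomenonPair(meta=d, mlr_estimate=mlr, mlr_variance=0.001))
        fits.append(fit_random_effects(d))
    return pairs, fits


class TestCorrelation:
    def test_identity_gives_perfect_fit(self):
        vals = [0.1, 0.3, 0.5, 0.7]
        pairs, fits = pairs_from_values(vals, vals)
        res = correlate_estimates(pairs, fits)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_fisher_interval_and_p_reproduce_reference_case(self):
        """r = 0.72 with n = 15 phenomena: Fisher-z CI ~ [0.32, 0.90] and
        t-based two-sided p ~ 0.003.  R's cor.test returns (0.3291, 0.9002,
        p = 0.00247) for this exact configuration; reported values based on
        the unrounded correlation differ in the last digit, hence the 0.01
        tolerance on the bounds."""
        lo, hi = fisher_ci(0.72, 15)
        assert lo == pytest.approx(0.3291299, abs=1e-6)  # matches R cor.test
        assert hi == pytest.approx(0.9002312, abs=1e-6)
        assert lo == pytest.approx(0.32, abs=0.01)
        assert hi == pytest.approx(0.90, abs=0.01)
        assert correlation_p_value(0.72, 15) == pytest.approx(0.003, abs=1e-3)

    def test_matches_brute_force_covariance(self, rng):
        for _ in range(10):
            ma = rng.normal(0.4, 0.2, size=8)
            mlr = 0.5 * ma + rng.normal(0, 0.1, size=8)
            pairs, fits = pairs_from_values(ma, mlr)
            res = correlate_estimates(pairs, fits)
            x = np.array([f.mu for f in fits])
            cov = np.mean((x - x.mean()) * (mlr - mlr.mean()))
            expected = cov / (x.std() * mlr.std())
            assert res.r == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        pairs, fits = pairs_from_values([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError, match="at least 3"):
            correlate_estimates(pairs, fits)

    def test_zero_variance_rejected(self):
        pairs, fits = pairs_from_values([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_estimates(pairs, fits)


class TestSensitivitySummary:
    def _inputs(self, naive_worst_mlr):
        """Build aligned inputs from (naive, worst|None, mlr) triples using
        one-study datasets (naive fit = the single estimate)."""
        from metacompare import RandomEffectsResults, SensitivityResult

        pairs, fits, sens, phats = [], [], [], []
        for i, (naive, worst, mlr) in enumerate(naive_worst_mlr):
            d = MetaDataset.from_arrays([naive], [0.01], phenomenon_id=f"p{i}")
            pairs.append(
                PhenomenonPair(meta=d, mlr_estimate=mlr, mlr_variance=0.001)
            )
            fits.append(fit_random_effects(d))
            sens.append(
                SensitivityResult(
                    eta=np.inf,
                    corrected_mu=None,
                    worst_case_mu=worst,
                    n_affirmative=0,
                    n_nonaffirmative=1 if worst is not None else 0,
                    estimable=worst is not None,
                )
            )
            phats.append(None)
        return pairs, fits, sens, phats

    def test_direct_arithmetic(self):
        pairs, fits, sens, phats = self._inputs(
            [(0.4, 0.2, 0.0), (0.2, 0.1, 0.0)]
        )
        s = sensitivity_summary(pairs, fits, sens, phats)
        assert s.n_analyzed == 2
        assert s.mean_naive == pytest.approx(0.3)
        assert s.mean_worst_case == pytest.approx(0.15)
        assert s.mean_ratio == pytest.approx(0.5)
        assert s.ratio_of_means == pytest.approx(0.5)
        assert s.mean_abs_diff == pytest.approx(0.15)
        assert s.prop_worst_exceeds_mlr == 1.0
        assert s.prop_worst_exceeds_null == 1.0

    def test_filter_excludes_naive_below_mlr_and_inestimable(self):
        pairs, fits, sens, phats = self._inputs(
            [
                (0.4, 0.2, 0.5),   # naive < MLR -> excluded
                (0.4, None, 0.0),  # worst case not estimable -> excluded
                (0.3, 0.1, 0.0),
            ]
        )
        s = sensitivity_summary(pairs, fits, sens, phats)
        assert s.n_analyzed == 1
        assert s.mean_naive == pytest.approx(0.3)

    def test_all_filtered_out(self):
        pairs, fits, sens, phats = self._inputs([(0.1, 0.05, 0.5)])
        s = sensitivity_summary(pairs, fits, sens, phats)
        assert s.n_analyzed == 0
        assert s.mean_naive is None


@pytest.fixture(scope="module")
def suite():
    return simulate_phenomenon_suite(
        SuiteTemplate(n_phenomena=8, k_range=(8, 15)), seed=21
    )


class TestFullComparison:

    def test_report_structure(self, suite):
        cfg = AnalysisConfig(seed=21, n_boot=200, eta_list=(1.0, 5.0))
        rep = run_full_comparison(suite, cfg)
        assert len(rep.per_phenomenon) == 8
        assert rep.correlation is not None
        assert set(rep.corrected["eta"]) == {1.0, 5.0}
        assert rep.summary.n_analyzed <= 8
        text = rep.summary_text()
        assert "Pearson r" in text

    def test_deterministic_byte_identical(self, suite):
        cfg = AnalysisConfig(seed=21, n_boot=200)
        j1 = run_full_comparison(suite, cfg).to_json()
        j2 = run_full_comparison(suite, cfg).to_json()
        assert j1 == j2

    def test_order_invariance(self, suite):
        cfg = AnalysisConfig(seed=21, n_boot=200)
        rep1 = run_full_comparison(suite, cfg)
        rep2 = run_full_comparison(list(reversed(suite)), cfg)
        assert rep1.to_json() == rep2.to_json()

    def test_single_phenomenon_partial_output(self, suite):
        rep = run_full_comparison(suite[:1], AnalysisConfig(n_boot=200))
        assert rep.correlation is None
        assert len(rep.per_phenomenon) == 1
        assert "naive_mu" in rep.per_phenomenon.columns

    def test_no_bias_world_concentrates_near_no_discrepancy(self):
        """eta=1 and mlr_mu = mu_true: the regression of MLR on MA
        estimates has slope near 1, and in a low-power literature (where
        almost every study is non-affirmative, so the worst-case subset is
        nearly the full set) the worst/naive ratio sits near 1 and the
        worst case rarely drops below zero."""
        from metacompare import SimConfig

        # low-power regime: small studies, homogeneous positive effects ->
        # few affirmative studies, so the worst-case subset ~ the full set
        t_lowpow = SuiteTemplate(
            n_phenomena=12, eta=1.0, mlr_offset=0.0, k_range=(20, 30),
            mu_mean=0.25, mu_sd=0.05, tau2_range=(0.001, 0.01),
            base=SimConfig(n_range=(10, 20)),
        )
        ratios, exceed_null = [], []
        for seed in range(8):
            rep = run_full_comparison(
                simulate_phenomenon_suite(t_lowpow, seed=seed),
                AnalysisConfig(seed=seed),
                compute_phat_ci=False,
            )
            if rep.summary.n_analyzed >= 3:
                ratios.append(rep.summary.mean_ratio)
                exceed_null.append(rep.summary.prop_worst_exceeds_null)
        assert 0.6 <= np.mean(ratios) <= 1.1
        assert np.mean(exceed_null) > 0.9

        # precise-estimation regime: large studies and wide mu spread ->
        # attenuation vanishes and the MLR-on-MA slope approaches 1
        t_precise = SuiteTemplate(
            n_phenomena=12, eta=1.0, mlr_offset=0.0, k_range=(30, 40),
            mu_mean=0.3, mu_sd=0.3, tau2_range=(0.005, 0.02),
            base=SimConfig(n_range=(300, 500), mlr_n=40_000),
        )
        slopes = [
            run_full_comparison(
                simulate_phenomenon_suite(t_precise, seed=seed),
                AnalysisConfig(seed=seed),
                compute_phat_ci=False,
            ).correlation.slope
            for seed in range(8)
        ]
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)

    def test_worst_case_conservative_even_without_bias(self):
        """In a well-powered eta=1 world the worst case still sits below
        the naive estimate: discarding significant-positive studies is a
        bound, not an unbiased correction."""
        t = SuiteTemplate(
            n_phenomena=10, eta=1.0, mlr_offset=0.0, k_range=(20, 30),
            mu_mean=0.5, mu_sd=0.1, tau2_range=(0.01, 0.05),
        )
        pairs = simulate_phenomenon_suite(t, seed=4)
        rep = run_full_comparison(
            pairs, AnalysisConfig(seed=4), compute_phat_ci=False
        )
        assert rep.summary.n_analyzed >= 3
        assert rep.summary.mean_ratio < 1.0

    def test_mean_ratio_bounded_by_one_when_worst_below_naive(self, suite):
        rep = run_full_comparison(
            suite, AnalysisConfig(seed=21), compute_phat_ci=False
        )
        df = rep.per_phenomenon[rep.per_phenomenon["included"]]
        if len(df) and (df["worst_case_mu"] <= df["naive_mu"]).all():
            assert rep.summary.mean_ratio <= 1.0
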