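"""Per-draw OLS, threshold classification, and the Monte Carlo aggregate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesothresh import (
    ContractError,
    LinearFit,
    McConfig,
    MonteCarloThreshold,
    SingularDesignError,
    SyntheticDesign,
    classify_threshold,
    generate_linear_threshold_cohorts,
    ols_fit,
    run_mc,
    threshold_estimate,
)


class TestOlsFit:
    def test_noiseless_line_recovered(self):
        ce = np.array([10.0, 50.0, 200.0, 600.0])
        fit = ols_fit(ce, 2.0 + 3.0 * ce)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.slope == pytest.approx(3.0)

    def test_constant_response(self):
        fit = ols_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(5.0)

    def test_central_table1_fit(self, table1):
        fit = MonteCarloThreshold(table1).central_fit()
        assert fit.intercept == pytest.approx(-0.0425670, rel=1e-5)
        assert fit.slope == pytest.approx(0.00146986, rel=1e-5)
        assert -fit.intercept / fit.slope == pytest.approx(28.96, abs=0.01)

    @pytest.mark.parametrize("ce, y", [
        ([1.0, 2.0], [1.0, 2.0]),            # too few points
        ([3.0, 3.0, 3.0], [1.0, 2.0, 3.0]),  # no exposure variance
    ])
    def test_degenerate_designs_rejected(self, ce, y):
        with pytest.raises(SingularDesignError):
            ols_fit(ce, y)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_statsmodels(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        ce = rng.uniform(1, 800, 8)
        y = rng.normal(0.1 + 0.002 * ce, 0.05)
        fit = ols_fit(ce, y)
        ref = sm.OLS(y, sm.add_constant(ce)).fit().params
        assert fit.intercept == pytest.approx(ref[0], rel=1e-9, abs=1e-12)
        assert fit.slope == pytest.approx(ref[1], rel=1e-9, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("a, b, expected", [
        (-0.04, 0.0015, True),
        (0.1, 0.001, False),
        (-1.0, 0.0, False),   # B > 0 is strict
        (0.0, 0.001, True),   # A <= 0 is inclusive
    ])
    def test_rule(self, a, b, expected):
        assert classify_threshold(LinearFit(a, b)) is expected

    @pytest.mark.parametrize("a, b, expected", [
        (-1.0, 0.5, 2.0),
        (0.0, 1.0, 0.0),
    ])
    def test_threshold_estimate(self, a, b, expected):
        assert threshold_estimate(LinearFit(a, b)) == pytest.approx(expected)

    def test_threshold_estimate_contract(self):
        with pytest.raises(ContractError):
            threshold_estimate(LinearFit(0.1, 0.001))


class TestMonteCarlo:
    def test_zero_noise_collapses_to_central_fit(self, table1):
        model = MonteCarloThreshold(table1)
        central = model.central_fit()
        res = model.fit(McConfig(n_iter=50, degenerate=True, seed=0))
        assert res.fraction_threshold == 1.0
        expected = -central.intercept / central.slope
        assert res.mean_threshold == pytest.approx(expected, rel=1e-12)
        assert res.p5 == pytest.approx(expected) and res.p95 == pytest.approx(expected)
        assert res.mean_slope == pytest.approx(central.slope, rel=1e-12)

    def test_same_seed_reproducible(self, table1):
        cfg = McConfig(n_iter=500, seed=42)
        a = run_mc(table1, cfg)
        b = run_mc(table1, cfg)
        assert a == b

    def test_result_invariants(self, table1):
        res = MonteCarloThreshold(table1).fit(n_iter=2000, seed=3)
        assert 0.0 <= res.fraction_threshold <= 1.0
        assert res.p5 <= res.mean_threshold <= res.p95
        assert res.ci_low <= res.mean_threshold <= res.ci_high
        assert res.n_threshold == round(res.fraction_threshold * res.n_iter)

    def test_wider_jitter_does_not_shrink_spread(self, table1):
        model = MonteCarloThreshold(table1)
        narrow = model.fit(n_iter=4000, exposure_jitter=0.05, seed=11)
        wide = model.fit(n_iter=4000, exposure_jitter=0.45, seed=11)
        assert wide.p95 - wide.p5 >= narrow.p95 - narrow.p5

    def test_poisson_mean_conventions_differ(self, table1):
        # the excess column and raw counts disagree (Connecticut), so the
        # two conventions must give visibly different threshold fractions
        by_excess = MonteCarloThreshold(table1).fit(n_iter=2000, seed=5)
        by_cases = MonteCarloThreshold(table1).fit(
            n_iter=2000, seed=5, poisson_mean="cases")
        assert by_excess.fraction_threshold > by_cases.fraction_threshold

    def test_needs_three_cohorts(self, table1):
        from mesothresh import CohortTable
        with pytest.raises(ContractError):
            MonteCarloThreshold(CohortTable(list(table1)[:2]))

    @pytest.mark.parametrize("true_threshold", [10.0, 30.0, 50.0])
    def test_recovery_brackets_true_threshold(self, table1, true_threshold):
        """The conditional threshold distribution brackets the generating T*.

        Cohorts larger than the historical ones are used so that the
        single realized table is close to its generating curve;
        realization noise, not estimator bias, otherwise dominates.
        """
        design = SyntheticDesign(
            ce=tuple(table1.column("cumulative_fcc_years")),
            tm=10_000.0,
            true_slope=0.0016,
            true_threshold=true_threshold,
            exposure_error=0.0,
            seed=2024,
        )
        synthetic = generate_linear_threshold_cohorts(design)
        res = MonteCarloThreshold(synthetic).fit(n_iter=3000, seed=7)
        assert res.p5 <= true_threshold <= res.p95
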