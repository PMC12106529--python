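"""Monte Carlo threshold classification for cohort dose-response.

Per iteration the observed mesothelioma burden of each cohort is
re-drawn (Poisson counts around the cohort mean, with total expected
mortality held at its point value) and the reported cumulative exposure
is perturbed by independent uniform multiplicative error.  An ordinary
least-squares line

    100 * M / TM = A + B * CE

is fitted to the re-drawn cohorts; a draw is classified as supporting a
threshold when ``A <= 0`` and ``B > 0``, in which case the implied
threshold is ``-A/B`` f/cc-years.  Aggregating over draws yields the
fraction of threshold-consistent models and the distribution of the
implied threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohorts import CohortTable
from .errors import ContractError, SingularDesignError

__all__ = [
    "LinearFit",
    "McConfig",
    "McResult",
    "MonteCarloThreshold",
    "ols_fit",
    "classify_threshold",
    "threshold_estimate",
    "run_mc",
]


@dataclass(frozen=True)
class LinearFit:
    """Intercept A (% excess) and slope B (% excess per f/cc-year)."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ContractError("linear fit coefficients must be finite")


def ols_fit(ce, y) -> LinearFit:
    """Simple OLS of y on ce via the normal-equation closed form."""
    ce = np.asarray(ce, dtype=float)
    y = np.asarray(y, dtype=float)
    if ce.shape != y.shape or ce.size < 3:
        raise SingularDesignError("need >= 3 paired points")
    sxx = float(np.sum((ce - ce.mean()) ** 2))
    if sxx == 0.0:
        raise SingularDesignError("cumulative exposures are all equal")
    slope = float(np.sum((ce - ce.mean()) * (y - y.mean()))) / sxx
    intercept = float(y.mean() - slope * ce.mean())
    return LinearFit(intercept, slope)


def classify_threshold(fit: LinearFit) -> bool:
    """True iff the fit supports a threshold: A <= 0 and B > 0 (strict)."""
    return fit.intercept <= 0.0 and fit.slope > 0.0


def threshold_estimate(fit: LinearFit) -> float:
    """Implied threshold -A/B (f/cc-years) of a threshold-classified fit."""
    if not classify_threshold(fit):
        raise ContractError("threshold_estimate requires A <= 0 and B > 0")
    return -fit.intercept / fit.slope


@dataclass(frozen=True)
class McConfig:
    """Simulation settings.

    ``poisson_mean`` selects the Poisson mean per cohort: ``"excess"``
    uses ``excess_rate * TM`` (consistent with the published excess
    column), ``"cases"`` uses the raw observed case count.  The two
    differ where a table's excess column disagrees with M/TM.
    ``degenerate`` disables all noise (fixed means, no exposure jitter)
    so the simulation collapses onto the central OLS fit.
    """

    n_iter: int = 10_000
    exposure_jitter: float = 0.30
    seed: int = 0
    poisson_mean: str = "excess"
    degenerate: bool = False
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ContractError("n_iter must be >= 1")
        if not 0.0 <= self.exposure_jitter < 1.0:
            raise ContractError("exposure_jitter must lie in [0, 1)")
        if self.poisson_mean not in ("excess", "cases"):
            raise ContractError("poisson_mean must be 'excess' or 'cases'")


@dataclass(frozen=True)
class McResult:
    """Aggregate of the threshold-classification Monte Carlo.

    Threshold statistics (mean, CI, percentiles) are conditional on the
    threshold-classified draws; ``mean_slope`` averages over all draws
    and ``mean_slope_threshold`` over the threshold-classified subset.
    """

    fraction_threshold: float
    mean_threshold: float
    ci_low: float
    ci_high: float
    p5: float
    p95: float
    mean_slope: float
    mean_slope_threshold: float
    n_iter: int
    n_threshold: int
    config: McConfig = field(repr=False)
    #: per-draw -A/B over threshold-classified draws (only with keep_draws)
    thresholds: np.ndarray | None = field(default=None, repr=False, compare=False)

    def summary(self) -> str:
        lines = [
            "Monte Carlo threshold classification",
            f"  iterations:           {self.n_iter}",
            f"  threshold fraction:   {self.fraction_threshold:.3f}",
            f"  mean threshold:       {self.mean_threshold:.1f} f/cc-years "
            f"(95% CI {self.ci_low:.1f}-{self.ci_high:.1f})",
            f"  5th/95th percentile:  {self.p5:.1f} / {self.p95:.1f} f/cc-years",
            f"  mean slope (all):     {self.mean_slope:.5f} %/f/cc-yr",
            f"  mean slope (thresh):  {self.mean_slope_threshold:.5f} %/f/cc-yr",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fraction_threshold": self.fraction_threshold,
            "mean_threshold": self.mean_threshold,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p5": self.p5,
            "p95": self.p95,
            "mean_slope": self.mean_slope,
            "mean_slope_threshold": self.mean_slope_threshold,
            "n_iter": self.n_iter,
            "n_threshold": self.n_threshold,
            "seed": self.config.seed,
        }


class MonteCarloThreshold:
    """Monte Carlo threshold model over a cohort table.

    Parameters
    ----------
    table : CohortTable
        Cohort summaries; needs at least three cohorts with unequal
        cumulative exposures.
    """

    def __init__(self, table: CohortTable) -> None:
        if len(table) < 3:
            raise ContractError("Monte Carlo needs at least 3 cohorts")
        self.table = table
        self.ce = np.array(table.column("cumulative_fcc_years"), dtype=float)
        self.tm = np.array(table.column("expected_mortality"), dtype=float)
        self.cases = np.array(table.column("meso_cases"), dtype=float)
        self.excess = np.array(table.column("excess_rate"), dtype=float)

    def central_fit(self) -> LinearFit:
        """Deterministic OLS on the published central values."""
        return ols_fit(self.ce, self.excess * 100.0)

    def fit(self, config: McConfig | None = None, **kwargs) -> McResult:
        """Run the simulation and aggregate.

        Accepts either a ready :class:`McConfig` or its fields as
        keyword arguments.
        """
        if config is None:
            config = McConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword fields, not both")
        rng = np.random.default_rng(config.seed)
        n, k = config.n_iter, len(self.ce)
        lam = self.excess * self.tm if config.poisson_mean == "excess" else self.cases

        if config.degenerate:
            m = np.tile(lam, (n, 1))
            ce = np.tile(self.ce, (n, 1))
        else:
            m = rng.poisson(lam, size=(n, k)).astype(float)
            j = config.exposure_jitter
            ce = rng.uniform((1.0 - j) * self.ce, (1.0 + j) * self.ce, size=(n, k))

        y = m / self.tm * 100.0
        ce_mean = ce.mean(axis=1, keepdims=True)
        sxx = ((ce - ce_mean) ** 2).sum(axis=1)
        ok = sxx > 0
        if not ok.any():
            raise SingularDesignError("every iteration produced a degenerate design")
        slope = np.full(n, np.nan)
        slope[ok] = ((ce[ok] - ce_mean[ok]) * y[ok]).sum(axis=1) / sxx[ok]
        intercept = y.mean(axis=1) - slope * ce.mean(axis=1)

        is_thr = ok & (intercept <= 0.0) & (slope > 0.0)
        frac = float(is_thr.sum()) / n
        thr = -intercept[is_thr] / slope[is_thr]
        if thr.size:
            mean_t = float(thr.mean())
            se = float(thr.std(ddof=1) / np.sqrt(thr.size)) if thr.size > 1 else 0.0
            z = stats.norm.ppf(0.975)
            ci = (mean_t - z * se, mean_t + z * se)
            p5, p95 = (float(q) for q in np.percentile(thr, [5.0, 95.0]))
            mean_slope_thr = float(slope[is_thr].mean())
        else:
            mean_t = float("nan")
            ci = (float("nan"), float("nan"))
            p5 = p95 = mean_slope_thr = float("nan")

        return McResult(
            fraction_threshold=frac,
            mean_threshold=mean_t,
            ci_low=ci[0],
            ci_high=ci[1],
            p5=p5,
            p95=p95,
            mean_slope=float(slope[ok].mean()),
            mean_slope_threshold=mean_slope_thr,
            n_iter=n,
            n_threshold=int(is_thr.sum()),
            config=config,
            thresholds=thr.copy() if config.keep_draws else None,
        )


def run_mc(table: CohortTable, config: McConfig) -> McResult:
    """Functional wrapper: ``MonteCarloThreshold(table).fit(config)``."""
    return MonteCarloThreshold(table).fit(config)
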