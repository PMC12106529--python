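"""End-to-end orchestration: run every analysis, emit one report.

``run_all`` executes the conceptual curve grid, the Monte Carlo
threshold simulation, the lifetime-risk fits (10-year lag / power 1.5
and 20-year lag / power 1.8 variants), the filter-model fit, the
single-anchor LAA simulation and the cross-mineral extrapolation, and
returns one nested dict.  The same config always produces the same
report; all stochastic entries carry their seed and size.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohorts import CohortTable, builtin_table1, load_cohorts
from .conceptual import ThreeFactorModel
from .filter_model import FilterModel, LaaAnchorConfig, laa_anchor_sim
from .minerals import (
    DEFAULT_POTENCY_RATIOS,
    ThresholdEstimate,
    combine_central_tendency,
    scale_by_potency_ratio,
)
from .montecarlo import McConfig, MonteCarloThreshold
from .peto import PetoParams, PetoThresholdModel, cumulative_threshold, intensity_threshold

log = logging.getLogger("mesothresh")

REPORT_SCHEMA_VERSION = 1

#: Published best-fit parameter sets for the lifetime-risk model.
PRINTED_PETO_PARAMS = PetoParams(k_m=0.0042e-8, lifespan=85.9, threshold=2.8, power=1.5, lag=10.0)
PRINTED_PETO_PARAMS_LAG20 = PetoParams(k_m=0.1e-8, lifespan=99.9, threshold=2.0, power=1.8, lag=20.0)

#: Illustrative parameters of the conceptual three-factor curve.
CONCEPTUAL_PARAMS = dict(lam=0.0072, beta=0.00125, alpha=0.000187)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one end-to-end run."""

    data: str | None = None          # CSV path; None -> built-in table
    seed: int = 0
    n_iter: int = 10_000
    exposure_jitter: float = 0.30
    poisson_mean: str = "excess"
    laa_draws: int = 10_000
    reference_threshold: float = 90.0
    max_duration_years: float = 45.0
    potency_ratios: dict = field(default_factory=lambda: dict(DEFAULT_POTENCY_RATIOS))
    out_dir: str | None = None

    def load_table(self) -> CohortTable:
        return load_cohorts(self.data) if self.data else builtin_table1()


def run_all(config: RunConfig) -> dict:
    """Execute every analysis; return (and optionally write) the report."""
    table = config.load_table()
    log.info("loaded %d cohorts (%s); seed=%d", len(table), table.label, config.seed)

    # Conceptual curve: analytic structure only; the grid goes to CSV.
    concept = ThreeFactorModel(**CONCEPTUAL_PARAMS)
    x_low, x_high = concept.sign_boundaries()
    stat_pts = concept.stationary_points()

    mc = MonteCarloThreshold(table).fit(McConfig(
        n_iter=config.n_iter,
        exposure_jitter=config.exposure_jitter,
        seed=config.seed,
        poisson_mean=config.poisson_mean,
    ))
    central = MonteCarloThreshold(table).central_fit()

    peto_model = PetoThresholdModel(table, power=1.5, lag=10.0)
    peto_printed = peto_model.evaluate(PRINTED_PETO_PARAMS)
    peto_fitted = peto_model.fit()
    peto_lag20 = PetoThresholdModel(table, power=1.8, lag=20.0).evaluate(PRINTED_PETO_PARAMS_LAG20)

    filt = FilterModel(table, s_source="unrounded").fit()
    laa = laa_anchor_sim(LaaAnchorConfig(n_draws=config.laa_draws, seed=config.seed))

    ref = config.reference_threshold
    minerals = {
        name: scale_by_potency_ratio(ref, ratio)
        for name, ratio in config.potency_ratios.items()
        if name != "chrysotile"
    }
    chrysotile_estimates = [
        ThresholdEstimate("chrysotile", "monte-carlo", mc.mean_threshold),
        ThresholdEstimate("chrysotile", "lifetime-risk", cumulative_threshold(
            intensity_threshold(PRINTED_PETO_PARAMS.threshold, 1.5), config.max_duration_years)),
        ThresholdEstimate("chrysotile", "filter", filt.threshold),
    ]

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": {
            "data": config.data or "builtin",
            "seed": config.seed,
            "n_iter": config.n_iter,
            "exposure_jitter": config.exposure_jitter,
            "poisson_mean": config.poisson_mean,
            "laa_draws": config.laa_draws,
            "reference_threshold": config.reference_threshold,
            "potency_ratios": config.potency_ratios,
        },
        "conceptual": {
            "params": CONCEPTUAL_PARAMS,
            "negative_region_upper": x_low,
            "positive_region_upper": x_high,
            "stationary_points": stat_pts,
        },
        "mc": mc.to_dict() | {
            "central_intercept": central.intercept,
            "central_slope": central.slope,
            "central_threshold": -central.intercept / central.slope
            if central.slope > 0 and central.intercept <= 0 else None,
        },
        "peto": {
            "printed_params": peto_printed.to_dict(),
            "fitted": peto_fitted.to_dict(),
            "lag20_printed_params": peto_lag20.to_dict(),
            "cumulative_threshold_fcc_years": cumulative_threshold(
                intensity_threshold(PRINTED_PETO_PARAMS.threshold, 1.5),
                config.max_duration_years,
            ),
        },
        "filter": filt.to_dict(),
        "laa_anchor": laa.to_dict(),
        "minerals": minerals,
        "chrysotile_central_tendency": combine_central_tendency(chrysotile_estimates),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        concept.curve_table(x_max=900.0).to_csv(out / "conceptual_curve.csv", index=False)
        table.to_dataframe().to_csv(out / "cohorts.csv", index=False)
        log.info("report written to %s", out / "report.json")
    return report


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
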