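"""Synthetic cohort tables with known ground truth.

The generators invert the data models the analyses assume, so that
parameter recovery can be tested without any external data:

* :func:`generate_linear_threshold_cohorts` draws Poisson mesothelioma
  counts around a piecewise-linear excess-rate function of cumulative
  exposure, ``r(CE) = max(0, B* (CE - T*)) / 100``, optionally with
  uniform multiplicative error on the *reported* exposure.  The Poisson
  mean always uses the latent (un-jittered) exposure: the jitter mimics
  exposure-assessment error, not variation in the true dose.
* :func:`generate_peto_cohorts` draws counts around the closed-form
  lifetime-risk model evaluated at supplied exposure histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import CohortRecord, CohortTable
from .errors import ContractError, DataValidationError
from .peto import PetoParams, lifetime_risk

__all__ = ["SyntheticDesign", "generate_linear_threshold_cohorts", "generate_peto_cohorts"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a linear-threshold synthetic table.

    ``ce`` may be an explicit sequence of cumulative exposures
    (f/cc-years) or None, in which case ``n_cohorts`` values are drawn
    log-uniformly over ``ce_range``.  ``tm`` is the per-cohort expected
    mortality (recycled if scalar).  ``true_slope`` is in % excess per
    f/cc-year; ``true_threshold`` in f/cc-years.
    """

    n_cohorts: int = 6
    ce: tuple | None = None
    ce_range: tuple[float, float] = (20.0, 800.0)
    tm: tuple | float = 1000.0
    true_slope: float = 0.0016
    true_threshold: float = 25.0
    exposure_error: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 2:
            raise ContractError("need at least 2 cohorts")
        if self.true_slope < 0:
            raise DataValidationError("true_slope must be >= 0")
        if self.true_threshold < 0:
            raise DataValidationError("true_threshold must be >= 0")
        if not 0.0 <= self.exposure_error < 1.0:
            raise DataValidationError("exposure_error must lie in [0, 1)")


def _as_array(value, n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n)
    if arr.size != n:
        raise ContractError(f"expected {n} values, got {arr.size}")
    return arr


def generate_linear_threshold_cohorts(design: SyntheticDesign) -> CohortTable:
    """One synthetic table under the linear-threshold excess model.

    Deterministic given ``design.seed``.  Raises if any cohort's true
    excess rate exceeds 1 (Poisson mean would exceed the cohort size).
    """
    rng = np.random.default_rng(design.seed)
    if design.ce is None:
        lo, hi = design.ce_range
        ce_true = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_cohorts))
    else:
        ce_true = _as_array(design.ce, design.n_cohorts)
    tm = _as_array(design.tm, design.n_cohorts)

    rate = np.maximum(0.0, design.true_slope * (ce_true - design.true_threshold)) / 100.0
    if np.any(rate > 1.0):
        raise DataValidationError("true excess rate exceeds 1 for some cohort")
    m = rng.poisson(rate * tm)

    if design.exposure_error > 0:
        err = design.exposure_error
        ce_reported = ce_true * rng.uniform(1.0 - err, 1.0 + err, design.n_cohorts)
    else:
        ce_reported = ce_true

    # Nominal exposure histories consistent with the reported CE.
    duration = np.full(design.n_cohorts, 20.0)
    intensity = ce_reported / duration
    records = []
    for i in range(design.n_cohorts):
        excess = float(m[i] / tm[i])
        records.append(CohortRecord(
            name=f"synthetic-{i}",
            duration_years=float(duration[i]),
            intensity_fcc=float(intensity[i]),
            cumulative_fcc_years=float(ce_reported[i]),
            onset_age=25.0,
            meso_cases=int(m[i]),
            expected_mortality=float(tm[i]),
            excess_rate=excess,
            survival=1.0 - excess,
        ))
    return CohortTable(records, label=f"linear-threshold synthetic (seed={design.seed})")


def generate_peto_cohorts(
    params: PetoParams,
    designs,
    seed: int = 0,
) -> CohortTable:
    """Synthetic table under the lifetime-risk model.

    ``designs`` is a sequence of ``(intensity, duration, onset_age,
    expected_mortality)`` rows; every row must satisfy
    ``lifespan > onset_age + lag`` so an observable window exists.
    Counts are Poisson with mean ``risk * TM`` (risk clamped at 0).
    """
    rows = [tuple(map(float, row)) for row in designs]
    if not rows:
        raise ContractError("need at least 1 design row")
    for e, d, y, tm in rows:
        if params.lifespan <= y + params.lag:
            raise ContractError(
                f"no observable window: lifespan {params.lifespan} <= onset {y} + lag {params.lag}"
            )
        if tm <= 0:
            raise DataValidationError("expected mortality must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for i, (e, d, y, tm) in enumerate(rows):
        risk = lifetime_risk(params, e, d, y)  # 0 when d == 0
        m = int(rng.poisson(risk * tm))
        excess = m / tm
        records.append(CohortRecord(
            name=f"peto-synthetic-{i}",
            duration_years=d if d > 0 else 1e-9,  # record invariant needs D > 0
            intensity_fcc=e,
            cumulative_fcc_years=e * d,
            onset_age=y,
            meso_cases=m,
            expected_mortality=tm,
            excess_rate=excess,
            survival=1.0 - excess,
        ))
    return CohortTable(records, label=f"peto synthetic (seed={seed})")
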