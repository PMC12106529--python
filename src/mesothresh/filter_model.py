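"""Quadratic-in-log-dose "filter" survival model.

The filter model (Schaeffer's carcinogen-threshold construction)
regresses the survival rate function S — the fraction of a cohort's
expected deaths not attributable to mesothelioma — on the log of
cumulative exposure:

    S = c + a*ln(CE + 1) + b*[ln(CE + 1)]^2

The carcinogen threshold is read off where the second derivative of S
with respect to CE vanishes and changes sign.  With u = ln(CE + 1),

    d2S/dCE2 = (2b - a - 2b*u) / (CE + 1)^2,

whose root is CE = exp(1 - a/(2b)) - 1.  The conventional threshold
formula drops the -1 (exp(1 - a/(2b))); both are exposed here, the
conventional form as the reported threshold and the exact root through
:func:`survival_second_derivative`.

A single-anchor Monte Carlo (``laa_anchor_sim``) propagates the same
construction through one (CE, S) observation: with c and a drawn from
stated ranges, b is pinned by the anchor identity and the implied
threshold distribution is summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohorts import CohortTable
from .errors import ContractError, SingularDesignError

__all__ = [
    "FilterFit",
    "FilterModel",
    "LaaAnchorConfig",
    "LaaAnchorResult",
    "fit_filter",
    "threshold_from_fit",
    "survival_second_derivative",
    "laa_anchor_sim",
]


@dataclass(frozen=True)
class FilterFit:
    """Fitted quadratic-in-log-dose survival curve.

    ``threshold`` is exp(1 - a/(2b)) f/cc-years; NaN when b >= 0 or b
    is numerically zero (no interior inflection).
    """

    a: float
    b: float
    c: float
    pearson_r: float
    r_squared: float
    threshold: float
    s_source: str = "unrounded"
    fitted: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)

    def predict(self, ce):
        u = np.log(np.asarray(ce, dtype=float) + 1.0)
        return self.c + self.a * u + self.b * u * u

    def summary(self) -> str:
        return "\n".join([
            "Filter model (quadratic in ln(CE+1))",
            f"  c = {self.c:.4f}  a = {self.a:.5f}  b = {self.b:.6f}",
            f"  Pearson R = {self.pearson_r:.3f}  R^2 = {self.r_squared:.3f}",
            f"  threshold exp(1 - a/2b) = {self.threshold:.1f} f/cc-years",
        ])

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "pearson_r": self.pearson_r, "r_squared": self.r_squared,
            "threshold": self.threshold, "s_source": self.s_source,
        }


def threshold_from_fit(a: float, b: float) -> float:
    """Conventional filter-model threshold exp(1 - a/(2b)) f/cc-years."""
    if b == 0:
        raise ContractError("threshold undefined for b = 0")
    return math.exp(1.0 - a / (2.0 * b))


def survival_second_derivative(fit: FilterFit, ce):
    """Analytic d2S/dCE2 of the fitted curve at cumulative exposure ce.

    Vanishes (with a sign change) at CE = exp(1 - a/(2b)) - 1, the
    exact inflection of the fitted survival curve.
    """
    ce = np.asarray(ce, dtype=float)
    if np.any(ce < 0):
        raise ContractError("CE must be >= 0")
    u = np.log(ce + 1.0)
    d2 = (2.0 * fit.b - fit.a - 2.0 * fit.b * u) / (ce + 1.0) ** 2
    return d2 if d2.ndim else float(d2)


class FilterModel:
    """Filter model bound to a cohort table.

    ``s_source`` chooses the survival response: ``"unrounded"`` uses
    ``1 - excess_rate`` (full precision of the excess column);
    ``"printed"`` uses the table's survival column as stored.
    """

    def __init__(self, table: CohortTable, s_source: str = "unrounded") -> None:
        if len(table) < 4:
            raise ContractError("filter fit needs at least 4 cohorts")
        if s_source not in ("unrounded", "printed"):
            raise ContractError("s_source must be 'unrounded' or 'printed'")
        self.table = table
        self.s_source = s_source
        self.ce = np.array(table.column("cumulative_fcc_years"), dtype=float)
        if s_source == "unrounded":
            self.s = 1.0 - np.array(table.column("excess_rate"), dtype=float)
        else:
            self.s = np.array(table.column("survival"), dtype=float)

    def fit(self) -> FilterFit:
        """OLS of S on (1, u, u^2), u = ln(CE+1), by normal equations."""
        u = np.log(self.ce + 1.0)
        x = np.column_stack([np.ones_like(u), u, u * u])
        gram = x.T @ x
        if np.linalg.matrix_rank(gram) < 3:
            raise SingularDesignError("collinear design: too few distinct exposures")
        coef = np.linalg.solve(gram, x.T @ self.s)
        c, a, b = (float(v) for v in coef)
        fitted = x @ coef
        if np.std(fitted) > 0 and np.std(self.s) > 0:
            r = float(np.corrcoef(fitted, self.s)[0, 1])
        else:
            r = float("nan")
        thr = threshold_from_fit(a, b) if abs(b) > 1e-12 else float("nan")
        return FilterFit(a, b, c, r, r * r, thr, self.s_source, fitted, self.s)


def fit_filter(table: CohortTable, use_unrounded_s: bool = True) -> FilterFit:
    """Functional wrapper around :class:`FilterModel`."""
    return FilterModel(table, "unrounded" if use_unrounded_s else "printed").fit()


@dataclass(frozen=True)
class LaaAnchorConfig:
    """Single-anchor Monte Carlo settings.

    The anchor identity ``anchor_s = c + u*a + u2*b`` pins b once c and
    a are drawn; ``u``/``u2`` default to the published anchor constants
    2.77 and 7.67 (ln 16 and ln^2 16).  Draws with |b| below 1e-12 or
    an implied threshold above ``threshold_cap`` are discarded (the
    threshold formula explodes as b -> 0).
    """

    anchor_s: float = 0.97
    u: float = 2.77
    u2: float = 7.67
    c_range: tuple[float, float] = (0.9, 1.0)
    a_range: tuple[float, float] = (-0.87, 1.3)
    n_draws: int = 10_000
    seed: int = 0
    threshold_cap: float = 100.0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ContractError("n_draws must be >= 1")
        if self.c_range[0] > self.c_range[1] or self.a_range[0] > self.a_range[1]:
            raise ContractError("parameter ranges must be ordered (low, high)")


@dataclass(frozen=True)
class LaaAnchorResult:
    mean: float
    sd: float
    n_kept: int
    n_discarded: int
    config: LaaAnchorConfig = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"Single-anchor threshold simulation: mean {self.mean:.2f} "
            f"f/cc-years, sd {self.sd:.2f} ({self.n_kept} kept, "
            f"{self.n_discarded} discarded)"
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd,
            "n_kept": self.n_kept, "n_discarded": self.n_discarded,
            "seed": self.config.seed if self.config else None,
        }


def laa_anchor_sim(config: LaaAnchorConfig | None = None, **kwargs) -> LaaAnchorResult:
    """Monte Carlo threshold for a mineral observed at a single anchor.

    Per draw: c ~ U(c_range), a ~ U(a_range);
    b = (anchor_s - c - u*a)/u2; threshold = exp(1 - a/(2b)).
    """
    if config is None:
        config = LaaAnchorConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword fields, not both")
    rng = np.random.default_rng(config.seed)
    c = rng.uniform(*config.c_range, size=config.n_draws)
    a = rng.uniform(*config.a_range, size=config.n_draws)
    b = (config.anchor_s - c - config.u * a) / config.u2
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        thr = np.exp(1.0 - a / (2.0 * b))
    keep = (np.abs(b) > 1e-12) & np.isfinite(thr) & (thr <= config.threshold_cap)
    kept = thr[keep]
    if kept.size == 0:
        raise ContractError("all draws discarded; widen ranges or raise the cap")
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return LaaAnchorResult(
        mean=float(kept.mean()),
        sd=sd,
        n_kept=int(kept.size),
        n_discarded=int(config.n_draws - kept.size),
        config=config,
    )
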