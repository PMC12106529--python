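"""Threshold-extended lifetime mesothelioma risk model.

The classical age-related mesothelioma incidence model takes incidence
proportional to exposure intensity times (time since first exposure
minus a lag) cubed.  Integrating that incidence over a working lifetime
gives a closed form for lifetime risk; extending it with an intensity
threshold ``Th`` (in (f/cc)^p units, p = 1.5 by default) gives

    R(V, Y, D, E) = (1/4) * K_M * max(0, E^p - Th)
                    * [ (V-Y-L)^4 - max(0, V-Y-L-D)^4 ]

with V the lifespan, Y the age at first exposure, D the exposure
duration, E the mean intensity, L the lag (10 years by default), and
K_M the potency coefficient.  The 1/4 coefficient is the exact
antiderivative factor of the cubed-time integrand.  Negative risk
increments (exposure below threshold, or no observable window) are
clamped to zero.

Fitting profiles K_M analytically (risk is linear in K_M) and grid
searches (V, Th) against the observed excess-mortality column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohorts import CohortTable
from .errors import ContractError, DataValidationError

__all__ = [
    "PetoParams",
    "PetoThresholdModel",
    "PetoResults",
    "lifetime_risk",
    "intensity_threshold",
    "cumulative_threshold",
]


@dataclass(frozen=True)
class PetoParams:
    """Parameters of the threshold-extended lifetime-risk model.

    k_m : potency coefficient (e.g. 0.0042e-8)
    lifespan : V, years
    threshold : Th, in (f/cc)^power units
    power : intensity exponent p (default 1.5)
    lag : latency L in years (default 10)
    """

    k_m: float
    lifespan: float
    threshold: float
    power: float = 1.5
    lag: float = 10.0

    def __post_init__(self) -> None:
        if self.k_m < 0 or self.threshold < 0:
            raise DataValidationError("k_m and threshold must be >= 0")
        if self.power <= 0:
            raise DataValidationError("power must be > 0")
        if self.lifespan <= self.lag:
            raise DataValidationError("lifespan must exceed the lag")


def lifetime_risk(params: PetoParams, intensity, duration, onset_age):
    """Lifetime mesothelioma risk fraction for one exposure history.

    Vectorized over intensity/duration/onset_age.  Zero whenever
    ``E^p <= Th`` or the observation window ``V - Y - L`` is empty.
    """
    e = np.asarray(intensity, dtype=float)
    d = np.asarray(duration, dtype=float)
    y = np.asarray(onset_age, dtype=float)
    if np.any(e < 0) or np.any(d < 0) or np.any(y < 0):
        raise DataValidationError("intensity, duration and onset age must be >= 0")
    window = np.maximum(0.0, params.lifespan - y - params.lag)
    tail = np.maximum(0.0, window - d)
    dose_term = np.maximum(0.0, e ** params.power - params.threshold)
    r = 0.25 * params.k_m * dose_term * (window ** 4 - tail ** 4)
    r = np.maximum(0.0, r)
    return r if r.ndim else float(r)


def intensity_threshold(th: float, power: float) -> float:
    """Convert the model threshold Th to exposure intensity Th^(1/p) f/cc."""
    if th < 0 or power <= 0:
        raise DataValidationError("need Th >= 0 and power > 0")
    return th ** (1.0 / power)


def cumulative_threshold(intensity: float, max_duration: float) -> float:
    """Cumulative-exposure threshold: intensity x maximum duration."""
    if intensity < 0 or max_duration < 0:
        raise DataValidationError("inputs must be >= 0")
    return intensity * max_duration


@dataclass(frozen=True)
class PetoResults:
    """Fit (or evaluation) of the lifetime-risk model on a cohort table."""

    params: PetoParams
    pearson_r: float
    r_squared: float
    sse: float
    predicted: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    cohort_names: tuple = field(repr=False, default=())

    def summary(self) -> str:
        p = self.params
        lines = [
            "Threshold-extended lifetime-risk model",
            f"  K_M = {p.k_m:.4e}  V = {p.lifespan:.1f} y  Th = {p.threshold:.2f}"
            f"  p = {p.power:g}  lag = {p.lag:g} y",
            f"  intensity threshold: {intensity_threshold(p.threshold, p.power):.2f} f/cc",
            f"  Pearson R = {self.pearson_r:.3f}  R^2 = {self.r_squared:.3f}",
            "  cohort        observed   predicted",
        ]
        for name, o, pr in zip(self.cohort_names, self.observed, self.predicted):
            lines.append(f"  {name:<13s} {o:9.5f}  {pr:9.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "k_m": p.k_m,
            "lifespan": p.lifespan,
            "threshold": p.threshold,
            "power": p.power,
            "lag": p.lag,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "sse": self.sse,
            "intensity_threshold_fcc": intensity_threshold(p.threshold, p.power),
            "per_cohort": {
                n: {"observed": float(o), "predicted": float(pr)}
                for n, o, pr in zip(self.cohort_names, self.observed, self.predicted)
            },
        }


class PetoThresholdModel:
    """Lifetime-risk model bound to a cohort table.

    ``evaluate(params)`` scores a given parameter set against the
    observed excess column; ``fit()`` grid-searches (V, Th) with K_M
    profiled analytically by least squares.
    """

    def __init__(self, table: CohortTable, power: float = 1.5, lag: float = 10.0) -> None:
        self.table = table
        self.power = float(power)
        self.lag = float(lag)
        self.e = np.array(table.column("intensity_fcc"), dtype=float)
        self.d = np.array(table.column("duration_years"), dtype=float)
        self.y = np.array(table.column("onset_age"), dtype=float)
        self.observed = np.array(table.column("excess_rate"), dtype=float)
        self.names = tuple(table.column("name"))

    def _results(self, params: PetoParams) -> PetoResults:
        pred = lifetime_risk(params, self.e, self.d, self.y)
        obs = self.observed
        sse = float(np.sum((pred - obs) ** 2))
        if np.std(pred) > 0 and np.std(obs) > 0:
            r = float(np.corrcoef(pred, obs)[0, 1])
        else:
            r = float("nan")
        return PetoResults(params, r, r * r, sse, pred, obs, self.names)

    def evaluate(self, params: PetoParams) -> PetoResults:
        """Score an externally supplied parameter set (no fitting)."""
        if params.power != self.power or params.lag != self.lag:
            params = PetoParams(params.k_m, params.lifespan, params.threshold,
                                self.power, self.lag)
        return self._results(params)

    def fit(
        self,
        lifespan_bounds: tuple[float, float] = (70.0, 100.0),
        lifespan_step: float = 0.1,
        threshold_bounds: tuple[float, float] | None = None,
        threshold_step: float = 0.01,
    ) -> PetoResults:
        """Least-squares grid fit of (V, Th) with analytic K_M profiling.

        The threshold grid defaults to [0, min(E^p)): a threshold at or
        above every cohort's dose term predicts zero risk everywhere and
        is unidentifiable.  Ties in SSE resolve to the first grid point
        scanned (smallest V, then smallest Th).
        """
        if len(self.table) < 4:
            raise ContractError("fit needs at least 4 cohorts")
        if np.std(self.observed) == 0:
            raise ContractError("observed excess rates have zero variance")
        if threshold_bounds is None:
            threshold_bounds = (0.0, float(np.min(self.e ** self.power)))
        v_grid = np.arange(lifespan_bounds[0], lifespan_bounds[1] + 1e-9, lifespan_step)
        th_grid = np.arange(threshold_bounds[0], threshold_bounds[1], threshold_step)
        if v_grid.size == 0 or th_grid.size == 0:
            raise ContractError("empty parameter grid")

        # risk = K_M * f(V, Th); profile K_M = <y, f>/<f, f> per grid point
        window = np.maximum(0.0, v_grid[:, None] - self.y[None, :] - self.lag)
        tail = np.maximum(0.0, window - self.d[None, :])
        g = 0.25 * (window ** 4 - tail ** 4)                      # (nV, k)
        h = np.maximum(0.0, self.e ** self.power - th_grid[:, None])  # (nTh, k)
        f = g[:, None, :] * h[None, :, :]                          # (nV, nTh, k)
        yv = self.observed
        num = np.einsum("vtk,k->vt", f, yv)
        den = np.einsum("vtk,vtk->vt", f, f)
        with np.errstate(invalid="ignore", divide="ignore"):
            k_m = np.where(den > 0, np.maximum(0.0, num) / np.where(den > 0, den, 1.0), 0.0)
        sse = np.sum(yv ** 2) - 2 * k_m * num + k_m ** 2 * den
        iv, it = np.unravel_index(np.argmin(sse), sse.shape)
        params = PetoParams(
            k_m=float(k_m[iv, it]),
            lifespan=float(v_grid[iv]),
            threshold=float(th_grid[it]),
            power=self.power,
            lag=self.lag,
        )
        return self._results(params)
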