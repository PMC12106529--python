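"""Conceptual three-factor excess-risk model.

Mesothelioma induction is pictured as the joint outcome of three
exposure-dependent processes: inflammation (probability ``lam*X - 1``,
a threshold process that only turns positive above ``X = 1/lam``), cell
survival under cytotoxic pressure (``1 - beta*X``), and secretion of
immunosuppressive / immortalization proteins (``alpha*X``).  Their
product

    P(X) = (lam*X - 1) * (1 - beta*X) * alpha*X

is an excess-rate surrogate for cumulative exposure X (f/cc-years).  It
is negative below ``1/lam`` (response below baseline), positive on
``(1/lam, 1/beta)``, and negative again beyond ``1/beta`` where induced
cell death dominates.  The model is conceptual — it is never fitted to
cohort data — but its analytic structure (sign boundaries, stationary
points) is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DataValidationError

__all__ = ["ConceptualParams", "ThreeFactorModel", "response", "sign_boundaries", "stationary_points"]


@dataclass(frozen=True)
class ConceptualParams:
    """Rate constants of the three factors, each per f/cc-years.

    ``lam > beta`` is required for a positive-response window
    ``(1/lam, 1/beta)`` to exist.
    """

    lam: float
    beta: float
    alpha: float

    def __post_init__(self) -> None:
        if min(self.lam, self.beta, self.alpha) <= 0:
            raise DataValidationError("lam, beta, alpha must all be positive")


def response(params: ConceptualParams, x):
    """Excess-rate surrogate P(X) = (lam*X - 1)(1 - beta*X)(alpha*X).

    Accepts scalar or array X >= 0.  Negative values are meaningful
    ("below baseline") and are not clipped.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DataValidationError("exposure X must be >= 0")
    p = (params.lam * x - 1.0) * (1.0 - params.beta * x) * (params.alpha * x)
    return p if p.ndim else float(p)


def sign_boundaries(params: ConceptualParams) -> tuple[float, float]:
    """Exact interval (1/lam, 1/beta) on which the response is positive."""
    if params.lam <= params.beta:
        raise ContractError("lam must exceed beta for a positive-response window")
    return 1.0 / params.lam, 1.0 / params.beta


def stationary_points(params: ConceptualParams) -> list[float]:
    """Real stationary points of P(X), ascending.

    dP/dX = 0 reduces to the quadratic
    ``3*beta*lam*X^2 - 2*(lam+beta)*X + 1 = 0`` (alpha cancels), solved
    exactly; the second root is the local maximum of the response.
    Returns [] when the discriminant is negative.
    """
    if params.lam <= params.beta:
        raise ContractError("lam must exceed beta for a positive-response window")
    a = 3.0 * params.beta * params.lam
    b = -2.0 * (params.lam + params.beta)
    c = 1.0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    return list(roots)


class ThreeFactorModel:
    """Parametric three-factor dose-response curve.

    Not a fitted model: construct it from chosen rate constants and
    interrogate the curve.  ``curve_table`` emits the four-curve grid
    (P and each factor) used for illustration.
    """

    def __init__(self, lam: float, beta: float, alpha: float) -> None:
        self.params = ConceptualParams(lam, beta, alpha)

    def response(self, x):
        return response(self.params, x)

    def sign_boundaries(self) -> tuple[float, float]:
        return sign_boundaries(self.params)

    def stationary_points(self) -> list[float]:
        return stationary_points(self.params)

    def local_maximum(self) -> float:
        """Exposure at which the response peaks (second stationary point)."""
        pts = self.stationary_points()
        if len(pts) < 2:
            raise ContractError("response has no interior maximum for these parameters")
        return pts[1]

    def curve_table(self, x_max: float, n: int = 201) -> pd.DataFrame:
        """Grid of the response and its three factors on [0, x_max]."""
        x = np.linspace(0.0, float(x_max), n)
        p = self.params
        return pd.DataFrame({
            "exposure_fcc_years": x,
            "excess_response": response(p, x),
            "inflammation": p.lam * x - 1.0,
            "cell_survival": 1.0 - p.beta * x,
            "immortalization": p.alpha * x,
        })
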