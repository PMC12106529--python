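"""Cross-mineral threshold extrapolation by potency ratios.

Mesothelioma potency differs by orders of magnitude across asbestiform
mineral types.  Treating no-observed-adverse-effect levels as inversely
proportional to potency, a threshold estimated for a reference mineral
(here non-textile chrysotile) scales to another mineral by dividing by
the potency ratio.  The default ratio table relative to non-textile
chrysotile — crocidolite 364, amosite 86, Libby amphibole (LAA,
a tremolite surrogate) 21 — ships as configuration data, since
different meta-analyses give somewhat different absolute potencies.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ContractError, DataValidationError

__all__ = [
    "ThresholdEstimate",
    "PotencyTable",
    "DEFAULT_POTENCY_RATIOS",
    "scale_by_potency_ratio",
    "threshold_from_potency",
    "combine_central_tendency",
]

#: Mesothelioma potency relative to non-textile chrysotile.
DEFAULT_POTENCY_RATIOS: dict[str, float] = {
    "chrysotile": 1.0,
    "crocidolite": 364.0,
    "amosite": 86.0,
    "LAA": 21.0,
}


@dataclass(frozen=True)
class ThresholdEstimate:
    """One method's threshold estimate for one mineral.

    ``dispersion`` (same units) is optional — e.g. the SD of a
    simulated threshold distribution.
    """

    mineral: str
    method: str
    value: float
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DataValidationError("threshold value must be > 0")


class PotencyTable:
    """Mineral -> potency ratio relative to the reference mineral.

    Optionally carries absolute potencies R_M (% excess per f/cc-year)
    per mineral.  The reference mineral must have ratio 1.
    """

    def __init__(
        self,
        ratios: Mapping[str, float],
        absolute: Mapping[str, float] | None = None,
        reference: str = "chrysotile",
    ) -> None:
        self.ratios = dict(ratios)
        self.absolute = dict(absolute or {})
        self.reference = reference
        if any(v <= 0 for v in self.ratios.values()):
            raise DataValidationError("all potency ratios must be > 0")
        if self.ratios.get(reference) != 1.0:
            raise DataValidationError(f"reference mineral {reference!r} must have ratio 1")

    def scale(self, reference_threshold: float, mineral: str) -> float:
        """Threshold for *mineral* implied by the reference threshold."""
        if mineral not in self.ratios:
            raise KeyError(mineral)
        return scale_by_potency_ratio(reference_threshold, self.ratios[mineral])


def scale_by_potency_ratio(reference_threshold: float, ratio: float) -> float:
    """reference_threshold / ratio (both must be positive)."""
    if reference_threshold <= 0 or ratio <= 0:
        raise DataValidationError("threshold and ratio must be > 0")
    return reference_threshold / ratio


def threshold_from_potency(
    reference_threshold: float,
    reference_potency: float,
    target_potency: float,
) -> float:
    """Scale a threshold by absolute potencies: T_ref * R_ref / R_target."""
    if reference_potency <= 0 or target_potency <= 0:
        raise DataValidationError("potencies must be > 0")
    if reference_threshold <= 0:
        raise DataValidationError("reference threshold must be > 0")
    return reference_threshold * reference_potency / target_potency


def combine_central_tendency(estimates: Iterable[ThresholdEstimate]) -> float:
    """Arithmetic mean of several method-level estimates for one mineral."""
    ests = list(estimates)
    if not ests:
        raise ContractError("need at least one estimate")
    minerals = {e.mineral for e in ests}
    if len(minerals) > 1:
        raise ContractError(f"cannot combine estimates across minerals: {sorted(minerals)}")
    return statistics.fmean(e.value for e in ests)
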