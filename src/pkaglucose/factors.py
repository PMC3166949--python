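"""Induction and repression factors and glucose-response strength calls.

The induction factor of a gene is the ratio of its replicate-averaged
signal 30 minutes after glucose addition to its signal in the ethanol
baseline; the repression factor is the reciprocal orientation (ethanol
over glucose).  A gene counts as glucose-responsive in a strain when the
factor reaches 1.8-fold.  A response that survives loss of PKA is
"total" when at least one PKA-null strain's factor is no less than 70%
of the reference strain's; a response that is still present (>= 1.8) but
below the 70% criterion is "partial"; otherwise "none".

Denominators are floored at a small signal value so near-zero baselines
cannot blow a ratio up; floored factors are flagged and, by default, do
not count as support for a "total" call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .io import Strain
from .normalization import DEFAULT_SIGNAL_FLOOR

__all__ = [
    "Direction",
    "Strength",
    "ResponseThresholds",
    "ResponseFactor",
    "ResponseCall",
    "induction_factor",
    "repression_factor",
    "response_factor",
    "classify_response_strength",
    "count_responders",
]


class Direction(Enum):
    INDUCTION = "INDUCTION"
    REPRESSION = "REPRESSION"


class Strength(Enum):
    TOTAL = "TOTAL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


@dataclass(frozen=True)
class ResponseThresholds:
    """Fold-change thresholds of the response taxonomy.

    induction_min / repression_min : minimum fold for a strain to count
        as responsive (1.8-fold in both directions).
    strong_induction_min : the "more than 4-fold" induction reporting tier.
    repression_tier_strong / _very_strong : the 4- and 15-fold repression
        reporting tiers.  Tiers are reporting bins, not call thresholds.
    total_fraction : a PKA-null factor must reach this fraction of the
        reference factor for the response to be "total" (0.7).
    sustain_min : minimum growth-condition fold for a response to count
        as sustained rather than transient; defaults to the direction's
        responsiveness threshold when None.
    persistence_fraction : a response also counts as sustained only when
        the growth-condition factor keeps at least this fraction of the
        30-minute factor; a factor that collapses relative to its early
        value is transient even if it stays above ``sustain_min``.
    """

    induction_min: float = 1.8
    strong_induction_min: float = 4.0
    repression_min: float = 1.8
    repression_tier_strong: float = 4.0
    repression_tier_very_strong: float = 15.0
    total_fraction: float = 0.7
    sustain_min: float | None = None
    persistence_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 1 < self.induction_min <= self.strong_induction_min:
            raise ValueError("require 1 < induction_min <= strong_induction_min")
        if not (
            1
            < self.repression_min
            <= self.repression_tier_strong
            <= self.repression_tier_very_strong
        ):
            raise ValueError(
                "require 1 < repression_min <= repression_tier_strong"
                " <= repression_tier_very_strong"
            )
        if not 0 < self.total_fraction <= 1:
            raise ValueError("total_fraction must be in (0, 1]")
        if not 0 <= self.persistence_fraction <= 1:
            raise ValueError("persistence_fraction must be in [0, 1]")

    def responsive_min(self, direction: Direction) -> float:
        return (
            self.induction_min if direction is Direction.INDUCTION else self.repression_min
        )

    def sustain_threshold(self, direction: Direction) -> float:
        return self.sustain_min if self.sustain_min is not None else self.responsive_min(direction)


@dataclass(frozen=True)
class ResponseFactor:
    """One gene's fold-change in one strain for one condition pair."""

    gene: str
    strain: Strain | None
    direction: Direction
    value: float
    floored: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"factor must be positive, got {self.value}")


@dataclass(frozen=True)
class ResponseCall:
    """Strength of a gene's glucose response across the PKA-null strains."""

    gene: str
    direction: Direction
    ref_responsive: bool
    strength: Strength | None
    supporting_strain: Strain | None = None


def _ratio(numerator: float, denominator: float, floor: float) -> tuple[float, bool]:
    if numerator < 0 or denominator < 0:
        raise ValueError("signals must be non-negative")
    if floor <= 0:
        raise ValueError("floor must be positive")
    floored = denominator < floor
    return numerator / max(denominator, floor), floored


def induction_factor(
    glucose_mean: float,
    ethanol_mean: float,
    floor: float = DEFAULT_SIGNAL_FLOOR,
    gene: str = "",
    strain: Strain | None = None,
) -> ResponseFactor:
    """Fold-increase on glucose: glucose signal over (floored) ethanol signal."""
    value, floored = _ratio(glucose_mean, ethanol_mean, floor)
    return ResponseFactor(gene, strain, Direction.INDUCTION, value, floored)


def repression_factor(
    ethanol_mean: float,
    glucose_mean: float,
    floor: float = DEFAULT_SIGNAL_FLOOR,
    gene: str = "",
    strain: Strain | None = None,
) -> ResponseFactor:
    """Fold-decrease on glucose: ethanol signal over (floored) glucose signal."""
    value, floored = _ratio(ethanol_mean, glucose_mean, floor)
    return ResponseFactor(gene, strain, Direction.REPRESSION, value, floored)


def response_factor(
    direction: Direction,
    ethanol_mean: float,
    glucose_mean: float,
    floor: float = DEFAULT_SIGNAL_FLOOR,
    gene: str = "",
    strain: Strain | None = None,
) -> ResponseFactor:
    """Directional dispatch with a fixed (ethanol, glucose) argument order."""
    if direction is Direction.INDUCTION:
        return induction_factor(glucose_mean, ethanol_mean, floor, gene, strain)
    return repression_factor(ethanol_mean, glucose_mean, floor, gene, strain)


def classify_response_strength(
    ref: ResponseFactor,
    null_factors: Sequence[ResponseFactor],
    thresholds: ResponseThresholds | None = None,
    allow_floored_support: bool = False,
) -> ResponseCall:
    """Call a gene's response strength from its per-strain factors.

    The gene must first be responsive in the reference strain (factor at
    or above the direction's threshold).  It is then TOTAL when any
    PKA-null strain's factor reaches ``total_fraction`` of the reference
    factor, PARTIAL when some PKA-null strain is itself responsive but
    below the 70% criterion, and NONE otherwise.  Floored factors do not
    support TOTAL unless ``allow_floored_support``.
    """
    thresholds = thresholds or ResponseThresholds()
    for nf in null_factors:
        if nf.direction is not ref.direction:
            raise ValueError(
                f"direction mismatch: {nf.direction} vs reference {ref.direction}"
            )
        if nf.gene != ref.gene:
            raise ValueError(f"gene mismatch: {nf.gene!r} vs reference {ref.gene!r}")
    responsive_min = thresholds.responsive_min(ref.direction)
    ref_responsive = ref.value >= responsive_min
    if not ref_responsive:
        return ResponseCall(ref.gene, ref.direction, False, None)
    supporting = None
    for nf in null_factors:
        if nf.floored and not allow_floored_support:
            continue
        if nf.value >= thresholds.total_fraction * ref.value:
            supporting = nf.strain
            break
    if supporting is not None:
        return ResponseCall(ref.gene, ref.direction, True, Strength.TOTAL, supporting)
    if any(nf.value >= responsive_min for nf in null_factors):
        return ResponseCall(ref.gene, ref.direction, True, Strength.PARTIAL)
    return ResponseCall(ref.gene, ref.direction, True, Strength.NONE)


def count_responders(
    factors: Sequence[ResponseFactor], thresholds: ResponseThresholds | None = None
) -> dict[str, int]:
    """Cumulative tier counts for one strain and direction.

    Induction: genes at or above 1.8-fold and strictly above the 4-fold
    tier.  Repression: genes at or above the 1.8-, 4- and 15-fold tiers
    (inclusive).  All factors must share a direction.
    """
    thresholds = thresholds or ResponseThresholds()
    if not factors:
        return {}
    directions = {f.direction for f in factors}
    if len(directions) > 1:
        raise ValueError("count_responders requires a single direction")
    direction = directions.pop()
    values = np.asarray([f.value for f in factors])
    if direction is Direction.INDUCTION:
        return {
            f">={thresholds.induction_min:g}x": int((values >= thresholds.induction_min).sum()),
            f">{thresholds.strong_induction_min:g}x": int(
                (values > thresholds.strong_induction_min).sum()
            ),
        }
    return {
        f">={thresholds.repression_min:g}x": int((values >= thresholds.repression_min).sum()),
        f">={thresholds.repression_tier_strong:g}x": int(
            (values >= thresholds.repression_tier_strong).sum()
        ),
        f">={thresholds.repression_tier_very_strong:g}x": int(
            (values >= thresholds.repression_tier_very_strong).sum()
        ),
    }
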