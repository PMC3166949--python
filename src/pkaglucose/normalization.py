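"""Global per-array scaling, replicate averaging, and replicate QC.

Arrays are made comparable by multiplying each sample column so that its
mean signal equals a fixed target (150 signal units by default, the
standard global-scaling convention for this array generation).  Scaling
uses the plain mean over all gene features; a trimmed mean is available
as an option.  The pipeline order is fixed: scale each array, then
average biological replicates, then compute response factors — this makes
every downstream ratio invariant to per-array loading differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Condition, ExpressionMatrix, SampleDescriptor, SchemaError, Strain, match_samples

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationConfig",
    "ScalingReport",
    "ReplicateQCReport",
    "NormalizationError",
    "global_scale",
    "average_replicates",
    "replicate_qc",
]

DEFAULT_TARGET_SIGNAL = 150.0
DEFAULT_SIGNAL_FLOOR = 1.0
DEFAULT_QC_THRESHOLD = 0.25


class NormalizationError(ValueError):
    """An array cannot be scaled (e.g. all-zero column)."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Scaling target and the signal floor used by downstream ratios.

    target_signal : mean signal every array is scaled to (signal units).
    signal_floor  : minimum denominator for fold-change ratios, so that
                    near-zero signals do not blow factors up (signal units).
    trim_fraction : fraction trimmed from each tail of the per-array
                    signal distribution before taking the mean; 0 is the
                    plain mean over all gene features (default).
    """

    target_signal: float = DEFAULT_TARGET_SIGNAL
    signal_floor: float = DEFAULT_SIGNAL_FLOOR
    trim_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.target_signal <= 0:
            raise ValueError("target_signal must be positive")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class ScalingReport:
    """Per-sample scale factors and pre-scaling means."""

    scale_factors: pd.Series
    pre_means: pd.Series
    target_signal: float


@dataclass(frozen=True)
class ReplicateQCReport:
    """Replicate-deviation quality check.

    ``deviations`` holds, for every (gene, strain, condition, replicate)
    with a positive group mean, the relative deviation |x - mean| / mean.
    ``flagged_fraction`` is the proportion of (gene, group) entries with
    any replicate deviating by more than ``threshold``.
    """

    deviations: pd.DataFrame  # columns: gene, strain, condition, replicate, deviation
    threshold: float
    flagged_fraction: float
    n_groups: int
    n_flagged: int
    n_zero_mean: int
    n_single_replicate_groups: int

    @property
    def within_fraction(self) -> float:
        """Fraction of (gene, group) entries whose replicates all stay within threshold."""
        return 1.0 - self.flagged_fraction


def _column_means(data: pd.DataFrame, trim_fraction: float) -> pd.Series:
    if trim_fraction == 0.0:
        return data.mean(axis=0)
    values = np.sort(data.to_numpy(), axis=0)
    n = values.shape[0]
    k = int(np.floor(trim_fraction * n))
    if n - 2 * k <= 0:
        raise NormalizationError("trim_fraction leaves no values to average")
    return pd.Series(values[k : n - k].mean(axis=0), index=data.columns)


def global_scale(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> tuple[ExpressionMatrix, ScalingReport]:
    """Scale every array so its mean signal equals ``config.target_signal``.

    Each sample column is multiplied by target / mean(column).  Within-array
    ratios are preserved exactly, so all downstream induction and
    repression factors are invariant to per-array scale.  Idempotent:
    applying it to already-scaled data is the identity (up to rounding).
    """
    config = config or NormalizationConfig()
    pre_means = _column_means(matrix.data, config.trim_fraction)
    zero = pre_means[pre_means <= 0]
    if not zero.empty:
        raise NormalizationError(
            f"cannot scale all-zero sample(s): {zero.index.tolist()}"
        )
    factors = config.target_signal / pre_means
    scaled = matrix.data * factors
    report = ScalingReport(
        scale_factors=factors, pre_means=pre_means, target_signal=config.target_signal
    )
    logger.info(
        "globally scaled %d arrays to target %.6g (factors %.3g..%.3g)",
        len(factors), config.target_signal, factors.min(), factors.max(),
    )
    return ExpressionMatrix(data=scaled, scaled=True), report


def _groups(
    matrix: ExpressionMatrix, samples: Sequence[SampleDescriptor]
) -> dict[tuple[Strain, Condition], list[str]]:
    mapping = match_samples(matrix, samples)
    groups: dict[tuple[Strain, Condition], list[str]] = {}
    for sid, desc in mapping.items():
        groups.setdefault(desc.group, []).append(sid)
    return groups


def group_column_name(strain: Strain, condition: Condition) -> str:
    return f"{strain.name}:{condition.name}"


def average_replicates(
    matrix: ExpressionMatrix, samples: Sequence[SampleDescriptor]
) -> ExpressionMatrix:
    """Collapse biological replicates to one column per (strain, condition).

    The value is the arithmetic mean of the replicate signals per gene.
    Columns are named ``STRAIN:CONDITION``.  Requires scaled input so
    replicate arrays are on a common scale before averaging.
    """
    if not matrix.scaled:
        raise ValueError("average_replicates requires a globally scaled matrix")
    groups = _groups(matrix, samples)
    columns = {
        group_column_name(strain, cond): matrix.data[sids].mean(axis=1)
        for (strain, cond), sids in groups.items()
    }
    averaged = pd.DataFrame(columns, index=matrix.data.index)
    return ExpressionMatrix(data=averaged, scaled=True)


def replicate_qc(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleDescriptor],
    threshold: float = DEFAULT_QC_THRESHOLD,
) -> ReplicateQCReport:
    """Check how far replicates stray from their group mean.

    For every gene and (strain, condition) group with at least two
    replicates and a positive mean, computes |x_i - mean| / mean per
    replicate.  Groups whose mean is zero are skipped and counted;
    single-replicate groups are skipped and logged.  An entry is flagged
    when any replicate deviates by more than ``threshold`` (default 25%,
    the level replicate arrays of this design generally stay within).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    groups = _groups(matrix, samples)
    multi = {g: sids for g, sids in groups.items() if len(sids) >= 2}
    skipped = len(groups) - len(multi)
    if skipped:
        logger.info("replicate_qc: skipping %d single-replicate group(s)", skipped)
    if not multi:
        raise SchemaError("replicate_qc requires at least one group with >=2 replicates")

    records: list[pd.DataFrame] = []
    n_groups = 0
    n_flagged = 0
    n_zero = 0
    for (strain, cond), sids in multi.items():
        block = matrix.data[sids]
        means = block.mean(axis=1)
        positive = means > 0
        n_zero += int((~positive).sum())
        dev = (block.sub(means, axis=0)).abs().div(means, axis=0)[positive]
        n_groups += int(positive.sum())
        n_flagged += int((dev.max(axis=1) > threshold).sum())
        long = dev.stack().rename("deviation").reset_index()
        long.columns = ["gene", "sample_id", "deviation"]
        long["strain"] = strain.name
        long["condition"] = cond.name
        records.append(long)
    deviations = pd.concat(records, ignore_index=True)[
        ["gene", "strain", "condition", "sample_id", "deviation"]
    ]
    flagged_fraction = n_flagged / n_groups if n_groups else 0.0
    return ReplicateQCReport(
        deviations=deviations,
        threshold=threshold,
        flagged_fraction=flagged_fraction,
        n_groups=n_groups,
        n_flagged=n_flagged,
        n_zero_mean=n_zero,
        n_single_replicate_groups=skipped,
    )
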