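"""Per-gene regulatory profiles: PKA-dependence class, transience, and
gluconeogenic PKA requirement.

The four-class taxonomy is determined by three observations per gene:
whether it responds to glucose in the PKA-proficient reference strain,
whether the response survives in strains devoid of PKA, and whether PKA
activation alone (no glucose) reproduces it.

    class 1  PKA-independent      glucose response survives loss of PKA,
                                  PKA activation alone does nothing
    class 2  PKA-only             response lost without PKA, PKA
                                  activation alone suffices
    class 3  redundant pathways   response survives loss of PKA and PKA
                                  activation alone also works
    class 4  cooperative pathways response lost (or merely partial)
                                  without PKA, activation alone does not
                                  reproduce it

When no PKA-activation condition was measured, classes 1/3 and 2/4
cannot be separated; a surviving response is reported as class 1 with a
flag and a lost response as UNRESOLVED rather than guessed.

Transience compares the 30-minute response with steady exponential
growth on glucose: responsive early but not during growth is TRANSIENT,
responsive in both is SUSTAINED.

Under gluconeogenic growth (ethanol, no glucose), a gene whose
expression drops at least 2-fold in *both* PKA-null strains relative to
the reference needs PKA for full expression; drops confined to one
suppressor background point at the suppressor mutation (e.g. Msn2/4
dependence) instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .io import Condition, ExpressionMatrix, SampleDescriptor, Strain
from .normalization import (
    DEFAULT_SIGNAL_FLOOR,
    NormalizationConfig,
    average_replicates,
    global_scale,
    group_column_name,
)
from .factors import (
    Direction,
    ResponseCall,
    ResponseFactor,
    ResponseThresholds,
    Strength,
    classify_response_strength,
    response_factor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PkaClass",
    "Transience",
    "GluconeogenicCategory",
    "SuppressorBalance",
    "TransienceCall",
    "GluconeogenicCall",
    "GeneRegulatoryProfile",
    "ProfileConfig",
    "classify_pka_dependence",
    "classify_transience",
    "pka_requirement_gluconeogenic",
    "compare_suppressors",
    "normalize_to_reference",
    "build_profiles",
]


class PkaClass(Enum):
    CLASS1_PKA_INDEPENDENT = "CLASS1_PKA_INDEPENDENT"
    CLASS2_PKA_ONLY = "CLASS2_PKA_ONLY"
    CLASS3_REDUNDANT = "CLASS3_REDUNDANT"
    CLASS4_COOPERATIVE = "CLASS4_COOPERATIVE"
    NOT_GLUCOSE_REGULATED = "NOT_GLUCOSE_REGULATED"
    UNRESOLVED = "UNRESOLVED"


class Transience(Enum):
    TRANSIENT = "TRANSIENT"
    SUSTAINED = "SUSTAINED"
    GROWTH_ONLY = "GROWTH_ONLY"
    NONE = "NONE"


class GluconeogenicCategory(Enum):
    PKA_REQUIRED = "PKA_REQUIRED"
    MSN_DEPENDENT = "MSN_DEPENDENT"
    YAK_DEPENDENT = "YAK_DEPENDENT"
    SUPPRESSOR_DIVERGENT = "SUPPRESSOR_DIVERGENT"
    UNCHANGED = "UNCHANGED"


class SuppressorBalance(Enum):
    HIGHER_IN_MSN = "HIGHER_IN_MSN"
    HIGHER_IN_YAK = "HIGHER_IN_YAK"
    SIMILAR = "SIMILAR"


@dataclass(frozen=True)
class TransienceCall:
    value: Transience
    short_factor: float
    growth_factor: float


@dataclass(frozen=True)
class GluconeogenicCall:
    value: GluconeogenicCategory
    fold_vs_ref_msn: float
    fold_vs_ref_yak: float


@dataclass
class GeneRegulatoryProfile:
    """Assembled per-gene calls; derived fields are reproducible from the
    stored factors."""

    gene: str
    direction: Direction
    ref_factor: float
    msn_factor: float | None
    yak_factor: float | None
    activation_factor: float | None
    ref_responsive: bool
    strength: Strength | None
    supporting_strain: Strain | None
    pka_class: PkaClass
    class_flag: bool                     # class 1 assigned without activation data
    transience: Transience | None
    gluconeogenic: GluconeogenicCategory | None
    suppressor_balance: SuppressorBalance | None
    floored: bool


def classify_pka_dependence(
    ref_call: ResponseCall,
    pka_null_call: ResponseCall,
    pka_activation_call: ResponseCall | None = None,
) -> tuple[PkaClass, bool]:
    """Map (reference, PKA-null, PKA-activated) responses to the four-class
    taxonomy.

    ``pka_null_call`` summarizes both PKA-null strains (TOTAL if either
    strain meets the 70% criterion).  Returns ``(pka_class, flag)``; the
    flag marks a class-1 assignment made without activation data, where
    class 3 cannot be excluded.
    """
    if pka_null_call.direction is not ref_call.direction:
        raise ValueError("direction mismatch between reference and PKA-null calls")
    if pka_activation_call is not None and (
        pka_activation_call.direction is not ref_call.direction
    ):
        raise ValueError("direction mismatch between reference and activation calls")
    if not ref_call.ref_responsive:
        return PkaClass.NOT_GLUCOSE_REGULATED, False
    null_total = pka_null_call.strength is Strength.TOTAL
    if pka_activation_call is None:
        if null_total:
            return PkaClass.CLASS1_PKA_INDEPENDENT, True
        return PkaClass.UNRESOLVED, False
    activated = pka_activation_call.ref_responsive
    if null_total and not activated:
        return PkaClass.CLASS1_PKA_INDEPENDENT, False
    if not null_total and activated:
        return PkaClass.CLASS2_PKA_ONLY, False
    if null_total and activated:
        return PkaClass.CLASS3_REDUNDANT, False
    return PkaClass.CLASS4_COOPERATIVE, False


def classify_transience(
    short_factor: ResponseFactor,
    growth_factor: ResponseFactor,
    thresholds: ResponseThresholds | None = None,
) -> TransienceCall:
    """Compare the 30-minute response with the steady-growth response.

    A response is SUSTAINED when the growth-condition factor both stays
    above the sustain threshold and keeps at least ``persistence_fraction``
    of the 30-minute factor; a response that collapses during growth —
    either below threshold or to a small fraction of its early value —
    is TRANSIENT.
    """
    thresholds = thresholds or ResponseThresholds()
    if growth_factor.direction is not short_factor.direction:
        raise ValueError("direction mismatch between short-term and growth factors")
    if growth_factor.strain is not short_factor.strain:
        raise ValueError("strain mismatch between short-term and growth factors")
    r = thresholds.responsive_min(short_factor.direction)
    sustain = thresholds.sustain_threshold(short_factor.direction)
    short_on = short_factor.value >= r
    growth_on = growth_factor.value >= sustain
    persists = growth_factor.value >= thresholds.persistence_fraction * short_factor.value
    if short_on and growth_on and persists:
        value = Transience.SUSTAINED
    elif short_on:
        value = Transience.TRANSIENT
    elif growth_on:
        value = Transience.GROWTH_ONLY
    else:
        value = Transience.NONE
    return TransienceCall(value, short_factor.value, growth_factor.value)


def pka_requirement_gluconeogenic(
    ref_signal: float,
    msn_signal: float,
    yak_signal: float,
    fold: float = 2.0,
    floor: float = DEFAULT_SIGNAL_FLOOR,
) -> GluconeogenicCall:
    """Is PKA required for full expression under gluconeogenic growth?

    Signals are replicate-averaged, scaled ethanol-growth values.  A
    mutant counts as reduced when its signal is at most ref/fold.
    Reduction in both mutants implicates PKA itself; reduction in only
    one implicates that strain's suppressor mutation.
    """
    if min(ref_signal, msn_signal, yak_signal) < 0:
        raise ValueError("signals must be non-negative")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    msn_reduced = msn_signal <= ref_signal / fold
    yak_reduced = yak_signal <= ref_signal / fold
    fold_msn = ref_signal / max(msn_signal, floor)
    fold_yak = ref_signal / max(yak_signal, floor)
    if msn_reduced and yak_reduced:
        category = GluconeogenicCategory.PKA_REQUIRED
    elif msn_reduced:
        category = GluconeogenicCategory.MSN_DEPENDENT
    elif yak_reduced:
        category = GluconeogenicCategory.YAK_DEPENDENT
    else:
        category = GluconeogenicCategory.UNCHANGED
    return GluconeogenicCall(category, fold_msn, fold_yak)


def compare_suppressors(
    msn_signal: float,
    yak_signal: float,
    fold: float = 2.0,
    floor: float = DEFAULT_SIGNAL_FLOOR,
) -> SuppressorBalance:
    """Which suppressor background expresses the gene more (>= fold apart)?"""
    if min(msn_signal, yak_signal) < 0:
        raise ValueError("signals must be non-negative")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if msn_signal / max(yak_signal, floor) >= fold:
        return SuppressorBalance.HIGHER_IN_MSN
    if yak_signal / max(msn_signal, floor) >= fold:
        return SuppressorBalance.HIGHER_IN_YAK
    return SuppressorBalance.SIMILAR


def normalize_to_reference(
    signals: dict[str, float], reference_key: str, scale: float = 100.0
) -> dict[str, float]:
    """Express signals relative to a reference entry set to ``scale``
    (the layout used to report Msn2/4-target expression)."""
    ref = signals[reference_key]
    if ref <= 0:
        raise ValueError("reference signal must be positive")
    return {key: value / ref * scale for key, value in signals.items()}


# --- end-to-end profile assembly ------------------------------------------

@dataclass(frozen=True)
class ProfileConfig:
    """Knobs of the profile-assembly pipeline."""

    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    thresholds: ResponseThresholds = field(default_factory=ResponseThresholds)
    gluconeogenic_fold: float = 2.0
    suppressor_fold: float = 2.0
    allow_floored_support: bool = False
    skip_scaling: bool = False


_NULL_STRAINS = (Strain.TPK_NULL_MSN, Strain.TPK_NULL_YAK)


def build_profiles(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleDescriptor],
    config: ProfileConfig | None = None,
) -> list[GeneRegulatoryProfile]:
    """Run the whole per-gene pipeline: scale, average replicates, compute
    directional factors, call strength, PKA class, transience and the
    gluconeogenic category.

    Requires at minimum the reference strain and one PKA-null strain in
    the ethanol baseline and the 30-minute glucose conditions.  The
    PKA-activation pseudo-condition (reference genotype) and the
    glucose-growth condition are used when present and the corresponding
    calls are omitted when not.
    """
    config = config or ProfileConfig()
    thresholds = config.thresholds
    floor = config.normalization.signal_floor

    if not matrix.scaled and not config.skip_scaling:
        matrix, _ = global_scale(matrix, config.normalization)
    elif not matrix.scaled:
        matrix = ExpressionMatrix(data=matrix.data, scaled=True)
    averaged = average_replicates(matrix, samples)
    cols = set(averaged.data.columns)

    def col(strain: Strain, cond: Condition) -> str | None:
        name = group_column_name(strain, cond)
        return name if name in cols else None

    required = [
        (Strain.REF_PKA_PLUS, Condition.ETHANOL),
        (Strain.REF_PKA_PLUS, Condition.GLUCOSE_30MIN),
    ]
    missing = [f"{s.name}:{c.name}" for s, c in required if col(s, c) is None]
    null_present = [
        s
        for s in _NULL_STRAINS
        if col(s, Condition.ETHANOL) and col(s, Condition.GLUCOSE_30MIN)
    ]
    if not null_present:
        missing.append("a PKA-null strain in ETHANOL and GLUCOSE_30MIN")
    if missing:
        raise ValueError(f"cannot build profiles; missing conditions: {missing}")
    if len(null_present) == 1:
        logger.warning(
            "only one PKA-null strain present (%s); the 70%% total rule applies "
            "over that strain alone", null_present[0].name,
        )

    data = averaged.data
    has_activation = col(Strain.REF_PKA_PLUS, Condition.PKA_ACTIVATED) is not None
    has_growth = col(Strain.REF_PKA_PLUS, Condition.GLUCOSE_GROWTH) is not None
    has_gluconeogenic = all(col(s, Condition.ETHANOL) for s in _NULL_STRAINS)

    profiles: list[GeneRegulatoryProfile] = []
    for gene in data.index:
        row = data.loc[gene]

        def signal(strain: Strain, cond: Condition) -> float:
            return float(row[group_column_name(strain, cond)])

        e_ref = signal(Strain.REF_PKA_PLUS, Condition.ETHANOL)
        g_ref = signal(Strain.REF_PKA_PLUS, Condition.GLUCOSE_30MIN)
        ind = response_factor(
            Direction.INDUCTION, e_ref, g_ref, floor, gene, Strain.REF_PKA_PLUS
        )
        rep = response_factor(
            Direction.REPRESSION, e_ref, g_ref, floor, gene, Strain.REF_PKA_PLUS
        )
        direction = Direction.INDUCTION if ind.value >= rep.value else Direction.REPRESSION
        ref_factor = ind if direction is Direction.INDUCTION else rep

        null_factors: dict[Strain, ResponseFactor] = {}
        for strain in null_present:
            null_factors[strain] = response_factor(
                direction,
                signal(strain, Condition.ETHANOL),
                signal(strain, Condition.GLUCOSE_30MIN),
                floor,
                gene,
                strain,
            )
        call = classify_response_strength(
            ref_factor,
            list(null_factors.values()),
            thresholds,
            config.allow_floored_support,
        )

        activation_factor: ResponseFactor | None = None
        activation_call: ResponseCall | None = None
        if has_activation:
            # Activation responds "as glucose would": induced genes rise,
            # repressed genes fall relative to the ethanol baseline.
            activation_factor = response_factor(
                direction,
                e_ref,
                signal(Strain.REF_PKA_PLUS, Condition.PKA_ACTIVATED),
                floor,
                gene,
                Strain.REF_PKA_PLUS,
            )
            activation_call = ResponseCall(
                gene,
                direction,
                activation_factor.value >= thresholds.responsive_min(direction),
                None,
            )
        pka_class, class_flag = classify_pka_dependence(call, call, activation_call)

        transience: Transience | None = None
        if has_growth:
            growth_factor = response_factor(
                direction,
                e_ref,
                signal(Strain.REF_PKA_PLUS, Condition.GLUCOSE_GROWTH),
                floor,
                gene,
                Strain.REF_PKA_PLUS,
            )
            transience = classify_transience(ref_factor, growth_factor, thresholds).value

        gluconeogenic: GluconeogenicCategory | None = None
        balance: SuppressorBalance | None = None
        if has_gluconeogenic:
            e_msn = signal(Strain.TPK_NULL_MSN, Condition.ETHANOL)
            e_yak = signal(Strain.TPK_NULL_YAK, Condition.ETHANOL)
            gcall = pka_requirement_gluconeogenic(
                e_ref, e_msn, e_yak, config.gluconeogenic_fold, floor
            )
            balance = compare_suppressors(e_msn, e_yak, config.suppressor_fold, floor)
            gluconeogenic = gcall.value
            if (
                gluconeogenic is GluconeogenicCategory.UNCHANGED
                and balance is not SuppressorBalance.SIMILAR
            ):
                gluconeogenic = GluconeogenicCategory.SUPPRESSOR_DIVERGENT

        msn = null_factors.get(Strain.TPK_NULL_MSN)
        yak = null_factors.get(Strain.TPK_NULL_YAK)
        profiles.append(
            GeneRegulatoryProfile(
                gene=gene,
                direction=direction,
                ref_factor=ref_factor.value,
                msn_factor=msn.value if msn else None,
                yak_factor=yak.value if yak else None,
                activation_factor=activation_factor.value if activation_factor else None,
                ref_responsive=call.ref_responsive,
                strength=call.strength,
                supporting_strain=call.supporting_strain,
                pka_class=pka_class,
                class_flag=class_flag,
                transience=transience,
                gluconeogenic=gluconeogenic,
                suppressor_balance=balance,
                floored=ref_factor.floored
                or any(f.floored for f in null_factors.values()),
            )
        )
    return profiles
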