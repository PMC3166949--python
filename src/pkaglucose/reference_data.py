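"""Published reference measurements for representative glucose-regulated
genes in *S. cerevisiae* strains lacking PKA.

These small tables ship with the package so worked examples, tests and
the reproduction script can run offline.  They hold transcript-level
induction/repression factors and probe-set signal values for a handful
of marker genes, measured in the PKA-proficient reference strain
(*TPK1 TPK2 TPK3*) and the two viable PKA-null suppressor strains
(*tpk1 tpk2 tpk3 msn2 msn4* and *tpk1 tpk2 tpk3 yak1*).

Layout conventions: per-strain keys are the :class:`~pkaglucose.io.Strain`
names; factor tables map gene -> strain -> (30-min factor, steady-growth
factor); signal tables map gene -> strain -> signal units.
"""

from __future__ import annotations

from .io import Strain

REF = Strain.REF_PKA_PLUS.name
MSN = Strain.TPK_NULL_MSN.name
YAK = Strain.TPK_NULL_YAK.name

#: Induction factors (30 min after glucose; steady growth on glucose+ethanol)
#: for genes whose glucose induction was followed over time.
INDUCTION_FACTORS: dict[str, dict[str, tuple[float, float]]] = {
    "PDC1": {REF: (12.8, 27.0), MSN: (15.0, 21.0), YAK: (1.2, 4.4)},
    "PDC5": {REF: (235.0, 1.3), MSN: (70.0, 4.3), YAK: (1.8, 2.0)},
    "ALD5": {REF: (5.0, 3.0), MSN: (3.4, 3.2), YAK: (0.9, 0.6)},
    "TMT1": {REF: (9.7, 2.0), MSN: (1.7, 1.9), YAK: (1.1, 0.7)},
    "YMC2": {REF: (11.0, 4.0), MSN: (2.2, 1.9), YAK: (0.8, 0.7)},
    "ATR1": {REF: (13.8, 2.3), MSN: (2.6, 2.9), YAK: (1.4, 0.9)},
}

#: Repression factors (same condition pair, reciprocal orientation).
REPRESSION_FACTORS: dict[str, dict[str, tuple[float, float]]] = {
    "TPS1": {REF: (7.7, 1.3), MSN: (1.3, 1.5), YAK: (1.1, 0.3)},
    "TPS2": {REF: (7.1, 1.6), MSN: (1.1, 1.1), YAK: (1.3, 0.4)},
    "HXT6/7": {REF: (30.0, 68.0), MSN: (0.2, 0.2), YAK: (1.4, 0.3)},
    "GRX2": {REF: (9.5, 2.9), MSN: (0.7, 0.9), YAK: (1.4, 0.5)},
    "PEP4": {REF: (15.0, 1.8), MSN: (0.4, 1.0), YAK: (1.2, 0.6)},
}

#: Ethanol-growth (gluconeogenic) signal values for genes expressed
#: differently in the two PKA-null suppressor backgrounds.
GLUCONEOGENIC_SIGNALS: dict[str, dict[str, float]] = {
    "HXK1": {REF: 459, MSN: 77, YAK: 228},
    "HSP104": {REF: 327, MSN: 121, YAK: 229},
    "MSC1": {REF: 629, MSN: 58, YAK: 296},
    "SOL4": {REF: 148, MSN: 28, YAK: 107},
    "YKL187c": {REF: 321, MSN: 28, YAK: 124},
    "GLC3": {REF: 390, MSN: 96, YAK: 425},
    "GLK1": {REF: 852, MSN: 465, YAK: 889},
    "GPX1": {REF: 271, MSN: 41, YAK: 196},
    "GSY2": {REF: 184, MSN: 45, YAK: 245},
    "HSP12": {REF: 3790, MSN: 807, YAK: 2436},
    "HPF1": {REF: 650, MSN: 137, YAK: 611},
    "NCA3": {REF: 744, MSN: 134, YAK: 683},
    "SOD1": {REF: 1964, MSN: 841, YAK: 1558},
    "STF2": {REF: 838, MSN: 183, YAK: 1004},
    "TPS1": {REF: 569, MSN: 245, YAK: 612},
    "TSL1": {REF: 274, MSN: 45, YAK: 245},
    "ATF2": {REF: 31, MSN: 33, YAK: 173},
    "PRM5": {REF: 116, MSN: 339, YAK: 164},
    "SSA2": {REF: 997, MSN: 1519, YAK: 611},
    "DAL3": {REF: 198, MSN: 403, YAK: 58},
    "FSH1": {REF: 220, MSN: 271, YAK: 68},
}

#: Msn2/4-activated, PKA-dependent glucose-repressed genes: expression in
#: ethanol ("Et") and after glucose addition ("Glu"), normalized so the
#: reference strain's ethanol value is 100.
MSN_TARGET_EXPRESSION: dict[str, dict[str, dict[str, float]]] = {
    "GPX1": {REF: {"Et": 100, "Glu": 6}, MSN: {"Et": 15, "Glu": 8}, YAK: {"Et": 73, "Glu": 45}},
    "GSY2": {REF: {"Et": 100, "Glu": 13}, MSN: {"Et": 23, "Glu": 15}, YAK: {"Et": 80, "Glu": 62}},
    "HPF1": {REF: {"Et": 100, "Glu": 41}, MSN: {"Et": 21, "Glu": 42}, YAK: {"Et": 94, "Glu": 108}},
    "MSC1": {REF: {"Et": 100, "Glu": 4}, MSN: {"Et": 9, "Glu": 6}, YAK: {"Et": 45, "Glu": 39}},
    "TSL1": {REF: {"Et": 100, "Glu": 8}, MSN: {"Et": 16, "Glu": 9}, YAK: {"Et": 90, "Glu": 92}},
}

#: The four-class PKA-dependence taxonomy: for each (class, direction),
#: whether the response is seen in the reference strain with glucose, in
#: the PKA-null strains with glucose, and upon PKA activation without
#: glucose, plus representative genes.
CLASS_TABLE: list[dict] = [
    {"pka_class": 1, "direction": "INDUCTION", "pka_plus": True, "pka_minus": True,
     "pka_activated": False, "genes": ["PFK1", "ENO2"]},
    {"pka_class": 1, "direction": "REPRESSION", "pka_plus": True, "pka_minus": True,
     "pka_activated": False, "genes": ["CRC1", "PCK1", "MLS1"]},
    {"pka_class": 2, "direction": "INDUCTION", "pka_plus": True, "pka_minus": False,
     "pka_activated": True, "genes": ["ARG3", "THR4"]},
    {"pka_class": 2, "direction": "REPRESSION", "pka_plus": True, "pka_minus": False,
     "pka_activated": True, "genes": ["GRX2", "PEP4"]},
    {"pka_class": 3, "direction": "INDUCTION", "pka_plus": True, "pka_minus": True,
     "pka_activated": True, "genes": ["HXT3", "RPL7A", "HOR2"]},
    {"pka_class": 3, "direction": "REPRESSION", "pka_plus": True, "pka_minus": True,
     "pka_activated": True, "genes": ["ACS1", "ADY2", "CIT3"]},
    {"pka_class": 4, "direction": "INDUCTION", "pka_plus": True, "pka_minus": False,
     "pka_activated": False, "genes": ["SDT1", "STR3"]},
    {"pka_class": 4, "direction": "REPRESSION", "pka_plus": True, "pka_minus": False,
     "pka_activated": False, "genes": ["HXT6", "MDH1"]},
]
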