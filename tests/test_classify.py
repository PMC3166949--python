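"""Four-class PKA taxonomy, transience, gluconeogenic calls, profiles."""

import numpy as np
import pytest

import pkaglucose as pk
from pkaglucose import (
    Direction,
    GluconeogenicCategory,
    PkaClass,
    ResponseCall,
    ResponseFactor,
    Strength,
    SuppressorBalance,
    Transience,
)
from pkaglucose import reference_data as rd

from conftest import make_matrix


def call(responsive=True, strength=Strength.TOTAL, direction=Direction.INDUCTION,
         gene="g"):
    return ResponseCall(gene, direction, responsive,
                        strength if responsive else None)


class TestFourClassMap:
    @pytest.mark.parametrize("row", rd.CLASS_TABLE, ids=lambda r: f"class{r['pka_class']}_{r['direction'].lower()}")
    def test_reproduces_all_published_class_rows(self, row):
        """Every (class, direction) row of the published taxonomy maps to the
        right class from its (PKA+, PKA-, PKA-activated) response pattern."""
        direction = Direction[row["direction"]]
        null_strength = Strength.TOTAL if row["pka_minus"] else Strength.NONE
        got, flag = pk.classify_pka_dependence(
            call(row["pka_plus"], direction=direction),
            call(True, null_strength, direction),
            call(row["pka_activated"], None, direction),
        )
        want = {
            1: PkaClass.CLASS1_PKA_INDEPENDENT,
            2: PkaClass.CLASS2_PKA_ONLY,
            3: PkaClass.CLASS3_REDUNDANT,
            4: PkaClass.CLASS4_COOPERATIVE,
        }[row["pka_class"]]
        assert got is want
        assert flag is False

    def test_partial_null_response_maps_to_class4(self):
        got, _ = pk.classify_pka_dependence(
            call(), call(True, Strength.PARTIAL), call(False, None)
        )
        assert got is PkaClass.CLASS4_COOPERATIVE

    def test_unresponsive_reference_gates_everything(self):
        got, _ = pk.classify_pka_dependence(
            call(False), call(True, Strength.TOTAL), call(True, None)
        )
        assert got is PkaClass.NOT_GLUCOSE_REGULATED

    def test_missing_activation_degrades_gracefully(self):
        got, flag = pk.classify_pka_dependence(call(), call(True, Strength.TOTAL), None)
        assert got is PkaClass.CLASS1_PKA_INDEPENDENT and flag is True
        got, flag = pk.classify_pka_dependence(call(), call(True, Strength.NONE), None)
        assert got is PkaClass.UNRESOLVED and flag is False

    def test_map_is_total_over_the_call_domain(self):
        for strength in Strength:
            for activated in (True, False):
                got, _ = pk.classify_pka_dependence(
                    call(), call(True, strength), call(activated, None)
                )
                assert got in (
                    PkaClass.CLASS1_PKA_INDEPENDENT,
                    PkaClass.CLASS2_PKA_ONLY,
                    PkaClass.CLASS3_REDUNDANT,
                    PkaClass.CLASS4_COOPERATIVE,
                )

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            pk.classify_pka_dependence(
                call(), call(direction=Direction.REPRESSION), None
            )


class TestTransience:
    @staticmethod
    def _trans(short, growth, direction):
        sf = ResponseFactor("g", pk.Strain.REF_PKA_PLUS, direction, short)
        gf = ResponseFactor("g", pk.Strain.REF_PKA_PLUS, direction, growth)
        return pk.classify_transience(sf, gf).value

    @pytest.mark.parametrize(
        "table, direction, expected",
        [
            (rd.INDUCTION_FACTORS, Direction.INDUCTION,
             {"PDC1": Transience.SUSTAINED, "PDC5": Transience.TRANSIENT,
              "ALD5": Transience.SUSTAINED, "TMT1": Transience.TRANSIENT,
              "YMC2": Transience.TRANSIENT, "ATR1": Transience.TRANSIENT}),
            (rd.REPRESSION_FACTORS, Direction.REPRESSION,
             {"TPS1": Transience.TRANSIENT, "TPS2": Transience.TRANSIENT,
              "HXT6/7": Transience.SUSTAINED, "GRX2": Transience.TRANSIENT,
              "PEP4": Transience.TRANSIENT}),
        ],
        ids=["induction", "repression"],
    )
    def test_reference_strain_marker_genes(self, table, direction, expected):
        """Feeding the published reference-strain factors reproduces the
        transient/sustained behaviour reported for every marker gene."""
        for gene, want in expected.items():
            short, growth = table[gene][rd.REF]
            assert self._trans(short, growth, direction) is want, gene

    def test_unresponsive_gene_is_none(self):
        assert self._trans(1.0, 1.0, Direction.INDUCTION) is Transience.NONE

    def test_growth_only_category(self):
        assert self._trans(1.1, 5.0, Direction.INDUCTION) is Transience.GROWTH_ONLY

    def test_strain_mismatch_rejected(self):
        sf = ResponseFactor("g", pk.Strain.REF_PKA_PLUS, Direction.INDUCTION, 5.0)
        gf = ResponseFactor("g", pk.Strain.TPK_NULL_MSN, Direction.INDUCTION, 5.0)
        with pytest.raises(ValueError, match="strain"):
            pk.classify_transience(sf, gf)


class TestGluconeogenic:
    def test_reduced_in_both_mutants_requires_pka(self):
        got = pk.pka_requirement_gluconeogenic(459, 77, 228)
        assert got.value is GluconeogenicCategory.PKA_REQUIRED
        assert got.fold_vs_ref_msn == pytest.approx(459 / 77)

    def test_reduced_only_in_msn_background(self):
        got = pk.pka_requirement_gluconeogenic(3790, 807, 2436)
        assert got.value is GluconeogenicCategory.MSN_DEPENDENT

    def test_unchanged_when_similar(self):
        got = pk.pka_requirement_gluconeogenic(100, 100, 100)
        assert got.value is GluconeogenicCategory.UNCHANGED

    def test_all_bundled_pka_required_genes_detected(self):
        """Genes reduced in both suppressor backgrounds among the bundled
        gluconeogenic signals are exactly those with >=2-fold drops."""
        for gene, row in rd.GLUCONEOGENIC_SIGNALS.items():
            got = pk.pka_requirement_gluconeogenic(row[rd.REF], row[rd.MSN], row[rd.YAK])
            both = row[rd.MSN] <= row[rd.REF] / 2 and row[rd.YAK] <= row[rd.REF] / 2
            assert (got.value is GluconeogenicCategory.PKA_REQUIRED) == both, gene

    def test_suppressor_divergence_calls(self):
        assert pk.compare_suppressors(403, 58) is SuppressorBalance.HIGHER_IN_MSN
        assert pk.compare_suppressors(33, 173) is SuppressorBalance.HIGHER_IN_YAK
        assert pk.compare_suppressors(100, 100) is SuppressorBalance.SIMILAR

    def test_rescaling_invariance(self):
        for k in (0.1, 3.7, 120.0):
            a = pk.pka_requirement_gluconeogenic(459, 77, 228)
            b = pk.pka_requirement_gluconeogenic(459 * k, 77 * k, 228 * k)
            assert a.value is b.value
            assert pk.compare_suppressors(403 * k, 58 * k) is SuppressorBalance.HIGHER_IN_MSN


class TestNormalizeToReference:
    def test_reference_set_to_100(self):
        out = pk.normalize_to_reference({"a": 50.0, "b": 25.0}, "a")
        assert out == {"a": 100.0, "b": 50.0}

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pk.normalize_to_reference({"a": 0.0}, "a")


class TestBuildProfiles:
    def test_noiseless_profiles_match_planted_truth(self):
        config = pk.SimulationConfig(
            n_genes=400, replicate_cv=0.0, array_scale_jitter=0.0, seed=9
        )
        matrix, samples, truth = pk.generate_dataset(config)
        profiles = pk.build_profiles(matrix, samples)
        score = pk.score_recovery(truth, profiles)
        assert score.overall_class_accuracy == 1.0
        assert score.transience_accuracy == 1.0
        assert score.gluconeogenic_accuracy == 1.0

    def test_gene_order_invariance(self):
        matrix, samples, _ = pk.generate_dataset(pk.SimulationConfig(n_genes=50, seed=2))
        profiles = {p.gene: p for p in pk.build_profiles(matrix, samples)}
        permuted = pk.ExpressionMatrix(matrix.data.iloc[::-1], scaled=False)
        for p in pk.build_profiles(permuted, samples):
            q = profiles[p.gene]
            assert (p.pka_class, p.transience, p.gluconeogenic, p.strength) == (
                q.pka_class, q.transience, q.gluconeogenic, q.strength
            )
            # factors agree up to summation-order rounding in column means
            assert p.ref_factor == pytest.approx(q.ref_factor, rel=1e-12)
            assert p.msn_factor == pytest.approx(q.msn_factor, rel=1e-12)

    def test_missing_required_condition_is_informative_error(self, duplicate_design):
        keep = [s for s in duplicate_design if s.condition is pk.Condition.ETHANOL]
        matrix = make_matrix(
            np.full((3, len(keep)), 50.0), samples=[s.sample_id for s in keep]
        )
        with pytest.raises(ValueError, match="GLUCOSE_30MIN"):
            pk.build_profiles(matrix, keep)

    def test_profiles_without_activation_are_degraded_not_guessed(self):
        config = pk.SimulationConfig(
            n_genes=300, replicate_cv=0.0, array_scale_jitter=0.0,
            include_activation=False, seed=4,
        )
        matrix, samples, truth = pk.generate_dataset(config)
        profiles = pk.build_profiles(matrix, samples)
        for p in profiles:
            truth_class = truth.labels.at[p.gene, "pka_class"]
            if truth_class in ("CLASS1_PKA_INDEPENDENT", "CLASS3_REDUNDANT"):
                assert p.pka_class is PkaClass.CLASS1_PKA_INDEPENDENT
                assert p.class_flag is True
            elif truth_class in ("CLASS2_PKA_ONLY", "CLASS4_COOPERATIVE"):
                assert p.pka_class is PkaClass.UNRESOLVED
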