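"""Worked example on the bundled published marker-gene measurements.

Feeds published induction/repression factors through the response
taxonomy: the 70% rule for PKA-independence, the transience comparison
between the 30-minute pulse and steady growth, and the gluconeogenic
PKA-requirement call from ethanol-growth signals.
"""

import pkaglucose as pk
from pkaglucose import Direction, ResponseFactor
from pkaglucose import reference_data as rd


def rf(gene, value, direction=Direction.INDUCTION, strain=pk.Strain.REF_PKA_PLUS):
    return ResponseFactor(gene, strain, direction, value)


print("response strength (30 min after glucose):")
for gene in ("PDC1", "ALD5"):
    ref30 = rd.INDUCTION_FACTORS[gene][rd.REF][0]
    call = pk.classify_response_strength(
        rf(gene, ref30),
        [rf(gene, rd.INDUCTION_FACTORS[gene][rd.MSN][0], strain=pk.Strain.TPK_NULL_MSN),
         rf(gene, rd.INDUCTION_FACTORS[gene][rd.YAK][0], strain=pk.Strain.TPK_NULL_YAK)],
    )
    print(f"  {gene:<6} ref x{ref30:<5g} -> {call.strength.name}"
          + (f" (via {call.supporting_strain.name})" if call.supporting_strain else ""))

print("\ntransience in the reference strain (30 min vs steady growth):")
for table, direction in ((rd.INDUCTION_FACTORS, Direction.INDUCTION),
                         (rd.REPRESSION_FACTORS, Direction.REPRESSION)):
    for gene, rows in table.items():
        short, growth = rows[rd.REF]
        call = pk.classify_transience(rf(gene, short, direction), rf(gene, growth, direction))
        print(f"  {gene:<7} {direction.name.lower():<10} x{short:<6g} -> x{growth:<5g}"
              f"  {call.value.name}")

print("\ngluconeogenic PKA requirement (ethanol-growth signals):")
for gene in ("HXK1", "HSP12", "DAL3", "ATF2"):
    row = rd.GLUCONEOGENIC_SIGNALS[gene]
    need = pk.pka_requirement_gluconeogenic(row[rd.REF], row[rd.MSN], row[rd.YAK])
    balance = pk.compare_suppressors(row[rd.MSN], row[rd.YAK])
    print(f"  {gene:<6} ref {row[rd.REF]:>5} msn {row[rd.MSN]:>5} yak {row[rd.YAK]:>5}"
          f"  -> {need.value.name} / {balance.name}")
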