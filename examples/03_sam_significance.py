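"""SAM permutation significance on a duplicate-vs-duplicate comparison.

With two replicates per group there are only C(4,2) = 6 label
permutations, all enumerated exhaustively.  The relative difference
d = (mean2 - mean1)/(s + s0) is compared against the permutation-null
order statistics; Delta is chosen as the smallest value whose estimated
false discovery rate is at most 5%.

A sparse responsive fraction is simulated here on purpose: global
scaling forces every array's mean to the same target, so when a large
share of genes responds, the compensation slightly shifts all other
genes between conditions, and SAM — which is sensitive to any
reproducible shift, not to fold thresholds — will detect that too.
The fold-change taxonomy downstream is immune to it.
"""

import pkaglucose as pk

matrix, samples, truth = pk.generate_dataset(
    pk.SimulationConfig(n_genes=1000, responsive_fraction=0.02, seed=3)
)
scaled, _ = pk.global_scale(matrix)
ref = pk.Strain.REF_PKA_PLUS
g1 = [s.sample_id for s in samples
      if s.strain is ref and s.condition is pk.Condition.ETHANOL]
g2 = [s.sample_id for s in samples
      if s.strain is ref and s.condition is pk.Condition.GLUCOSE_30MIN]

result = pk.sam_two_group(scaled, g1, g2, pk.SamConfig(seed=0))
print(f"fudge factor s0 = {result.s0:.3f}")
print(f"chosen Delta    = {result.delta:.3f}")
print(f"genes called    = {result.n_called} / {len(result.d)}")
print(f"estimated FDR   = {result.estimated_fdr:.3f}")

planted = set(truth.labels.index[truth.labels["pka_class"] != "NOT_GLUCOSE_REGULATED"])
called = set(result.called.index[result.called])
print(f"planted responsive genes: {len(planted)}")
print(f"called genes that were planted responsive: "
      f"{len(called & planted)} / {len(called)}")
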