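"""Simulate a phenotype-selected haploid backcross population.

Builds a small SNP map, backcrosses a trait-expressing recombinant to the 3S
parent, assigns rough/smooth phenotypes at 21/30/37 C under a two-rule
epistatic trait model, and selects trait-expressing segregants into
temperature-sensitivity classes.
"""

import numpy as np

import cryptomap as cm

mm = cm.build_marker_map(n_chromosomes=4, chromosome_length=500_000, n_markers=600, seed=11)
print(f"marker map: {mm.n_markers} SNPs on {len(mm.chromosomes)} chromosomes")

# two AND-rules: one enables expression up to 30 C, the other only at 21 C
model = cm.TraitModel(
    "GP-demo",
    "rule_based",
    rules=(
        cm.TraitRule({mm.nearest_marker("chr1", 250_000): "BY",
                      mm.nearest_marker("chr2", 250_000): "BY"}, max_temperature=30),
        cm.TraitRule({mm.nearest_marker("chr3", 250_000): "BY",
                      mm.nearest_marker("chr4", 250_000): "BY"}, max_temperature=21),
    ),
)

parent = cm.make_rough_parent(mm, model, seed=12)
pop = cm.make_backcross(parent, "3S", n=2000, marker_map=mm, recomb_rate=3e-6, seed=13)
pop = cm.assign_phenotypes(pop, model)

for tclass in ("21", "30", "37"):
    n = cm.select_rough(pop, tclass).n_segregants
    print(f"class {tclass} (rough up to {tclass} C): {n} segregants")
print(f"rough at 21 C in total: {cm.select_rough(pop, 'any').n_segregants} of {pop.n_segregants}")

# Each rule contributes one temperature class; the 1:1 backcross segregation
# makes ~1/4 of progeny carry a given two-locus combination, and the
# rule-based model is monotone: every class-30 segregant is also rough at 21 C.
freqs = (pop.genotypes == cm.P1).mean(axis=0)
seg = cm.segregating_mask(parent, cm.P2)
print(f"mean BY-allele frequency at segregating markers: {freqs[seg].mean():.3f} (expect ~0.5)")
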