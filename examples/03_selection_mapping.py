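"""Map trait loci by allele-frequency enrichment among selected segregants.

Among backcross progeny selected for the trait, causal loci are distorted
away from the 1:1 segregation expectation.  The scan collapses markers with
identical genotype vectors, applies exact binomial tests with a
per-population Bonferroni correction, and reports each locus as a peak
marker plus its drop-2 confidence interval.
"""

import numpy as np

import cryptomap as cm

mm = cm.build_marker_map(n_chromosomes=6, chromosome_length=600_000, n_markers=1200, seed=31)
causal_a = mm.nearest_marker("chr2", 300_000)
causal_b = mm.nearest_marker("chr4", 300_000)
model = cm.TraitModel(
    "GP-demo", "rule_based",
    rules=(cm.TraitRule({causal_a: "BY", causal_b: "BY"}, max_temperature=21),),
)

parent = cm.make_rough_parent(mm, model, seed=32)
pop = cm.assign_phenotypes(
    cm.make_backcross(parent, "3S", 3000, mm, 3e-6, seed=33), model
)
selected = cm.select_rough(pop, "any").subset(np.arange(150))

counts = cm.simulate_read_counts(selected, 2.5, 0.002, seed=34)
geno = cm.call_genotypes(counts, cm.HmmParams(error_rate=0.002))
mask = cm.segregating_mask(parent, cm.P2)

calls, scan = cm.call_loci(geno, mask, gp="GP-demo", backcross="3S", tclass="any", alpha=0.01)
m = scan["group"].nunique()
print(f"{len(scan)} segregating markers collapsed into {m} unique tests "
      f"(Bonferroni threshold P < {0.01 / m:.2e})")
for c in calls:
    print(f"locus on {c.chrom}: peak {c.peak_id} (-log10 P = {c.peak_score:.1f}), "
          f"interval {c.start}-{c.end}, enriched allele {c.allele}")
for name, marker in (("A", causal_a), ("B", causal_b)):
    pos = mm.table["pos"].iloc[mm.index_of(marker)]
    hit = any(c.start <= pos <= c.end and c.chrom == marker.split("_")[0] for c in calls)
    print(f"planted locus {name} ({marker}) inside a reported interval: {hit}")
# Both planted loci should be recovered with the BY allele enriched; the
# remaining chromosomes stay below the Bonferroni threshold.
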