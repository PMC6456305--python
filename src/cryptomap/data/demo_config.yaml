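# Demonstration pipeline config: two genetic perturbations with contrasting
# architectures on a scaled-down genome (6 x 600-kb chromosomes, 900 markers).
#
# GP-rule is rule-based (epistatic) with two AND-rules and a 30C-capable
# class; GP-mult is multiplicative (additive), 21C-only.  The two GPs share
# the chr1:300000 locus (BY allele), so the consolidated catalog shows
# cross-GP sharing.  Loci resolve to the nearest marker at run time.
seed: 20210
marker_map:
  n_chromosomes: 6
  chromosome_length: 600000
  n_markers: 900
recomb_rate: 3.0e-6
n_progeny: 3000
max_selected_per_class: 150
min_selected: 25
coverage:
  mean: 2.5
  error_rate: 0.002
hmm:
  min_posterior: 0.9
mapping:
  alpha: 0.01
interactions:
  fdr: 1.0e-4
  end_exclusion: 30000
  mc_reps: 0
genotyping: hmm
backcrosses: ["3S"]
gps:
  - id: GP-rule
    mode: rule_based
    rules:
      - required: {"chr1:300000": "BY", "chr2:300000": "BY"}
        max_temperature: 30
      - required: {"chr3:300000": "BY", "chr4:300000": "BY"}
        max_temperature: 21
  - id: GP-mult
    mode: multiplicative
    baseline: 0.02
    effects:
      "chr1:300000": {allele: "BY", factor: 3.0}
      "chr5:300000": {allele: "BY", factor: 3.0}
      "chr6:300000": {allele: "BY", factor: 3.0}
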