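"""Simulation studies validating each statistical stage of the pipeline.

These are first-class, deterministic (seeded) experiments used both by the
test suite and by the reproduction script: family-wise error of the
Bonferroni binomial scan under the null, recovery of planted AND-rule loci,
coverage of the drop-2 interval, and the additive-vs-epistatic
discrimination of the multi-locus chi-square test.  Problem sizes default to
the study conditions scaled to a desk-sized genome (6 x 600-kb chromosomes,
1,200 markers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import P1, P2, MarkerMap, build_marker_map
from .simulate import (
    DEFAULT_RECOMB_RATE,
    TraitModel,
    TraitRule,
    assign_phenotypes,
    make_backcross,
    make_rough_parent,
    select_rough,
)
from .hmm import from_truth
from .mapping import call_loci, segregating_mask
from .interactions import additivity_analysis

_MAP_KW = dict(n_chromosomes=6, chromosome_length=600_000, n_markers=1200)


def _default_map(rng: np.random.Generator) -> MarkerMap:
    return build_marker_map(seed=rng, **_MAP_KW)


@dataclass
class ExperimentSummary:
    """Replicate-level outcome rate of a simulation experiment."""

    n_replicates: int
    n_hits: int

    @property
    def rate(self) -> float:
        return self.n_hits / self.n_replicates


def null_fwer_experiment(
    n_replicates: int = 100,
    n_selected: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
) -> ExperimentSummary:
    """Fraction of null replicates (no causal locus) calling >= 1 locus.

    Segregants are an unselected random sample of a backcross between a
    random F2-like rough parent and BY; with Bonferroni correction at
    family-wise alpha the fraction should stay at or below alpha-level
    expectations (conservative under marker dependence).
    """
    rng = np.random.default_rng(seed)
    mm = _default_map(rng)
    hits = 0
    for _ in range(n_replicates):
        # random recombinant parent: any locus may segregate, none is causal
        parent = make_backcross(
            np.ones(mm.n_markers, dtype=np.int8), "BY", 1, mm, DEFAULT_RECOMB_RATE, rng
        ).genotypes[0]
        pop = make_backcross(parent, "3S", n_selected, mm, DEFAULT_RECOMB_RATE, rng)
        mask = segregating_mask(parent, P2)
        if not mask.any():
            continue
        calls, _ = call_loci(
            from_truth(mm, pop.genotypes), mask, "null", "3S", "any", alpha
        )
        hits += bool(calls)
    return ExperimentSummary(n_replicates=n_replicates, n_hits=hits)


def _planted_two_locus_model(mm: MarkerMap) -> TraitModel:
    """An AND-rule requiring the BY allele on chr2 and on chr4.

    Both loci require the non-recurrent allele of a 3S backcross, so both
    segregate 1:1 and both are mappable in a single selected population.
    """
    rule = TraitRule(
        required={
            mm.nearest_marker("chr2", 300_000): P1,
            mm.nearest_marker("chr4", 300_000): P1,
        },
        max_temperature=21,
    )
    return TraitModel(perturbation_id="planted", mode="rule_based", rules=(rule,))


def planted_recovery_experiment(
    n_replicates: int = 100,
    n_selected: int = 150,
    seed: int = 0,
    alpha: float = 0.01,
) -> ExperimentSummary:
    """Recovery of both loci of a planted 2-locus AND rule with correct alleles.

    A replicate is a hit when, mapping n_selected trait-selected backcross
    segregants, each required locus falls inside a called interval on its
    chromosome whose enriched allele matches the planted one.
    """
    rng = np.random.default_rng(seed)
    mm = _default_map(rng)
    model = _planted_two_locus_model(mm)
    required = {m: a for r in model.rules for m, a in r.required.items()}
    hits = 0
    for _ in range(n_replicates):
        parent = make_rough_parent(mm, model, rng)
        pop = make_backcross(parent, "3S", 20 * n_selected, mm, DEFAULT_RECOMB_RATE, rng)
        pop = assign_phenotypes(pop, model)
        selected = select_rough(pop, "any")
        if selected.n_segregants < n_selected:
            continue
        selected = selected.subset(np.arange(n_selected))
        mask = segregating_mask(parent, P2)
        calls, _ = call_loci(from_truth(mm, selected.genotypes), mask, "planted", "3S", "any", alpha)
        ok = True
        for marker_id, allele in required.items():
            row = mm.table.iloc[mm.index_of(marker_id)]
            found = any(
                c.chrom == row["chrom"]
                and c.start <= row["pos"] <= c.end
                and c.allele == ("BY" if allele == P1 else "3S")
                for c in calls
            )
            ok &= found
        hits += ok
    return ExperimentSummary(n_replicates=n_replicates, n_hits=hits)


def interval_coverage_experiment(
    n_replicates: int = 200,
    n_selected: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
) -> ExperimentSummary:
    """Drop-2 interval coverage of a planted causal marker.

    One causal locus (BY allele required, chr2) is planted; a replicate is a
    hit when the causal marker position lies inside the reported interval of
    a called locus on its chromosome.  Replicates calling no locus on the
    causal chromosome count as misses.
    """
    rng = np.random.default_rng(seed)
    mm = _default_map(rng)
    causal = mm.nearest_marker("chr2", 300_000)
    model = TraitModel(
        perturbation_id="planted",
        mode="rule_based",
        rules=(TraitRule(required={causal: P1}, max_temperature=21),),
    )
    row = mm.table.iloc[mm.index_of(causal)]
    hits = 0
    for _ in range(n_replicates):
        parent = make_rough_parent(mm, model, rng)
        pop = make_backcross(parent, "3S", 4 * n_selected, mm, DEFAULT_RECOMB_RATE, rng)
        pop = assign_phenotypes(pop, model)
        selected = select_rough(pop, "any")
        if selected.n_segregants < n_selected:
            continue
        selected = selected.subset(np.arange(n_selected))
        mask = segregating_mask(parent, P2)
        calls, _ = call_loci(from_truth(mm, selected.genotypes), mask, "planted", "3S", "any", alpha)
        hits += any(
            c.chrom == row["chrom"] and c.start <= row["pos"] <= c.end for c in calls
        )
    return ExperimentSummary(n_replicates=n_replicates, n_hits=hits)


def _additive_model(mm: MarkerMap) -> TraitModel:
    """Three unlinked enrichment loci, uncapped products (additive architecture).

    All favored alleles are BY so that every locus segregates in a 3S
    backcross; baseline 0.02 with factors 3 keeps the per-segregant trait
    probability below 1 (max 0.54), so selected multi-locus genotype
    frequencies factorize exactly.
    """
    return TraitModel(
        perturbation_id="additive",
        mode="multiplicative",
        baseline=0.02,
        effects={
            mm.nearest_marker("chr1", 300_000): (P1, 3.0),
            mm.nearest_marker("chr3", 300_000): (P1, 3.0),
            mm.nearest_marker("chr5", 300_000): (P1, 3.0),
        },
    )


def _epistatic_model(mm: MarkerMap) -> TraitModel:
    """Two alternative AND-rules over four unlinked loci (epistatic architecture).

    Two distinct allele combinations each suffice for trait expression, so
    all four loci stay polymorphic among selected segregants (segregants
    selected via one rule carry random alleles at the other rule's loci)
    while joint frequencies deviate strongly from per-locus products.
    """
    return TraitModel(
        perturbation_id="epistatic",
        mode="rule_based",
        rules=(
            TraitRule(
                required={
                    mm.nearest_marker("chr1", 300_000): P1,
                    mm.nearest_marker("chr3", 300_000): P1,
                },
                max_temperature=21,
            ),
            TraitRule(
                required={
                    mm.nearest_marker("chr5", 300_000): P1,
                    mm.nearest_marker("chr6", 300_000): P1,
                },
                max_temperature=21,
            ),
        ),
    )


def additivity_discrimination_experiment(
    architecture: str,
    n_replicates: int = 100,
    n_selected: int = 150,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExperimentSummary:
    """Rejection rate of the multi-locus additivity test under a known architecture.

    ``architecture`` is "additive" (multiplicative per-locus enrichment; the
    test should retain the null) or "epistatic" (two alternative AND-rules;
    the test should reject).  Counts replicates with P < alpha.
    """
    if architecture not in ("additive", "epistatic"):
        raise ValueError("architecture must be 'additive' or 'epistatic'")
    rng = np.random.default_rng(seed)
    mm = _default_map(rng)
    model = _additive_model(mm) if architecture == "additive" else _epistatic_model(mm)
    loci = list(model.loci)
    rejections = 0
    n_done = 0
    while n_done < n_replicates:
        parent = make_rough_parent(mm, model, rng)
        pop = make_backcross(parent, "3S", 15 * n_selected, mm, DEFAULT_RECOMB_RATE, rng)
        pop = assign_phenotypes(pop, model, rng)
        selected = select_rough(pop, "21")
        if selected.n_segregants < n_selected:
            continue
        selected = selected.subset(np.arange(n_selected))
        result = additivity_analysis(from_truth(mm, selected.genotypes), loci)
        if not result.applicable:
            continue
        rejections += result.p_value < alpha
        n_done += 1
    return ExperimentSummary(n_replicates=n_replicates, n_hits=rejections)
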