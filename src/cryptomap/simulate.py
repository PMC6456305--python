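"""Simulation of haploid backcross segregant populations.

The generator emulates the study design behind selection-based mapping of
cryptic variants: a trait-expressing ("rough") recombinant haploid is
backcrossed to one of the two original parents, haploid progeny are produced
by meiosis with Haldane (no-interference) recombination, phenotypes are
assigned by a perturbation-gated trait model at three temperatures
(21/30/37 C), trait-expressing segregants are selected into temperature-
sensitivity classes, and low-coverage sequencing is emulated as Poisson
per-site read depth with a symmetric per-read error rate.

Two trait-model modes are supported:

* ``rule_based`` — the phenotype is expressed iff some rule's required
  multi-locus allele combination is carried; each rule caps the maximal
  expression temperature.  Deterministic; models epistatic (AND-gate)
  architectures with genotypic heterogeneity when several rules coexist.
* ``multiplicative`` — the phenotype is expressed at 21 C with probability
  ``baseline * prod(factor_l over carried favored alleles)`` (clipped at 1)
  and never at 30/37 C.  Among selected segregants with unlinked loci this
  makes multi-locus genotype frequencies factorize into per-locus allele
  frequencies — the additive architecture signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import P1, MarkerMap, allele_code

#: default recombination rate, Morgans per bp (~3 expected crossovers on a 1-Mb chromosome)
DEFAULT_RECOMB_RATE = 3e-6

TEMPERATURES = (21, 30, 37)

#: temperature-sensitivity class labels = maximal temperature of trait expression
CLASSES = ("21", "30", "37")


@dataclass(frozen=True)
class TraitRule:
    """One epistatic AND-rule: required alleles plus the maximal expression temperature."""

    required: dict[str, int]  # marker_id -> allele code
    max_temperature: int

    def __post_init__(self) -> None:
        if self.max_temperature not in TEMPERATURES:
            raise ValueError(f"max_temperature must be one of {TEMPERATURES}")
        object.__setattr__(
            self, "required", {m: allele_code(a) for m, a in self.required.items()}
        )


@dataclass(frozen=True)
class TraitModel:
    """Perturbation-gated genotype->phenotype rules for one genetic perturbation."""

    perturbation_id: str
    mode: str  # "rule_based" | "multiplicative"
    rules: tuple[TraitRule, ...] = ()
    effects: dict[str, tuple[int, float]] = field(default_factory=dict)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("rule_based", "multiplicative"):
            raise ValueError(f"unknown trait-model mode {self.mode!r}")
        if self.mode == "rule_based" and not self.rules:
            raise ValueError("rule_based model needs at least one rule")
        if self.mode == "multiplicative":
            if not (0 < self.baseline <= 1):
                raise ValueError("baseline trait probability must be in (0, 1]")
            eff = {}
            for m, (a, f) in self.effects.items():
                f = float(f)
                if not np.isfinite(f) or f < 1:
                    raise ValueError("enrichment factors must be finite and >= 1")
                eff[m] = (allele_code(a), f)
            object.__setattr__(self, "effects", eff)

    @property
    def loci(self) -> tuple[str, ...]:
        if self.mode == "rule_based":
            out: list[str] = []
            for r in self.rules:
                out.extend(m for m in r.required if m not in out)
            return tuple(out)
        return tuple(self.effects)


@dataclass
class Population:
    """A backcross segregant population on a shared marker map.

    ``genotypes`` is the true (simulated) calls matrix, segregants x markers,
    values in {0, 1}.  ``phenotypes`` (once assigned) has boolean columns
    ``rough21/rough30/rough37`` and a ``tclass`` column in
    {"21", "30", "37", "smooth"}.
    """

    marker_map: MarkerMap
    genotypes: np.ndarray
    rough_parent: np.ndarray
    recurrent: int
    phenotypes: pd.DataFrame | None = None

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    def subset(self, index: np.ndarray) -> "Population":
        phen = None if self.phenotypes is None else self.phenotypes.iloc[index].reset_index(drop=True)
        return replace(self, genotypes=self.genotypes[index], phenotypes=phen)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def haldane(distance_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a map distance in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_morgans, dtype=float)))


def simulate_gametes(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    marker_map: MarkerMap,
    recomb_rate: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` meiotic gametes of ``parent_a x parent_b`` as an (n, m) allele matrix.

    Each chromosome starts from a fair random parent; between adjacent markers
    the parental state switches with the Haldane recombination fraction
    r = (1 - exp(-2 * rate * d)) / 2, the probability of an odd
    Poisson(rate * d) crossover count.  Chromosomes assort independently.
    """
    if recomb_rate < 0:
        raise ValueError("recombination rate must be >= 0")
    m = marker_map.n_markers
    if parent_a.shape != (m,) or parent_b.shape != (m,):
        raise ValueError("parents must be defined on the same marker map")
    rng = _as_rng(seed)
    out = np.empty((n, m), dtype=np.int8)
    for chrom in marker_map.chrom_names:
        sl = marker_map.chrom_slice(chrom)
        mc = sl.stop - sl.start
        if mc == 0:
            continue
        r = haldane(np.diff(marker_map.positions(chrom)).astype(float) * recomb_rate)
        start = rng.integers(0, 2, size=n)
        switches = rng.random((n, mc - 1)) < r
        state = np.empty((n, mc), dtype=np.int8)
        state[:, 0] = start
        if mc > 1:
            state[:, 1:] = switches
            np.bitwise_xor.accumulate(state, axis=1, out=state)
        out[:, sl] = np.where(state == 0, parent_a[sl], parent_b[sl])
    return out


def simulate_gamete(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    marker_map: MarkerMap,
    recomb_rate: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Single-gamete convenience wrapper around :func:`simulate_gametes`."""
    return simulate_gametes(parent_a, parent_b, marker_map, recomb_rate, 1, seed)[0]


def make_rough_parent(
    marker_map: MarkerMap,
    model: TraitModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Simulate a trait-expressing F2-like recombinant haploid.

    An F2 gamete of the pure parental haplotypes is drawn, then conditioned on
    carrying the alleles the trait model requires (all rule alleles, or all
    favored alleles in multiplicative mode) — a trait-expressing founder
    necessarily carries them.  Conditioning flips the entire contiguous
    same-parent block containing a required locus, preserving the natural
    block structure of a recombinant haplotype (a lone single-marker island
    would be an artifact no real meiosis produces).
    """
    rng = _as_rng(seed)
    pure_p1 = np.zeros(marker_map.n_markers, dtype=np.int8)
    pure_p2 = np.ones(marker_map.n_markers, dtype=np.int8)
    hap = simulate_gametes(pure_p1, pure_p2, marker_map, DEFAULT_RECOMB_RATE, 1, rng)[0]
    if model.mode == "rule_based":
        wanted = {m: a for rule in model.rules for m, a in rule.required.items()}
    else:
        wanted = {m: a for m, (a, _) in model.effects.items()}
    for marker_id, allele in wanted.items():
        idx = marker_map.index_of(marker_id)
        if hap[idx] == allele:
            continue
        chrom = str(marker_map.table["chrom"].iloc[idx])
        sl = marker_map.chrom_slice(chrom)
        lo = idx
        while lo > sl.start and hap[lo - 1] == hap[idx]:
            lo -= 1
        hi = idx
        while hi < sl.stop - 1 and hap[hi + 1] == hap[idx]:
            hi += 1
        hap[lo : hi + 1] = allele
    return hap


def make_backcross(
    rough_parent: np.ndarray,
    recurrent: int | str,
    n: int,
    marker_map: MarkerMap,
    recomb_rate: float,
    seed: int | np.random.Generator,
) -> Population:
    """Backcross a trait-expressing haploid to a pure recurrent parent.

    Markers where the rough parent already carries the recurrent allele are
    fixed in the progeny; the rest segregate 1:1.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    rec = allele_code(recurrent)
    recurrent_hap = np.full(marker_map.n_markers, rec, dtype=np.int8)
    gametes = simulate_gametes(
        rough_parent.astype(np.int8), recurrent_hap, marker_map, recomb_rate, n, seed
    )
    return Population(
        marker_map=marker_map,
        genotypes=gametes,
        rough_parent=rough_parent.astype(np.int8),
        recurrent=rec,
    )


def assign_phenotypes(
    pop: Population,
    model: TraitModel,
    seed: int | np.random.Generator | None = None,
) -> Population:
    """Score every segregant rough/smooth at 21, 30 and 37 C under ``model``.

    rule_based mode is deterministic: rough at temperature T iff some rule
    with ``max_temperature >= T`` has all its required alleles, so expression
    is monotone in temperature.  multiplicative mode is stochastic at 21 C
    only (requires ``seed``).
    """
    G = pop.genotypes
    n = pop.n_segregants
    mm = pop.marker_map
    if model.mode == "rule_based":
        rough = {t: np.zeros(n, dtype=bool) for t in TEMPERATURES}
        for rule in model.rules:
            idx = [mm.index_of(marker) for marker in rule.required]
            want = np.array(list(rule.required.values()), dtype=np.int8)
            carried = (G[:, idx] == want).all(axis=1)
            for t in TEMPERATURES:
                if rule.max_temperature >= t:
                    rough[t] |= carried
        r21, r30, r37 = rough[21], rough[30], rough[37]
    else:
        rng = _as_rng(seed if seed is not None else 0)
        p = np.full(n, model.baseline, dtype=float)
        for marker_id, (allele, factor) in model.effects.items():
            p *= np.where(G[:, mm.index_of(marker_id)] == allele, factor, 1.0)
        p = np.minimum(p, 1.0)
        r21 = rng.random(n) < p
        r30 = np.zeros(n, dtype=bool)
        r37 = np.zeros(n, dtype=bool)
    tclass = np.where(r37, "37", np.where(r30, "30", np.where(r21, "21", "smooth")))
    phen = pd.DataFrame({"rough21": r21, "rough30": r30, "rough37": r37, "tclass": tclass})
    return replace(pop, phenotypes=phen)


def select_rough(pop: Population, class_filter: str = "any") -> Population:
    """Keep segregants rough at 21 C, optionally restricted to one temperature class.

    ``class_filter`` is "any" (all rough-at-21 segregants) or an exact
    temperature-sensitivity class: "21" (21 C only), "30" (up to 30 C),
    "37" (up to 37 C).
    """
    if pop.phenotypes is None:
        raise ValueError("phenotypes must be assigned before selection")
    if class_filter not in ("any",) + CLASSES:
        raise ValueError(f"invalid class filter {class_filter!r}")
    phen = pop.phenotypes
    if class_filter == "any":
        keep = phen["rough21"].to_numpy()
    else:
        keep = (phen["tclass"] == class_filter).to_numpy()
    return pop.subset(np.flatnonzero(keep))


@dataclass
class AlleleCountMatrix:
    """Per-segregant per-marker read counts for the two parental alleles."""

    marker_map: MarkerMap
    n_p1: np.ndarray
    n_p2: np.ndarray

    def __post_init__(self) -> None:
        if self.n_p1.shape != self.n_p2.shape:
            raise ValueError("count matrices must share a shape")
        if self.n_p1.shape[1] != self.marker_map.n_markers:
            raise ValueError("count matrices must match the marker map")
        if (self.n_p1 < 0).any() or (self.n_p2 < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_segregants(self) -> int:
        return self.n_p1.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.n_p1 + self.n_p2


def simulate_read_counts(
    pop: Population,
    mean_coverage: float,
    error_rate: float,
    seed: int | np.random.Generator,
) -> AlleleCountMatrix:
    """Emulate low-coverage sequencing of a population.

    Depth at each (segregant, site) is Poisson(``mean_coverage``); each read
    reports the true allele with probability ``1 - error_rate``, else the
    other parental allele.
    """
    if mean_coverage < 0:
        raise ValueError("mean coverage must be >= 0")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    rng = _as_rng(seed)
    depth = rng.poisson(mean_coverage, size=pop.genotypes.shape)
    errors = rng.binomial(depth, error_rate)
    correct = depth - errors
    truth_is_p1 = pop.genotypes == P1
    n_p1 = np.where(truth_is_p1, correct, errors)
    n_p2 = np.where(truth_is_p1, errors, correct)
    return AlleleCountMatrix(marker_map=pop.marker_map, n_p1=n_p1, n_p2=n_p2)
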