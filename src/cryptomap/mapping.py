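"""Selection-based (BSA-style) locus mapping in phenotype-selected segregants.

Among backcross progeny selected for the trait, a causal locus shows an
allele-frequency distortion away from the 1:1 backcross expectation.  The
scan:

1. restricts to markers that actually segregate in the backcross
   (:func:`segregating_mask`);
2. collapses markers carrying identical genotype vectors across all selected
   segregants into single statistical tests (:func:`collapse_markers`);
3. computes an exact two-sided binomial P-value per collapsed group against
   the 1:1 null (:func:`binomial_scan`), dropping missing calls per marker;
4. applies a per-population Bonferroni correction at family-wise alpha = 0.01
   (:func:`significant_markers`);
5. merges maximal runs of adjacent significant markers into loci, and reports
   each locus as its peak marker plus the "drop-2" interval — the contiguous
   stretch of markers whose -log10(P) stays within 2 of the peak
   (:func:`delimit_interval`, :func:`call_loci`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .markers import ALLELE_LABELS, MISSING, P1, P2
from .hmm import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusCall:
    """A significant trait-associated locus in one mapping population."""

    gp: str
    backcross: str
    tclass: str
    chrom: str
    peak_id: str
    peak_pos: int
    start: int
    end: int
    allele: str  # enriched parental allele, "BY" | "3S"
    peak_score: float  # -log10 P at the peak marker

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("peak must lie inside its interval")
        if self.allele not in ALLELE_LABELS:
            raise ValueError(f"enriched allele must be one of {ALLELE_LABELS}")


@dataclass
class CollapsedGroups:
    """Partition of tested markers into identical-genotype-vector groups."""

    marker_indices: np.ndarray  # indices (into the marker map) of tested markers
    group_of: np.ndarray  # per tested marker: group id
    representatives: np.ndarray  # per group: leftmost member (marker-map index)

    @property
    def n_groups(self) -> int:
        return len(self.representatives)


def collapse_markers(
    calls: np.ndarray, marker_indices: np.ndarray | None = None
) -> CollapsedGroups:
    """Group markers whose call vectors (including missingness) are identical.

    Collapsed markers carry the same information across all segregants and
    form a single statistical test; the group representative is the leftmost
    member.
    """
    if calls.size == 0:
        raise ValueError("cannot collapse an empty genotype matrix")
    if marker_indices is None:
        marker_indices = np.arange(calls.shape[1])
    marker_indices = np.asarray(marker_indices)
    cols = calls[:, marker_indices].T
    _, first, inverse = np.unique(cols, axis=0, return_index=True, return_inverse=True)
    # renumber groups by leftmost member so representatives are ordered
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    group_of = rank[inverse]
    representatives = marker_indices[first[order]]
    return CollapsedGroups(
        marker_indices=marker_indices, group_of=group_of, representatives=representatives
    )


def segregating_mask(rough_parent: np.ndarray, recurrent: int) -> np.ndarray:
    """Markers informative in a backcross: rough parent carries the non-recurrent allele."""
    if recurrent not in (P1, P2):
        raise ValueError("recurrent parent must be P1 (0) or P2 (1)")
    if (rough_parent == MISSING).any():
        raise ValueError("rough-parent genotype must be fully known")
    return rough_parent != recurrent


def binomial_pvalues(n_p1: np.ndarray, n_p2: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial P-value of each allele split against p = 1/2.

    For the symmetric null the two-sided P is 2*BinomCDF(min(k, n-k)),
    capped at 1.  Entries with no informative calls get NaN.
    """
    n_p1 = np.asarray(n_p1, dtype=np.int64)
    n_p2 = np.asarray(n_p2, dtype=np.int64)
    n = n_p1 + n_p2
    k = np.minimum(n_p1, n_p2)
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * binom.cdf(k, np.maximum(n, 1), 0.5))
    p = np.where(n_p1 == n_p2, 1.0, p)
    return np.where(n == 0, np.nan, p)


def significant_markers(pvalues: np.ndarray, m: int, alpha: float = 0.01) -> np.ndarray:
    """Bonferroni flags: raw P below alpha / m, with m tests in this population."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        return np.asarray(pvalues) < alpha / m


def delimit_interval(
    scores: np.ndarray, positions: np.ndarray, peak_index: int
) -> tuple[int, int]:
    """Drop-2 interval around a peak along one chromosome's tested markers.

    Walk outward from the peak over contiguous markers whose -log10(P) is
    within 2 of the peak's; the interval is bounded by the outermost such
    markers (1-based inclusive bp).  The first marker strictly more than
    2 below the peak is excluded.
    """
    scores = np.asarray(scores, dtype=float)
    threshold = scores[peak_index] - 2.0
    left = peak_index
    while left > 0 and scores[left - 1] >= threshold:
        left -= 1
    right = peak_index
    while right < len(scores) - 1 and scores[right + 1] >= threshold:
        right += 1
    return int(positions[left]), int(positions[right])


def scan_table(
    genotypes: GenotypeMatrix,
    mask: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-tested-marker scan statistics for one selected population.

    Returns one row per mask-passing marker with its collapsed group id,
    allele counts among selected segregants (missing excluded), exact
    binomial P, -log10(P) and the Bonferroni significance flag computed
    with m = number of collapsed groups with at least one informative call.
    """
    mm = genotypes.marker_map
    tested = np.flatnonzero(mask)
    if tested.size == 0:
        return pd.DataFrame(
            columns=[
                "marker_id", "chrom", "pos", "group", "n_p1", "n_p2",
                "n_missing", "p_value", "neg_log10_p", "significant",
            ]
        )
    groups = collapse_markers(genotypes.calls, tested)
    rep_calls = genotypes.calls[:, groups.representatives]
    n_p1 = (rep_calls == P1).sum(axis=0)
    n_p2 = (rep_calls == P2).sum(axis=0)
    n_missing = (rep_calls == MISSING).sum(axis=0)
    informative = (n_p1 + n_p2) > 0
    m = int(informative.sum())
    skipped = groups.n_groups - m
    if skipped:
        logger.info("skipping %d collapsed group(s) with no informative calls", skipped)
    pvals = binomial_pvalues(n_p1, n_p2)
    sig = (
        significant_markers(pvals, m, alpha) if m else np.zeros(groups.n_groups, dtype=bool)
    )
    g = groups.group_of
    table = mm.table.iloc[tested]
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10 = -np.log10(pvals)
    return pd.DataFrame(
        {
            "marker_id": table["marker_id"].to_numpy(),
            "chrom": table["chrom"].to_numpy(),
            "pos": table["pos"].to_numpy(),
            "group": g,
            "n_p1": n_p1[g],
            "n_p2": n_p2[g],
            "n_missing": n_missing[g],
            "p_value": pvals[g],
            "neg_log10_p": neg_log10[g],
            "significant": sig[g] & informative[g],
        }
    )


def call_loci(
    genotypes: GenotypeMatrix,
    mask: np.ndarray,
    gp: str,
    backcross: str,
    tclass: str,
    alpha: float = 0.01,
) -> tuple[list[LocusCall], pd.DataFrame]:
    """Full mapping scan for one (GP, backcross, temperature-class) population.

    Each maximal run of adjacent significant tested markers on a chromosome
    becomes one locus: the peak is the run's maximal -log10(P) marker
    (leftmost on ties), the interval is the peak's drop-2 interval over the
    chromosome's tested markers, and the enriched allele is the majority
    parental allele at the peak.  Returns the locus calls and the scan table.
    """
    scan = scan_table(genotypes, mask, alpha)
    calls: list[LocusCall] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sig = sub["significant"].to_numpy()
        if not sig.any():
            continue
        scores = sub["neg_log10_p"].to_numpy()
        positions = sub["pos"].to_numpy()
        boundaries = np.flatnonzero(np.diff(sig.astype(int)))
        run_edges = np.concatenate([[0], boundaries + 1, [len(sig)]])
        for a, b in zip(run_edges[:-1], run_edges[1:]):
            if not sig[a]:
                continue
            run_scores = scores[a:b]
            peak_local = a + int(np.argmax(run_scores))  # argmax -> leftmost tie
            start, end = delimit_interval(scores, positions, peak_local)
            row = sub.iloc[peak_local]
            allele = ALLELE_LABELS[P1] if row["n_p1"] > row["n_p2"] else ALLELE_LABELS[P2]
            calls.append(
                LocusCall(
                    gp=gp,
                    backcross=backcross,
                    tclass=tclass,
                    chrom=str(chrom),
                    peak_id=str(row["marker_id"]),
                    peak_pos=int(row["pos"]),
                    start=start,
                    end=end,
                    allele=allele,
                    peak_score=float(row["neg_log10_p"]),
                )
            )
    return calls, scan
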