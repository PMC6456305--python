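"""Genotypic heterogeneity and additivity/epistasis tests.

Two complementary analyses of selected (trait-expressing) segregants:

* :func:`two_locus_scan` — for every pair of collapsed marker groups,
  compare the observed 2x2 two-locus genotype counts with the expectation
  under independence (product of the single-locus allele frequencies) by a
  Pearson chi-square test, then control the FDR over all pairs with
  Benjamini-Hochberg at a stringent threshold (default 1e-4).  Markers
  within 30 kb of chromosome ends are excluded.  Significant pairs reveal
  genotypic heterogeneity: distinct multi-locus genotype classes among the
  selected.
* :func:`additivity_test` — compare observed multi-locus genotype counts
  over all 2^L combinations of L mapped loci with expected counts computed
  as n times the product of per-locus allele frequencies; chi-square with
  df = 2^L - 1.  Agreement indicates additive locus action among the
  selected; departure indicates epistasis.  Only loci with both parental
  alleles present qualify, and at least two such loci are required.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .markers import ALLELE_LABELS, MISSING, P1, P2, MarkerMap
from .hmm import GenotypeMatrix
from .mapping import collapse_markers

DEFAULT_FDR = 1e-4
DEFAULT_END_EXCLUSION = 30_000


def end_exclusion_mask(marker_map: MarkerMap, end_exclusion: int = DEFAULT_END_EXCLUSION) -> np.ndarray:
    """Markers farther than ``end_exclusion`` bp from both chromosome ends."""
    pos = marker_map.table["pos"].to_numpy()
    chrom = marker_map.table["chrom"].to_numpy()
    lengths = np.array([marker_map.chrom_length(c) for c in chrom])
    return (pos >= end_exclusion) & (pos <= lengths - end_exclusion)


def two_locus_scan(
    genotypes: GenotypeMatrix,
    fdr: float = DEFAULT_FDR,
    end_exclusion: int = DEFAULT_END_EXCLUSION,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Chi-square scan of all collapsed marker-group pairs for two-locus structure.

    Expected two-locus genotype frequencies are products of the two
    single-locus allele frequencies computed among segregants informative at
    both markers.  Pairs where either group is monomorphic are skipped.
    Returns one row per tested pair with chi2, P, BH q-value and a
    ``significant`` flag (q < fdr).
    """
    mm = genotypes.marker_map
    keep = end_exclusion_mask(mm, end_exclusion)
    if mask is not None:
        keep &= mask
    tested = np.flatnonzero(keep)
    if tested.size < 2:
        raise ValueError("need at least two markers after end exclusion")
    groups = collapse_markers(genotypes.calls, tested)
    reps = groups.representatives
    calls = genotypes.calls[:, reps]
    is1 = (calls == P2).astype(np.float64)
    valid = (calls != MISSING).astype(np.float64)
    # pairwise joint counts via matrix products over jointly informative segregants
    n_pair = valid.T @ valid
    c11 = is1.T @ is1
    c10 = is1.T @ (valid - is1)
    c01 = (valid - is1).T @ is1
    c00 = (valid - is1).T @ (valid - is1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa1 = (c11 + c10) / n_pair  # freq of P2 at A among jointly informative
        fb1 = (c11 + c01) / n_pair
    rows = []
    g = groups.n_groups
    rep_ids = mm.table["marker_id"].to_numpy()[reps]
    rep_chroms = mm.table["chrom"].to_numpy()[reps]
    for i, j in itertools.combinations(range(g), 2):
        n = n_pair[i, j]
        if n == 0:
            continue
        fa, fb = fa1[i, j], fb1[i, j]
        if fa in (0.0, 1.0) or fb in (0.0, 1.0):
            continue  # monomorphic among jointly informative segregants
        obs = np.array([c00[i, j], c01[i, j], c10[i, j], c11[i, j]])
        exp = n * np.array(
            [(1 - fa) * (1 - fb), (1 - fa) * fb, fa * (1 - fb), fa * fb]
        )
        stat = float(((obs - exp) ** 2 / exp).sum())
        rows.append(
            {
                "marker_a": rep_ids[i],
                "marker_b": rep_ids[j],
                "same_chrom": bool(rep_chroms[i] == rep_chroms[j]),
                "n": int(n),
                "n00": int(obs[0]),
                "n01": int(obs[1]),
                "n10": int(obs[2]),
                "n11": int(obs[3]),
                "chi2": stat,
                "p_value": float(chi2.sf(stat, df=1)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "marker_a", "marker_b", "same_chrom", "n", "n00", "n01", "n10", "n11",
            "chi2", "p_value",
        ],
    )
    if len(out):
        rejected, qvals, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
        out["q_value"] = qvals
        out["significant"] = rejected
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def infer_allele_combinations(
    genotypes: GenotypeMatrix, locus_markers: list[str]
) -> pd.DataFrame:
    """Enumerate observed multi-locus genotype classes among selected segregants.

    Segregants missing a call at any listed locus are dropped.  Combinations
    are reported with counts and frequencies, sorted by descending count and
    lexicographically by genotype label on ties.
    """
    if not locus_markers:
        raise ValueError("need at least one called locus")
    mm = genotypes.marker_map
    idx = [mm.index_of(m) for m in locus_markers]
    calls = genotypes.calls[:, idx]
    complete = (calls != MISSING).all(axis=1)
    calls = calls[complete]
    labels = [
        "/".join(ALLELE_LABELS[a] for a in row) for row in calls.astype(int).tolist()
    ]
    counts = pd.Series(labels, dtype=object).value_counts()
    df = (
        counts.rename_axis("combination")
        .reset_index(name="count")
        .sort_values(["count", "combination"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    df["frequency"] = df["count"] / max(len(calls), 1)
    return df


def multilocus_expected(frequencies_p1: np.ndarray, n: int) -> np.ndarray:
    """Expected counts for all 2^L multi-locus genotypes under independence.

    ``frequencies_p1`` gives each locus's P1 (BY) allele frequency among the
    selected segregants; genotype g gets n * prod_l f_l(g_l).  Genotypes are
    ordered by ``itertools.product((P1, P2), repeat=L)``.
    """
    f = np.asarray(frequencies_p1, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise ValueError("need allele frequencies for at least two loci")
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("monomorphic loci must be excluded before computing expectations")
    expected = np.array(
        [
            n * np.prod([f[l] if g[l] == P1 else 1 - f[l] for l in range(len(f))])
            for g in itertools.product((P1, P2), repeat=len(f))
        ]
    )
    return expected


@dataclass(frozen=True)
class AdditivityResult:
    """Outcome of the multi-locus additivity test (or its inapplicability)."""

    applicable: bool
    n_loci: int = 0
    n: int = 0
    chi2: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    p_monte_carlo: float = float("nan")
    any_small_expected: bool = False
    reason: str = ""


def additivity_test(
    observed: np.ndarray,
    expected: np.ndarray,
    mc_reps: int = 0,
    seed: int | np.random.Generator | None = None,
) -> AdditivityResult:
    """Chi-square comparison of observed vs expected multi-locus genotype counts.

    df = (number of genotype cells) - 1.  Small expected cells are kept
    unpooled; when any expected count is below 5 and ``mc_reps > 0``, a
    Monte-Carlo P-value is added by multinomial resampling from the expected
    frequencies.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must align")
    n = observed.sum()
    if abs(expected.sum() - n) > 1e-6 * max(n, 1):
        raise ValueError("expected counts must sum to the number of segregants")
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = observed.size - 1
    p = float(chi2.sf(stat, df=df))
    small = bool((expected < 5).any())
    p_mc = float("nan")
    if small and mc_reps > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        probs = expected / expected.sum()
        draws = rng.multinomial(int(round(n)), probs, size=mc_reps)
        stats = ((draws - expected) ** 2 / expected).sum(axis=1)
        p_mc = float((1 + (stats >= stat - 1e-12).sum()) / (1 + mc_reps))
    return AdditivityResult(
        applicable=True,
        n_loci=int(np.log2(observed.size)),
        n=int(round(n)),
        chi2=stat,
        df=df,
        p_value=p,
        p_monte_carlo=p_mc,
        any_small_expected=small,
    )


def additivity_analysis(
    genotypes: GenotypeMatrix,
    locus_markers: list[str],
    mc_reps: int = 0,
    seed: int | np.random.Generator | None = None,
) -> AdditivityResult:
    """Additivity/epistasis test over the peak markers of mapped loci.

    Applies the inclusion rules: loci monomorphic among the selected
    segregants are excluded, and the test is only performed when at least
    two qualifying loci remain (otherwise an explicit not-applicable result
    is returned).  Segregants missing a call at any qualifying locus are
    dropped.
    """
    mm = genotypes.marker_map
    idx = [mm.index_of(m) for m in locus_markers]
    calls = genotypes.calls[:, idx]
    polymorphic = [
        j for j in range(calls.shape[1])
        if (calls[:, j] == P1).any() and (calls[:, j] == P2).any()
    ]
    if len(polymorphic) < 2:
        return AdditivityResult(
            applicable=False,
            n_loci=len(polymorphic),
            reason="fewer than two loci with both parental alleles among selected segregants",
        )
    calls = calls[:, polymorphic]
    complete = (calls != MISSING).all(axis=1)
    calls = calls[complete]
    n, L = calls.shape
    f_p1 = (calls == P1).mean(axis=0)
    if ((f_p1 <= 0) | (f_p1 >= 1)).any():
        # monomorphic after dropping incomplete segregants
        keep = np.flatnonzero((f_p1 > 0) & (f_p1 < 1))
        if len(keep) < 2:
            return AdditivityResult(
                applicable=False,
                n_loci=len(keep),
                reason="fewer than two polymorphic loci after dropping incomplete segregants",
            )
        calls = calls[:, keep]
        L = len(keep)
        f_p1 = (calls == P1).mean(axis=0)
    expected = multilocus_expected(f_p1, n)
    codes = calls.astype(int) @ (1 << np.arange(L - 1, -1, -1))
    observed = np.bincount(codes, minlength=2**L).astype(float)
    return additivity_test(observed, expected, mc_reps=mc_reps, seed=seed)
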