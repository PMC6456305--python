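"""Two-state HMM genotype calling from sparse allele counts.

Each haploid segregant's chromosome is a two-state chain over the parental
origins {P1, P2}.  Emissions are binomial read-error likelihoods of the
observed allele counts; transitions between adjacent markers follow the
Haldane map function, so recombination probability grows with physical
distance.  Posterior (forward-backward) decoding yields a per-marker
posterior for each state; a genotype is called where the larger posterior
clears ``min_posterior``, otherwise the site is left missing.  Uncovered
sites stay in the chain with uninformative emissions, so linkage imputes
through them — which is what makes genome-wide genotyping possible at
~2.5x coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .markers import MISSING, MarkerMap
from .simulate import DEFAULT_RECOMB_RATE, AlleleCountMatrix, haldane


@dataclass(frozen=True)
class HmmParams:
    """Genotype-calling HMM parameters.

    error_rate
        Per-read probability of reporting the wrong parental allele.
    recomb_rate
        Morgans per bp, governing marker-to-marker transition probabilities.
    min_posterior
        Posterior required to make a call; below it the site is missing.
    initial
        State prior at the first marker of each chromosome (default fair).
    """

    error_rate: float = 0.002
    recomb_rate: float = DEFAULT_RECOMB_RATE
    min_posterior: float = 0.9
    initial: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if self.recomb_rate < 0:
            raise ValueError("recombination rate must be >= 0")
        if not (0.5 <= self.min_posterior <= 1):
            raise ValueError("min_posterior must be in [0.5, 1]")
        if abs(sum(self.initial) - 1) > 1e-12 or min(self.initial) < 0:
            raise ValueError("initial state probabilities must be a distribution")


@dataclass
class GenotypeMatrix:
    """Genotype calls (segregants x markers) with per-site posterior confidence.

    ``calls`` values are 0 (P1), 1 (P2) or -1 (missing); ``posterior`` holds
    the posterior probability of the more probable state at each site;
    ``provenance`` records whether calls are simulated truth or HMM output.
    """

    marker_map: MarkerMap
    calls: np.ndarray
    posterior: np.ndarray
    provenance: str = "hmm"

    def __post_init__(self) -> None:
        if self.calls.shape != self.posterior.shape:
            raise ValueError("calls and posterior must share a shape")
        if self.calls.shape[1] != self.marker_map.n_markers:
            raise ValueError("calls must match the marker map")

    @property
    def n_segregants(self) -> int:
        return self.calls.shape[0]


def from_truth(marker_map: MarkerMap, genotypes: np.ndarray) -> GenotypeMatrix:
    """Wrap simulated true genotypes as a fully confident GenotypeMatrix."""
    return GenotypeMatrix(
        marker_map=marker_map,
        calls=genotypes.astype(np.int8),
        posterior=np.ones_like(genotypes, dtype=float),
        provenance="true",
    )


def emission_likelihoods(
    n_p1: np.ndarray | int, n_p2: np.ndarray | int, error_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial read-error likelihoods of counts under each hidden state.

    L(P1) = C(n, n_p2) (1-e)^n_p1 e^n_p2 and symmetrically for P2.  Sites
    with no reads are state-uninformative (both likelihoods 1).
    """
    if not (0 <= error_rate < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    n_p1 = np.asarray(n_p1)
    n_p2 = np.asarray(n_p2)
    if (n_p1 < 0).any() or (n_p2 < 0).any():
        raise ValueError("read counts must be non-negative")
    n = n_p1 + n_p2
    like_p1 = binom.pmf(n_p2, n, error_rate)
    like_p2 = binom.pmf(n_p1, n, error_rate)
    return like_p1, like_p2


def transition_matrix(distance_bp: float, recomb_rate: float) -> np.ndarray:
    """2x2 parental-origin transition matrix across a physical distance."""
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    if recomb_rate < 0:
        raise ValueError("recombination rate must be >= 0")
    r = float(haldane(distance_bp * recomb_rate))
    return np.array([[1 - r, r], [r, 1 - r]])


def _chrom_posteriors(
    e1: np.ndarray, e2: np.ndarray, r: np.ndarray, initial: tuple[float, float]
) -> np.ndarray:
    """Scaled forward-backward over one chromosome, vectorized over segregants.

    e1, e2: (n, m) emission likelihoods; r: (m-1,) switch probabilities.
    Returns posteriors of state P1, shape (n, m).
    """
    n, m = e1.shape
    alpha = np.empty((n, m, 2))
    scale = np.empty((n, m))
    alpha[:, 0, 0] = initial[0] * e1[:, 0]
    alpha[:, 0, 1] = initial[1] * e2[:, 0]
    s = alpha[:, 0, :].sum(axis=1)
    if (s == 0).any():
        raise ValueError("zero-likelihood observation (conflicting counts with error_rate 0?)")
    scale[:, 0] = s
    alpha[:, 0, :] /= s[:, None]
    for j in range(1, m):
        a0, a1 = alpha[:, j - 1, 0], alpha[:, j - 1, 1]
        rj = r[j - 1]
        alpha[:, j, 0] = e1[:, j] * (a0 * (1 - rj) + a1 * rj)
        alpha[:, j, 1] = e2[:, j] * (a0 * rj + a1 * (1 - rj))
        s = alpha[:, j, :].sum(axis=1)
        if (s == 0).any():
            raise ValueError("zero-likelihood observation (conflicting counts with error_rate 0?)")
        scale[:, j] = s
        alpha[:, j, :] /= s[:, None]
    beta = np.empty((n, m, 2))
    beta[:, m - 1, :] = 1.0
    for j in range(m - 2, -1, -1):
        rj = r[j]
        b0 = beta[:, j + 1, 0] * e1[:, j + 1]
        b1 = beta[:, j + 1, 1] * e2[:, j + 1]
        beta[:, j, 0] = ((1 - rj) * b0 + rj * b1) / scale[:, j + 1]
        beta[:, j, 1] = (rj * b0 + (1 - rj) * b1) / scale[:, j + 1]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post[:, :, 0]


def posterior_decode(counts: AlleleCountMatrix, params: HmmParams) -> np.ndarray:
    """Posterior probability of the P1 state at every (segregant, marker).

    Chromosomes are decoded independently; markers must be position-sorted
    (guaranteed by MarkerMap).
    """
    mm = counts.marker_map
    e1, e2 = emission_likelihoods(counts.n_p1, counts.n_p2, params.error_rate)
    out = np.empty(counts.n_p1.shape, dtype=float)
    for chrom in mm.chrom_names:
        sl = mm.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        r = haldane(np.diff(mm.positions(chrom)).astype(float) * params.recomb_rate)
        out[:, sl] = _chrom_posteriors(
            e1[:, sl], e2[:, sl], np.atleast_1d(r), params.initial
        )
    return out


def call_genotypes(counts: AlleleCountMatrix, params: HmmParams) -> GenotypeMatrix:
    """Decode every segregant and call genotypes at the posterior threshold."""
    post_p1 = posterior_decode(counts, params)
    best = np.maximum(post_p1, 1 - post_p1)
    calls = np.where(post_p1 >= 0.5, 0, 1).astype(np.int8)
    calls[best < params.min_posterior] = MISSING
    return GenotypeMatrix(
        marker_map=counts.marker_map, calls=calls, posterior=best, provenance="hmm"
    )
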