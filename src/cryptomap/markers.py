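"""Biallelic SNP marker maps for a two-parent haploid cross.

Alleles are encoded as integers throughout the package: ``0`` for the P1
(BY-like) parent, ``1`` for the P2 (3S-like) parent, ``-1`` for missing.
Coordinates are 1-based inclusive; conversion to BED happens only at the
BED boundary (:mod:`cryptomap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

P1 = 0
P2 = 1
MISSING = -1

#: human-readable parent labels, index by allele code
ALLELE_LABELS = ("BY", "3S")

_BASES = np.array(list("ACGT"))


def allele_code(label: int | str) -> int:
    """Normalize an allele given as 0/1 or as a parent label ('BY'/'3S')."""
    if isinstance(label, str):
        try:
            return ALLELE_LABELS.index(label)
        except ValueError:
            raise ValueError(f"unknown parent allele label {label!r}") from None
    if label not in (P1, P2):
        raise ValueError(f"allele code must be 0 or 1, got {label!r}")
    return int(label)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic SNP markers on named chromosomes.

    Parameters
    ----------
    chromosomes
        Tuple of ``(name, length_bp)`` pairs, in genome order.
    table
        DataFrame with columns ``chrom, pos, allele_p1, allele_p2, marker_id``,
        sorted by chromosome (in ``chromosomes`` order) then position.
    """

    chromosomes: tuple[tuple[str, int], ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "allele_p1", "allele_p2", "marker_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker table missing columns {required - set(self.table.columns)}")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("marker_ids must be unique")
        if (self.table["allele_p1"] == self.table["allele_p2"]).any():
            raise ValueError("markers must be biallelic (distinct parental alleles)")
        lengths = dict(self.chromosomes)
        slices: dict[str, slice] = {}
        start = 0
        for name, _ in self.chromosomes:
            block = self.table["chrom"].to_numpy() == name
            n = int(block.sum())
            if n and not block[start : start + n].all():
                raise ValueError("markers must be grouped by chromosome in genome order")
            pos = self.table["pos"].to_numpy()[start : start + n]
            if n:
                if not (np.diff(pos) > 0).all():
                    raise ValueError(f"positions must be strictly increasing on {name}")
                if pos[0] < 1 or pos[-1] > lengths[name]:
                    raise ValueError(f"marker position outside chromosome {name}")
            slices[name] = slice(start, start + n)
            start += n
        if start != len(self.table):
            raise ValueError("marker table contains chromosomes not in the map")
        object.__setattr__(self, "_slices", slices)
        object.__setattr__(
            self, "_id_index", {m: i for i, m in enumerate(self.table["marker_id"])}
        )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of this chromosome's markers."""
        return self._slices[chrom]  # type: ignore[attr-defined]

    def positions(self, chrom: str | None = None) -> np.ndarray:
        pos = self.table["pos"].to_numpy()
        return pos if chrom is None else pos[self.chrom_slice(chrom)]

    def index_of(self, marker_id: str) -> int:
        try:
            return self._id_index[marker_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown marker_id {marker_id!r}") from None

    def nearest_marker(self, chrom: str, pos: int) -> str:
        """marker_id of the marker closest to ``chrom:pos`` (ties -> leftmost)."""
        sl = self.chrom_slice(chrom)
        if sl.start == sl.stop:
            raise ValueError(f"no markers on chromosome {chrom}")
        p = self.positions(chrom)
        i = int(np.argmin(np.abs(p.astype(np.int64) - int(pos))))
        return str(self.table["marker_id"].iloc[sl.start + i])


def build_marker_map(
    n_chromosomes: int,
    chromosome_length: int,
    n_markers: int,
    seed: int | np.random.Generator,
) -> MarkerMap:
    """Place ``n_markers`` biallelic SNPs uniformly at random on equal-length chromosomes.

    Positions are deduplicated and sorted; the result is deterministic for a
    given seed.  A scaled-down stand-in for a real inter-strain SNP map.
    """
    if n_chromosomes < 1 or chromosome_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    if n_markers > n_chromosomes * chromosome_length:
        raise ValueError("more markers requested than distinct genomic positions")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_markers:
        k = n_markers - len(chosen)
        c = rng.integers(0, n_chromosomes, size=2 * k)
        p = rng.integers(1, chromosome_length + 1, size=2 * k)
        for ci, pi in zip(c.tolist(), p.tolist()):
            if len(chosen) == n_markers:
                break
            chosen.add((ci, pi))
    sites = sorted(chosen)
    ref = _BASES[rng.integers(0, 4, size=n_markers)]
    alt = np.array([_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in ref])
    table = pd.DataFrame(
        {
            "chrom": [names[c] for c, _ in sites],
            "pos": [p for _, p in sites],
            "allele_p1": ref,
            "allele_p2": alt,
        }
    )
    table["marker_id"] = table["chrom"] + "_" + table["pos"].astype(str)
    chromosomes = tuple((nm, chromosome_length) for nm in names)
    return MarkerMap(chromosomes=chromosomes, table=table)
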