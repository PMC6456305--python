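"""Cross-perturbation locus catalog.

Locus calls from different genetic perturbations (GPs), backcrosses and
temperature classes are consolidated under the assumption that overlapping
intervals on the same chromosome represent the same underlying cryptic
variant: intervals are merged by single linkage (any >= 1 bp overlap,
1-based inclusive coordinates) and each catalog entry records the union
interval, the member calls, the set of GPs it was detected under and an
allele-state summary ("both" when members disagree on the enriched parental
allele).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .mapping import LocusCall


@dataclass(frozen=True)
class CatalogEntry:
    """One distinct locus in the consolidated catalog."""

    locus_id: str
    chrom: str
    start: int
    end: int
    members: tuple[LocusCall, ...]
    gps: frozenset[str]
    allele_summary: str  # "BY" | "3S" | "both"

    @property
    def n_gps(self) -> int:
        return len(self.gps)


def consolidate(calls: list[LocusCall]) -> list[CatalogEntry]:
    """Single-linkage merge of overlapping locus intervals, per chromosome.

    The result is sorted by chromosome name then start position and is
    invariant to the input order.
    """
    by_chrom: dict[str, list[LocusCall]] = {}
    for call in calls:
        if call.start > call.end:
            raise ValueError(f"invalid interval for {call.peak_id}")
        by_chrom.setdefault(call.chrom, []).append(call)
    entries: list[CatalogEntry] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.gp))
        cluster: list[LocusCall] = []
        cluster_end = -1
        clusters: list[list[LocusCall]] = []
        for call in chrom_calls:
            if cluster and call.start > cluster_end:
                clusters.append(cluster)
                cluster = []
                cluster_end = -1
            cluster.append(call)
            cluster_end = max(cluster_end, call.end)
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            alleles = {m.allele for m in members}
            entries.append(
                CatalogEntry(
                    locus_id="",  # assigned after global sort
                    chrom=chrom,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    members=tuple(members),
                    gps=frozenset(m.gp for m in members),
                    allele_summary="both" if len(alleles) > 1 else next(iter(alleles)),
                )
            )
    entries.sort(key=lambda e: (e.chrom, e.start))
    return [
        CatalogEntry(
            locus_id=f"L{i + 1:02d}",
            chrom=e.chrom,
            start=e.start,
            end=e.end,
            members=e.members,
            gps=e.gps,
            allele_summary=e.allele_summary,
        )
        for i, e in enumerate(entries)
    ]


def gp_sharing_counts(catalog: list[CatalogEntry]) -> dict[int, int]:
    """Number of catalog loci detected under exactly 1, 2 and 3 GPs."""
    counts = {1: 0, 2: 0, 3: 0}
    for entry in catalog:
        counts[entry.n_gps] = counts.get(entry.n_gps, 0) + 1
    return counts


def per_gp_counts(catalog: list[CatalogEntry]) -> dict[str, int]:
    """Number of catalog loci whose GP set contains each GP."""
    counts: dict[str, int] = {}
    for entry in catalog:
        for gp in sorted(entry.gps):
            counts[gp] = counts.get(gp, 0) + 1
    return counts


def catalog_to_frame(catalog: list[CatalogEntry]) -> pd.DataFrame:
    """Flat summary table of a consolidated catalog."""
    return pd.DataFrame(
        {
            "locus_id": [e.locus_id for e in catalog],
            "chrom": [e.chrom for e in catalog],
            "start": [e.start for e in catalog],
            "end": [e.end for e in catalog],
            "gps": [",".join(sorted(e.gps)) for e in catalog],
            "n_gps": [e.n_gps for e in catalog],
            "allele": [e.allele_summary for e in catalog],
            "n_members": [len(e.members) for e in catalog],
        }
    )


def load_known_catalog_calls() -> list[LocusCall]:
    """Locus calls encoding the published 21-locus catalog of the BYx3S
    rough-colony system.

    The chromosome, GP-set and enriched-allele structure per locus is the
    published one (GPa: IRA2 loss-of-function; GPb: FLO11 promoter
    recombination; GPc: flo8 sfl1 double knockout); interval coordinates are
    SYNTHETIC placeholders (the study's bp intervals are not reprinted in
    the main text) constructed so that calls for the same gene overlap
    across GPs and calls for different genes never do.  All catalog
    statistics (locus count, GP sharing, per-GP counts, allele summaries)
    depend only on the published structure.
    """
    path = resources.files("cryptomap.data").joinpath("known_loci_synthetic_intervals.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    calls = []
    for row in table.itertuples(index=False):
        calls.append(
            LocusCall(
                gp=row.gp,
                backcross=row.backcross,
                tclass=str(row.tclass),
                chrom=row.chrom,
                peak_id=f"{row.gene}:{row.gp}",
                peak_pos=int((row.start + row.end) // 2),
                start=int(row.start),
                end=int(row.end),
                allele=row.allele,
                peak_score=float(row.peak_score),
            )
        )
    return calls
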