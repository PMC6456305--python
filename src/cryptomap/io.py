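"""Text-format readers and writers.

All tables are plain TSV.  Genotype matrices are written as segregants x
marker_ids with values in {0, 1, NA} (0 = P1/BY, 1 = P2/3S).  Allele counts
can additionally round-trip through a minimal uncompressed VCF (GT + AD)
via pysam for interoperability.  Internal coordinates are 1-based
inclusive; BED output converts to 0-based half-open at this boundary only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .markers import MISSING, MarkerMap
from .hmm import GenotypeMatrix
from .mapping import LocusCall
from .simulate import AlleleCountMatrix, Population


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    table = marker_map.table[["chrom", "pos", "allele_p1", "allele_p2", "marker_id"]]
    table.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path, chromosome_lengths: dict[str, int] | None = None) -> MarkerMap:
    """Read a marker-map TSV; chromosome lengths default to the last marker position."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    names = list(dict.fromkeys(table["chrom"]))
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(table.loc[table["chrom"] == c, "pos"].max()) for c in names
        }
    chromosomes = tuple((c, chromosome_lengths[c]) for c in names)
    return MarkerMap(chromosomes=chromosomes, table=table.reset_index(drop=True))


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    calls = genotypes.calls.astype(object)
    calls[genotypes.calls == MISSING] = "NA"
    df = pd.DataFrame(calls, columns=genotypes.marker_map.marker_ids)
    df.insert(0, "segregant", [f"seg{i:04d}" for i in range(genotypes.n_segregants)])
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, marker_map: MarkerMap, provenance: str = "file") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.drop(columns=["segregant"])
    if list(df.columns) != list(marker_map.marker_ids):
        raise ValueError("genotype columns do not match the marker map")
    calls = df.to_numpy(dtype=object)
    out = np.where(pd.isna(calls) | (calls == "NA"), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        marker_map=marker_map,
        calls=out,
        posterior=np.where(out == MISSING, np.nan, 1.0),
        provenance=provenance,
    )


def write_posteriors(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.posterior, columns=genotypes.marker_map.marker_ids)
    df.insert(0, "segregant", [f"seg{i:04d}" for i in range(genotypes.n_segregants)])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_allele_counts(counts: AlleleCountMatrix, path: str | Path) -> None:
    """Long-format counts TSV: one row per (segregant, marker) with reads."""
    n, m = counts.n_p1.shape
    seg = np.repeat([f"seg{i:04d}" for i in range(n)], m)
    pd.DataFrame(
        {
            "segregant": seg,
            "marker_id": np.tile(counts.marker_map.marker_ids, n),
            "n_p1": counts.n_p1.ravel(),
            "n_p2": counts.n_p2.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path, marker_map: MarkerMap) -> AlleleCountMatrix:
    df = pd.read_csv(path, sep="\t")
    seg_ids = list(dict.fromkeys(df["segregant"]))
    seg_index = {s: i for i, s in enumerate(seg_ids)}
    m_index = {m: i for i, m in enumerate(marker_map.marker_ids)}
    n_p1 = np.zeros((len(seg_ids), marker_map.n_markers), dtype=np.int64)
    n_p2 = np.zeros_like(n_p1)
    rows = df["segregant"].map(seg_index).to_numpy()
    cols = df["marker_id"].map(m_index)
    if cols.isna().any():
        raise ValueError("allele-count file contains markers absent from the map")
    cols = cols.to_numpy(dtype=np.int64)
    n_p1[rows, cols] = df["n_p1"].to_numpy()
    n_p2[rows, cols] = df["n_p2"].to_numpy()
    return AlleleCountMatrix(marker_map=marker_map, n_p1=n_p1, n_p2=n_p2)


def write_phenotypes(pop: Population, path: str | Path) -> None:
    if pop.phenotypes is None:
        raise ValueError("population has no phenotypes")
    df = pop.phenotypes.copy()
    df.insert(0, "segregant", [f"seg{i:04d}" for i in range(pop.n_segregants)])
    df.to_csv(path, sep="\t", index=False)


def write_locus_calls(calls: list[LocusCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gp": [c.gp for c in calls],
            "backcross": [c.backcross for c in calls],
            "tclass": [c.tclass for c in calls],
            "chrom": [c.chrom for c in calls],
            "peak_id": [c.peak_id for c in calls],
            "peak_pos": [c.peak_pos for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "allele": [c.allele for c in calls],
            "peak_score": [c.peak_score for c in calls],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_locus_calls(path: str | Path) -> list[LocusCall]:
    df = pd.read_csv(path, sep="\t", dtype={"tclass": str})
    return [
        LocusCall(
            gp=r.gp,
            backcross=r.backcross,
            tclass=str(r.tclass),
            chrom=r.chrom,
            peak_id=r.peak_id,
            peak_pos=int(r.peak_pos),
            start=int(r.start),
            end=int(r.end),
            allele=r.allele,
            peak_score=float(r.peak_score),
        )
        for r in df.itertuples(index=False)
    ]


def intervals_to_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write chrom/start/end (+ name/score if present) intervals as BED.

    Input coordinates are 1-based inclusive; BED is 0-based half-open, so
    start - 1 / end.
    """
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "locus_id", getattr(row, "name", "."))
            score = getattr(row, "peak_score", 0)
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\t{score}\n")


def bed_to_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED file back to 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]) + 1,
                    "end": int(fields[2]),
                    "name": fields[3] if len(fields) > 3 else ".",
                }
            )
    return pd.DataFrame(rows)


def write_vcf(counts: AlleleCountMatrix, genotypes: GenotypeMatrix | None, path: str | Path) -> None:
    """Write counts (AD) and optional calls (GT) as a minimal uncompressed VCF."""
    mm = counts.marker_map
    header = pysam.VariantHeader()
    for name, length in mm.chromosomes:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype (haploid parental origin)")
    header.formats.add("AD", "R", "Integer", "Read depth per parental allele")
    samples = [f"seg{i:04d}" for i in range(counts.n_segregants)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        table = mm.table
        for j in range(mm.n_markers):
            rec = vcf.new_record(
                contig=str(table["chrom"].iloc[j]),
                start=int(table["pos"].iloc[j]) - 1,
                stop=int(table["pos"].iloc[j]),
                alleles=(str(table["allele_p1"].iloc[j]), str(table["allele_p2"].iloc[j])),
                id=str(table["marker_id"].iloc[j]),
            )
            for i, s in enumerate(samples):
                rec.samples[s]["AD"] = (int(counts.n_p1[i, j]), int(counts.n_p2[i, j]))
                if genotypes is not None:
                    call = int(genotypes.calls[i, j])
                    rec.samples[s]["GT"] = (None,) if call == MISSING else (call,)
            vcf.write(rec)


def read_vcf_allele_counts(path: str | Path, marker_map: MarkerMap) -> AlleleCountMatrix:
    """Read AD fields from a VCF into an AlleleCountMatrix on ``marker_map``."""
    m_index = {m: i for i, m in enumerate(marker_map.marker_ids)}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        n_p1 = np.zeros((len(samples), marker_map.n_markers), dtype=np.int64)
        n_p2 = np.zeros_like(n_p1)
        for rec in vcf:
            j = m_index.get(rec.id)
            if j is None:
                raise ValueError(f"VCF record {rec.id} absent from the marker map")
            for i, s in enumerate(samples):
                ad = rec.samples[s].get("AD")
                if ad is not None:
                    n_p1[i, j] = ad[0] or 0
                    n_p2[i, j] = ad[1] or 0
    return AlleleCountMatrix(marker_map=marker_map, n_p1=n_p1, n_p2=n_p2)
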