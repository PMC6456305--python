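"""End-to-end pipeline: simulate -> genotype -> map -> interactions -> catalog.

A run is fully specified by a YAML/dict config (seeds included) and is
deterministic: the same config produces byte-identical outputs.  Trait-model
loci are specified as ``"chrom:pos"`` strings resolved to the nearest marker
once the marker map is built.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .markers import MarkerMap, build_marker_map
from .simulate import (
    CLASSES,
    DEFAULT_RECOMB_RATE,
    TraitModel,
    TraitRule,
    assign_phenotypes,
    make_backcross,
    make_rough_parent,
    select_rough,
    simulate_read_counts,
)
from .hmm import GenotypeMatrix, HmmParams, call_genotypes, from_truth
from .mapping import LocusCall, call_loci, segregating_mask
from .interactions import (
    AdditivityResult,
    additivity_analysis,
    two_locus_scan,
)
from .catalog import CatalogEntry, catalog_to_frame, consolidate
from . import io as cio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``data/demo_config.yaml``)."""

    seed: int
    marker_map: dict[str, int]
    gps: list[dict[str, Any]]
    backcrosses: list[str]
    n_progeny: int = 2000
    max_selected_per_class: int = 150
    min_selected: int = 20
    recomb_rate: float = DEFAULT_RECOMB_RATE
    coverage: dict[str, float] = field(default_factory=lambda: {"mean": 2.5, "error_rate": 0.002})
    hmm: dict[str, float] = field(default_factory=dict)
    mapping: dict[str, float] = field(default_factory=lambda: {"alpha": 0.01})
    interactions: dict[str, float] = field(
        default_factory=lambda: {"fdr": 1e-4, "end_exclusion": 30000, "mc_reps": 0}
    )
    genotyping: str = "hmm"  # "hmm" | "true"
    write_counts: bool = False
    write_posteriors: bool = False

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.genotyping not in ("hmm", "true"):
            raise ValueError("genotyping must be 'hmm' or 'true'")
        for bc in cfg.backcrosses:
            if bc not in ("BY", "3S"):
                raise ValueError("backcrosses must be 'BY' and/or '3S'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _resolve_model(spec: dict[str, Any], marker_map: MarkerMap) -> TraitModel:
    """Build a TraitModel from a config entry, resolving chrom:pos locus selectors."""

    def marker(sel: str) -> str:
        chrom, pos = str(sel).split(":")
        return marker_map.nearest_marker(chrom, int(pos))

    mode = spec["mode"]
    if mode == "rule_based":
        rules = tuple(
            TraitRule(
                required={marker(k): v for k, v in r["required"].items()},
                max_temperature=int(r["max_temperature"]),
            )
            for r in spec["rules"]
        )
        return TraitModel(perturbation_id=spec["id"], mode=mode, rules=rules)
    effects = {
        marker(k): (v["allele"], float(v["factor"])) for k, v in spec["effects"].items()
    }
    return TraitModel(
        perturbation_id=spec["id"],
        mode=mode,
        effects=effects,
        baseline=float(spec["baseline"]),
    )


@dataclass
class PopulationResult:
    """Mapping and interaction results for one (GP, backcross, class)."""

    gp: str
    backcross: str
    tclass: str
    n_selected: int
    genotypes: GenotypeMatrix
    locus_calls: list[LocusCall]
    scan: pd.DataFrame
    pair_tests: pd.DataFrame | None = None
    combinations: pd.DataFrame | None = None
    additivity: AdditivityResult | None = None


@dataclass
class RunResult:
    marker_map: MarkerMap
    models: dict[str, TraitModel]
    populations: list[PopulationResult]
    catalog: list[CatalogEntry]

    @property
    def locus_calls(self) -> list[LocusCall]:
        return [c for p in self.populations for c in p.locus_calls]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline for every (GP, backcross, temperature class).

    Selected segregants of each temperature-sensitivity class are sequenced
    (simulated read counts), genotyped (HMM posterior decoding by default),
    mapped (binomial scan, Bonferroni, drop-2 intervals), and — on the
    21 C-only class — tested for two-locus heterogeneity and multi-locus
    additivity.  All locus calls are consolidated into the catalog.
    """
    root = np.random.SeedSequence(config.seed)
    try:
        mm = build_marker_map(
            n_chromosomes=int(config.marker_map["n_chromosomes"]),
            chromosome_length=int(config.marker_map["chromosome_length"]),
            n_markers=int(config.marker_map["n_markers"]),
            seed=np.random.default_rng(root.spawn(1)[0]),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[marker_map] {exc}") from exc

    hmm_params = HmmParams(
        error_rate=float(config.hmm.get("error_rate", config.coverage["error_rate"])),
        recomb_rate=float(config.hmm.get("recomb_rate", config.recomb_rate)),
        min_posterior=float(config.hmm.get("min_posterior", 0.9)),
    )
    alpha = float(config.mapping.get("alpha", 0.01))
    fdr = float(config.interactions.get("fdr", 1e-4))
    end_excl = int(config.interactions.get("end_exclusion", 30000))
    mc_reps = int(config.interactions.get("mc_reps", 0))

    models: dict[str, TraitModel] = {}
    results: list[PopulationResult] = []
    for gi, gp_spec in enumerate(config.gps):
        gp_ss = np.random.SeedSequence(config.seed, spawn_key=(1, gi))
        try:
            model = _resolve_model(gp_spec, mm)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"[trait_model:{gp_spec.get('id')}] {exc}") from exc
        models[model.perturbation_id] = model
        rough_parent = make_rough_parent(mm, model, np.random.default_rng(gp_ss.spawn(1)[0]))
        for bi, backcross in enumerate(config.backcrosses):
            bc_ss = np.random.SeedSequence(config.seed, spawn_key=(2, gi, bi))
            streams = [np.random.default_rng(s) for s in bc_ss.spawn(3 + len(CLASSES))]
            try:
                pop = make_backcross(
                    rough_parent, backcross, config.n_progeny, mm, config.recomb_rate, streams[0]
                )
                pop = assign_phenotypes(pop, model, streams[1])
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"[simulate:{model.perturbation_id}x{backcross}] {exc}") from exc
            mask = segregating_mask(rough_parent, pop.recurrent)
            for ci, tclass in enumerate(CLASSES):
                selected = select_rough(pop, tclass)
                if selected.n_segregants < config.min_selected:
                    continue
                if selected.n_segregants > config.max_selected_per_class:
                    selected = selected.subset(np.arange(config.max_selected_per_class))
                label = f"{model.perturbation_id}x{backcross}@{tclass}"
                try:
                    counts = simulate_read_counts(
                        selected,
                        float(config.coverage["mean"]),
                        float(config.coverage["error_rate"]),
                        streams[3 + ci],
                    )
                    if config.genotyping == "hmm":
                        geno = call_genotypes(counts, hmm_params)
                    else:
                        geno = from_truth(mm, selected.genotypes)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError(f"[genotype:{label}] {exc}") from exc
                try:
                    calls, scan = call_loci(
                        geno, mask, model.perturbation_id, backcross, tclass, alpha
                    )
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError(f"[map:{label}] {exc}") from exc
                res = PopulationResult(
                    gp=model.perturbation_id,
                    backcross=backcross,
                    tclass=tclass,
                    n_selected=selected.n_segregants,
                    genotypes=geno,
                    locus_calls=calls,
                    scan=scan,
                )
                if tclass == "21":
                    try:
                        res.pair_tests = two_locus_scan(
                            geno, fdr=fdr, end_exclusion=end_excl, mask=mask
                        )
                        # one peak marker per distinct locus: overlapping calls
                        # (split significant runs) collapse to their strongest peak
                        peaks = [
                            max(e.members, key=lambda c: c.peak_score).peak_id
                            for e in consolidate(calls)
                        ]
                        if peaks:
                            res.combinations = infer_combinations_safe(geno, peaks)
                        if len(peaks) >= 2:
                            res.additivity = additivity_analysis(
                                geno, peaks, mc_reps=mc_reps, seed=streams[2]
                            )
                    except Exception as exc:  # noqa: BLE001
                        raise PipelineError(f"[interactions:{label}] {exc}") from exc
                results.append(res)

    try:
        catalog = consolidate([c for r in results for c in r.locus_calls])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[catalog] {exc}") from exc
    run = RunResult(marker_map=mm, models=models, populations=results, catalog=catalog)
    if outdir is not None:
        _write_outputs(run, config, Path(outdir))
    return run


def infer_combinations_safe(geno: GenotypeMatrix, peaks: list[str]) -> pd.DataFrame:
    from .interactions import infer_allele_combinations

    return infer_allele_combinations(geno, peaks)


def _write_outputs(run: RunResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_marker_map(run.marker_map, outdir / "marker_map.tsv")
    cio.write_locus_calls(run.locus_calls, outdir / "locus_calls.tsv")
    cat = catalog_to_frame(run.catalog)
    cat.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    if len(cat):
        cio.intervals_to_bed(cat.assign(peak_score=0), outdir / "catalog.bed")
    else:
        (outdir / "catalog.bed").write_text("")
    for res in run.populations:
        pdir = outdir / "populations" / f"{res.gp}_{res.backcross}_c{res.tclass}"
        pdir.mkdir(parents=True, exist_ok=True)
        cio.write_genotypes(res.genotypes, pdir / "genotypes.tsv")
        res.scan.to_csv(pdir / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        if res.pair_tests is not None:
            res.pair_tests.to_csv(
                pdir / "pair_tests.tsv", sep="\t", index=False, float_format="%.6g"
            )
        if res.combinations is not None:
            res.combinations.to_csv(
                pdir / "allele_combinations.tsv", sep="\t", index=False, float_format="%.6g"
            )
        if res.additivity is not None:
            with open(pdir / "additivity.json", "w") as fh:
                json.dump(
                    {k: _jsonable(v) for k, v in vars(res.additivity).items()},
                    fh,
                    indent=2,
                    sort_keys=True,
                )
                fh.write("\n")
    manifest = {
        "cryptomap_version": __version__,
        "config": {k: _jsonable(v) for k, v in vars(config).items()},
        "n_locus_calls": len(run.locus_calls),
        "n_catalog_loci": len(run.catalog),
        "populations": [
            {"gp": r.gp, "backcross": r.backcross, "tclass": r.tclass, "n_selected": r.n_selected}
            for r in run.populations
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, float) and np.isnan(v):
        return None
    return v
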