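"""End-to-end orchestration: reads -> allele calls -> genotypes -> report.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical outputs (log lines go to stderr, never into reports).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .calling import AlignmentParams, call_gene
from .io import (
    parse_target_manifest,
    read_germination_table,
    read_sequences,
    write_genotype_table,
)
from .model import (
    Cas12muxError,
    GeneZygosity,
    GerminationRecord,
    InputError,
    PlantGenotype,
    TargetSite,
    ZygosityThresholds,
)
from .report import efficiency_summary, tally_population
from .zygosity import call_multiplex, classify_germination, make_gene_zygosity

__all__ = ["PipelineConfig", "StageError", "genotype_population", "run_pipeline"]

log = logging.getLogger("cas12mux")


class StageError(Cas12muxError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    manifest: str
    amplicons: str
    reads_dir: str
    germination: Optional[str] = None
    outdir: str = "cas12mux_out"
    label: str = "population"
    thresholds: ZygosityThresholds = field(default_factory=ZygosityThresholds)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    subs_are_mutations: bool = False
    presume_type3_mutant: bool = True
    pooled_type2_all_mutant: bool = False

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = ZygosityThresholds(**raw["thresholds"])
        if "alignment" in raw:
            raw["alignment"] = AlignmentParams(**raw["alignment"])
        return cls(**raw)


def _discover_pools(reads_dir: Path, genes: Sequence[str]) -> Dict[Tuple[str, str], Path]:
    """Find ``<plant>__<gene>.fastq[.gz]`` read pools."""
    pools: Dict[Tuple[str, str], Path] = {}
    gene_set = set(genes)
    for path in sorted(reads_dir.iterdir()):
        name = path.name
        for suffix in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
            if name.endswith(suffix):
                stem = name[: -len(suffix)]
                break
        else:
            continue
        if "__" not in stem:
            continue
        plant, gene = stem.rsplit("__", 1)
        if gene in gene_set:
            pools[(plant, gene)] = path
    return pools


def genotype_population(
    sites: Sequence[TargetSite],
    pools: Mapping[Tuple[str, str], Sequence[str]],
    thresholds: ZygosityThresholds = ZygosityThresholds(),
    alignment: AlignmentParams = AlignmentParams(),
    subs_are_mutations: bool = False,
) -> List[PlantGenotype]:
    """Call every plant x gene pool and aggregate to plant genotypes."""
    site_by_gene = {s.gene_id: s for s in sites}
    plants: Dict[str, Dict[str, Optional[GeneZygosity]]] = {}
    for (plant, gene), reads in pools.items():
        site = site_by_gene.get(gene)
        if site is None:
            raise InputError(f"read pool references unknown gene {gene!r}")
        collapsed = call_gene(list(reads), site, alignment, thresholds, subs_are_mutations)
        call = None if collapsed is None else make_gene_zygosity(gene, collapsed, thresholds)
        plants.setdefault(plant, {})[gene] = call
    targeted = [s.gene_id for s in sites]
    out = []
    for plant in sorted(plants):
        calls = plants[plant]
        for gene in targeted:  # genes with no pool at all -> no-call
            calls.setdefault(gene, None)
        out.append(call_multiplex(plant, calls, targeted))
    return out


def run_pipeline(config: Union[PipelineConfig, str, Path]) -> Dict[str, object]:
    """call -> genotype -> tally -> report; writes TSV + JSON artifacts.

    Returns a summary dict (also written to ``report.json``).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    log.info("thresholds in effect: %s", config.thresholds)
    log.info("alignment params: %s", config.alignment)

    try:
        sites = parse_target_manifest(config.manifest, config.amplicons)
    except Exception as exc:
        raise StageError("manifest", str(exc)) from exc

    reads_dir = Path(config.reads_dir)
    if not reads_dir.is_dir():
        raise StageError("reads", f"reads directory not found: {reads_dir}")
    pool_paths = _discover_pools(reads_dir, [s.gene_id for s in sites])
    if not pool_paths:
        raise StageError("reads", f"no <plant>__<gene>.fastq pools under {reads_dir}")

    try:
        pools = {
            key: [seq for _, seq, _ in read_sequences(path)]
            for key, path in pool_paths.items()
        }
        plants = genotype_population(
            sites, pools, config.thresholds, config.alignment, config.subs_are_mutations)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("call", str(exc)) from exc

    germination: List[GerminationRecord] = []
    if config.germination:
        try:
            germination = read_germination_table(config.germination)
            germ_by_id = {g.plant_id: g for g in germination}
            for p in plants:
                rec = germ_by_id.get(p.plant_id)
                if rec is not None:
                    p.germination_type = classify_germination(rec)
        except Exception as exc:
            raise StageError("germination", str(exc)) from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_table(plants, outdir / "genotypes.tsv")

    summary: Dict[str, object] = {
        "label": config.label,
        "n_plants": len(plants),
        "n_genes": len(sites),
        "n_sextuple_no_wt": sum(p.is_sextuple_no_wt for p in plants),
        "n_full_lof": sum(p.is_full_lof for p in plants),
        "n_unresolved": sum(p.unresolved for p in plants),
        "thresholds": vars(config.thresholds),
        "caveat": (
            "predicted_type3 is a heuristic genotype-to-phenotype rule; "
            "rare sextuple mutants without in-frame alleles have been "
            "observed to germinate, possibly through late-stage editing."
        ),
    }
    if germination:
        try:
            tally = tally_population(
                plants, germination,
                presume_type3_mutant=config.presume_type3_mutant,
                pooled_type2_all_mutant=config.pooled_type2_all_mutant,
                label=config.label)
            summary["efficiency"] = efficiency_summary(tally).to_dict()
        except Exception as exc:
            raise StageError("tally", str(exc)) from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
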