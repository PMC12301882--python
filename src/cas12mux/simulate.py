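"""Synthetic T1-like populations with known per-gene editing outcomes.

The generator emulates the inputs of an amplicon deep-sequencing genotyping
experiment: for every plant x gene it draws a zygosity archetype, composes an
allele mixture, and emits amplicon reads with sequencing noise.

Archetypes (before noise):

* Ho — one mutant allele at fraction 1.0
* Bi — two distinct mutant alleles at 0.5 / 0.5
* He — one mutant allele and WT at 0.5 / 0.5
* Chi — ``chimera_allele_count`` mutant alleles plus WT from a flat random
  simplex, every mutant fraction below the He threshold
* WT — reference only

Reads are allocated to alleles in exact largest-remainder proportion, so the
realized composition (which is what the truth table stores) is analytically
known and sampling jitter enters only through the finite depth. The chimeric
sampler additionally keeps every mutant fraction at or above the allele
floor and the total mutant fraction below the Ho/Bi threshold, so each truth
label is consistent with the calling rules it will be scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .calling import apply_events, _left_normalize
from .io import write_fastq, write_germination_table, write_target_manifest
from .model import (
    Allele,
    ConfigError,
    GerminationRecord,
    MutationEvent,
    MutationKind,
    TargetSite,
    WT_ALLELE,
    Zygosity,
    ZygosityThresholds,
    revcomp,
)

__all__ = [
    "IndelModel",
    "SimulationConfig",
    "TruthRecord",
    "Population",
    "synthetic_manifest",
    "simulate_population",
    "simulate_germination",
    "write_truth_table",
    "read_truth_table",
    "truth_is_sextuple",
    "truth_is_full_lof",
]

DEFAULT_CLASS_PROBS: Mapping[str, float] = {
    "WT": 0.02, "Ho": 0.55, "Bi": 0.35, "He": 0.04, "Chi": 0.04,
}

_CLASS_ORDER = ["WT", "Ho", "Bi", "He", "Chi"]


@dataclass(frozen=True)
class IndelModel:
    """Indel size spectrum: geometric-decaying deletions of 1-30 nt (the bulk
    of Cas12a repair outcomes) and insertions of 1-10 nt, positions uniform
    within the cleavage window. ``in_frame_mass``, when set, forces that
    probability mass onto sizes that are multiples of 3."""

    p_deletion: float = 0.7
    del_max: int = 30
    ins_max: int = 10
    geom_p: float = 0.2
    in_frame_mass: Optional[float] = None

    def draw(self, rng: np.random.Generator, site: TargetSite) -> MutationEvent:
        ws, we = site.cleavage_window
        is_del = rng.random() < self.p_deletion
        cap = self.del_max if is_del else self.ins_max
        cap = min(cap, we - ws - 1) if is_del else cap
        size = int(min(rng.geometric(self.geom_p), cap))
        if self.in_frame_mass is not None and rng.random() < self.in_frame_mass:
            size = max(3, 3 * round(size / 3))
            size = min(size, cap - (cap % 3) if cap >= 3 else size)
        if is_del:
            start = int(rng.integers(ws, we - size + 1))
            return MutationEvent(position=start, kind=MutationKind.DELETION, length=size)
        pos = int(rng.integers(ws + 1, we))
        seq = "".join(rng.choice(list("ACGT"), size=size))
        return MutationEvent(position=pos, kind=MutationKind.INSERTION,
                             length=size, seq=seq)


@dataclass
class SimulationConfig:
    n_plants: int = 200
    genes: Sequence[TargetSite] = ()
    class_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    indel_model: IndelModel = field(default_factory=IndelModel)
    substitution_error_rate: float = 0.001
    depth: int = 100
    chimera_allele_count: int = 4
    seed: int = 0
    thresholds: ZygosityThresholds = field(default_factory=ZygosityThresholds)

    def __post_init__(self):
        if self.n_plants < 1 or self.depth < 1:
            raise ConfigError("n_plants and depth must be >= 1")
        unknown = set(self.class_probs) - set(_CLASS_ORDER)
        if unknown:
            raise ConfigError(f"unknown zygosity classes in class_probs: {unknown}")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("class_probs must sum to 1")
        if not self.genes:
            object.__setattr__(self, "genes", synthetic_manifest())


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one plant x gene: the labeled class and the realized
    allele composition (fractions sum to 1)."""

    plant_id: str
    gene_id: str
    true_class: Zygosity
    alleles: Tuple[Tuple[Allele, float], ...]

    def __post_init__(self):
        if abs(sum(f for _, f in self.alleles) - 1.0) > 1e-9:
            raise ConfigError("truth allele fractions must sum to 1")


@dataclass
class Population:
    config: SimulationConfig
    reads: Dict[Tuple[str, str], List[str]]
    truth: List[TruthRecord]

    @property
    def plant_ids(self) -> List[str]:
        seen: List[str] = []
        for rec in self.truth:
            if rec.plant_id not in seen:
                seen.append(rec.plant_id)
        return seen


# --------------------------------------------------------------------------
# reference fixture

_PP2C_GENES = ["HAI1", "HAI2", "HAI3", "AHG1", "AHG3", "HAB2"]


def synthetic_manifest(n_genes: int = 6, amplicon_len: int = 220,
                       spacer_len: int = 23, pam_offset: int = 88,
                       seed: int = 91) -> Tuple[TargetSite, ...]:
    """Deterministic synthetic six-gene reference set.

    Gene names follow the six targeted clade A PP2C genes; the amplicon
    sequences themselves are synthetic (random with a planted TTTC PAM +
    spacer), standing in for unavailable primer/amplicon tables. Two genes
    are placed on the minus strand to exercise strand handling.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for k in range(n_genes):
        gene = _PP2C_GENES[k] if k < len(_PP2C_GENES) else f"GENE{k + 1}"
        seq = list(rng.choice(list("ACGT"), size=amplicon_len))
        pam = "TTTC"
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
        proto = pam + spacer
        seq[pam_offset:pam_offset + len(proto)] = list(proto)
        plus_seq = "".join(seq)
        strand = "-" if k % 3 == 2 else "+"
        if strand == "+":
            amp = plus_seq
            interval = (pam_offset + 4, pam_offset + 4 + spacer_len)
        else:
            amp = revcomp(plus_seq)  # protospacer now on the minus strand
            interval = (len(amp) - (pam_offset + 4 + spacer_len),
                        len(amp) - (pam_offset + 4))
        sites.append(
            TargetSite(
                gene_id=gene, amplicon_id=f"{gene}_amplicon", amplicon_seq=amp,
                pam_seq=pam, spacer_seq=spacer, strand=strand,
                spacer_interval=interval,
            )
        )
    return tuple(sites)


# --------------------------------------------------------------------------
# population simulation


def _largest_remainder(fracs: Sequence[float], depth: int) -> List[int]:
    """Integer read counts proportional to fractions, summing to depth."""
    raw = [f * depth for f in fracs]
    counts = [int(x) for x in raw]
    short = depth - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _draw_allele(rng: np.random.Generator, site: TargetSite,
                 model: IndelModel, taken: set) -> Allele:
    """Draw a mutant allele, stored in the same leftmost-normalized form the
    caller reports, and kept only if the normalized event still touches the
    cleavage window (otherwise it would be invisible to calling)."""
    ws, we = site.cleavage_window
    for _ in range(200):
        ev = _left_normalize([model.draw(rng, site)], site.amplicon_seq, 0)[0]
        if ev.kind is MutationKind.INSERTION:
            if ev.position < ws:
                continue
        elif ev.end() <= ws:
            continue
        allele = Allele((ev,))
        if allele.key() not in taken:
            return allele
    raise ConfigError("could not draw a distinct mutant allele")


def _compose(rng: np.random.Generator, cls: str, site: TargetSite,
             cfg: SimulationConfig) -> List[Tuple[Allele, int]]:
    """Allele mixture for one plant x gene, as (allele, read_count)."""
    depth, model = cfg.depth, cfg.indel_model
    taken: set = set()
    if cls == "WT":
        return [(WT_ALLELE, depth)]
    if cls == "Ho":
        return [(_draw_allele(rng, site, model, taken), depth)]
    if cls == "Bi":
        a = _draw_allele(rng, site, model, taken)
        taken.add(a.key())
        b = _draw_allele(rng, site, model, taken)
        ca, cb = _largest_remainder([0.5, 0.5], depth)
        return [(a, ca), (b, cb)]
    if cls == "He":
        a = _draw_allele(rng, site, model, taken)
        ca, cw = _largest_remainder([0.5, 0.5], depth)
        return [(a, ca), (WT_ALLELE, cw)]
    # Chi: flat simplex over k mutant alleles + WT, constrained so the
    # realized composition is classified Chi under the calling rules
    k = cfg.chimera_allele_count
    th = cfg.thresholds
    for _ in range(2000):
        fracs = rng.dirichlet(np.ones(k + 1))
        counts = _largest_remainder(list(fracs), depth)
        mut_counts, wt_count = counts[:k], counts[k]
        realized = [c / depth for c in mut_counts]
        if any(f < th.allele_floor_fraction for f in realized):
            continue
        if any(f >= th.he_min for f in realized):
            continue
        if sum(realized) >= th.ho_bi_min:
            continue
        alleles = []
        for c in mut_counts:
            a = _draw_allele(rng, site, model, taken)
            taken.add(a.key())
            alleles.append((a, c))
        alleles.append((WT_ALLELE, wt_count))
        return alleles
    raise ConfigError("chimeric composition sampling did not converge")


def _mutate_read(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    bases = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = alts[int(rng.integers(3))]
    return "".join(bases)


def simulate_population(config: SimulationConfig,
                        outdir: Union[str, Path, None] = None) -> Population:
    """Draw a population and its read pools; fully reproducible from the seed.

    When ``outdir`` is given, writes one FASTQ per plant x gene
    (``<plant>__<gene>.fastq``), the truth TSV, the reference FASTA +
    manifest, and the resolved config as JSON.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.array([config.class_probs.get(c, 0.0) for c in _CLASS_ORDER])
    reads: Dict[Tuple[str, str], List[str]] = {}
    truth: List[TruthRecord] = []
    width = max(4, len(str(config.n_plants)))
    for i in range(config.n_plants):
        pid = f"plant-{i + 1:0{width}d}"
        for site in config.genes:
            cls = _CLASS_ORDER[int(rng.choice(len(_CLASS_ORDER), p=probs))]
            mixture = _compose(rng, cls, site, config)
            pool: List[str] = []
            for allele, count in mixture:
                base = apply_events(site.amplicon_seq, allele.events)
                for _ in range(count):
                    pool.append(_mutate_read(rng, base, config.substitution_error_rate))
            rng.shuffle(pool)
            reads[(pid, site.gene_id)] = pool
            truth.append(
                TruthRecord(
                    plant_id=pid, gene_id=site.gene_id, true_class=Zygosity(cls),
                    alleles=tuple((a, c / config.depth) for a, c in mixture),
                )
            )
    pop = Population(config=config, reads=reads, truth=truth)
    if outdir is not None:
        _write_population(pop, Path(outdir))
    return pop


def _write_population(pop: Population, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for (pid, gene), pool in pop.reads.items():
        write_fastq(outdir / f"{pid}__{gene}.fastq",
                    ((f"{pid}:{gene}:{i}", seq) for i, seq in enumerate(pool)))
    write_truth_table(pop.truth, outdir / "truth.tsv")
    with open(outdir / "reference.fasta", "w") as fh:
        for site in pop.config.genes:
            fh.write(f">{site.amplicon_id}\n{site.amplicon_seq}\n")
    write_target_manifest(list(pop.config.genes), outdir / "targets.tsv")
    cfg = asdict(pop.config)
    cfg["genes"] = [s.gene_id for s in pop.config.genes]
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)


def write_truth_table(truth: Sequence[TruthRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("plant_id\tgene_id\ttrue_class\talleles\n")
        for rec in truth:
            alleles = "|".join(f"{a.key()}@{f:.6g}" for a, f in rec.alleles)
            fh.write(f"{rec.plant_id}\t{rec.gene_id}\t{rec.true_class.value}\t{alleles}\n")


def read_truth_table(path: Union[str, Path]) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, gene, cls, alleles = line.rstrip("\n").split("\t")
            pairs = []
            for tok in alleles.split("|"):
                key, frac = tok.rsplit("@", 1)
                pairs.append((Allele.from_key(key), float(frac)))
            out.append(TruthRecord(pid, gene, Zygosity(cls), tuple(pairs)))
    return out


# --------------------------------------------------------------------------
# germination simulation


def truth_is_sextuple(records: Sequence[TruthRecord]) -> bool:
    """All targeted genes Ho or Bi in the truth labels."""
    return all(r.true_class in (Zygosity.HO, Zygosity.BI) for r in records)


def truth_is_full_lof(records: Sequence[TruthRecord]) -> bool:
    """Sextuple with no in-frame (3x) allele at any gene."""
    return truth_is_sextuple(records) and not any(
        a.is_in_frame_3x for r in records for a, _ in r.alleles)


def simulate_germination(
    truth: Sequence[TruthRecord],
    in_frame_rescue_prob: float = 1.0,
    seed: int = 0,
    delay_days: Sequence[int] = (14, 21, 28),
    stunted_prob: float = 0.5,
    observation_horizon: int = 70,
) -> List[GerminationRecord]:
    """Genotype -> germination phenotype, applied deterministically per rule.

    Full-LOF sextuple plants never germinate within the horizon. Sextuple
    plants rescued by an in-frame 3x allele (probability
    ``in_frame_rescue_prob``) germinate late — stunted seedlings (long
    roots, weak shoot) take 21 d or more — otherwise they too fail to
    germinate. All other plants germinate normally at day 7.
    """
    rng = np.random.default_rng(seed)
    by_plant: Dict[str, List[TruthRecord]] = {}
    order: List[str] = []
    for rec in truth:
        if rec.plant_id not in by_plant:
            order.append(rec.plant_id)
        by_plant.setdefault(rec.plant_id, []).append(rec)
    out: List[GerminationRecord] = []
    for pid in order:
        recs = by_plant[pid]
        if truth_is_full_lof(recs):
            out.append(GerminationRecord(pid, germinated=False,
                                         observation_horizon=observation_horizon))
        elif truth_is_sextuple(recs):
            if rng.random() < in_frame_rescue_prob:
                stunted = bool(rng.random() < stunted_prob)
                days = [d for d in delay_days if d >= 21] if stunted else list(delay_days)
                day = int(rng.choice(days))
                out.append(GerminationRecord(pid, germinated=True,
                                             day_of_germination=day, stunted=stunted,
                                             observation_horizon=observation_horizon))
            else:
                out.append(GerminationRecord(pid, germinated=False,
                                             observation_horizon=observation_horizon))
        else:
            out.append(GerminationRecord(pid, germinated=True, day_of_germination=7,
                                         observation_horizon=observation_horizon))
    return out
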