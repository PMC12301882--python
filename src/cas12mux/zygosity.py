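"""Zygosity classification, multiplex aggregation and heritability checks.

The per-gene rule set, driven by HTS read fractions:

* Ho — a single mutant allele holds >= 95% of retained reads.
* Bi — two or more distinct mutant alleles jointly hold >= 95%.
* He — neither of the above, but the top mutant type holds >= 45%.
* Chi — a mutant type exists but the top one holds < 45%.
* WT — no mutant allele retained.

Wild-type reads are never a "type of mutation": they enter denominators but
do not count toward the 45% dominant-type rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .calling import CollapseResult
from .model import (
    Allele,
    AlleleCall,
    GeneZygosity,
    GerminationRecord,
    GerminationType,
    InputError,
    PlantGenotype,
    Zygosity,
    ZygosityThresholds,
)

__all__ = [
    "classify_zygosity",
    "make_gene_zygosity",
    "FrameAnnotation",
    "annotate_frame",
    "call_multiplex",
    "classify_germination",
    "HeritabilityVerdict",
    "compare_generations",
]

_EPS = 1e-9


def classify_zygosity(
    allele_calls: Sequence[AlleleCall],
    wt_fraction: float,
    thresholds: ZygosityThresholds = ZygosityThresholds(),
) -> Zygosity:
    """Apply the threshold rules to mutant allele fractions plus WT.

    ``allele_calls`` must contain mutant alleles only; fractions together
    with ``wt_fraction`` must sum to 1 (tolerance 1e-6).
    """
    for c in allele_calls:
        if not c.allele.is_mutant:
            raise InputError("allele_calls must contain mutant alleles only")
    total_mut = sum(c.fraction for c in allele_calls)
    if abs(total_mut + wt_fraction - 1.0) > 1e-6:
        raise InputError(
            f"fractions sum to {total_mut + wt_fraction:.8f}, expected 1")
    if not allele_calls:
        return Zygosity.WT
    top = max(c.fraction for c in allele_calls)
    if top >= thresholds.ho_bi_min - _EPS:
        return Zygosity.HO
    if len(allele_calls) >= 2 and total_mut >= thresholds.ho_bi_min - _EPS:
        return Zygosity.BI
    if top >= thresholds.he_min - _EPS:
        return Zygosity.HE
    return Zygosity.CHI


def make_gene_zygosity(gene_id: str, collapsed: CollapseResult,
                       thresholds: ZygosityThresholds = ZygosityThresholds()) -> GeneZygosity:
    """Package a collapse result as a classified per-gene call."""
    cls = classify_zygosity(collapsed.allele_calls, collapsed.wt_fraction, thresholds)
    return GeneZygosity(
        gene_id=gene_id,
        zygosity_class=cls,
        allele_calls=collapsed.allele_calls,
        wt_fraction=collapsed.wt_fraction,
    )


class FrameAnnotation(str, Enum):
    WT = "wt"
    FRAMESHIFT = "frameshift-LOF-candidate"
    IN_FRAME_3X = "in-frame-3x-candidate"


def annotate_frame(allele: Allele) -> FrameAnnotation:
    """Frameshift vs in-frame (3x) annotation from the net indel length.

    An allele whose insertions minus deletions are a multiple of 3 preserves
    the reading frame and may retain partial protein function.
    """
    if not allele.is_mutant:
        return FrameAnnotation.WT
    if allele.is_in_frame_3x:
        return FrameAnnotation.IN_FRAME_3X
    return FrameAnnotation.FRAMESHIFT


def call_multiplex(
    plant_id: str,
    gene_calls: Mapping[str, Optional[GeneZygosity]],
    targeted_genes: Sequence[str],
) -> PlantGenotype:
    """Aggregate per-gene calls into a plant-level multiplex genotype.

    A plant is a sextuple (no-WT) mutant when every targeted gene is Ho or
    Bi; it is full loss-of-function when additionally no retained allele is
    an in-frame 3x indel — such plants are predicted never to germinate.
    A no-call at any targeted gene marks the plant unresolved and excludes
    it from sextuple counts.
    """
    missing = [g for g in targeted_genes if g not in gene_calls]
    if missing:
        raise InputError(f"{plant_id}: targeted genes absent from calls: {missing}")
    calls = {g: gene_calls[g] for g in targeted_genes}
    unresolved = any(c is None for c in calls.values())
    if unresolved:
        sextuple = full_lof = False
    else:
        sextuple = all(
            c.zygosity_class in (Zygosity.HO, Zygosity.BI) for c in calls.values())
        full_lof = sextuple and not any(c.has_in_frame_3x for c in calls.values())
    return PlantGenotype(
        plant_id=plant_id,
        gene_calls=calls,
        is_sextuple_no_wt=sextuple,
        is_full_lof=full_lof,
        predicted_type3=full_lof,
        unresolved=unresolved,
    )


def classify_germination(record: GerminationRecord) -> GerminationType:
    """Map an observation to the Type-0..Type-3 germination taxonomy.

    Type-3: never germinated within the observation horizon. Type-2:
    germinated but stunted (long roots, weak shoot). Type-0: normal
    germination by day 7. Type-1: delayed but otherwise normal.
    """
    if not record.germinated:
        return GerminationType.TYPE3
    if record.day_of_germination is None:
        raise InputError(f"{record.plant_id}: germinated but no day recorded")
    if record.stunted:
        return GerminationType.TYPE2
    if record.day_of_germination <= 7:
        return GerminationType.TYPE0
    return GerminationType.TYPE1


# --------------------------------------------------------------------------
# T1 -> T2 heritability


@dataclass(frozen=True)
class HeritabilityVerdict:
    """Per-gene and overall verdict comparing a T2 plant to its T1 parent."""

    plant_pair: Tuple[str, str]
    per_gene: Mapping[str, str]  # heritable | novel-allele | inconsistent
    overall: bool


def compare_generations(t1: PlantGenotype, t2: PlantGenotype) -> HeritabilityVerdict:
    """Check that T2 alleles are a Mendelian subset of the T1 alleles.

    Per gene: ``heritable`` when the T2 mutant allele set is a nonempty
    subset of T1's (selfing of a biallelic plant may fix either allele) or
    when both generations retain WT; ``novel-allele`` when T2 shows an allele
    absent from T1; ``inconsistent`` when T2 is WT although T1 had no WT
    allele (Ho/Bi), or when either call is missing.
    """
    if set(t1.gene_calls) != set(t2.gene_calls):
        raise InputError(
            f"gene sets differ between {t1.plant_id} and {t2.plant_id}")
    per_gene: Dict[str, str] = {}
    for gene in t1.gene_calls:
        c1, c2 = t1.gene_calls[gene], t2.gene_calls[gene]
        if c1 is None or c2 is None:
            per_gene[gene] = "inconsistent"
            continue
        a1 = {a.key() for a in c1.mutant_alleles}
        a2 = {a.key() for a in c2.mutant_alleles}
        if a2 - a1:
            per_gene[gene] = "novel-allele"
        elif not a2 and c1.zygosity_class in (Zygosity.HO, Zygosity.BI):
            per_gene[gene] = "inconsistent"
        else:
            per_gene[gene] = "heritable"
    return HeritabilityVerdict(
        plant_pair=(t1.plant_id, t2.plant_id),
        per_gene=per_gene,
        overall=all(v == "heritable" for v in per_gene.values()),
    )
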