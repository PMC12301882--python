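"""Population tallies and efficiency reporting.

Percentages are printed at one decimal with half-up rounding, computed on
exact rationals so 45/61 -> 73.8 and 124/138 -> 89.9. Cells with a zero
denominator are reported as not-applicable (None), never as 0%.

Two aggregates are reported per population:

* ``aggregate_germinated`` — confirmed sextuple mutants among germinated
  seedlings (Types 0-2).
* ``aggregate_with_type3`` — the estimated overall efficiency under the
  presumption that never-germinating (Type-3) seeds, and seedlings lost
  before genotyping, are sextuple mutants as well. The presumption rests on
  the observation that in-frame-rescued genotypes are enriched among
  germinated seedlings, so seeds that never germinate are very likely
  full loss-of-function mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .model import (
    GerminationRecord,
    GerminationType,
    InputError,
    PlantGenotype,
    PopulationTally,
)
from .zygosity import classify_germination

__all__ = ["ratio_percent", "tally_population", "EfficiencyReport", "efficiency_summary"]

_GERMINATED = (GerminationType.TYPE0, GerminationType.TYPE1, GerminationType.TYPE2)


def ratio_percent(mutant: int, total: int) -> Optional[float]:
    """100*mutant/total at one decimal, half-up; None for an empty cell."""
    if mutant < 0 or total < 0:
        raise InputError("negative count")
    if total == 0:
        return None
    pct = Decimal(100 * mutant) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class TallyWithLosses(PopulationTally):
    """Tally plus, per type, the count of germinated seedlings that died
    before genotyping (included in totals; presumed mutant only in the
    estimated overall aggregate)."""

    not_recovered: Dict[GerminationType, int] = field(default_factory=dict)


def tally_population(
    plants: Sequence[PlantGenotype],
    germination: Sequence[GerminationRecord],
    presume_type3_mutant: bool = False,
    pooled_type2_all_mutant: bool = False,
    label: str = "population",
) -> TallyWithLosses:
    """Join genotypes to germination records and count mutants per type.

    The germination table is the denominator authority (it can represent
    seeds that never produced a genotypable plant). A germinated plant with
    no genotype is counted as "not recovered": in the total, not a confirmed
    mutant. ``pooled_type2_all_mutant`` applies the pooled-sample inference
    that stunted (Type-2) seedlings genotyped only as a bulk DNA pool are all
    mutants.
    """
    by_id: Dict[str, PlantGenotype] = {}
    for p in plants:
        if p.plant_id in by_id:
            raise InputError(f"duplicate plant id {p.plant_id!r} in genotypes")
        by_id[p.plant_id] = p
    seen = set()
    counts: Dict[GerminationType, Tuple[int, int]] = {
        gt: (0, 0) for gt in GerminationType}
    losses: Dict[GerminationType, int] = {gt: 0 for gt in GerminationType}
    for rec in germination:
        if rec.plant_id in seen:
            raise InputError(f"duplicate plant id {rec.plant_id!r} in germination table")
        seen.add(rec.plant_id)
        gt = classify_germination(rec)
        mut, tot = counts[gt]
        plant = by_id.get(rec.plant_id)
        if gt is GerminationType.TYPE3:
            is_mut = presume_type3_mutant
        elif plant is None:
            is_mut = pooled_type2_all_mutant and gt is GerminationType.TYPE2
            if not is_mut:
                losses[gt] += 1
        else:
            is_mut = plant.is_sextuple_no_wt and not plant.unresolved
        counts[gt] = (mut + (1 if is_mut else 0), tot + 1)
    return TallyWithLosses(label=label, counts=counts, not_recovered=losses)


@dataclass
class EfficiencyReport:
    """Per-type and aggregate mutant percentages for one population."""

    label: str
    per_type: Mapping[GerminationType, Tuple[int, int, Optional[float]]]
    aggregate_germinated: Tuple[int, int, Optional[float]]
    aggregate_with_type3: Tuple[int, int, Optional[float]]

    def to_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "per_type": {
                gt.value: {"mutant": m, "total": t, "percent": pct}
                for gt, (m, t, pct) in self.per_type.items()
            },
            "aggregate_germinated": dict(
                zip(("mutant", "total", "percent"), self.aggregate_germinated)),
            "aggregate_with_type3": dict(
                zip(("mutant", "total", "percent"), self.aggregate_with_type3)),
        }


def efficiency_summary(tally: PopulationTally) -> EfficiencyReport:
    """Compute the per-type and aggregate efficiency percentages.

    The germinated aggregate sums Types 0-2 as counted. The with-Type-3
    estimate presumes every Type-3 seed mutant and additionally counts
    unrecovered germinated seedlings as mutants (they are part of the same
    presumption: lost before genotyping, not shown non-mutant).
    """
    per_type: Dict[GerminationType, Tuple[int, int, Optional[float]]] = {}
    for gt in GerminationType:
        m, t = tally.counts.get(gt, (0, 0))
        per_type[gt] = (m, t, ratio_percent(m, t))
    gm = sum(per_type[gt][0] for gt in _GERMINATED)
    gt_tot = sum(per_type[gt][1] for gt in _GERMINATED)
    losses = getattr(tally, "not_recovered", {})
    lost = sum(losses.get(g, 0) for g in _GERMINATED)
    t3_m, t3_t = tally.counts.get(GerminationType.TYPE3, (0, 0))
    all_m = gm + lost + t3_t
    all_t = gt_tot + t3_t
    return EfficiencyReport(
        label=tally.label,
        per_type=per_type,
        aggregate_germinated=(gm, gt_tot, ratio_percent(gm, gt_tot)),
        aggregate_with_type3=(all_m, all_t, ratio_percent(all_m, all_t)),
    )
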