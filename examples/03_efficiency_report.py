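"""Efficiency reporting from per-category germination/genotype counts.

Reproduces the editing-efficiency arithmetic for the two published
six-target T1 populations from their transcribed (mutant, total) counts:
confirmed sextuple mutants among germinated seedlings, and the overall
estimate when never-germinating seeds are presumed mutant.
"""

from cas12mux.model import GerminationType
from cas12mux.report import TallyWithLosses, efficiency_summary

T0, T1, T2, T3 = GerminationType

populations = {
    "p6xV1": TallyWithLosses(
        "p6xV1", {T0: (11, 21), T1: (14, 20), T2: (20, 20), T3: (77, 77)},
        not_recovered={T0: 2}),
    "p6xV2": TallyWithLosses(
        "p6xV2", {T0: (16, 37), T1: (15, 45), T2: (21, 21), T3: (111, 111)},
        not_recovered={T0: 8}),
}

for label, tally in populations.items():
    rep = efficiency_summary(tally)
    print(f"{label}:")
    for gt, (m, t, pct) in rep.per_type.items():
        print(f"  {gt.value}: {pct}% ({m}/{t})")
    m, t, pct = rep.aggregate_germinated
    print(f"  sextuple among germinated (Types 0-2): {pct}% ({m}/{t})")
    m, t, pct = rep.aggregate_with_type3
    print(f"  overall estimate (Type-3 presumed mutant): {pct}% ({m}/{t})")

# Type-2 (stunted) seedlings were genotyped as a bulk pool with no wild-type
# reads detected, hence 100% in that cell; Type-3 seeds never germinate and
# enter only the estimated overall efficiency. Percentages are half-up at
# one decimal on exact rationals.
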