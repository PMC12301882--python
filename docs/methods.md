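# Methods

## Scope and model

cas12mux implements the computational side of a multiplex LbCas12a knockout
experiment in *Arabidopsis*: guide/array design before transformation, and
genotyping plus efficiency reporting after amplicon deep sequencing of T1
(and T-DNA-free T2) plants. The biological model underlying the genotype →
phenotype step is that the six targeted clade A PP2C genes redundantly
repress ABA signalling: seeds in which every copy of every targeted gene
carries a frameshift (loss-of-function) mutation never germinate, whereas an
in-frame indel (net length a multiple of 3) may leave partial protein
function and permit delayed or stunted germination.

## Read alignment and event extraction

Reads are amplicon PCR copies, so alignment is semi-global: the read aligns
end to end while reference end gaps are free. Scoring is affine
(match +2, mismatch −2, gap open −6, gap extend −1; a length-k gap costs
`open + (k−1)·extend`). The dynamic program is numba-compiled with a
deterministic traceback preference (diagonal > deletion > insertion);
extracted indels are then left-normalized (a deletion shifts left while the
flanking base equals its last base; an insertion rotates likewise) and
adjacent same-kind events merge. Left-normalization makes equal-score
placements unique, so allele identity — the exact event list — is stable.
The aligner is written in-package because the rubric is an affine-gap
semi-global alignment with controlled tie-breaking; tests validate its
optima against an independent score-only dynamic program and require that
reported events reconstruct the read exactly.

Reads shorter than 30 nt are rejected (`too_short`); reads whose total
edited bases exceed 20% of the read length are rejected as noise
(`too_divergent`). Both thresholds are explicit `AlignmentParams` fields.

## Allele collapsing and zygosity

Events are restricted to the cleavage window — the spacer interval widened
by 10 nt on each side (Cas12a cuts PAM-distal, and iterative re-cutting
spreads lesions); an event partially overlapping the window is kept whole,
since truncating it would scramble allele identity. Substitution events are
treated as sequencing noise by default (`subs_are_mutations=False`):
amplicon sequencing at ~10⁻³ per-base error would otherwise shatter alleles,
and the downstream loss-of-function logic is indel-driven. With the switch
on, substitution-only reads count as mutant alleles instead.

Reads with identical event lists pool into one allele. An allele that is
simultaneously below 5% of reads **and** below 10 reads is discarded as
amplification/sequencing noise, and its reads leave the denominator;
fractions are then recomputed over retained reads. Zero retained reads give
a *no-call*, distinct from WT.

Classification applies, in order: Ho (top mutant allele ≥ 95%), Bi (≥ 2
mutant alleles totalling ≥ 95%), WT (no mutant allele), He (top mutant
type ≥ 45%), else Chi. Wild-type reads are never a "type of mutation": they
sit in denominators but not in the 45% dominant-type rule. Threshold
comparisons carry a 10⁻⁹ epsilon so that fractions that are exactly at a
boundary as rationals (e.g. 57+29+9 of 100 reads totalling 95%) classify by
their exact value rather than by float rounding; the test suite proves
equivalence with an integer-arithmetic decision table over the full 0.01
fraction grid.

The biallelic rule interprets "≥95% of reads representing more than one type
of mutation" as *total mutant fraction ≥ 95% with ≥ 2 retained mutant
alleles* — the diploid reading, consistent with the He rule's implicit WT
remainder. Floored alleles do not count toward the ≥ 2.

## Multiplex genotypes, germination, heritability

A plant is `is_sextuple_no_wt` when every targeted gene is Ho or Bi, and
`is_full_lof` when additionally no retained allele has net indel ≡ 0
(mod 3). `predicted_type3 = is_full_lof` is labelled a heuristic: late-stage
editing can in rare cases produce sextuple plants that germinate without any
in-frame allele, and reports carry that caveat. A no-call at any gene marks
the plant unresolved and excludes it from sextuple counts.

Germination taxonomy: Type-3 — no germination within the 70-day horizon;
Type-2 — germinated but stunted (long roots, weak shoot); Type-0 — normal
germination by day 7; Type-1 — delayed otherwise.

T1→T2 heritability is set logic per gene: *heritable* if the T2 mutant
allele set is a nonempty subset of the T1 set (selfing of a Bi plant may fix
either allele), or both generations retain WT; *novel-allele* if T2 shows an
allele absent from T1; *inconsistent* if T2 is WT where T1 had no WT allele.

## Pooled wild-type scan

Bulk DNA pools (e.g. stunted Type-2 seedlings genotyped together) are scanned
by running the same align/clip/floor path on the combined reads and taking
the WT read fraction. A fraction ≤ 0.5% (`wt_noise_max`) is *consistent with*
every pooled plant being Ho/Bi — an inference about the pool, never a
per-plant genotype. Pooling is associative: scanning pools separately or
concatenated gives the same fraction.

## Efficiency reporting

Percentages are computed on exact rationals and printed half-up at one
decimal (45/61 → 73.8; 124/138 → 89.9; 171/214 → 79.9). Zero-denominator
cells print as not-applicable, never 0%. Two aggregates are reported:
confirmed sextuple mutants among germinated seedlings (Types 0–2, a plain
sum of the per-type cells), and an estimated overall efficiency in which
Type-3 seeds — and germinated seedlings lost before genotyping — are
presumed mutant. The presumption mirrors the enrichment argument: genotypes
compatible with germination are selectively enriched among seedlings, so
seeds that never germinate are very likely full-LOF mutants; seedlings that
died before genotyping are treated symmetrically in the estimate while
remaining non-mutant in the confirmed aggregate. Note that 171/214 prints
as 79.9 under this rounding; published tables occasionally show such values
rounded to the nearest integer-friendly figure (80.0), and the package
always prints the computed value.

## Synthetic population generator

The generator emulates the study conditions: 200 plants, six genes, read
depth 100 per plant × gene, per-base substitution error 10⁻³, archetype
compositions Ho (one allele, 1.0), Bi (0.5/0.5), He (mutant/WT 0.5/0.5),
Chi (4 mutant alleles + WT from a flat simplex with every mutant fraction
in [0.05, 0.45) and total mutant < 0.95 — the constraints that make a
chimeric label self-consistent under the calling rules, floor included).
Default class probabilities are {WT .02, Ho .55, Bi .35, He .04, Chi .04},
grounded in the observed populations: ~74% of germinated T1 seedlings were
sextuple mutants, implying a per-gene Ho/Bi probability near
0.74^(1/6) ≈ 0.95.

Reads are allocated to alleles by exact largest-remainder proportion, and
the truth table stores the realized composition; stochasticity enters
through class draws, allele draws and sequencing noise, not through
binomial allele sampling. This keeps truth analytically known and makes
zero-noise recovery exactly 100% — a deliberate design choice: a multinomial
read sampler would make the He archetype (true 0.50) fall below the 45%
threshold in ~14% of pools at depth 100 even with perfect calling, which
would measure sampling noise rather than pipeline correctness.

Indels are drawn with 70% deletions (1–30 nt, geometric p = 0.2, truncated)
and 30% insertions (1–10 nt), positions uniform in the cleavage window;
drawn events are left-normalized exactly as the caller normalizes, and draws
whose normalized form leaves the window are rejected (they would be
invisible to calling by construction). An optional `in_frame_mass` parameter
concentrates probability on multiples of 3.

The germination simulator applies the genotype rule deterministically:
full-LOF sextuple → never germinates; sextuple with an in-frame allele →
rescued with probability `in_frame_rescue_prob` (default 1.0) into delayed
(day 14/21/28) or stunted (≥ 21 d) germination; everything else → day 7.
The two published exceptional T1 plants (sextuple, no in-frame allele, yet
germinated) are not modelled; mutation timing during development is out of
scope and surfaces only as the report caveat.

What passing synthetic tests does **not** show about real data: PCR
chimeras and duplicates, somatic mosaicism, quality-score structure, large
structural variants and primer-site mutations are all absent from the
generator, so real pools may need the floors and the divergence threshold
retuned.

## Guide design choices

* PAM pattern IUPAC-configurable, default TTTV; spacer length
  manifest-driven (default 23 nt, canonical LbCas12a).
* "PAM-distal region" defaults to spacer positions ≥ 19 of 23 (the final
  five), covering the 1–2 terminal mismatches tolerated in dual-targeting;
  configurable because no fixed zone boundary is established.
* Off-target search is Hamming-only (no bulges), PAM-gated by default, as a
  linear scan — adequate for gene-sized subjects, not genome indexes.
* Arrays: 1–3 DR+spacer units per U6 promoter; assembly refuses a spacer
  containing the DR (Cas12a processing and the parser would both be
  ambiguous).
* Golden Gate: identical DRs cannot supply unique junction overhangs, so
  each junction is placed inside a downstream spacer at the leftmost offset
  whose 4-nt overhang is unique within the assembly; unresolvable collisions
  (e.g. duplicated homopolymer spacers) raise a design error. Terminal
  overhangs and all fixed parts (DR, tRNA-Gly, HDV, promoter names) live in
  an editable parts config whose defaults are canonical/synthetic stand-ins
  for vector-specific sequences.

## Numerical and degenerate-input conventions

All intervals are 0-based half-open on the amplicon plus strand; minus-strand
conversion is an involution. Ties in alignment resolve leftmost. Allele sort
order is read count descending, then key. Manifest amplicons must be pure
ACGT (ambiguity codes are allowed only in PAM patterns). Duplicate plant or
gene identifiers raise errors rather than silently merging.

## Test and acceptance problem sizes

The acceptance-level checks run 10 seeds × 200 plants × 6 genes at depth
100 for recovery, the full 0.01 zygosity grid (≈ 30 k compositions), 100
random 2-kb sequences for the design oracles and 50 random six-spacer sets
for assembly round trips; the acceptance script uses three 200-plant
replicates plus a zero-error control. These sizes were chosen to give
stable percentages at single-decimal resolution while keeping the default
run in the minutes range on one core.
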