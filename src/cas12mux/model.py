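"""Shared domain types for multiplex Cas12a genotyping.

Conventions used throughout the package:

* All intervals are 0-based, half-open, on the **plus strand** of the amplicon
  (or subject) sequence, regardless of which strand the protospacer lies on.
* For a minus-strand target site, ``spacer_seq`` is the reverse complement of
  the plus-strand amplicon slice at ``spacer_interval``.
* The PAM sits immediately 5' of the spacer on the protospacer strand
  (LbCas12a places its TTTV PAM upstream of the protospacer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

__all__ = [
    "Cas12muxError",
    "ManifestError",
    "ConfigError",
    "InputError",
    "DesignError",
    "MutationKind",
    "MutationEvent",
    "Allele",
    "WT_ALLELE",
    "AlleleCall",
    "ZygosityThresholds",
    "Zygosity",
    "GeneZygosity",
    "GerminationType",
    "GerminationRecord",
    "PlantGenotype",
    "PopulationTally",
    "TargetSite",
    "revcomp",
    "minus_to_plus_interval",
    "iupac_match",
    "IUPAC",
]


class Cas12muxError(Exception):
    """Base class for all package errors."""


class ManifestError(Cas12muxError):
    """Target manifest does not validate against its amplicons."""


class ConfigError(Cas12muxError):
    """Invalid configuration value."""


class InputError(Cas12muxError):
    """Invalid data handed to an operation."""


class DesignError(Cas12muxError):
    """A construct design cannot be realised (e.g. ambiguous overhangs)."""


# --------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def minus_to_plus_interval(start: int, end: int, seq_len: int) -> Tuple[int, int]:
    """Map a 0-based half-open interval on the minus strand to plus-strand
    coordinates. Involution: applying it twice is the identity."""
    return seq_len - end, seq_len - start


def iupac_match(pattern: str, seq: str) -> bool:
    """Does ``seq`` match the IUPAC ``pattern`` position by position?"""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern, seq):
        allowed = IUPAC.get(p)
        if allowed is None:
            raise ConfigError(f"invalid IUPAC code {p!r} in pattern {pattern!r}")
        if s not in allowed:
            return False
    return True


# --------------------------------------------------------------------------
# target sites


@dataclass(frozen=True)
class TargetSite:
    """One gene's amplicon with its protospacer, PAM and calling window.

    ``spacer_interval`` is the plus-strand interval of the protospacer on the
    amplicon. ``cleavage_window`` is where indel calls are accepted; Cas12a
    cuts PAM-distal and re-cutting spreads events, so the window defaults to
    the spacer widened by ``window_pad`` nt on each side, clipped to the
    amplicon.
    """

    gene_id: str
    amplicon_id: str
    amplicon_seq: str
    pam_seq: str
    spacer_seq: str
    strand: str
    spacer_interval: Tuple[int, int]
    cleavage_window: Tuple[int, int] = None  # type: ignore[assignment]
    window_pad: int = 10
    pam_pattern: str = "TTTV"

    def __post_init__(self):
        seq = self.amplicon_seq.upper()
        object.__setattr__(self, "amplicon_seq", seq)
        object.__setattr__(self, "pam_seq", self.pam_seq.upper())
        object.__setattr__(self, "spacer_seq", self.spacer_seq.upper())
        if self.strand not in "+-":
            raise ManifestError(f"{self.gene_id}: strand must be '+' or '-'")
        if any(b not in "ACGT" for b in seq):
            raise ManifestError(
                f"{self.gene_id}: amplicon contains non-ACGT letters; "
                "ambiguity codes are allowed only in PAM patterns"
            )
        s, e = self.spacer_interval
        if not (0 <= s < e <= len(seq)):
            raise ManifestError(f"{self.gene_id}: spacer interval {s, e} out of bounds")
        if e - s != len(self.spacer_seq):
            raise ManifestError(
                f"{self.gene_id}: spacer interval length {e - s} != spacer length "
                f"{len(self.spacer_seq)}"
            )
        observed = seq[s:e] if self.strand == "+" else revcomp(seq[s:e])
        if observed != self.spacer_seq:
            raise ManifestError(
                f"{self.gene_id}: spacer sequence does not match amplicon at "
                f"[{s},{e}) on strand {self.strand}"
            )
        if not iupac_match(self.pam_pattern, self.pam_seq):
            raise ManifestError(
                f"{self.gene_id}: PAM {self.pam_seq} does not match pattern "
                f"{self.pam_pattern}"
            )
        # PAM is immediately 5' of the spacer on the protospacer strand.
        plen = len(self.pam_seq)
        if self.strand == "+":
            ps, pe = s - plen, s
            pam_obs = seq[ps:pe] if ps >= 0 else None
        else:
            ps, pe = e, e + plen
            pam_obs = revcomp(seq[ps:pe]) if pe <= len(seq) else None
        if pam_obs != self.pam_seq:
            raise ManifestError(
                f"{self.gene_id}: declared PAM {self.pam_seq} not found adjacent "
                f"to spacer (strand {self.strand})"
            )
        if self.cleavage_window is None:
            win = (max(0, s - self.window_pad), min(len(seq), e + self.window_pad))
            object.__setattr__(self, "cleavage_window", win)
        ws, we = self.cleavage_window
        if not (0 <= ws < we <= len(seq)):
            raise ManifestError(f"{self.gene_id}: cleavage window out of bounds")

    @property
    def spacer_len(self) -> int:
        return len(self.spacer_seq)


# --------------------------------------------------------------------------
# mutations and alleles


class MutationKind(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    SUBSTITUTION = "substitution"


@dataclass(frozen=True, order=True)
class MutationEvent:
    """A single mutation in amplicon (plus-strand) coordinates.

    ``seq`` holds the inserted bases for insertions and the replacement bases
    for substitutions; it is empty for deletions. For insertions the event sits
    *between* amplicon positions ``position-1`` and ``position``.
    """

    position: int
    kind: MutationKind
    length: int
    seq: str = ""

    def __post_init__(self):
        if self.length <= 0:
            raise InputError("mutation length must be positive")
        if self.kind is MutationKind.DELETION:
            if self.seq:
                raise InputError("deletions carry no sequence")
        elif len(self.seq) != self.length:
            raise InputError(f"{self.kind.value} seq length != event length")

    def key(self) -> str:
        c = {"insertion": "I", "deletion": "D", "substitution": "S"}[self.kind.value]
        return f"{c}{self.position}:{self.length}" + (f":{self.seq}" if self.seq else "")

    @classmethod
    def from_key(cls, key: str) -> "MutationEvent":
        kinds = {"I": MutationKind.INSERTION, "D": MutationKind.DELETION,
                 "S": MutationKind.SUBSTITUTION}
        kind = kinds[key[0]]
        parts = key[1:].split(":")
        pos, length = int(parts[0]), int(parts[1])
        seq = parts[2] if len(parts) > 2 else ""
        return cls(position=pos, kind=kind, length=length, seq=seq)

    @property
    def signed_indel(self) -> int:
        if self.kind is MutationKind.INSERTION:
            return self.length
        if self.kind is MutationKind.DELETION:
            return -self.length
        return 0

    def end(self) -> int:
        """One past the last reference base the event touches."""
        if self.kind is MutationKind.INSERTION:
            return self.position
        return self.position + self.length


@dataclass(frozen=True)
class Allele:
    """A collapsed set of mutation events; identity is the exact event list."""

    events: Tuple[MutationEvent, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(sorted(self.events)))

    @property
    def is_mutant(self) -> bool:
        return len(self.events) > 0

    @property
    def net_indel(self) -> int:
        return sum(e.signed_indel for e in self.events)

    @property
    def is_in_frame_3x(self) -> bool:
        return self.is_mutant and self.net_indel % 3 == 0

    def key(self) -> str:
        return "+".join(e.key() for e in self.events) if self.events else "WT"

    @classmethod
    def from_key(cls, key: str) -> "Allele":
        if key == "WT" or not key:
            return cls(())
        return cls(tuple(MutationEvent.from_key(k) for k in key.split("+")))


WT_ALLELE = Allele(())


@dataclass(frozen=True)
class AlleleCall:
    """One allele with its read support within a line x gene pool."""

    allele: Allele
    read_count: int
    fraction: float

    def __post_init__(self):
        if self.read_count < 0:
            raise InputError("read_count must be non-negative")
        if not 0.0 <= self.fraction <= 1.0 + 1e-12:
            raise InputError("fraction must lie in [0, 1]")


# --------------------------------------------------------------------------
# zygosity


@dataclass(frozen=True)
class ZygosityThresholds:
    """Read-fraction thresholds for the Ho/Bi/He/Chi calling rules.

    ``ho_bi_min``: one mutant allele at or above this fraction is homozygous;
    two or more mutant alleles jointly at or above it are biallelic.
    ``he_min``: a single dominant mutant type at or above this fraction (but
    below the Ho/Bi rule) is heterozygous, otherwise chimeric. The allele
    floor discards alleles that are simultaneously below a fraction and a read
    count, treating them as amplification/sequencing noise. ``wt_noise_max``
    bounds the WT read fraction still consistent with an all-mutant pool.
    """

    ho_bi_min: float = 0.95
    he_min: float = 0.45
    allele_floor_fraction: float = 0.05
    allele_floor_reads: int = 10
    wt_noise_max: float = 0.005

    def __post_init__(self):
        if not 0.0 < self.he_min < self.ho_bi_min <= 1.0:
            raise ConfigError("require 0 < he_min < ho_bi_min <= 1")


class Zygosity(str, Enum):
    WT = "WT"
    HO = "Ho"
    BI = "Bi"
    HE = "He"
    CHI = "Chi"


@dataclass(frozen=True)
class GeneZygosity:
    """Per-gene call: class, retained mutant alleles (descending fraction),
    and the WT read fraction."""

    gene_id: str
    zygosity_class: Zygosity
    allele_calls: Tuple[AlleleCall, ...]
    wt_fraction: float

    def __post_init__(self):
        fracs = [c.fraction for c in self.allele_calls]
        if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise InputError("allele_calls must be sorted by descending fraction")

    @property
    def mutant_alleles(self) -> Tuple[Allele, ...]:
        return tuple(c.allele for c in self.allele_calls)

    @property
    def has_in_frame_3x(self) -> bool:
        return any(c.allele.is_in_frame_3x for c in self.allele_calls)


# --------------------------------------------------------------------------
# germination and plants


class GerminationType(str, Enum):
    TYPE0 = "Type-0"
    TYPE1 = "Type-1"
    TYPE2 = "Type-2"
    TYPE3 = "Type-3"


@dataclass(frozen=True)
class GerminationRecord:
    """One seed/plant's germination observation.

    ``day_of_germination`` is the plate-scoring day (7, 14, 21, 28, ...);
    ``stunted`` marks seedlings with long roots but weak shoot development.
    """

    plant_id: str
    germinated: bool
    day_of_germination: Optional[int] = None
    stunted: bool = False
    observation_horizon: int = 70

    def __post_init__(self):
        if self.day_of_germination is not None and not self.germinated:
            raise InputError(f"{self.plant_id}: day_of_germination set but not germinated")


@dataclass
class PlantGenotype:
    """Cross-gene aggregation of one plant's zygosity calls.

    ``is_sextuple_no_wt``: every targeted gene is Ho or Bi (no WT allele
    anywhere). ``is_full_lof``: additionally no allele is an in-frame (3x)
    indel, hence every copy of every gene is presumed loss of function.
    ``predicted_type3`` flags plants expected never to germinate; it is a
    labeled heuristic, not a genotype fact.
    """

    plant_id: str
    gene_calls: Mapping[str, Optional[GeneZygosity]]
    is_sextuple_no_wt: bool
    is_full_lof: bool
    predicted_type3: bool
    germination_type: Optional[GerminationType] = None
    unresolved: bool = False


@dataclass
class PopulationTally:
    """Mutant / total counts per germination type for one population."""

    label: str
    counts: Mapping[GerminationType, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for gt, (mut, tot) in self.counts.items():
            if mut < 0 or tot < 0:
                raise InputError(f"{self.label}/{gt}: negative count")
            if mut > tot:
                raise InputError(f"{self.label}/{gt}: mutant count exceeds total")
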