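"""crRNA selection and tandem-array construction for LbCas12a.

Covers TTTV PAM scanning, homolog dual-targeting through PAM-distal
mismatches, Hamming off-target enumeration, six-guide array splitting across
two U6 promoters, seamless DR+spacer array assembly, and Golden Gate
annealed-oligo rendering with in-silico ligation.

Spacer positions are numbered 1 at the PAM-proximal base (Cas12a's PAM is 5'
of the protospacer, so position 1 is the first spacer base after the PAM).
The "PAM-distal region" defaults to positions >= 19 of a 23-nt spacer.

All fixed parts (direct repeat, tRNA-Gly, HDV ribozyme, promoter names,
terminal overhangs) live in :data:`DEFAULT_PARTS` and can be overridden; the
defaults are canonical/synthetic stand-ins, editable because exact plasmid
parts vary between vector systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .model import (
    ConfigError,
    DesignError,
    IUPAC,
    InputError,
    TargetSite,
    iupac_match,
    minus_to_plus_interval,
    revcomp,
)

__all__ = [
    "DEFAULT_PARTS",
    "CrRNAUnit",
    "CrRNAArray",
    "DualTargetPair",
    "OffTargetHit",
    "OligoPair",
    "scan_pam_sites",
    "find_dual_targets",
    "enumerate_offtargets",
    "split_six",
    "assemble_array",
    "parse_array",
    "design_oligos",
    "simulate_ligation",
    "plan_six_guide_assembly",
]

# Canonical LbCas12a mature direct repeat; tRNA-Gly / HDV ribozyme flanks
# release precise guide ends from a U6 polymerase-III transcript. These are
# editable stand-ins for vector-specific parts.
DEFAULT_PARTS: Dict[str, object] = {
    "direct_repeat": "AATTTCTACTAAGTGTAGAT",
    "trna_gly": (
        "AACAAAGCACCAGTGGTCTAGTGGTAGAATAGTACCCTGCCACGGTACAGACCCGGGTTCGATTCCCGGCTGGTGCA"
    ),
    "hdv_ribozyme": (
        "GGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGAC"
    ),
    "promoters": ("U6-26", "U6-29"),
    "start_overhang": "AGAT",
    "end_overhang": "CGTC",
}


@dataclass(frozen=True)
class CrRNAUnit:
    """One direct-repeat + spacer unit of a Cas12a crRNA array."""

    spacer_seq: str
    direct_repeat: str = DEFAULT_PARTS["direct_repeat"]  # type: ignore[assignment]

    def __post_init__(self):
        if not self.spacer_seq or any(b not in "ACGT" for b in self.spacer_seq):
            raise DesignError(f"spacer must be nonempty ACGT, got {self.spacer_seq!r}")

    def render(self) -> str:
        return self.direct_repeat + self.spacer_seq


@dataclass(frozen=True)
class CrRNAArray:
    """Ordered crRNA units under one U6 promoter, with tRNA/HDV flanks."""

    promoter_id: str
    units: Tuple[CrRNAUnit, ...]
    flank_5: str = DEFAULT_PARTS["trna_gly"]  # type: ignore[assignment]
    flank_3: str = DEFAULT_PARTS["hdv_ribozyme"]  # type: ignore[assignment]

    def __post_init__(self):
        if not self.units:
            raise DesignError("array must contain at least one unit")

    @property
    def spacers(self) -> Tuple[str, ...]:
        return tuple(u.spacer_seq for u in self.units)

    def core(self) -> str:
        return "".join(u.render() for u in self.units)

    def render(self) -> str:
        return self.flank_5 + self.core() + self.flank_3


@dataclass(frozen=True)
class DualTargetPair:
    """A crRNA perfectly matching gene A whose protospacer in gene B differs
    only at PAM-distal spacer positions (1 = PAM-proximal)."""

    site_a: TargetSite
    site_b: TargetSite
    mismatch_positions: Tuple[int, ...]


@dataclass(frozen=True)
class OffTargetHit:
    subject_id: str
    position: int  # plus-strand start of the protospacer window
    strand: str
    mismatches: int


# --------------------------------------------------------------------------
# PAM scanning


def _pattern_ok(pattern: str) -> None:
    for ch in pattern:
        if ch not in IUPAC:
            raise ConfigError(f"invalid IUPAC code {ch!r} in PAM pattern {pattern!r}")


def _scan_strand(seq: str, pattern: str, spacer_len: int) -> List[int]:
    """Protospacer-strand offsets of PAM starts (numpy column-wise match)."""
    plen = len(pattern)
    n = len(seq)
    if n < plen + spacer_len:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    limit = n - plen - spacer_len + 1
    ok = np.ones(limit, dtype=bool)
    for k, ch in enumerate(pattern):
        allowed = np.array([ord(b) for b in IUPAC[ch]], dtype=np.uint8)
        ok &= np.isin(arr[k:k + limit], allowed)
    return np.flatnonzero(ok).tolist()


def scan_pam_sites(
    seq: str,
    pam_pattern: str = "TTTV",
    spacer_len: int = 23,
    both_strands: bool = True,
    amplicon_id: str = "subject",
) -> List[TargetSite]:
    """All protospacers with a matching PAM immediately 5' of them.

    Returns validated :class:`TargetSite` objects sorted by plus-strand
    spacer coordinate, then strand.
    """
    _pattern_ok(pam_pattern)
    seq = seq.upper()
    plen = len(pam_pattern)
    sites: List[TargetSite] = []
    for off in _scan_strand(seq, pam_pattern, spacer_len):
        s = off + plen
        sites.append(TargetSite(
            gene_id=f"{amplicon_id}:{s}:+", amplicon_id=amplicon_id,
            amplicon_seq=seq, pam_seq=seq[off:s], spacer_seq=seq[s:s + spacer_len],
            strand="+", spacer_interval=(s, s + spacer_len), pam_pattern=pam_pattern))
    if both_strands:
        rc = revcomp(seq)
        for off in _scan_strand(rc, pam_pattern, spacer_len):
            s = off + plen
            interval = minus_to_plus_interval(s, s + spacer_len, len(seq))
            sites.append(TargetSite(
                gene_id=f"{amplicon_id}:{interval[0]}:-", amplicon_id=amplicon_id,
                amplicon_seq=seq, pam_seq=rc[off:s], spacer_seq=rc[s:s + spacer_len],
                strand="-", spacer_interval=interval, pam_pattern=pam_pattern))
    sites.sort(key=lambda t: (t.spacer_interval[0], t.strand))
    return sites


# --------------------------------------------------------------------------
# homolog dual targeting


def find_dual_targets(
    seq_a: str,
    seq_b: str,
    max_mm: int = 2,
    distal_zone_start: int = 19,
    spacer_len: int = 23,
    pam_pattern: str = "TTTV",
    symmetric: bool = False,
) -> List[DualTargetPair]:
    """Sites where one crRNA can cut both homologs.

    The crRNA adopts gene A's protospacer (full complementarity); gene B's
    site may differ at up to ``max_mm`` positions, all within the PAM-distal
    zone (positions >= ``distal_zone_start``, counting 1 at the PAM-proximal
    end). With ``symmetric`` the B-anchored search is added as well.
    """
    if distal_zone_start > spacer_len:
        raise ConfigError("distal_zone_start exceeds spacer length")
    pairs = _dual_one_way(seq_a, seq_b, max_mm, distal_zone_start, spacer_len,
                          pam_pattern, "geneA", "geneB")
    if symmetric:
        pairs += _dual_one_way(seq_b, seq_a, max_mm, distal_zone_start, spacer_len,
                               pam_pattern, "geneB", "geneA")
    return pairs


def _dual_one_way(seq_a, seq_b, max_mm, distal_zone_start, spacer_len,
                  pam_pattern, id_a, id_b) -> List[DualTargetPair]:
    sites_a = scan_pam_sites(seq_a, pam_pattern, spacer_len, amplicon_id=id_a)
    sites_b = scan_pam_sites(seq_b, pam_pattern, spacer_len, amplicon_id=id_b)
    out = []
    for sa in sites_a:
        for sb in sites_b:
            mism = tuple(
                k + 1
                for k, (x, y) in enumerate(zip(sa.spacer_seq, sb.spacer_seq))
                if x != y
            )
            if len(mism) <= max_mm and all(p >= distal_zone_start for p in mism):
                out.append(DualTargetPair(site_a=sa, site_b=sb, mismatch_positions=mism))
    return out


# --------------------------------------------------------------------------
# off-target enumeration


def enumerate_offtargets(
    spacer: str,
    subjects: Union[Mapping[str, str], Iterable[Tuple[str, str]]],
    max_mm: int = 3,
    require_pam: bool = True,
    pam_pattern: str = "TTTV",
) -> List[OffTargetHit]:
    """All windows (both strands) within Hamming distance ``max_mm`` of the
    spacer, optionally gated on a canonical PAM 5' of the window. Bulges
    (indels) are not considered. Sorted by mismatch count, then coordinate.
    """
    _pattern_ok(pam_pattern)
    spacer = spacer.upper()
    L = len(spacer)
    plen = len(pam_pattern)
    sp = np.frombuffer(spacer.encode("ascii"), dtype=np.uint8)
    hits: List[OffTargetHit] = []
    items = subjects.items() if isinstance(subjects, Mapping) else subjects
    for sid, seq in items:
        seq = seq.upper()
        n = len(seq)
        if n < L + plen:
            warnings.warn(f"subject {sid!r} shorter than spacer+PAM; skipped")
            continue
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm = (win != sp).sum(axis=1)
            for j in np.flatnonzero(mm <= max_mm):
                j = int(j)
                if require_pam:
                    if j < plen or not iupac_match(pam_pattern, s[j - plen:j]):
                        continue
                pos = j if strand == "+" else n - (j + L)
                hits.append(OffTargetHit(sid, pos, strand, int(mm[j])))
    hits.sort(key=lambda h: (h.mismatches, h.subject_id, h.position, h.strand))
    return hits


# --------------------------------------------------------------------------
# array assembly


def split_six(spacers: Sequence[str],
              parts: Optional[Mapping[str, object]] = None) -> Tuple[CrRNAArray, CrRNAArray]:
    """Split six spacers into two three-unit arrays under U6-26 / U6-29.

    Order is preserved; any upstream permutation is accepted (spacer
    positioning within arrays has a negligible effect on editing)."""
    if len(spacers) != 6:
        raise InputError(f"exactly 6 spacers required, got {len(spacers)}")
    p = dict(DEFAULT_PARTS, **(parts or {}))
    dr = str(p["direct_repeat"])
    units = tuple(CrRNAUnit(s.upper(), dr) for s in spacers)
    proms = p["promoters"]
    mk = lambda prom, us: CrRNAArray(
        promoter_id=prom, units=us,
        flank_5=str(p["trna_gly"]), flank_3=str(p["hdv_ribozyme"]))
    return mk(proms[0], units[:3]), mk(proms[1], units[3:])


def assemble_array(array: CrRNAArray) -> str:
    """Render an array to DNA: flank_5 + (DR+spacer)*n + flank_3.

    Refused when the DR occurs inside any spacer — the parser (and Cas12a
    processing) could not split such an array unambiguously."""
    for u in array.units:
        if u.direct_repeat in u.spacer_seq:
            raise DesignError(
                f"direct repeat occurs inside spacer {u.spacer_seq}; "
                "array would be ambiguous to process")
    return array.render()


def parse_array(seq: str, direct_repeat: str,
                flank_5: str = "", flank_3: str = "") -> List[str]:
    """Split an assembled array back into its spacers on exact DR matches."""
    if flank_5:
        if not seq.startswith(flank_5):
            raise InputError("sequence does not start with the given 5' flank")
        seq = seq[len(flank_5):]
    if flank_3:
        if not seq.endswith(flank_3):
            raise InputError("sequence does not end with the given 3' flank")
        seq = seq[: len(seq) - len(flank_3)]
    if not seq.startswith(direct_repeat):
        raise InputError("array core does not begin with the direct repeat")
    spacers = seq.split(direct_repeat)[1:]
    if any(not s for s in spacers):
        raise InputError("empty spacer between direct repeats")
    return spacers


# --------------------------------------------------------------------------
# Golden Gate oligo rendering


@dataclass(frozen=True)
class OligoPair:
    """An annealed primer pair: top strand = 5' overhang + duplex core;
    bottom strand = 5' overhang + reverse complement of the core. The two
    4-nt overhangs protrude 5' on opposite ends and dictate assembly order."""

    top_strand: str
    bottom_strand: str
    overhang_5: str
    overhang_3: str
    enzyme_context: str = "BbsI"

    @property
    def core(self) -> str:
        return self.top_strand[len(self.overhang_5):]

    def __post_init__(self):
        if len(self.overhang_5) != 4 or len(self.overhang_3) != 4:
            raise DesignError("overhangs must be 4 nt")
        if self.bottom_strand != self.overhang_3 + revcomp(self.core):
            raise DesignError("bottom strand is not overhang + revcomp(core)")


def _check_overhang_collisions(overhangs: Sequence[str]) -> None:
    seen: Dict[str, int] = {}
    for ov in overhangs:
        if ov in seen:
            raise DesignError(
                f"overhang {ov} occurs twice in one assembly; "
                "Golden Gate ordering would be ambiguous")
        seen[ov] = 1


def design_oligos(
    source: Union[str, CrRNAArray, Sequence[str]],
    parts: Optional[Mapping[str, object]] = None,
    enzyme_context: str = "BbsI",
) -> List[OligoPair]:
    """Render a spacer or a crRNA array as annealed Golden Gate oligo pairs.

    For a single spacer the duplex core is the spacer itself between the
    configured terminal overhangs. For an array, the full DR+spacer core is
    cut once inside each downstream spacer, at the leftmost offset whose
    4-nt overhang collides with no other overhang in the assembly; ligating
    the pairs in overhang order reconstructs the array core exactly.
    """
    p = dict(DEFAULT_PARTS, **(parts or {}))
    start_ov = str(p["start_overhang"])
    end_ov = str(p["end_overhang"])

    if isinstance(source, str):
        core = source.upper()
        pair = OligoPair(
            top_strand=start_ov + core,
            bottom_strand=end_ov + revcomp(core),
            overhang_5=start_ov, overhang_3=end_ov,
            enzyme_context=enzyme_context)
        _check_overhang_collisions([start_ov, revcomp(end_ov)])
        return [pair]

    if isinstance(source, CrRNAArray):
        array = source
    else:
        dr = str(p["direct_repeat"])
        array = CrRNAArray(promoter_id="adhoc",
                           units=tuple(CrRNAUnit(s.upper(), dr) for s in source))
    core = array.core()
    dr_len = len(array.units[0].direct_repeat)
    # one junction inside each of spacers 2..n (identical DRs cannot supply
    # unique overhangs); slide each junction along its spacer until the 4-nt
    # overhang collides with none already chosen
    spacer_starts = []
    off = 0
    for u in array.units[:-1]:
        off += len(u.render())
        spacer_starts.append(off + dr_len)
    taken = {start_ov, revcomp(end_ov)}
    junctions = [0]
    for k, s0 in enumerate(spacer_starts):
        slen = len(array.units[k + 1].spacer_seq)
        for d in range(slen - 3):
            ov = core[s0 + d:s0 + d + 4]
            if ov not in taken:
                taken.add(ov)
                junctions.append(s0 + d)
                break
        else:
            raise DesignError(
                f"no collision-free overhang within spacer {k + 2}; "
                "Golden Gate ordering would be ambiguous")
    junctions.append(len(core))

    tops = []
    for k in range(len(junctions) - 1):
        seg = core[junctions[k]:junctions[k + 1]]
        ov5 = start_ov if k == 0 else seg[:4]
        body = seg if k == 0 else seg[4:]
        tops.append((ov5, body))
    _check_overhang_collisions([ov for ov, _ in tops] + [revcomp(end_ov)])

    pairs = []
    for k, (ov5, body) in enumerate(tops):
        if k + 1 < len(tops):
            ov3 = revcomp(tops[k + 1][0])
        else:
            ov3 = end_ov
        pairs.append(OligoPair(
            top_strand=ov5 + body, bottom_strand=ov3 + revcomp(body),
            overhang_5=ov5, overhang_3=ov3, enzyme_context=enzyme_context))
    return pairs


def simulate_ligation(pairs: Sequence[OligoPair], start_overhang: str,
                      end_overhang: str) -> str:
    """Chain oligo pairs by sticky-end complementarity; return the assembled
    top strand. Ambiguous or dangling junctions raise a design error."""
    pool = list(pairs)
    current = start_overhang
    out: List[str] = []
    while pool:
        matches = [p for p in pool if p.overhang_5 == current]
        if len(matches) != 1:
            raise DesignError(
                f"ligation at overhang {current}: {len(matches)} candidate "
                "fragments (expected exactly 1)")
        frag = matches[0]
        pool.remove(frag)
        out.append(frag.overhang_5 + frag.core if out else frag.core)
        current = revcomp(frag.overhang_3)
    if current != revcomp(end_overhang):
        raise DesignError("assembly does not terminate at the vector overhang")
    return "".join(out)


def plan_six_guide_assembly(
    spacers: Sequence[str],
    parts: Optional[Mapping[str, object]] = None,
) -> Dict[str, object]:
    """Two-level assembly plan for a six-guide construct: BbsI-level oligo
    pairs for each three-unit U6 array, verified by in-silico ligation (the
    BsaI level then moves the verified cassettes into the binary vector)."""
    p = dict(DEFAULT_PARTS, **(parts or {}))
    arr1, arr2 = split_six(spacers, p)
    plan: Dict[str, object] = {"arrays": (arr1, arr2), "oligos": {}, "cores": {}}
    for arr in (arr1, arr2):
        pairs = design_oligos(arr, p, enzyme_context="BbsI")
        assembled = simulate_ligation(
            pairs, str(p["start_overhang"]), str(p["end_overhang"]))
        if assembled != arr.core():
            raise DesignError(f"in-silico ligation failed for {arr.promoter_id}")
        plan["oligos"][arr.promoter_id] = pairs  # type: ignore[index]
        plan["cores"][arr.promoter_id] = assembled  # type: ignore[index]
    return plan
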