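"""Turn read pools into collapsed allele calls with fractions.

The stages for one line x gene pool are:

1. :func:`align_read` — semi-global alignment of each read against the
   amplicon, extraction of mutation events in reference coordinates,
   left-normalization and merging of adjacent events, and rejection of
   over-divergent or too-short reads.
2. :func:`collapse_alleles` — clip events to the cleavage window, pool reads
   with identical event lists into alleles, apply the allele floor, and
   recompute fractions over retained reads.
3. :func:`pooled_wt_fraction` / :func:`infer_pool_homozygosity` — the pooled
   wild-type scan used for bulk samples (e.g. stunted seedlings genotyped as
   one DNA pool).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ._align import _dp_traceback, encode
from .model import (
    Allele,
    AlleleCall,
    ConfigError,
    InputError,
    MutationEvent,
    MutationKind,
    TargetSite,
    WT_ALLELE,
    ZygosityThresholds,
)

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "align_read",
    "apply_events",
    "collapse_alleles",
    "CollapseResult",
    "call_gene",
    "pooled_wt_fraction",
    "infer_pool_homozygosity",
    "MIN_READ_LENGTH",
]

MIN_READ_LENGTH = 30


@dataclass(frozen=True)
class AlignmentParams:
    """Affine alignment scores plus the read-level noise rejection threshold."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -1
    max_read_mismatch_frac: float = 0.2

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match):
            raise ConfigError("require gap_open <= gap_extend <= 0 <= match")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Events (reference coordinates) of one read, or a rejection reason."""

    events: Tuple[MutationEvent, ...] = ()
    ref_start: int = 0
    ref_end: int = 0
    score: int = 0
    rejected: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.rejected is None


def apply_events(ref: str, events: Sequence[MutationEvent], start: int = 0,
                 end: Optional[int] = None) -> str:
    """Reconstruct the read implied by ``events`` over ``ref[start:end]``."""
    if end is None:
        end = len(ref)
    out: List[str] = []
    cursor = start
    for ev in sorted(events):
        if ev.position < cursor and ev.kind is not MutationKind.INSERTION:
            raise InputError("overlapping events")
        out.append(ref[cursor:ev.position])
        if ev.kind is MutationKind.DELETION:
            cursor = ev.position + ev.length
        elif ev.kind is MutationKind.SUBSTITUTION:
            out.append(ev.seq)
            cursor = ev.position + ev.length
        else:
            out.append(ev.seq)
            cursor = ev.position
    out.append(ref[cursor:end])
    return "".join(out)


def _extract_events(ops, read: str, ref: str, ref_start: int):
    """Convert a traceback op string into merged per-run mutation events."""
    events: List[MutationEvent] = []
    i, j = 0, ref_start
    run_kind = None  # type: Optional[MutationKind]
    run_pos = run_len = 0
    run_seq: List[str] = []

    def flush():
        nonlocal run_kind, run_len, run_seq
        if run_kind is not None:
            events.append(
                MutationEvent(
                    position=run_pos,
                    kind=run_kind,
                    length=run_len,
                    seq="" if run_kind is MutationKind.DELETION else "".join(run_seq),
                )
            )
        run_kind, run_len, run_seq = None, 0, []

    for op in ops:
        if op == 0:  # diagonal
            if read[i] != ref[j]:
                if run_kind is MutationKind.SUBSTITUTION and run_pos + run_len == j:
                    run_len += 1
                    run_seq.append(read[i])
                else:
                    flush()
                    run_kind, run_pos, run_len, run_seq = (
                        MutationKind.SUBSTITUTION, j, 1, [read[i]])
            else:
                flush()
            i += 1
            j += 1
        elif op == 1:  # deletion (ref consumed)
            if run_kind is MutationKind.DELETION and run_pos + run_len == j:
                run_len += 1
            else:
                flush()
                run_kind, run_pos, run_len = MutationKind.DELETION, j, 1
            j += 1
        else:  # insertion (read consumed)
            if run_kind is MutationKind.INSERTION and run_pos == j:
                run_len += 1
                run_seq.append(read[i])
            else:
                flush()
                run_kind, run_pos, run_len, run_seq = (
                    MutationKind.INSERTION, j, 1, [read[i]])
            i += 1
    flush()
    return events, j


def _left_normalize(events: List[MutationEvent], ref: str, ref_start: int) -> List[MutationEvent]:
    """Shift indels to their leftmost equivalent placement and re-merge.

    A deletion at p of length L moves to p-1 when ref[p-1] == ref[p+L-1]; an
    insertion rotates left when its last base equals the reference base to its
    left. Shifts stop at the alignment start or at the previous event.
    """
    out: List[MutationEvent] = []
    for ev in sorted(events):
        bound = out[-1].end() if out else ref_start
        if ev.kind is MutationKind.DELETION:
            p, L = ev.position, ev.length
            while p - 1 >= bound and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            ev = MutationEvent(position=p, kind=ev.kind, length=L)
        elif ev.kind is MutationKind.INSERTION:
            p, s = ev.position, ev.seq
            while p - 1 >= bound and p - 1 >= ref_start and s[-1] == ref[p - 1]:
                s = ref[p - 1] + s[:-1]
                p -= 1
            ev = MutationEvent(position=p, kind=ev.kind, length=ev.length, seq=s)
        # merge with previous event of same kind at contiguous positions
        if out:
            prev = out[-1]
            if (prev.kind is ev.kind and ev.kind is not MutationKind.INSERTION
                    and prev.position + prev.length == ev.position):
                out[-1] = MutationEvent(
                    position=prev.position, kind=prev.kind,
                    length=prev.length + ev.length, seq=prev.seq + ev.seq)
                continue
            if (prev.kind is ev.kind is MutationKind.INSERTION
                    and prev.position == ev.position):
                out[-1] = MutationEvent(
                    position=prev.position, kind=prev.kind,
                    length=prev.length + ev.length, seq=prev.seq + ev.seq)
                continue
        out.append(ev)
    return out


def align_read(read: str, site: TargetSite,
               params: AlignmentParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Align one read against the amplicon and extract mutation events.

    Returns a rejection (with reason code) for reads shorter than
    ``MIN_READ_LENGTH`` or whose total edited-base fraction exceeds
    ``params.max_read_mismatch_frac``.
    """
    read = read.upper()
    if len(read) < MIN_READ_LENGTH:
        return AlignmentResult(rejected="too_short")
    ref = site.amplicon_seq
    if read == ref:  # fast path: exact wild-type read
        return AlignmentResult(events=(), ref_start=0, ref_end=len(ref),
                               score=params.match * len(read))
    ops, ref_start, score = _dp_traceback(
        encode(read), encode(ref),
        params.match, params.mismatch, params.gap_open, params.gap_extend)
    events, ref_end = _extract_events(ops, read, ref, ref_start)
    events = _left_normalize(events, ref, ref_start)
    edited = sum(e.length for e in events)
    if edited / len(read) > params.max_read_mismatch_frac:
        return AlignmentResult(rejected="too_divergent")
    return AlignmentResult(events=tuple(events), ref_start=ref_start,
                           ref_end=ref_end, score=int(score))


# --------------------------------------------------------------------------
# collapsing


@dataclass(frozen=True)
class CollapseResult:
    """Retained mutant alleles (descending fraction), WT fraction and the
    retained-read denominator for one line x gene."""

    allele_calls: Tuple[AlleleCall, ...]
    wt_fraction: float
    wt_reads: int
    total_reads: int


def _clip_to_window(events: Iterable[MutationEvent], window: Tuple[int, int],
                    subs_are_mutations: bool) -> Tuple[MutationEvent, ...]:
    """Keep events with at least one base inside the cleavage window.

    Events partially overlapping the window are kept whole (identity would be
    scrambled by truncation); substitutions are treated as sequencing noise
    unless ``subs_are_mutations`` is set.
    """
    ws, we = window
    kept = []
    for ev in events:
        if ev.kind is MutationKind.SUBSTITUTION and not subs_are_mutations:
            continue
        if ev.kind is MutationKind.INSERTION:
            inside = ws <= ev.position <= we
        else:
            inside = ev.position < we and ev.end() > ws
        if inside:
            kept.append(ev)
    return tuple(kept)


def collapse_alleles(
    events_per_read: Sequence[Sequence[MutationEvent]],
    site: TargetSite,
    thresholds: ZygosityThresholds = ZygosityThresholds(),
    subs_are_mutations: bool = False,
) -> Optional[CollapseResult]:
    """Pool identical in-window event lists into alleles with fractions.

    Alleles that are simultaneously below ``allele_floor_fraction`` and below
    ``allele_floor_reads`` are treated as noise: the allele is dropped and its
    reads leave the denominator. Returns None (a no-call distinct from WT)
    when no reads survive. Idempotent: collapsing the per-read expansion of a
    result reproduces it.
    """
    counts: Counter = Counter()
    for events in events_per_read:
        allele = Allele(_clip_to_window(events, site.cleavage_window, subs_are_mutations))
        counts[allele] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    retained: Dict[Allele, int] = {}
    for allele, n in counts.items():
        if allele.is_mutant and (n / total < thresholds.allele_floor_fraction
                                 and n < thresholds.allele_floor_reads):
            continue  # noise allele: reads leave the denominator
        retained[allele] = n
    denom = sum(retained.values())
    if denom == 0:
        return None
    wt_reads = retained.get(WT_ALLELE, 0)
    mutant = sorted(
        ((a, n) for a, n in retained.items() if a.is_mutant),
        key=lambda kv: (-kv[1], kv[0].key()),
    )
    calls = tuple(AlleleCall(a, n, n / denom) for a, n in mutant)
    return CollapseResult(
        allele_calls=calls,
        wt_fraction=wt_reads / denom,
        wt_reads=wt_reads,
        total_reads=denom,
    )


def _align_pool(reads: Sequence[str], site: TargetSite,
                params: AlignmentParams) -> List[Tuple[MutationEvent, ...]]:
    """Align a pool, deduplicating identical reads (amplicon pools are highly
    redundant, so this is the main throughput lever)."""
    cache: Dict[str, Optional[Tuple[MutationEvent, ...]]] = {}
    out: List[Tuple[MutationEvent, ...]] = []
    for read in reads:
        if read not in cache:
            res = align_read(read, site, params)
            cache[read] = res.events if res.ok else None
        ev = cache[read]
        if ev is not None:
            out.append(ev)
    return out


def call_gene(reads: Sequence[str], site: TargetSite,
              params: AlignmentParams = DEFAULT_PARAMS,
              thresholds: ZygosityThresholds = ZygosityThresholds(),
              subs_are_mutations: bool = False) -> Optional[CollapseResult]:
    """Full per-pool path: align, filter, collapse. None means no-call."""
    events = _align_pool(reads, site, params)
    if not events:
        return None
    return collapse_alleles(events, site, thresholds, subs_are_mutations)


def pooled_wt_fraction(pools: Sequence[Sequence[str]], site: TargetSite,
                       params: AlignmentParams = DEFAULT_PARAMS,
                       thresholds: ZygosityThresholds = ZygosityThresholds(),
                       subs_are_mutations: bool = False) -> Optional[float]:
    """Combined WT read fraction across pooled plants, after the same
    clipping and filtering as per-plant calling. None when nothing aligns.

    Pooling then scanning equals scanning the concatenated pool, so the
    result is invariant to how plants were split into pools.
    """
    combined: List[str] = [r for pool in pools for r in pool]
    result = call_gene(combined, site, params, thresholds, subs_are_mutations)
    if result is None:
        return None
    return result.wt_fraction


def infer_pool_homozygosity(wt_fraction: float,
                            thresholds: ZygosityThresholds = ZygosityThresholds()) -> str:
    """Advisory call for a pooled sample: ``all-mutant-consistent`` when the
    WT read fraction is within sequencing noise, else ``wt-detected``.

    This is an inference about the pool, not a per-plant genotype.
    """
    if not 0.0 <= wt_fraction <= 1.0:
        raise InputError("wt_fraction must lie in [0, 1]")
    return ("all-mutant-consistent" if wt_fraction <= thresholds.wt_noise_max
            else "wt-detected")
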