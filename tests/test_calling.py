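"""Alignment event extraction and allele collapsing.

The alignment oracle is an independent score-only dynamic program (plain
Python, separate formulation): for random read/reference pairs the aligner's
score must equal the oracle optimum, and the reported events must reconstruct
the read exactly from the reference slice.
"""

import numpy as np
import pytest

from conftest import random_dna
from cas12mux.calling import (
    AlignmentParams,
    align_read,
    apply_events,
    collapse_alleles,
    call_gene,
    infer_pool_homozygosity,
    pooled_wt_fraction,
)
from cas12mux.model import (
    Allele,
    ConfigError,
    MutationEvent,
    MutationKind,
    TargetSite,
    WT_ALLELE,
    ZygosityThresholds,
)

PARAMS = AlignmentParams()


def oracle_score(read, ref, p=PARAMS):
    """Score-only affine semi-global DP (read global, reference ends free)."""
    m, n = len(read), len(ref)
    NEG = float("-inf")
    M = [0.0] * (n + 1)          # row i=0: free leading reference gap
    X = [NEG] * (n + 1)
    Y = [NEG] * (n + 1)
    for i in range(1, m + 1):
        prevM, prevX, prevY = M, X, Y
        M = [NEG] * (n + 1)
        X = [NEG] * (n + 1)
        Y = [NEG] * (n + 1)
        Y[0] = p.gap_open + (i - 1) * p.gap_extend
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = p.match if ri == ref[j - 1] else p.mismatch
            M[j] = max(prevM[j - 1], prevX[j - 1], prevY[j - 1]) + s
            X[j] = max(M[j - 1] + p.gap_open, X[j - 1] + p.gap_extend,
                       Y[j - 1] + p.gap_open)
            Y[j] = max(prevM[j] + p.gap_open, prevX[j] + p.gap_open,
                       prevY[j] + p.gap_extend)
    return max(max(M), max(X), max(Y))


def _site_for(amp):
    """Wrap a sequence carrying TTTC+23nt at position 10 as a TargetSite."""
    return TargetSite(
        gene_id="t", amplicon_id="t", amplicon_seq=amp, pam_seq="TTTC",
        spacer_seq=amp[14:37], strand="+", spacer_interval=(14, 37))


class TestAlignRead:
    def test_wt_read_has_no_events(self, site):
        res = align_read(site.amplicon_seq, site)
        assert res.ok and res.events == ()
        # a clean internal slice covering the window is also WT
        ws, we = site.cleavage_window
        res = align_read(site.amplicon_seq[ws - 10:we + 10], site)
        assert res.ok and res.events == ()

    def test_twelve_nt_deletion_at_cut_site(self, site):
        """An in-frame 12-bp deletion is recovered as one deletion event."""
        cut = site.spacer_interval[1] - 4  # PAM-distal cleavage region
        read = site.amplicon_seq[:cut] + site.amplicon_seq[cut + 12:]
        res = align_read(read, site)
        assert res.ok
        assert len(res.events) == 1
        ev = res.events[0]
        assert ev.kind is MutationKind.DELETION and ev.length == 12
        assert Allele(res.events).is_in_frame_3x

    def test_short_read_rejected(self, site):
        res = align_read("ACGT" * 5, site)
        assert not res.ok and res.rejected == "too_short"

    def test_divergent_read_rejected(self, site, rng):
        junk = random_dna(rng, len(site.amplicon_seq))
        res = align_read(junk, site)
        assert not res.ok and res.rejected == "too_divergent"

    def test_planted_indels_recovered_exactly(self, site, rng):
        """50 reads with one planted, left-normalized indel each: the aligner
        reports exactly the planted event."""
        from cas12mux.calling import _left_normalize

        ws, we = site.cleavage_window
        amp = site.amplicon_seq
        for _ in range(50):
            if rng.random() < 0.5:
                size = int(rng.integers(1, 25))
                pos = int(rng.integers(ws, we - size))
                ev = MutationEvent(pos, MutationKind.DELETION, size)
            else:
                size = int(rng.integers(1, 10))
                pos = int(rng.integers(ws + 1, we))
                ev = MutationEvent(pos, MutationKind.INSERTION, size,
                                   random_dna(rng, size))
            ev = _left_normalize([ev], amp, 0)[0]
            read = apply_events(amp, [ev])
            res = align_read(read, site)
            assert res.ok
            assert res.events == (ev,), (ev, res.events)

    @pytest.mark.parametrize("case_seed", range(6))
    def test_score_matches_oracle_and_reconstruction(self, case_seed):
        """Randomized suite: optimal score equals the independent DP oracle
        and events reconstruct the read from the aligned reference slice."""
        rng = np.random.default_rng(1000 + case_seed)
        amp = random_dna(rng, 10) + "TTTC" + random_dna(rng, 23) + random_dna(rng, 43)
        s = _site_for(amp)
        for _ in range(50):
            # mutated mid-length reads derived from the reference
            start = int(rng.integers(0, 20))
            length = int(rng.integers(30, len(amp) - start))
            read = list(amp[start:start + length])
            for _ in range(int(rng.integers(0, 6))):
                op = rng.random()
                pos = int(rng.integers(0, len(read)))
                if op < 0.4:
                    read[pos] = "ACGT"[int(rng.integers(4))]
                elif op < 0.7 and len(read) > 31:
                    del read[pos:pos + int(rng.integers(1, 4))]
                else:
                    read.insert(pos, "ACGT"[int(rng.integers(4))])
            read = "".join(read)
            if len(read) < 30:
                continue
            res = align_read(read, s, PARAMS)
            if not res.ok:
                continue
            assert res.score == oracle_score(read, amp)
            assert apply_events(amp, res.events, res.ref_start, res.ref_end) == read


class TestCollapse:
    def _events(self, site, pos_offset=0, size=4):
        ws, _ = site.cleavage_window
        return (MutationEvent(ws + 5 + pos_offset, MutationKind.DELETION, size),)

    def test_single_allele_fraction_one(self, site):
        ev = self._events(site)
        res = collapse_alleles([ev] * 100, site)
        assert len(res.allele_calls) == 1
        assert res.allele_calls[0].fraction == 1.0
        assert res.wt_fraction == 0.0

    def test_two_alleles_plus_wt_fractions(self, site):
        a = self._events(site, 0, 4)
        b = self._events(site, 3, 5)
        reads = [a] * 48 + [b] * 47 + [()] * 5
        res = collapse_alleles(reads, site)
        fracs = sorted((c.fraction for c in res.allele_calls), reverse=True)
        assert fracs == pytest.approx([0.48, 0.47])
        assert res.wt_fraction == pytest.approx(0.05)

    def test_floor_drops_singleton_and_shrinks_denominator(self, site):
        a = self._events(site, 0, 4)
        noise = self._events(site, 7, 2)
        reads = [a] * 98 + [noise] * 2
        res = collapse_alleles(reads, site)
        assert len(res.allele_calls) == 1
        assert res.total_reads == 98
        assert res.allele_calls[0].fraction == 1.0

    def test_floor_keeps_allele_meeting_read_count(self, site):
        # 10 reads is at the read floor: kept even below the fraction floor
        a = self._events(site, 0, 4)
        minor = self._events(site, 7, 2)
        reads = [a] * 290 + [minor] * 10
        res = collapse_alleles(reads, site)
        assert len(res.allele_calls) == 2

    def test_out_of_window_events_count_as_wt(self, site):
        ws, we = site.cleavage_window
        outside = (MutationEvent(we + 20, MutationKind.DELETION, 3),)
        res = collapse_alleles([outside] * 10, site)
        assert res.allele_calls == ()
        assert res.wt_fraction == 1.0

    def test_substitutions_noise_by_default_mutant_on_switch(self, site):
        ws, _ = site.cleavage_window
        sub = (MutationEvent(ws + 5, MutationKind.SUBSTITUTION, 1, "A"),)
        res = collapse_alleles([sub] * 20, site)
        assert res.wt_fraction == 1.0
        res2 = collapse_alleles([sub] * 20, site, subs_are_mutations=True)
        assert res2.wt_fraction == 0.0 and len(res2.allele_calls) == 1

    def test_no_reads_is_no_call(self, site):
        assert collapse_alleles([], site) is None

    def test_idempotent(self, site):
        a = self._events(site, 0, 4)
        b = self._events(site, 3, 5)
        reads = [a] * 48 + [b] * 47 + [()] * 5
        first = collapse_alleles(reads, site)
        expanded = (
            [c.allele.events for c in first.allele_calls for _ in range(c.read_count)]
            + [()] * first.wt_reads)
        second = collapse_alleles(expanded, site)
        assert second == first

    def test_fractions_sum_to_one(self, site, rng):
        reads = []
        for k in range(5):
            reads += [self._events(site, k, k + 1)] * int(rng.integers(1, 40))
        reads += [()] * 17
        res = collapse_alleles(reads, site)
        total = sum(c.fraction for c in res.allele_calls) + res.wt_fraction
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPooledScan:
    def test_all_mutant_pool_zero_wt(self, site):
        ws, _ = site.cleavage_window
        mut = apply_events(site.amplicon_seq,
                           [MutationEvent(ws + 5, MutationKind.DELETION, 7)])
        pools = [[mut] * 50 for _ in range(5)]
        assert pooled_wt_fraction(pools, site) == 0.0

    def test_one_wt_plant_among_nineteen(self, site):
        ws, _ = site.cleavage_window
        mut = apply_events(site.amplicon_seq,
                           [MutationEvent(ws + 5, MutationKind.DELETION, 7)])
        pools = [[mut] * 50 for _ in range(19)] + [[site.amplicon_seq] * 50]
        assert pooled_wt_fraction(pools, site) == pytest.approx(0.05)

    def test_all_wt_pool(self, site):
        assert pooled_wt_fraction([[site.amplicon_seq] * 30], site) == 1.0

    def test_pooling_order_invariance(self, site):
        ws, _ = site.cleavage_window
        mut = apply_events(site.amplicon_seq,
                           [MutationEvent(ws + 5, MutationKind.DELETION, 7)])
        wt = site.amplicon_seq
        pools = [[mut] * 10 + [wt] * 5, [wt] * 3 + [mut] * 2]
        concat = [[r for pool in pools for r in pool]]
        assert pooled_wt_fraction(pools, site) == pooled_wt_fraction(concat, site)

    def test_inference_thresholds(self):
        assert infer_pool_homozygosity(0.0) == "all-mutant-consistent"
        assert infer_pool_homozygosity(0.5) == "wt-detected"
        assert infer_pool_homozygosity(0.004) == "all-mutant-consistent"
        assert infer_pool_homozygosity(0.006) == "wt-detected"


def test_alignment_params_validation():
    with pytest.raises(ConfigError):
        AlignmentParams(gap_open=-1, gap_extend=-6)
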