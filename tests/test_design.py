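"""Guide design: PAM scanning, dual targets, off-targets, arrays, oligos.

Brute-force oracles (explicit sliding-window loops, IUPAC sets) validate the
vectorized implementations; fixtures with planted mismatches validate the
dual-target zone logic.
"""

import numpy as np
import pytest

from conftest import random_dna
from cas12mux.design import (
    DEFAULT_PARTS,
    CrRNAArray,
    CrRNAUnit,
    assemble_array,
    design_oligos,
    enumerate_offtargets,
    find_dual_targets,
    parse_array,
    plan_six_guide_assembly,
    scan_pam_sites,
    simulate_ligation,
    split_six,
)
from cas12mux.model import ConfigError, DesignError, IUPAC, InputError, revcomp

DR = DEFAULT_PARTS["direct_repeat"]


# --------------------------------------------------------------------------
# oracles


def oracle_scan(seq, pattern="TTTV", L=23):
    """Brute-force PAM scan: (plus_strand_spacer_start, strand) tuples."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - len(pattern) - L + 1):
            if all(s[i + k] in IUPAC[c] for k, c in enumerate(pattern)):
                start = i + len(pattern)
                if strand == "+":
                    out.add((start, "+"))
                else:
                    out.add((n - (start + L), "-"))
    return out


def oracle_offtargets(spacer, subjects, max_mm, require_pam, pattern="TTTV"):
    out = set()
    L = len(spacer)
    for sid, seq in subjects.items():
        n = len(seq)
        if n < L + len(pattern):
            continue
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for j in range(n - L + 1):
                mm = sum(1 for a, b in zip(s[j:j + L], spacer) if a != b)
                if mm > max_mm:
                    continue
                if require_pam:
                    if j < len(pattern):
                        continue
                    if not all(s[j - len(pattern) + k] in IUPAC[c]
                               for k, c in enumerate(pattern)):
                        continue
                pos = j if strand == "+" else n - (j + L)
                out.add((sid, pos, strand, mm))
    return out


# --------------------------------------------------------------------------
# PAM scanning


class TestScanPamSites:
    def test_no_pam_no_sites(self):
        assert scan_pam_sites("AC" * 100, both_strands=False) == []

    def test_single_forced_site(self, rng):
        seq = "TTTC" + random_dna(rng, 23)
        (site,) = scan_pam_sites(seq, both_strands=False)
        assert site.spacer_interval == (4, 27)
        assert site.pam_seq == "TTTC" and site.strand == "+"

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(501)
        for _ in range(10):
            seq = random_dna(rng, 2000)
            got = {(s.spacer_interval[0], s.strand) for s in scan_pam_sites(seq)}
            assert got == oracle_scan(seq)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ConfigError, match="IUPAC"):
            scan_pam_sites("ACGT" * 20, pam_pattern="TTTZ")


# --------------------------------------------------------------------------
# dual targets


def _homolog_pair(rng, mismatch_spacer_pos):
    """Two 'homologs' identical except at one spacer position of the single
    shared protospacer (1 = PAM-proximal)."""
    spacer = random_dna(rng, 23)
    seq_a = random_dna(rng, 40).replace("TTT", "ACG") + "TTTC" + spacer \
        + random_dna(rng, 40).replace("TTT", "ACG")
    k = mismatch_spacer_pos - 1
    base = spacer[k]
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    seq_b = seq_a[:44 + k] + alt + seq_a[44 + k + 1:]
    return seq_a, seq_b


class TestFindDualTargets:
    def test_identical_homologs_zero_mismatches(self, rng):
        seq = random_dna(rng, 300)
        pairs = find_dual_targets(seq, seq)
        assert pairs
        assert all(p.mismatch_positions == () for p in pairs)

    def test_distal_mismatch_found(self):
        rng = np.random.default_rng(61)
        seq_a, seq_b = _homolog_pair(rng, mismatch_spacer_pos=21)
        pairs = find_dual_targets(seq_a, seq_b)
        with_mm = [p for p in pairs if p.mismatch_positions]
        assert len(with_mm) == 1
        assert with_mm[0].mismatch_positions == (21,)

    def test_proximal_mismatch_rejected(self):
        rng = np.random.default_rng(62)
        seq_a, seq_b = _homolog_pair(rng, mismatch_spacer_pos=3)
        pairs = find_dual_targets(seq_a, seq_b)
        assert all(p.mismatch_positions == () for p in pairs)

    def test_symmetric_flag_swapping(self):
        rng = np.random.default_rng(63)
        seq_a, seq_b = _homolog_pair(rng, mismatch_spacer_pos=22)
        fwd = find_dual_targets(seq_a, seq_b, symmetric=True)
        rev = find_dual_targets(seq_b, seq_a, symmetric=True)
        key = lambda p: (p.site_a.spacer_seq, p.site_b.spacer_seq, p.mismatch_positions)
        assert sorted(map(key, fwd)) == sorted(
            (k[1], k[0], k[2]) for k in map(key, rev))

    def test_zone_beyond_spacer_rejected(self):
        with pytest.raises(ConfigError):
            find_dual_targets("A" * 100, "A" * 100, distal_zone_start=24)


# --------------------------------------------------------------------------
# off-targets


class TestEnumerateOfftargets:
    def test_perfect_site_single_hit(self, rng):
        spacer = random_dna(rng, 23)
        subject = "GG" + "TTTC" + spacer + "GG"
        hits = enumerate_offtargets(spacer, {"s": subject})
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 1
        assert exact[0].position == 6 and exact[0].strand == "+"

    def test_planted_two_mismatch_found_five_rejected(self):
        rng = np.random.default_rng(71)
        spacer = random_dna(rng, 23)

        def mutate(s, k):
            out = list(s)
            for i in range(k):
                out[2 + i * 3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[2 + i * 3]]
            return "".join(out)

        subjects = {
            "near": "AA" + "TTTG" + mutate(spacer, 2) + "CCAA",
            "far": "AA" + "TTTG" + mutate(spacer, 5) + "CCAA",
        }
        hits = enumerate_offtargets(spacer, subjects, max_mm=3)
        assert [(h.subject_id, h.mismatches) for h in hits] == [("near", 2)]

    def test_empty_subjects(self):
        assert enumerate_offtargets("ACGT" * 5 + "AAA", {}) == []

    def test_short_subject_warned_and_skipped(self, rng):
        spacer = random_dna(rng, 23)
        with pytest.warns(UserWarning, match="skipped"):
            hits = enumerate_offtargets(spacer, {"tiny": "ACGT"})
        assert hits == []

    def test_zero_mismatch_pam_gated_reduces_to_scan(self):
        """max_mm=0 with the PAM required finds exactly the scan sites whose
        spacer equals the query."""
        rng = np.random.default_rng(72)
        seq = random_dna(rng, 2000)
        sites = scan_pam_sites(seq)
        assert sites, "fixture must contain PAM sites"
        target = sites[len(sites) // 2]
        hits = enumerate_offtargets(target.spacer_seq, {"s": seq}, max_mm=0)
        expected = {
            (s.spacer_interval[0], s.strand)
            for s in sites if s.spacer_seq == target.spacer_seq}
        assert {(h.position, h.strand) for h in hits} == expected

    def test_matches_brute_force(self):
        rng = np.random.default_rng(73)
        spacer = random_dna(rng, 23)
        for require_pam in (True, False):
            subjects = {f"s{i}": random_dna(rng, 1500) for i in range(3)}
            # plant one close site to make the comparison non-trivial
            planted = "TTTA" + spacer[:20] + "AAA"
            subjects["s0"] = subjects["s0"][:700] + planted + subjects["s0"][700:]
            got = {(h.subject_id, h.position, h.strand, h.mismatches)
                   for h in enumerate_offtargets(spacer, subjects, 3, require_pam)}
            assert got == oracle_offtargets(spacer, subjects, 3, require_pam)


# --------------------------------------------------------------------------
# arrays and oligos


def _spacers(rng, n=6):
    return [random_dna(rng, 23) for _ in range(n)]


class TestSplitSix:
    def test_definitional_split(self, rng):
        sp = _spacers(rng)
        a1, a2 = split_six(sp)
        assert a1.promoter_id == "U6-26" and a2.promoter_id == "U6-29"
        assert list(a1.spacers) == sp[:3] and list(a2.spacers) == sp[3:]

    def test_swapped_order_same_multiset(self, rng):
        sp = _spacers(rng)
        swapped = sp[::-1]  # the alternative array ordering
        a1, a2 = split_six(sp)
        b1, b2 = split_six(swapped)
        assert sorted(a1.spacers + a2.spacers) == sorted(b1.spacers + b2.spacers)
        assert (a1.spacers, a2.spacers) != (b1.spacers, b2.spacers)

    def test_wrong_arity(self, rng):
        with pytest.raises(InputError, match="6"):
            split_six(_spacers(rng, 5))


class TestAssembleParse:
    def test_single_unit_render(self, rng):
        sp = random_dna(rng, 23)
        arr = CrRNAArray("U6-26", (CrRNAUnit(sp),))
        rendered = assemble_array(arr)
        assert rendered == arr.flank_5 + DR + sp + arr.flank_3

    def test_roundtrip_three_units(self, rng):
        sp = _spacers(rng, 3)
        arr = CrRNAArray("U6-26", tuple(CrRNAUnit(s) for s in sp))
        seq = assemble_array(arr)
        assert parse_array(seq, DR, arr.flank_5, arr.flank_3) == sp

    def test_dr_inside_spacer_refused(self):
        bad = ("AC" + DR + "A" * (21 - len(DR)))[:23].ljust(23, "A")
        assert DR in bad
        arr = CrRNAArray("U6-26", (CrRNAUnit(bad),))
        with pytest.raises(DesignError, match="ambiguous"):
            assemble_array(arr)


class TestOligos:
    def test_single_spacer_structure(self, rng):
        sp = random_dna(rng, 23)
        (pair,) = design_oligos(sp)
        assert pair.top_strand == DEFAULT_PARTS["start_overhang"] + sp
        assert pair.bottom_strand == DEFAULT_PARTS["end_overhang"] + revcomp(sp)

    def test_array_ligation_reconstructs_core(self, rng):
        sp = _spacers(rng)
        a1, _ = split_six(sp)
        pairs = design_oligos(a1)
        assembled = simulate_ligation(
            pairs, DEFAULT_PARTS["start_overhang"], DEFAULT_PARTS["end_overhang"])
        assert assembled == a1.core()

    def test_ligation_order_independent(self, rng):
        sp = _spacers(rng)
        a1, _ = split_six(sp)
        pairs = design_oligos(a1)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        assembled = simulate_ligation(
            shuffled, DEFAULT_PARTS["start_overhang"], DEFAULT_PARTS["end_overhang"])
        assert assembled == a1.core()

    def test_unresolvable_overhang_collision_rejected(self):
        # two identical homopolymer spacers offer only one candidate overhang
        sp = ["TTGG" + "C" * 19, "G" * 23, "G" * 23]
        arr = CrRNAArray("U6-26", tuple(CrRNAUnit(s) for s in sp))
        with pytest.raises(DesignError, match="ambiguous"):
            design_oligos(arr)

    def test_full_six_guide_plan(self, rng):
        plan = plan_six_guide_assembly(_spacers(rng))
        a1, a2 = plan["arrays"]
        assert plan["cores"][a1.promoter_id] == a1.core()
        assert plan["cores"][a2.promoter_id] == a2.core()
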