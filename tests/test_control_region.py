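"""CR domain partitioning, box scanning, C-strings and tandem repeats."""

import numpy as np
import pytest

from mitochar.control_region import (
    CRDomainSpec,
    DEFAULT_DOMAIN_SPEC,
    MotifDef,
    find_cstring,
    find_tandem_repeats,
    load_motif_library,
    partition_domains,
    scan_motifs,
)
from mitochar.synth_data import (
    CSTRING,
    FUSCATUS_REPEAT_UNIT,
    PROREGULUS_REPEAT_UNIT,
    random_sequence,
)

UNIFORM = {b: 0.25 for b in "ACGT"}


def rand(seed: int, n: int) -> str:
    return random_sequence(np.random.default_rng(seed), n, UNIFORM)


class TestDomains:
    def test_reported_boundaries_partition_1104nt_cr(self):
        cr = rand(0, 1104)
        parts = partition_domains(cr, DEFAULT_DOMAIN_SPEC)
        assert [len(parts[k]) for k in ("I", "II", "III")] == [424, 435, 245]
        assert "".join(parts.values()) == cr

    def test_even_split_reassembly(self):
        cr = rand(1, 300)
        spec = CRDomainSpec((1, 100), (101, 200), (201, 300))
        parts = partition_domains(cr, spec)
        assert "".join(parts.values()) == cr

    def test_boundary_beyond_sequence_raises(self):
        with pytest.raises(IndexError):
            partition_domains(rand(2, 1104), CRDomainSpec((1, 424), (425, 859), (860, 1200)))

    def test_noncontiguous_domains_rejected(self):
        with pytest.raises(ValueError):
            CRDomainSpec((1, 424), (430, 859), (860, 1104))


class TestMotifScan:
    def test_planted_bird_similarity_box_found_exactly(self):
        box = "CACTGATGCACTTTG"
        cr = rand(3, 1104)
        cr = cr[:699] + box + cr[699 + len(box):]
        hits = scan_motifs(
            cr, [MotifDef("bird-similarity", box, 3, "II")],
            domain_spec=DEFAULT_DOMAIN_SPEC,
        )
        (hit,) = hits
        assert (hit.start, hit.mismatches, hit.domain) == (700, 0, "II")

    def test_no_hit_beyond_mismatch_cap(self):
        assert scan_motifs("TTTT", [MotifDef("x", "AAAA", 1)]) == []

    def test_planted_edits_counted(self):
        lib = load_motif_library()
        fbox = next(m for m in lib if m.box_name == "F")
        pattern = list(fbox.pattern)
        pattern[4] = "A" if pattern[4] != "A" else "C"
        pattern[19] = "A" if pattern[19] != "A" else "C"
        cr = rand(4, 600)
        cr = cr[:99] + "".join(pattern) + cr[99 + len(pattern):]
        (hit,) = scan_motifs(cr, [fbox])
        assert hit.start == 100
        assert hit.mismatches == 2

    def test_zero_mismatch_agrees_with_substring_search(self):
        """Exact-match oracle: with max_mismatch=0 the scanner must find
        exactly the leftmost occurrence reported by str.find."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = random_sequence(rng, 400, UNIFORM)
            pat = random_sequence(rng, 6, UNIFORM)
            hits = scan_motifs(seq, [MotifDef("p", pat, 0)])
            idx = seq.find(pat)
            if idx == -1:
                assert hits == []
            else:
                assert hits[0].start == idx + 1
                assert hits[0].mismatches == 0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("ACGT", [])


class TestCString:
    def test_printed_cstring_found_with_one_interruption(self):
        hits = find_cstring(CSTRING, min_len=10, max_interruptions=1)
        assert hits == [(1, 18, 18)]

    def test_short_run_below_min_len(self):
        assert find_cstring("CCCCC", min_len=10) == []

    def test_two_interruptions_best_window_only(self):
        hits = find_cstring("CCCTCCCTCCC", min_len=5, max_interruptions=1)
        assert hits[0][2] == 7  # best single-interruption window, not all 11
        assert hits[0][0] == 1

    def test_interruption_must_be_single_base(self):
        # a two-base gap cannot be bridged
        hits = find_cstring("CCCCCCTTCCCCCC", min_len=10, max_interruptions=1)
        assert hits == []

    def test_planted_cstring_in_synthetic_cr1(self, synth_genome):
        rec, truth = synth_genome
        cr1 = rec.feature_sequence("CR1")
        span = truth.cstring_span
        hits = find_cstring(cr1, min_len=10, max_interruptions=1)
        assert any(s <= span[0] and e >= span[1] for s, e, _ in hits)


class TestTandemRepeats:
    def test_two_exact_copies_of_printed_46nt_unit(self):
        seq = rand(42, 100) + FUSCATUS_REPEAT_UNIT * 2 + rand(43, 100)
        reps = find_tandem_repeats(seq, 10, 200, 1.8, 80)
        assert len(reps) == 1
        top = reps[0]
        assert top.period == 46
        assert top.copy_number_1dp == 2.0
        assert top.consensus == FUSCATUS_REPEAT_UNIT

    def test_fractional_copies_of_printed_45nt_unit(self):
        u = PROREGULUS_REPEAT_UNIT
        seq = rand(44, 100) + u * 2 + u[:14] + rand(45, 100)
        reps = find_tandem_repeats(seq, 10, 200, 1.8, 80)
        top = reps[0]
        assert top.period == 45
        assert top.copy_number_1dp == pytest.approx(2.3)

    def test_random_sequence_has_no_long_period_repeat(self):
        seq = rand(1, 500)
        reps = find_tandem_repeats(seq, 10, 200, 1.8, 90)
        assert [r for r in reps if r.period >= 10 and r.copy_number >= 1.8] == []

    @pytest.mark.parametrize("period", [10, 20, 45, 46])
    @pytest.mark.parametrize("copies", [2.0, 2.5, 3.0])
    def test_parameter_recovery_planted_repeats(self, period, copies):
        recovered = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 * period + int(copies * 10) + seed)
            unit = random_sequence(rng, period, UNIFORM)
            rep_len = int(round(period * copies))
            planted = (unit * (rep_len // period + 2))[:rep_len]
            seq = (
                random_sequence(rng, 80, UNIFORM)
                + planted
                + random_sequence(rng, 80, UNIFORM)
            )
            reps = find_tandem_repeats(seq, 5, 120, 1.8, 80)
            if not reps:
                continue
            top = reps[0]
            # a planted unit may itself contain a shorter internal period;
            # accept the fundamental period or the planted one
            if top.period <= period and abs(
                top.period * top.copy_number - rep_len
            ) <= 4:
                recovered += 1
        assert recovered >= 19

    def test_copy_number_times_period_is_region_length(self):
        seq = rand(42, 100) + FUSCATUS_REPEAT_UNIT * 2 + rand(43, 100)
        (rep,) = find_tandem_repeats(seq, 10, 200, 1.8, 80)
        assert rep.copy_number * rep.period == rep.end - rep.start + 1

    def test_consensus_of_identical_units_is_the_unit(self):
        unit = "ACGTTGCAGG"
        seq = rand(9, 60) + unit * 3 + rand(10, 60)
        reps = find_tandem_repeats(seq, 5, 50, 1.8, 80)
        top = reps[0]
        assert top.period == len(unit)
        assert top.consensus == unit

    def test_invalid_period_bounds_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT" * 50, 1, 0)


def test_motif_library_loads_with_study_and_literature_boxes():
    lib = load_motif_library()
    names = {m.box_name for m in lib}
    assert {"C-string", "F", "E", "D", "C", "bird-similarity", "B", "CSB1"} <= names
    assert {"CSB2", "CSB3", "OH", "LSP", "HSP"} <= names
    for m in lib:
        assert m.max_mismatch < len(m.pattern)
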