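import numpy as np
import pytest

from _oracles import brute_force_runs, random_repeat_rich_sequence
from ssrscape.motifs import revcomp
from ssrscape.scan import (
    DEFAULT_MIN_REPEATS,
    ScanConfig,
    resolve_and_merge,
    scan,
    scan_sequence,
)


def runs_as_tuples(loci):
    return sorted((l.start, l.end, l.motif, l.n_repeats) for l in loci)


def filler(n):
    """Aperiodic spacer containing no qualifying repeat run (period 8 > max unit)."""
    return ("AACGGTCT" * (n // 8 + 1))[:n]


class TestScanSequence:
    def test_mono_at_threshold(self):
        loci = scan_sequence("A" * 10)
        assert runs_as_tuples(loci) == [(1, 10, "A", 10)]

    def test_mono_below_threshold(self):
        assert scan_sequence("A" * 9) == []

    def test_tri_at_threshold(self):
        loci = scan_sequence("ACG" * 6)
        assert runs_as_tuples(loci) == [(1, 18, "ACG", 6)]

    def test_n_breaks_runs(self):
        seq = "AT" * 3 + "N" + "AT" * 4  # both fragments below the di threshold
        assert scan_sequence(seq) == []

    def test_partial_trailing_unit_does_not_extend(self):
        loci = scan_sequence("ACG" * 6 + "AC")
        assert runs_as_tuples(loci) == [(1, 18, "ACG", 6)]

    def test_soft_masked_lowercase_scanned(self):
        assert runs_as_tuples(scan_sequence("a" * 10)) == [(1, 10, "A", 10)]

    def test_empty_sequence(self):
        assert scan_sequence("") == []

    def test_nonprimitive_unit_reported_at_smallest_period(self):
        loci = scan_sequence("AT" * 8)
        assert runs_as_tuples(loci) == [(1, 16, "AT", 8)]
        assert all(l.unit_size == 2 for l in loci)

    def test_offset_coordinates_one_based(self):
        loci = scan_sequence("GC" + "TTA" * 7)
        assert runs_as_tuples(loci) == [(3, 23, "TTA", 7)]


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sequences(self, rng):
        cfg = ScanConfig()
        for _ in range(250):
            seq = random_repeat_rich_sequence(rng, max_len=400)
            got = runs_as_tuples(scan_sequence(seq, cfg))
            expected = brute_force_runs(seq, cfg.min_repeats)
            assert got == expected, seq

    def test_strand_symmetry(self, rng):
        """Reverse complement preserves the class/length multiset and mirrors
        each locus (up to the < unit-size shift a partial trailing unit causes,
        since whole-unit truncation happens at opposite region ends)."""
        for _ in range(50):
            seq = random_repeat_rich_sequence(rng, max_len=400).replace("N", "A")
            fwd = scan_sequence(seq)
            rev = scan_sequence(revcomp(seq))
            n = len(seq)
            assert sorted((l.motif_class.canonical, l.length) for l in fwd) == sorted(
                (l.motif_class.canonical, l.length) for l in rev
            )
            rev_keys = [(l.motif_class.canonical, l.length, l.start) for l in rev]
            for l in fwd:
                mirror_start = n - l.end + 1
                assert any(
                    c == l.motif_class.canonical and ln == l.length
                    and abs(s - mirror_start) < l.unit_size
                    for c, ln, s in rev_keys
                )

    def test_threshold_monotonicity(self, rng):
        """Raising any minimum repeat count never adds loci."""
        base = ScanConfig()
        for k in range(1, 7):
            higher = dict(DEFAULT_MIN_REPEATS)
            higher[k] += 1
            stricter = ScanConfig(min_repeats=higher)
            for _ in range(20):
                seq = random_repeat_rich_sequence(rng, max_len=300)
                assert len(scan_sequence(seq, stricter)) <= len(scan_sequence(seq, base))


class TestResolveAndMerge:
    def test_single_run_unchanged(self):
        runs = scan_sequence("A" * 12)
        assert resolve_and_merge(runs) == runs

    def test_distant_runs_stay_perfect(self):
        seq = "A" * 12 + filler(120) + "A" * 12  # 120 bp apart > default 100
        out = scan("G" + seq)  # leading G so flanks differ
        kinds = [l.kind for l in out]
        assert kinds == ["perfect", "perfect"]

    def test_nearby_runs_merge_into_compound(self):
        seq = "G" + "AC" * 8 + "GT" + "AG" * 9 + "C"
        out = scan(seq)
        assert len(out) == 1
        (c,) = out
        assert c.kind == "compound"
        assert len(c.sub_loci) == 2
        assert c.start == c.sub_loci[0].start
        assert c.end == c.sub_loci[-1].end
        assert c.length == c.end - c.start + 1
        assert c.repeat_bp == sum(s.length for s in c.sub_loci)

    def test_merge_respects_max_interruption(self):
        seq = "G" + "AC" * 8 + filler(30) + "AG" * 9
        tight = ScanConfig(max_interruption=10)
        loose = ScanConfig(max_interruption=100)
        assert [l.kind for l in scan(seq, tight)] == ["perfect", "perfect"]
        assert [l.kind for l in scan(seq, loose)] == ["compound"]

    def test_overlap_resolution_prefers_longer_run(self):
        # poly-A (12 bp) overlapping an AT run (20 bp sharing the A tail)
        seq = "G" + "A" * 12 + "TA" * 9 + "CCG"
        out = scan_sequence(seq)
        resolved = resolve_and_merge(out, ScanConfig(max_interruption=0))
        spans = [(l.start, l.end) for l in resolved]
        for i in range(len(spans) - 1):
            assert spans[i][1] < spans[i + 1][0]
        assert max(l.length for l in resolved) == max(l.length for l in out)

    def test_output_sorted_and_disjoint(self, rng):
        cfg = ScanConfig(max_interruption=5)
        for _ in range(100):
            seq = random_repeat_rich_sequence(rng, max_len=500)
            out = resolve_and_merge(scan_sequence(seq, cfg), cfg)
            for a, b in zip(out, out[1:]):
                assert a.end < b.start


class TestScanConfig:
    def test_default_thresholds(self):
        assert ScanConfig().min_repeats == {1: 10, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4}

    def test_rejects_negative_interruption(self):
        with pytest.raises(ValueError):
            ScanConfig(max_interruption=-1)

    def test_rejects_threshold_below_two(self):
        with pytest.raises(ValueError):
            ScanConfig(min_repeats={1: 1, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4})
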