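import math

import numpy as np
import pytest

from _oracles import gotoh_score
from ssrscape.ltr import (
    DatingConfig,
    align_termini,
    bin_by_age,
    count_differences,
    divergence,
    insertion_time,
    log_fit,
)
from ssrscape.motifs import canonical_motif
from ssrscape.scan import SSRLocus
from ssrscape.simulate import simulate_ltr_pair


def _score(aln, cfg):
    """Score of a gapped alignment under open/extend-per-position scoring."""
    total, in_gap = 0.0, False
    for x, y in zip(*aln):
        if x == "-" or y == "-":
            total += cfg.gap_extend if in_gap else cfg.gap_open
            in_gap = True
        else:
            total += cfg.match if x == y else cfg.mismatch
            in_gap = False
    return total


class TestAlignTermini:
    def test_identical_strings_no_differences(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=100))
        aln = align_termini(s, s)
        assert count_differences(aln) == (0, 100)

    def test_single_substitution(self):
        aln = align_termini("ACGT", "ACTT")
        diff, ungapped = count_differences(aln)
        assert (diff, ungapped) == (1, 4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_termini("", "ACGT")

    def test_score_matches_full_matrix_dp_oracle(self, rng):
        cfg = DatingConfig()
        for _ in range(60):
            n, m = rng.integers(1, 51, size=2)
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            aln = align_termini(a, b, cfg)
            expected = gotoh_score(a, b, cfg.match, cfg.mismatch,
                                   cfg.gap_open, cfg.gap_extend)
            assert _score(aln, cfg) == pytest.approx(expected)


class TestDivergence:
    def test_zero_mismatches(self):
        assert divergence(("ACGT", "ACGT")) == 0.0

    def test_p_distance_one_in_hundred(self):
        a = "A" * 100
        b = "C" + "A" * 99
        assert divergence((a, b)) == pytest.approx(0.01)

    def test_gap_columns_excluded(self):
        aln = ("AC-GT", "ACCGA")  # 4 ungapped columns, 1 mismatch
        assert divergence(aln) == pytest.approx(0.25)

    def test_jukes_cantor_closed_form(self):
        a = "A" * 100
        b = "C" + "A" * 99
        expected = -0.75 * math.log(1 - 0.04 / 3)
        assert divergence((a, b), model="jukes-cantor") == pytest.approx(expected)
        assert divergence((a, b), model="jukes-cantor") == pytest.approx(0.010067, abs=1e-6)

    def test_jukes_cantor_undefined_beyond_saturation(self):
        aln = ("AAAA", "CCCC")
        with pytest.raises(ValueError):
            divergence(aln, model="jukes-cantor")


class TestInsertionTime:
    def test_zero_divergence_zero_age(self):
        assert insertion_time(0.0) == 0.0

    @pytest.mark.parametrize(("d", "mya"), [(0.026, 1.0), (0.0104, 0.4)])
    def test_printed_rate_arithmetic(self, d, mya):
        assert insertion_time(d) / 1e6 == pytest.approx(mya)

    def test_monotone_in_divergence_and_rate(self):
        assert insertion_time(0.02) > insertion_time(0.01)
        fast = DatingConfig(mutation_rate=2.6e-8)
        assert insertion_time(0.02, fast) < insertion_time(0.02)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(-0.1)


def _pair(eid, seq_id, start, end, age_mya, r=1.3e-8):
    from ssrscape.ltr import LTRPair

    d = 2 * r * age_mya * 1e6
    return LTRPair(element_id=eid, seq_id=seq_id, start=start, end=end,
                   five_prime=(start, start + 99), three_prime=(end - 99, end),
                   divergence=d, age_years=age_mya * 1e6)


def _locus(seq_id, start, end):
    return SSRLocus(seq_id=seq_id, start=start, end=end, motif="AT",
                    motif_class=canonical_motif("AT"),
                    n_repeats=(end - start + 1) // 2)


class TestBinByAge:
    def test_count_ratio_by_construction(self):
        pairs = [_pair("e1", "chr", 1_000, 6_000, age_mya=0.05)]
        loci = [_locus("chr", 2_000, 2_019), _locus("chr", 3_000, 3_019)]
        bins = bin_by_age(pairs, loci)
        assert bins.loc["0.0-0.1", "n_ltr"] == 1
        assert bins.loc["0.0-0.1", "count_ratio"] == pytest.approx(2.0)

    def test_partial_overlap_excluded(self):
        pairs = [_pair("e1", "chr", 1_000, 6_000, age_mya=0.05)]
        loci = [_locus("chr", 990, 1_009)]  # straddles the element edge
        bins = bin_by_age(pairs, loci)
        assert bins.loc["0.0-0.1", "n_ssr"] == 0

    def test_bin_assignment_edges(self):
        pairs = [_pair(f"e{i}", "chr", 1_000 * i, 1_000 * i + 500, age)
                 for i, age in enumerate([0.0, 0.05, 0.1, 0.95, 1.0, 2.0], 1)]
        bins = bin_by_age(pairs, [])
        assert bins.loc["0.0-0.1", "n_ltr"] == 2   # 0.0 and 0.05
        assert bins.loc["0.1-0.2", "n_ltr"] == 1   # 0.1 goes to [0.1, 0.2)
        assert bins.loc["0.9-1.0", "n_ltr"] == 1
        assert bins.loc["overflow", "n_ltr"] == 2  # 1.0 and 2.0

    def test_totals_conserved(self, small_genome):
        from ssrscape.ltr import date_element
        from ssrscape.scan import scan_genome

        g = small_genome
        loci = scan_genome(g.sequences)
        pairs = []
        for r in g.ltr_table.itertuples():
            seq = g.sequences[r.seq_id]
            pairs.append(date_element(
                r.element_id, r.seq_id, (r.start, r.end),
                (r.ltr5_start, r.ltr5_end), (r.ltr3_start, r.ltr3_end),
                seq[r.ltr5_start - 1:r.ltr5_end], seq[r.ltr3_start - 1:r.ltr3_end]))
        bins = bin_by_age(pairs, loci)
        inside = sum(
            1 for l in loci for p in pairs
            if l.seq_id == p.seq_id and l.start >= p.start and l.end <= p.end
        )
        assert int(bins.n_ssr.sum()) == inside
        assert int(bins.n_ltr.sum()) == len(pairs)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_by_age([], [], bin_width_mya=0)


class TestSimulatedPairRecovery:
    def test_age_zero_identical(self, rng):
        s5, s3, m = simulate_ltr_pair(500, 0.0, 1.3e-8, rng)
        assert s5 == s3 and m == 0

    def test_realized_mismatches_recovered_exactly_by_alignment(self, rng):
        for age in (0.1, 0.45, 0.9):
            s5, s3, m = simulate_ltr_pair(800, age, 1.3e-8, rng)
            aln = align_termini(s5, s3)
            diff, ungapped = count_differences(aln)
            assert (diff, ungapped) == (m, 800)

    def test_mean_divergence_within_binomial_error(self, rng):
        """Over 200 replicates, mean realized p within 3 binomial SEs."""
        age, r, L, reps = 0.4, 1.3e-8, 1_000, 200
        p = 2 * r * age * 1e6
        hats = [simulate_ltr_pair(L, age, r, rng)[2] / L for _ in range(reps)]
        se = math.sqrt(p * (1 - p) / L / reps)
        assert abs(np.mean(hats) - p) < 3 * se

    def test_saturated_age_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_ltr_pair(100, 50.0, 1.3e-8, rng)


class TestLogFit:
    def test_recovers_exact_coefficients(self):
        x = np.array([0.05, 0.15, 0.25, 0.35, 0.45])
        y = -3.0 * np.log(x) + 7.0
        a, b = log_fit(x, y)
        assert a == pytest.approx(7.0)
        assert b == pytest.approx(3.0)

    def test_rejects_nonpositive_x(self):
        with pytest.raises(ValueError):
            log_fit([0.0, 1.0], [1.0, 2.0])
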