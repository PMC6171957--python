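import math
import random
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compscan.composition_scan import ScanGrid, partition_proteome
from compscan.domain_classify import (
    BiasResult,
    define_ced_sets,
    find_homopolymers,
    find_lcds,
    fit_bias_threshold,
    min_pbias,
    pbias,
    proteome_frequencies,
    seg_positive_by_residue,
    shannon_entropy,
    single_ced_proteins,
)
from compscan.proteome_io import CANONICAL_AA, ProteinRecord
from conftest import random_sequence


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,L,expected",
        [
            ({"A": 12}, 12, 0.0),
            ({"A": 6, "G": 6}, 12, 1.0),
            ({"A": 8, "G": 4}, 12, 0.9183),
            ({aa: 1 for aa in "ACDEFGHIKLMN"}, 12, math.log2(12)),
        ],
    )
    def test_reference_values(self, counts, L, expected):
        assert shannon_entropy(counts, L) == pytest.approx(expected, abs=1e-4)

    @given(
        counts=st.lists(st.integers(0, 20), min_size=1, max_size=20),
    )
    def test_bounds(self, counts):
        L = sum(counts)
        if L == 0:
            return
        se = shannon_entropy(counts, L)
        assert 0.0 <= se <= math.log2(min(20, L)) + 1e-12
        if sum(c > 0 for c in counts) == 1:
            assert se == 0.0


class TestFindLcds:
    def test_polyA_20mer_yields_all_windows(self):
        calls = find_lcds("A" * 20, "p")
        assert len(calls) == 20 - 12 + 1
        assert all(c.assigned_residues == frozenset("A") for c in calls)
        assert all(c.entropy == 0.0 for c in calls)
        assert calls[0].start == 1 and calls[0].end == 12

    def test_fully_diverse_sequence_has_no_calls(self):
        assert find_lcds("ACDEFGHIKLMNPQRSTVWY", "p") == []

    def test_tied_maximum_assigns_both_residues(self):
        calls = find_lcds("AAAAAAGGGGGG", "p")
        assert len(calls) == 1
        assert calls[0].entropy == pytest.approx(1.0)
        assert calls[0].assigned_residues == frozenset("AG")

    def test_short_sequence_empty(self):
        assert find_lcds("MKV", "p") == []

    def test_unknowns_lower_entropy_but_are_never_assigned(self):
        calls = find_lcds("AAAAAA" + "X" * 6, "p")
        assert len(calls) == 1
        assert calls[0].assigned_residues == frozenset("A")


class TestPbias:
    @pytest.mark.parametrize(
        "w,n,f,expected",
        [
            (5, 5, 0.1, 1.0e-5),
            (10, 3, 0.05, 0.010475),
            (10, 0, 0.05, 0.95**10),
        ],
    )
    def test_binomial_point_mass(self, w, n, f, expected):
        assert pbias(w, n, f) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("w,f", [(25, 0.05), (100, 0.0104), (400, 0.3), (2500, 0.09)])
    def test_normalization(self, w, f):
        assert sum(pbias(w, n, f) for n in range(w + 1)) == pytest.approx(1.0, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pbias(5, 6, 0.1)
        with pytest.raises(ValueError):
            pbias(5, 2, 0.0)


def brute_force_min_pbias(seq, freqs, w_min=25, w_max=2500):
    """Oracle: direct enumeration over every residue, window size and position."""
    if len(seq) < w_min:
        return None
    best = None
    for w in range(w_min, min(w_max, len(seq)) + 1):
        for i in range(len(seq) - w + 1):
            sub = seq[i : i + w]
            for aa, f in freqs.items():
                p = pbias(w, sub.count(aa), f)
                if best is None or p < best[0]:
                    best = (p, w, aa, sub.count(aa))
    return best


class TestMinPbias:
    def test_below_minimum_window_absent(self):
        freqs = {aa: 0.05 for aa in CANONICAL_AA}
        assert min_pbias("A" * 20, freqs) is None

    def test_matches_exhaustive_oracle_on_short_sequences(self, rng):
        freqs = proteome_frequencies(
            [ProteinRecord("bg", random_sequence(rng, 2000))]
        )
        seqs = ["Q" * 25 + "ACDEF"] + [
            random_sequence(rng, rng.randint(25, 60)) for _ in range(8)
        ]
        for i, seq in enumerate(seqs):
            got = min_pbias(seq, freqs, f"s{i}")
            exp_p, exp_w, exp_aa, exp_n = brute_force_min_pbias(seq, freqs)
            assert got.p_min == pytest.approx(exp_p, rel=1e-9)
            assert (got.window, got.residue, got.count) == (exp_w, exp_aa, exp_n)

    def test_planted_tract_scores_lower_than_random(self, rng):
        freqs = {aa: 0.05 for aa in CANONICAL_AA}
        base = random_sequence(rng, 200)
        tract = "".join(
            "N" if rng.random() < 0.8 else rng.choice(CANONICAL_AA) for _ in range(30)
        )
        planted = base[:85] + tract + base[115:]
        assert min_pbias(planted, freqs).p_min < min_pbias(base, freqs).p_min


def collinear_results_with_outliers():
    """20 proteins on an exact log-log line, 3 pushed far below it."""
    results = []
    for i in range(20):
        length = 50 + 10 * i
        p = 10 ** (-2.0 * math.log10(length) + 1.0)
        if i in (4, 9, 15):
            p *= 1e-6
        results.append(BiasResult(f"p{i}", length, p, 25, "Q", 10))
    return results


class TestFitBiasThreshold:
    def test_planted_outliers_fall_below_line(self):
        results = collinear_results_with_outliers()
        thr = fit_bias_threshold(results, fraction=0.15)
        below_line = {
            r.protein_id
            for r in results
            if r.p_min < 10 ** (thr.slope * math.log10(r.length) + thr.intercept)
        }
        assert below_line == {"p4", "p9", "p15"}
        # the length-independent cap (a strict lower quantile) can only trim
        # the below-line set further, never extend it
        biased = {r.protein_id for r in results if thr.is_biased(r)}
        assert biased <= below_line

    def test_identical_pmins_yield_empty_biased_set(self):
        results = [
            BiasResult(f"p{i}", 50 + i, 1e-4, 25, "Q", 8) for i in range(20)
        ]
        thr = fit_bias_threshold(results)
        assert not any(thr.is_biased(r) for r in results)

    def test_below_line_count_bounded_and_maximal(self, rng):
        results = [
            BiasResult(
                f"p{i}", L := rng.randint(30, 500),
                10 ** (-1.5 * math.log10(L) - 3 * rng.random()), 25, "Q", 5,
            )
            for i in range(80)
        ]
        thr = fit_bias_threshold(results, fraction=0.15)
        x = np.log10([r.length for r in results])
        y = np.log10([r.p_min for r in results])
        resid = y - thr.slope * x
        k = math.floor(0.15 * len(results))
        below = int(np.sum(resid < thr.intercept))
        assert below <= k
        # raising the intercept to the next residual must break the bound
        next_intercept = np.sort(resid)[k + 1]
        assert int(np.sum(resid < next_intercept)) > k

    def test_biased_fraction_bounded_on_synthetic_proteome(self, rng):
        proteome = [
            ProteinRecord(f"p{i}", random_sequence(rng, rng.randint(30, 150)))
            for i in range(120)
        ]
        freqs = proteome_frequencies(proteome)
        results = [
            r for p in proteome if (r := min_pbias(p.seq, freqs, p.id)) is not None
        ]
        thr = fit_bias_threshold(results, fraction=0.15)
        biased = sum(thr.is_biased(r) for r in results)
        assert biased <= 0.15 * len(results)

    def test_degenerate_inputs_error(self):
        same_length = [BiasResult(f"p{i}", 100, 10**-i, 25, "Q", 5) for i in range(1, 13)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_bias_threshold(same_length)
        with pytest.raises(ValueError, match=">= 10"):
            fit_bias_threshold(same_length[:5])


class TestFindHomopolymers:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", []),
            ("AAAAA", [("A", 1, 5)]),
            ("QQQQQQNNNNN", [("Q", 1, 6), ("N", 7, 11)]),
            ("AAXAAAAA", [("A", 4, 8)]),  # unknown breaks the run; the tail still qualifies
            ("AAAXAAA", []),  # unknown splits an 7-run into two sub-threshold runs
            ("XXXXX", []),  # unknowns never form runs
        ],
    )
    def test_examples(self, seq, expected):
        calls = find_homopolymers(seq, "p")
        assert [(c.residue, c.start, c.end) for c in calls] == expected

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        pattern = re.compile(r"([ACDEFGHIKLMNPQRSTVWY])\1{4,}")
        for _ in range(40):
            seq = random_sequence(rng, rng.randint(5, 120), "ANQ")
            expected = [
                (m.group(1), m.start() + 1, m.end()) for m in pattern.finditer(seq)
            ]
            got = [(c.residue, c.start, c.end) for c in find_homopolymers(seq, "p")]
            assert got == expected

    def test_min_run_precondition(self):
        with pytest.raises(ValueError):
            find_homopolymers("AAAA", min_run=1)


class TestCedSets:
    @staticmethod
    def _partition_of(proteome, windows=(10,)):
        return partition_proteome(proteome, ScanGrid(residues=("Q", "N"), windows=windows))

    def test_cell_qualifies_at_75_percent_occupancy(self):
        # four proteins landing in one (Q, 10, 100) cell; 3 of 4 SEG-positive
        proteome = [ProteinRecord(f"p{i}", "Q" * 10) for i in range(4)]
        part = self._partition_of(proteome)
        seg = {"Q": {"p0", "p1", "p2"}}
        ced = define_ced_sets(part, seg, occupancy=0.75)
        assert ced["Q"] == {"p0", "p1", "p2", "p3"}

    def test_cell_below_occupancy_does_not_qualify(self):
        proteome = [ProteinRecord(f"p{i}", "Q" * 10) for i in range(4)]
        part = self._partition_of(proteome)
        ced = define_ced_sets(part, {"Q": {"p0", "p1"}}, occupancy=0.75)
        assert "Q" not in ced or ced["Q"] == set()

    def test_multi_ced_proteins_removed_and_sets_disjoint(self):
        sets = {"Q": {"a", "b", "both"}, "N": {"c", "both"}}
        single = single_ced_proteins(sets)
        assert single == {"Q": {"a", "b"}, "N": {"c"}}
        assert not (single["Q"] & single["N"])

    def test_end_to_end_on_planted_proteome(self, rng):
        # Q-homopolymer carriers are SEG-positive for Q; diverse proteins are not
        proteome = [
            ProteinRecord(f"q{i}", random_sequence(rng, 40) + "Q" * 15) for i in range(8)
        ] + [ProteinRecord(f"r{i}", "ACDEFGHIKLMNPQRSTVWY" * 3) for i in range(8)]
        part = self._partition_of(proteome, windows=(10, 20))
        seg = seg_positive_by_residue(proteome)
        ced = define_ced_sets(part, seg)
        assert {f"q{i}" for i in range(8)} <= ced.get("Q", set())
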