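"""Greedy KDIC/KDDIC motif discovery: information-content oracles, implant
recovery, greedy contracts and the length search."""

import math

import numpy as np
import pytest

from tfbsbench import simulate
from tfbsbench.discovery import (
    DiscoveryResult,
    Occurrence,
    greedy_discover,
    kddic,
    kdic,
    optimize_discovered_length,
    _site_string,
)
from tfbsbench.seqio import Peak, encode, reverse_complement
from tfbsbench.simulate import MarkovChain

UNIFORM = MarkovChain(0, np.full(4, 0.25))


def brute_kdic(site_strings, q, pseudocount):
    """Independent column-by-column recomputation of the KL objective."""
    N = len(site_strings)
    L = len(site_strings[0])
    total = 0.0
    for j in range(L):
        for a, base in enumerate("ACGT"):
            n = sum(s[j] == base for s in site_strings)
            f = (n + pseudocount * q[a]) / (N + pseudocount)
            total += f * math.log(f / q[a])
    return total


def implanted_peaks(motif, n, length, seed):
    peaks = simulate.generate_background(UNIFORM, n, length, seed=seed)
    return simulate.implant_sites(peaks, motif, 1, seed=seed + 1)


class TestKdic:
    def make(self, seqs):
        peaks = [Peak(id=f"p{i}", seq=s, height=1) for i, s in enumerate(seqs)]
        occ = [Occurrence(p.id, 0, "+") for p in peaks]
        return occ, peaks

    def test_identical_occurrences_reach_l_ln4(self):
        occ, peaks = self.make(["TGTTTACT"] * 20)
        val = kdic(occ, peaks, 8, pseudocount=1e-9)
        assert val == pytest.approx(8 * math.log(4), abs=1e-4)

    def test_background_composition_near_zero(self):
        rng = np.random.default_rng(0)
        occ, peaks = self.make([UNIFORM.generate(8, rng) for _ in range(500)])
        assert 0 <= kdic(occ, peaks, 8) < 0.2

    def test_nonnegative_and_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            seqs = [UNIFORM.generate(10, rng) for _ in range(15)]
            occ, peaks = self.make(seqs)
            val = kdic(occ, peaks, 10, pseudocount=0.7)
            assert val >= 0
            assert val == pytest.approx(
                brute_kdic(seqs, np.full(4, 0.25), 0.7), abs=1e-12)

    def test_out_of_bounds_occurrence(self):
        occ, peaks = self.make(["ACGTACGT"] * 3)
        with pytest.raises(ValueError, match="out of bounds"):
            kdic([Occurrence("p0", 5, "+")] + occ[1:], peaks, 8)

    def test_requires_two_occurrences(self):
        occ, peaks = self.make(["ACGTACGT"] * 3)
        with pytest.raises(ValueError, match="at least 2"):
            kdic(occ[:1], peaks, 8)


class TestKddic:
    def make(self, seqs):
        peaks = [Peak(id=f"p{i}", seq=s, height=1) for i, s in enumerate(seqs)]
        occ = [Occurrence(p.id, 0, "+") for p in peaks]
        return occ, peaks

    def test_identical_occurrences_reach_lm1_ln16(self):
        occ, peaks = self.make(["TGTTTACT"] * 20)
        val = kddic(occ, peaks, 8, pseudocount=1e-9)
        assert val == pytest.approx(7 * math.log(16), abs=1e-3)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        occ, peaks = self.make([UNIFORM.generate(9, rng) for _ in range(30)])
        assert kddic(occ, peaks, 9) >= 0

    def test_dependence_raises_kddic_over_column_shuffled(self):
        motif = simulate.first_order_dependent_motif(L=10, stay=0.75)
        rng = np.random.default_rng(3)
        seqs = [motif.sample(rng) for _ in range(200)]
        # destroy the dependence but keep the mononucleotide columns
        cols = [list(c) for c in zip(*seqs)]
        for c in cols:
            rng.shuffle(c)
        shuffled = ["".join(chars) for chars in zip(*cols)]
        occ_d, peaks_d = self.make(seqs)
        occ_s, peaks_s = self.make(shuffled)
        assert kddic(occ_d, peaks_d, 10) > kddic(occ_s, peaks_s, 10)


class TestGreedyDiscover:
    def test_recovers_literal_implants(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 50, 120, seed=30)
        res = greedy_discover(ps.peaks, 8, mode="mono", n_starts=10, seed=5)
        truth = {pid: e[0] for pid, e in ps.truth.items()}
        exact = sum(truth[o.peak_id][0] == o.offset for o in res.occurrences)
        assert exact >= 45
        by_id = {p.id: p for p in ps.peaks}
        strings = {_site_string(by_id[o.peak_id], o, 8)
                   for o in res.occurrences}
        assert strings <= {"TGTTTACT", reverse_complement("TGTTTACT")}

    def test_single_peak_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        peak = Peak(id="p", seq=UNIFORM.generate(60, rng), height=1)
        res = greedy_discover([peak], 8, mode="mono", n_starts=3, seed=7)
        assert len(res.occurrences) == 1
        found = res.occurrences[0]
        # oracle: enumerate every (offset, strand) and recompute the
        # objective of the single-window alignment
        best = None
        for strand in "+-":
            for off in range(len(peak.seq) - 8 + 1):
                s = peak.seq[off:off + 8]
                if strand == "-":
                    s = reverse_complement(s)
                obj = brute_kdic([s], np.full(4, 0.25), 1.0)
                if best is None or obj > best[0] + 1e-12:
                    best = (obj, off, strand)
        assert (found.offset, found.strand) == (best[1], best[2])
        assert res.objective == pytest.approx(best[0])

    def test_trace_nondecreasing_within_each_start(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 30, 80, seed=8)
        res = greedy_discover(ps.peaks, 8, n_starts=4, seed=9)
        for trace in res.trace:
            assert all(a <= b + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_objective_self_consistency(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 30, 80, seed=10)
        res = greedy_discover(ps.peaks, 8, n_starts=4, seed=11)
        recomputed = kdic(res.occurrences, ps.peaks, 8)
        assert res.objective == pytest.approx(recomputed, abs=1e-9)
        res_di = greedy_discover(ps.peaks, 8, mode="di", n_starts=2, seed=11)
        assert res_di.objective == pytest.approx(
            kddic(res_di.occurrences, ps.peaks, 8), abs=1e-9)

    def test_strand_coherence(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 40, 100, seed=12)
        rc_peaks = [Peak(id=p.id, seq=reverse_complement(p.seq),
                         height=p.height) for p in ps.peaks]
        a = greedy_discover(ps.peaks, 8, n_starts=6, seed=13)
        b = greedy_discover(rc_peaks, 8, n_starts=6, seed=13)
        assert a.objective == pytest.approx(b.objective, abs=1e-9)

    def test_motif_longer_than_peak_rejected(self):
        peak = Peak(id="p", seq="ACGTACGT", height=1)
        with pytest.raises(ValueError, match="exceeds"):
            greedy_discover([peak], 20, n_starts=1, seed=0)

    def test_determinism(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 20, 60, seed=14)
        a = greedy_discover(ps.peaks, 8, n_starts=3, seed=15)
        b = greedy_discover(ps.peaks, 8, n_starts=3, seed=15)
        assert a.occurrences == b.occurrences and a.objective == b.objective


class TestShapeWeighting:
    def test_constant_profile_equals_unweighted(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 20, 60, seed=16)
        flat = [Peak(id=p.id, seq=p.seq, height=p.height,
                     profile=[p.height] * len(p.seq)) for p in ps.peaks]
        a = greedy_discover(ps.peaks, 8, n_starts=2, seed=17, use_shape=True)
        b = greedy_discover(flat, 8, n_starts=2, seed=17, use_shape=True)
        assert a.occurrences == b.occurrences
        assert a.objective == pytest.approx(b.objective)

    def test_weighted_objective_matches_recomputation(self, consensus_motif):
        rng = np.random.default_rng(18)
        ps = implanted_peaks(consensus_motif, 15, 60, seed=19)
        peaks = []
        for p in ps.peaks:
            prof = rng.uniform(0.2, 1.0, size=len(p.seq))
            prof[int(rng.integers(len(p.seq)))] = 1.0
            peaks.append(Peak(id=p.id, seq=p.seq, height=1.0,
                              profile=list(prof)))
        res = greedy_discover(peaks, 8, n_starts=2, seed=20, use_shape=True)
        by_id = {p.id: p for p in peaks}
        weights = []
        for o in res.occurrences:
            prof = np.asarray(by_id[o.peak_id].profile)
            weights.append(prof[o.offset + 4] / prof.max())
        assert res.objective == pytest.approx(
            kdic(res.occurrences, peaks, 8, weights=weights), abs=1e-9)


class TestLengthSearch:
    def test_singleton_range_is_identity(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 25, 70, seed=21)
        res, table = optimize_discovered_length(ps.peaks, [8], seed=22,
                                                n_starts=2)
        assert res.L == 8 and list(table["length"]) == [8]

    def test_recovers_true_length_neighbourhood(self, sharp_motif):
        hits = 0
        for seed in (0, 1):
            ps = implanted_peaks(sharp_motif, 80, 120, seed=100 + seed)
            res, _ = optimize_discovered_length(
                ps.peaks, [8, 10, 12, 14, 16], seed=seed, n_starts=4)
            if 10 <= res.L <= 14:
                hits += 1
        assert hits >= 1

    def test_empty_range_rejected(self, consensus_motif):
        ps = implanted_peaks(consensus_motif, 10, 60, seed=23)
        with pytest.raises(ValueError, match="empty"):
            optimize_discovered_length(ps.peaks, [], seed=0)
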