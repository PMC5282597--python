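import numpy as np
import pytest
from scipy import stats

from transcomp import (SequenceRecord, call_fragments, conservation_compare,
                       consistency_profile, element_overlap_test,
                       frequency_matrix, randomized_fragment_fpr)
from transcomp.seqio import GenomicInterval, ScoreTrack
from transcomp.synthetic import (BenchmarkConfig, MarkovModel,
                                 balanced_signal_set, generate_benchmark,
                                 random_score_track, sample_sequence)
from conftest import random_dna


class TestProfile:
    def test_empty_sets_give_zero(self, rng):
        seq = random_dna(rng, 1200)
        prof = consistency_profile(seq, [], [], window=500, step=100)
        assert np.all(prof.scores == 0.0)
        assert prof.starts[0] == 0 and prof.starts[-1] <= 1200 - 500

    def test_favored_only_equals_frequency_sum(self, rng):
        """With no disfavored set, every window score equals the sum of
        favored-transition frequencies computed on the extracted window."""
        from transcomp import transition_frequency

        seq = random_dna(rng, 900)
        favored = ["A>C", "GC>T", "TTT>A"]
        prof = consistency_profile(seq, favored, [], window=300, step=150)
        for s, score in zip(prof.starts, prof.scores):
            sub = seq[s:s + 300]
            expected = sum(transition_frequency(sub, t) for t in favored)
            assert score == pytest.approx(expected, abs=1e-9)

    def test_additivity_recompute_from_scratch(self, rng):
        """Streamed window scores equal from-scratch scoring of the
        extracted subsequence, favored minus disfavored."""
        from transcomp import transition_frequency

        seq = random_dna(rng, 1500)
        favored = ["C>G", "ACG>T", "GGGG>A"]
        disfavored = ["T>A", "CC>C"]
        prof = consistency_profile(seq, favored, disfavored,
                                   window=400, step=213)
        for s, score in zip(prof.starts, prof.scores):
            sub = seq[s:s + 400]
            expected = (
                sum(transition_frequency(sub, t) for t in favored)
                - sum(transition_frequency(sub, t) for t in disfavored)
            )
            assert score == pytest.approx(expected, abs=1e-9)

    def test_short_sequence_skipped(self, caplog):
        prof = consistency_profile("ACGT" * 10, ["A>C"], [], window=500)
        assert prof is None

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            consistency_profile("A" * 600, [], [], window=500, step=0)


class TestFragmentCalls:
    def test_argmax_argmin_and_width(self, rng):
        recs = [SequenceRecord("s1", random_dna(rng, 2000))]
        calls = call_fragments(recs, ["A>A"], ["T>T"], window=500, step=50)
        assert len(calls) == 1
        c = calls[0]
        assert len(c.favored) == 500 and len(c.disfavored) == 500
        assert c.favored_score >= c.disfavored_score

    def test_leftmost_tie(self):
        # constant sequence: every window ties; leftmost window wins
        recs = [SequenceRecord("s", "A" * 1000)]
        calls = call_fragments(recs, ["A>A"], [], window=500, step=100)
        assert calls[0].favored.start == 0
        assert calls[0].disfavored.start == 0

    def test_short_sequences_skipped_in_batch(self, rng):
        recs = [SequenceRecord("long", random_dna(rng, 800)),
                SequenceRecord("short", "ACGT" * 20)]
        calls = call_fragments(recs, ["A>C"], [], window=500, step=100)
        assert [c.sequence_id for c in calls] == ["long"]

    def test_plant_and_recover(self):
        """The called favored window overlaps a planted feature-dense
        fragment by >= 250 bp in >= 90% of replicates."""
        bg = MarkovModel.skewed()
        signal = balanced_signal_set(n_pairs=6, delta=0.22, core_length=2,
                                     background=bg, seed=5)
        cfg = BenchmarkConfig(n_pos=50, n_neg=1, length_median=3000,
                              length_log_sd=0.3, min_length=1500,
                              background=bg, signal_mode="planted_fragment",
                              signal=signal, seed=17)
        records, truth = generate_benchmark(cfg)
        pos = [r for r in records if r.group_label == "positive"]
        calls = call_fragments(pos, truth.favored, truth.disfavored,
                               window=500, step=10)
        hits = 0
        for c in calls:
            (ps, pe), = truth.fragments[c.sequence_id]
            overlap = min(pe, c.favored.end) - max(ps, c.favored.start)
            hits += overlap >= 250
        assert hits / len(calls) >= 0.9

    def test_shift_invariance(self, rng):
        """Prepending plant-free background shifts the called window by
        about the prepended length."""
        bg = MarkovModel.skewed()
        signal = balanced_signal_set(n_pairs=6, delta=0.22, core_length=2,
                                     background=bg, seed=5)
        boosted = bg.with_boosts(signal)
        gen = np.random.default_rng(3)
        body = sample_sequence(bg, 1500, gen).sequence
        plant = sample_sequence(boosted, 500, gen).sequence
        pad = sample_sequence(bg, 1000, gen).sequence
        favored = sorted(k for k, d in signal.items() if d > 0)
        disfavored = sorted(k for k, d in signal.items() if d < 0)
        base_rec = SequenceRecord("a", body + plant + body)
        padded = SequenceRecord("b", pad + body + plant + body)
        c0 = call_fragments([base_rec], favored, disfavored, 500, 10)[0]
        c1 = call_fragments([padded], favored, disfavored, 500, 10)[0]
        assert abs((c1.favored.start - c0.favored.start) - 1000) <= 250


class TestConservationCompare:
    def test_identical_lists_p_one(self):
        res = conservation_compare([0.1, 0.5, 0.3], [0.1, 0.5, 0.3])
        assert res.degenerate and res.p == 1.0 and res.mean_diff == 0.0

    def test_constant_shift_degenerate(self):
        res = conservation_compare([1.1, 2.1, 3.1], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.p)
        assert res.mean_diff == pytest.approx(0.1)

    def test_matches_scipy_paired(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        res = conservation_compare(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_power_matches_textbook_oracle(self, rng):
        """Rejection rate at a planted shift tracks scipy's paired t within
        2% over 500 replicates."""
        mine = ref = 0
        for _ in range(500):
            d = rng.normal(0.5, 1.0, size=40)
            a = rng.normal(size=40)
            res = conservation_compare(a + d, a)
            mine += res.p < 0.05
            ref += stats.ttest_rel(a + d, a).pvalue < 0.05
        assert abs(mine - ref) / 500 <= 0.02

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            conservation_compare([1.0], [0.5])


class TestElementOverlap:
    def _hosts(self, rng, n=10, L=2000):
        return [SequenceRecord(f"h{i}", random_dna(rng, L)) for i in range(n)]

    def test_full_coverage(self, rng):
        hosts = self._hosts(rng)
        els = [GenomicInterval(h.id, 0, 2000) for h in hosts]
        frags = [GenomicInterval(h.id, 100, 600) for h in hosts]
        obs, p = element_overlap_test(frags, els, hosts, n_sim=200, seed=0)
        assert obs == 1.0 and p == 1.0

    def test_no_elements(self, rng):
        hosts = self._hosts(rng)
        frags = [GenomicInterval(h.id, 0, 500) for h in hosts]
        obs, p = element_overlap_test(frags, [], hosts, n_sim=200, seed=0)
        assert obs == 0.0 and p == 1.0

    def test_short_host_excluded(self, rng):
        hosts = self._hosts(rng, n=3) + [SequenceRecord("tiny", "ACGT" * 25)]
        frags = [GenomicInterval(h.id, 0, 500) for h in hosts[:3]]
        obs, p = element_overlap_test(frags, [], hosts, n_sim=50, seed=0)
        assert obs == 0.0

    def test_uniform_fragments_calibrated(self, rng):
        """Fragments drawn by the null mechanism give roughly uniform
        empirical P (no mass near 0)."""
        hosts = self._hosts(rng, n=30, L=3000)
        els = []
        for h in hosts:
            s = int(rng.integers(0, 2500))
            els.append(GenomicInterval(h.id, s, s + 300))
        pvals = []
        for rep in range(40):
            starts = rng.integers(0, 2501, size=len(hosts))
            frags = [GenomicInterval(h.id, int(s), int(s) + 500)
                     for h, s in zip(hosts, starts)]
            _, p = element_overlap_test(frags, els, hosts, n_sim=300,
                                        seed=rep)
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) < 0.25
        assert np.mean(pvals) > 0.25


class TestRandomizedFpr:
    def test_deterministic_and_bounded(self, null_benchmark):
        records, _ = null_benchmark
        sub = records[:12] + records[50:62]
        mat = frequency_matrix(sub, 2)
        track = random_score_track(sub, seed=9)
        r1 = randomized_fragment_fpr(mat, sub, track, n_sets=15,
                                     window=500, step=100, seed=21)
        r2 = randomized_fragment_fpr(mat, sub, track, n_sets=15,
                                     window=500, step=100, seed=21)
        assert r1.fpr == r2.fpr
        assert 0.0 <= r1.fpr <= 1.0
        assert len(r1.null_ps) == 15
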