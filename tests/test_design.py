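"""Score function, annealing search mechanics, and primer selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mtprime.design import (
    Candidate,
    PrimerChoice,
    ScoreComponents,
    SearchConfig,
    SearchResult,
    accept,
    acceptance_probability,
    evaluate,
    mutate,
    random_motif,
    score_fn,
    search,
    select_primer,
)
from mtprime.motif import IUPAC_ALPHABET, DegenerateMotif

from oracle import oracle_evaluate


class TestScoreFn:
    def test_published_yeast_coverage(self):
        """m=5039 of 6608 mRNAs, clean background -> the reported 76%."""
        s = score_fn(ScoreComponents(m=5039, t=0, r=0, m_t=6608))
        assert s == pytest.approx(5039 / 6608)
        assert round(s, 2) == 0.76

    def test_clean_background_score_is_coverage_fraction(self):
        assert score_fn(ScoreComponents(m=40, t=0, r=0, m_t=50)) == 0.8

    def test_background_hits_divide_the_score(self):
        assert score_fn(ScoreComponents(m=100, t=1, r=1, m_t=200)) == pytest.approx(100 / 600)

    def test_monotone_in_components(self):
        base = score_fn(ScoreComponents(m=50, t=1, r=1, m_t=100))
        assert score_fn(ScoreComponents(m=51, t=1, r=1, m_t=100)) > base
        assert score_fn(ScoreComponents(m=50, t=2, r=1, m_t=100)) < base
        assert score_fn(ScoreComponents(m=50, t=1, r=2, m_t=100)) < base

    def test_m_t_zero_rejected(self):
        with pytest.raises(ValueError):
            ScoreComponents(m=0, t=0, r=0, m_t=0)


class TestEvaluate:
    def test_planted_partition_counts_exact(self, planted):
        partition, truth = planted
        comps = evaluate(truth.motif, partition)
        assert comps.m == len(truth.planted_gene_ids)
        assert comps.t == 0 and comps.r == 0
        assert comps.m_t == partition.m_t

    def test_absent_motif_gives_zero_components(self, toy_partition):
        comps = evaluate("ACGTACGTACGA", toy_partition)
        assert (comps.m, comps.t, comps.r) == (0, 0, 0)

    def test_matches_brute_force_oracle_on_random_motifs(self, toy_partition, rng):
        for _ in range(25):
            motif = random_motif(4, rng)
            comps = evaluate(motif, toy_partition)
            assert (comps.m, comps.t, comps.r) == oracle_evaluate(
                motif.symbols, toy_partition
            )

    def test_occurrence_mode_counts_all_mrna_sites(self, toy_partition):
        comps = evaluate("WW", toy_partition, mrna_hit_mode="occurrences")
        # g1 "AATTACGTACGT" has W-pairs at offsets 0,1,2,3,7; others none
        assert comps.m == 5


class TestMutate:
    def test_hamming_distance_one_and_length_preserved(self, rng):
        motif = DegenerateMotif("NDKTBBBBDWGS")
        for _ in range(100):
            out = mutate(motif, rng)
            assert len(out.symbols) == 12
            diffs = sum(a != b for a, b in zip(out.symbols, motif.symbols))
            assert diffs == 1

    def test_uniform_over_positions_and_codes(self, rng):
        """Positions ~ uniform(12); replacement codes ~ uniform(14)."""
        motif = DegenerateMotif("A" * 12)
        n = 100_000
        pos_counts = np.zeros(12, int)
        code_counts: dict[str, int] = {}
        for _ in range(n):
            out = mutate(motif, rng)
            (p,) = [i for i, (a, b) in enumerate(zip(out.symbols, motif.symbols)) if a != b]
            pos_counts[p] += 1
            code_counts[out.symbols[p]] = code_counts.get(out.symbols[p], 0) + 1
        assert chisquare(pos_counts).pvalue > 1e-4
        codes = [code_counts.get(c, 0) for c in IUPAC_ALPHABET if c != "A"]
        assert len(codes) == 14
        assert chisquare(codes).pvalue > 1e-4


class TestAccept:
    def test_equal_scores_always_accepted(self):
        assert accept(0.5, 0.5, 0.999999)

    def test_half_ratio_threshold_is_exact(self):
        assert acceptance_probability(0.5, 1.0, 10.0) == 0.0009765625
        assert accept(0.5, 1.0, 0.0009765624)
        assert not accept(0.5, 1.0, 0.01)

    def test_zero_previous_score_always_accepts(self):
        assert accept(0.0, 0.0, 0.9999)
        assert accept(0.3, 0.0, 0.9999)

    def test_monotone_in_new_score(self, rng):
        for _ in range(200):
            s_old = float(rng.random())
            u = float(rng.random())
            s = float(rng.random())
            s_better = s + float(rng.random()) * (1 - s)
            if accept(s, s_old, u):
                assert accept(s_better, s_old, u)

    def test_improvements_always_accepted(self, rng):
        for _ in range(200):
            s_old = float(rng.random())
            s_new = s_old + float(rng.random())
            assert accept(s_new, s_old, float(rng.random()))

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            accept(-0.1, 0.5, 0.5)


class TestSearch:
    def test_zero_iterations_yields_initial_motifs_only(self, toy_partition):
        res = search(toy_partition, SearchConfig(motif_length=4, iterations=0, restarts=1, seed=9))
        assert len(res.ledger) == 1
        assert res.best.iteration == 0

    def test_same_seed_reproduces_ledger(self, toy_partition):
        cfg = SearchConfig(motif_length=4, iterations=300, restarts=2, seed=11)
        r1 = search(toy_partition, cfg)
        r2 = search(toy_partition, cfg)
        assert [(c.motif.symbols, c.score, c.iteration, c.restart) for c in r1.ledger] == [
            (c.motif.symbols, c.score, c.iteration, c.restart) for c in r2.ledger
        ]

    def test_ledger_ranked_and_consistent(self, toy_partition):
        res = search(toy_partition, SearchConfig(motif_length=4, iterations=300, restarts=2, seed=11))
        scores = [c.score for c in res.ledger]
        assert scores == sorted(scores, reverse=True)
        assert res.best.score == max(scores)
        for cand in res.ledger[:20]:
            comps = evaluate(cand.motif, toy_partition)
            assert comps == cand.components
            assert score_fn(comps) == cand.score

    def test_clean_background_best_score_bounded_by_one(self, toy_partition):
        from mtprime.transcriptome import TranscriptomePartition

        clean = TranscriptomePartition(mrna=list(toy_partition.mrna))
        res = search(clean, SearchConfig(motif_length=4, iterations=500, restarts=1, seed=2))
        best_m = res.best.components.m
        assert res.best.score == best_m / clean.m_t <= 1.0


class TestSelectPrimer:
    @staticmethod
    def _result(motif_strings):
        comps = ScoreComponents(m=1, t=0, r=0, m_t=2)
        ledger = [
            Candidate(DegenerateMotif(s), 0.5 - 0.01 * i, comps, i) for i, s in enumerate(motif_strings)
        ]
        return SearchResult(ledger=ledger, best=ledger[0], trajectory_summary=[])

    def test_published_yeast_primer_satisfies_gc_rule(self):
        res = self._result(["SCWHVVVVAMHN"])
        choice = select_primer(res, gc_rule_width=2)
        assert choice.primer.symbols == "NDKTBBBBDWGS"
        assert choice.rank == 0

    def test_skips_candidates_with_weak_3prime_end(self):
        # first primer ends in ..AA (weak); second is the yeast primer
        res = self._result(["TTACGTACGTAC", "SCWHVVVVAMHN"])
        choice = select_primer(res, gc_rule_width=2)
        assert choice.primer.symbols == "NDKTBBBBDWGS"
        assert choice.rank == 1

    def test_width_zero_returns_top_candidate(self):
        res = self._result(["TTACGTACGTAC"])
        choice = select_primer(res, gc_rule_width=0)
        assert choice.primer.symbols == "GTACGTACGTAA"

    def test_error_when_no_primer_ends_strong(self):
        res = self._result(["TTACGTACGTAC"])
        with pytest.raises(ValueError, match="gc_rule_width"):
            select_primer(res, gc_rule_width=2)
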