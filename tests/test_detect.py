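"""Seed-and-extend NUMT caller: Karlin statistics, e-values, calling,
and agreement with the exhaustive Smith-Waterman oracle."""

import math

import numpy as np
import pytest

from numtkit.detect import (
    call_numts,
    evalue,
    karlin_lambda,
    karlin_parameters,
    smith_waterman_oracle,
)
from numtkit.models import (
    AlignmentParams,
    GenomeSequence,
    LengthModel,
    SimulationConfig,
)
from numtkit.seqs import reverse_complement
from numtkit.simulate import (
    simulate_cohort,
    simulate_mt_genome,
    simulate_nuclear_genome,
)

from conftest import random_dna


class TestKarlinParameters:
    def test_lambda_uniform_unit_scores_is_ln3(self):
        """For +1/-1 scoring at uniform composition the root of
        0.25 e^lam + 0.75 e^-lam = 1 is analytically ln 3."""
        lam = karlin_lambda(1, -1, [0.25] * 4)
        assert lam == pytest.approx(math.log(3), abs=1e-9)

    def test_lambda_matches_independent_bisection(self):
        """+2/-3 at uniform composition, cross-checked against a plain
        bisection root-finder written here."""
        lam = karlin_lambda(2, -3, [0.25] * 4)

        def g(x):
            return 0.25 * math.exp(2 * x) + 0.75 * math.exp(-3 * x) - 1.0

        lo, hi = 1e-9, 5.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert lam == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            karlin_lambda(1, 0, [0.25] * 4)

    def test_k_finite_positive(self):
        lam, K = karlin_parameters(1, -1, [0.25] * 4)
        assert 0 < K < 10 and math.isfinite(K)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        assert evalue(0, 100, 200, 1.0, 0.3) == pytest.approx(0.3 * 100 * 200)

    def test_linear_in_subject_length(self):
        e1 = evalue(30, 16500, 500_000, math.log(3), 0.1)
        e2 = evalue(30, 16500, 1_000_000, math.log(3), 0.1)
        assert e2 == pytest.approx(2 * e1)

    def test_direct_arithmetic(self):
        e = evalue(30, 16500, 500_000, math.log(3), 0.1)
        assert e == pytest.approx(0.1 * 16500 * 5e5 * 3.0**-30, rel=1e-9)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 1000, 1000, 1.0, 0.1) for s in range(0, 50, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))


def _mt_and_background(seed=7):
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=1, chromosome_lengths=(200_000,), n_numts=0
    )
    return simulate_mt_genome(cfg), simulate_nuclear_genome(cfg)[0]


class TestCallNumts:
    def test_exact_planted_copy(self):
        """A verbatim 300 bp mt fragment flanked by N (so extension cannot
        creep into the background) is recovered at exact coordinates."""
        mt, chrom = _mt_and_background()
        frag = mt.sequence[2000:2300]
        seq = chrom.sequence[:1000] + "N" * 5 + frag + "N" * 5 + chrom.sequence[1000:]
        calls = call_numts(mt, [GenomeSequence("chr1", seq)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.nuclear_start, c.nuclear_end) == (1005, 1305)
        assert (c.mt_start, c.mt_end) == (2000, 2300)
        assert c.strand == "+"
        assert c.identity == pytest.approx(1.0)
        assert c.score == 300

    def test_reverse_complement_strand(self):
        mt, chrom = _mt_and_background()
        frag = reverse_complement(mt.sequence[2000:2300])
        seq = chrom.sequence[:1000] + "N" * 5 + frag + "N" * 5 + chrom.sequence[1000:]
        calls = call_numts(mt, [GenomeSequence("chr1", seq)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.nuclear_start, c.nuclear_end) == (1005, 1305)
        assert (c.mt_start, c.mt_end) == (2000, 2300)
        assert c.strand == "-"

    def test_origin_wrapping_insert(self):
        """An insert spanning the circular origin is called with wrapped
        mt coordinates (mt_start > mt_end)."""
        mt, chrom = _mt_and_background()
        L = len(mt)
        frag = mt.sequence[L - 150 :] + mt.sequence[:150]
        seq = chrom.sequence[:1000] + "N" * 5 + frag + "N" * 5 + chrom.sequence[1000:]
        calls = call_numts(mt, [GenomeSequence("chr1", seq)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.mt_start, c.mt_end) == (L - 150, 150)
        assert c.nuclear_end - c.nuclear_start == 300

    def test_empty_input_rejected(self):
        mt, chrom = _mt_and_background()
        with pytest.raises(ValueError):
            call_numts(GenomeSequence("chrM", "", circular=True), [chrom])
        with pytest.raises(ValueError):
            call_numts(mt, [])

    def test_emitted_evalues_below_threshold(self, default_calls):
        params = AlignmentParams()
        assert all(c.evalue <= params.evalue_threshold for c in default_calls)
        assert all(0 < c.identity <= 1 for c in default_calls)

    def test_calls_sorted(self, default_calls):
        keys = [(c.chromosome_id, c.nuclear_start) for c in default_calls]
        assert keys == sorted(keys)

    def test_numt_free_genome_yields_no_calls(self):
        """Independent-composition chromosomes at E <= 1e-3: expect zero
        chance calls in (nearly) every run."""
        zero = 0
        for seed in range(8):
            mt, chrom = _mt_and_background(seed=100 + seed)
            zero += len(call_numts(mt, [chrom])) == 0
        assert zero >= 7

    def test_recall_on_default_cohort(self, default_cohort, default_calls):
        """>= 95% of planted NUMTs >= 100 bp recovered with >= 50%
        reciprocal overlap (5% substitution divergence)."""
        nuclear, mt, truth, _ = default_cohort
        rec = _recall(truth, default_calls)
        assert rec >= 0.95

    def test_strand_involution(self):
        """Calling on the reverse-complemented chromosome mirrors the call
        set exactly, with strands flipped."""
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chromosome_lengths=(60_000,), n_numts=15,
            length_model=LengthModel(max_length=1500),
        )
        nuclear, mt, truth, _ = simulate_cohort(cfg)
        L = len(nuclear[0])
        fwd = call_numts(mt, nuclear)
        rc = GenomeSequence("chr1", reverse_complement(nuclear[0].sequence))
        rev = call_numts(mt, [rc])
        mirrored = sorted(
            (
                L - c.nuclear_end,
                L - c.nuclear_start,
                "-" if c.strand == "+" else "+",
                c.mt_start,
                c.mt_end,
                c.score,
            )
            for c in rev
        )
        orig = sorted(
            (c.nuclear_start, c.nuclear_end, c.strand, c.mt_start, c.mt_end, c.score)
            for c in fwd
        )
        assert orig == mirrored


def _recall(truth, calls, min_len=100, min_overlap=0.5):
    def recip(t, c):
        if t.chromosome_id != c.chromosome_id:
            return 0.0
        ov = min(t.nuclear_end, c.nuclear_end) - max(t.nuclear_start, c.nuclear_start)
        if ov <= 0:
            return 0.0
        return min(ov / t.length, ov / (c.nuclear_end - c.nuclear_start))

    big = [t for t in truth if t.length >= min_len]
    hit = sum(any(recip(t, c) >= min_overlap for c in calls) for t in big)
    return hit / len(big)


class TestSmithWatermanOracle:
    def test_identical_sequences(self):
        s = random_dna(np.random.default_rng(0), 50)
        score, qiv, siv = smith_waterman_oracle(s, s)
        assert score == 50
        assert qiv == (0, 50) and siv == (0, 50)

    def test_oracle_dominates_seeded_aligner(self, default_cohort, default_calls):
        """The oracle optimum bounds every emitted call's score on the
        reported interval pair."""
        nuclear, mt, _, _ = default_cohort
        chrom = {c.id: c for c in nuclear}
        mt2 = mt.sequence + mt.sequence
        L = len(mt)
        for c in default_calls[:25]:
            nseq = chrom[c.chromosome_id].sequence[c.nuclear_start : c.nuclear_end]
            ms, me = c.mt_start, c.mt_end
            if me <= ms:
                me += L
            mseq = mt2[ms:me]
            if c.strand == "-":
                mseq = reverse_complement(mseq)
            score, _, _ = smith_waterman_oracle(mseq, nseq)
            assert score >= c.score

    def test_matches_independent_reference(self):
        """Cross-check against biotite's optimal local aligner on random
        pairs with a shared block."""
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        alph = bseq.NucleotideSequence.alphabet_unamb
        mat = np.full((4, 4), -1, dtype=int)
        np.fill_diagonal(mat, 1)
        submat = balign.SubstitutionMatrix(alph, alph, mat)
        rng = np.random.default_rng(5)
        for _ in range(20):
            block = random_dna(rng, 40)
            a = random_dna(rng, 60) + block + random_dna(rng, 60)
            b = random_dna(rng, 30) + block + random_dna(rng, 30)
            score, _, _ = smith_waterman_oracle(a, b)
            ref = balign.align_optimal(
                bseq.NucleotideSequence(a), bseq.NucleotideSequence(b),
                submat, gap_penalty=(-8, -1), local=True, max_number=1,
            )[0].score
            assert score == ref

    def test_seeded_aligner_recovers_planted_blocks(self):
        """100 random 200 bp pairs with a planted 60 bp shared block: the
        seeded caller recovers the oracle interval in >= 95 cases."""
        rng = np.random.default_rng(11)
        params = AlignmentParams(evalue_threshold=10.0)
        recovered = 0
        for _ in range(100):
            block = random_dna(rng, 60)
            qpos, spos = int(rng.integers(0, 140)), int(rng.integers(0, 140))
            q = random_dna(rng, qpos) + block + random_dna(rng, 140 - qpos)
            s = random_dna(rng, spos) + block + random_dna(rng, 140 - spos)
            _, (ob, oe), _ = smith_waterman_oracle(q, s, params)
            calls = call_numts(
                GenomeSequence("q", q, circular=True),
                [GenomeSequence("s", s)],
                params,
            )
            for c in calls:
                ms, me = c.mt_start, c.mt_end
                if me <= ms:
                    me += len(q)
                ov = min(me, oe) - max(ms, ob)
                if ov > 0 and ov >= 0.9 * (oe - ob):
                    recovered += 1
                    break
        assert recovered >= 95
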