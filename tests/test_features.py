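"""Descriptor correctness: spec'd examples, brute-force equivalence, and
algebraic invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from numtkit.features import (
    DINUCLEOTIDE_PROPERTIES,
    assemble_features,
    canonical_kmers,
    feature_names,
    kmer,
    mismatch_profile,
    nac,
    nmbroto,
    rckmer,
    standardized_properties,
    zcurve,
)
from numtkit.models import DescriptorConfig
from numtkit.seqs import reverse_complement

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


# ---------------------------------------------------------------------------
# brute-force oracles (naive python, independent of the implementation)


def brute_kmer(s, k, type1=True):
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    windows = [s[i : i + k] for i in range(len(s) - k + 1)]
    windows = [w for w in windows if "N" not in w]
    counts = np.array([sum(w == km for w in windows) for km in kmers], float)
    return counts / len(windows) if type1 else counts


def brute_rckmer(s, k, type1=True):
    canon, _ = canonical_kmers(k)
    windows = [s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]]
    counts = np.array(
        [sum(min(w, reverse_complement(w)) == c for w in windows) for c in canon],
        float,
    )
    return counts / len(windows) if type1 else counts


def brute_nmbroto(s, nlag):
    props = standardized_properties()
    out = []
    for name in DINUCLEOTIDE_PROPERTIES:
        vals = {d: props[name]["ACGT".index(d[0]) * 4 + "ACGT".index(d[1])]
                for d in ["".join(p) for p in itertools.product("ACGT", repeat=2)]}
        p = [vals[s[i : i + 2]] for i in range(len(s) - 1)]
        for d in range(1, nlag + 1):
            terms = [p[i] * p[i + d] for i in range(len(p) - d)]
            out.append(sum(terms) / len(terms))
    return np.array(out)


def brute_zcurve9(s):
    out = []
    for ph in range(3):
        sub = s[ph::3]
        n = len(sub)
        a, c = sub.count("A") / n, sub.count("C") / n
        g, t = sub.count("G") / n, sub.count("T") / n
        out += [(a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)]
    return np.array(out)


def brute_mismatch(s, k, m):
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    windows = [s[i : i + k] for i in range(len(s) - k + 1)]

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    counts = np.array(
        [sum(ham(w, km) <= m for w in windows) for km in kmers], float
    )
    return counts / len(windows)


# ---------------------------------------------------------------------------


class TestExamples:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGT", [0.25, 0.25, 0.25, 0.25]),
            ("AAAA", [1, 0, 0, 0]),
            ("AACG", [0.5, 0.25, 0.25, 0]),
        ],
    )
    def test_nac(self, seq, expected):
        assert nac(seq) == pytest.approx(expected)

    def test_kmer_examples(self):
        v = kmer("AAAA", 2, 1)
        assert v[0] == 1.0 and v[1:].sum() == 0
        v = kmer("ACGT", 2, 1)
        # windows AC, CG, GT
        names = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        nz = {names[i]: x for i, x in enumerate(v) if x > 0}
        assert nz == pytest.approx({"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3})

    def test_kmer_type2_is_raw_counts(self):
        v = kmer("AAAAA", 2, 2)
        assert v[0] == 4.0

    def test_rckmer_canonical_count(self):
        canon, _ = canonical_kmers(3)
        assert len(canon) == 32

    def test_mismatch_profile_hand_worked(self):
        """"AAAA", k=3, m=1: both windows are AAA, so count(AAA)=2,
        count(AAC)=2 (distance 1), count(ACC)=0."""
        names = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        raw = mismatch_profile("AAAA", 3, 1) * 2  # L-k+1 = 2 windows
        byname = dict(zip(names, raw))
        assert byname["AAA"] == pytest.approx(2)
        assert byname["AAC"] == pytest.approx(2)
        assert byname["ACC"] == pytest.approx(0)

    def test_mismatch_total_identity(self):
        """Raw counts summed over all k-mers = (L-k+1) * sum_j C(k,j) 3^j
        (= 10 (L-2) for k=3, m=1)."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            s = random_dna(rng, int(rng.integers(20, 80)))
            L = len(s)
            total = mismatch_profile(s, 3, 1).sum() * (L - 2)
            assert total == pytest.approx(10 * (L - 2))

    def test_mismatch_m0_is_kmer_type1(self):
        rng = np.random.default_rng(2)
        s = random_dna(rng, 50)
        assert mismatch_profile(s, 3, 0) == pytest.approx(kmer(s, 3, 1))

    def test_nmbroto_polya_constant(self):
        props = standardized_properties()
        v = nmbroto("A" * 10, nlag=3)
        expected = [props[p][0] ** 2 for p in DINUCLEOTIDE_PROPERTIES for _ in range(3)]
        assert v == pytest.approx(expected)

    def test_nmbroto_alternating_matches_brute(self):
        s = "AC" * 6
        assert nmbroto(s, nlag=3) == pytest.approx(brute_nmbroto(s, 3), abs=1e-12)

    def test_property_table_standardized(self):
        for vals in standardized_properties().values():
            assert vals.mean() == pytest.approx(0, abs=1e-12)
            assert vals.std() == pytest.approx(1, abs=1e-12)

    def test_zcurve_polya(self):
        assert zcurve("A" * 9) == pytest.approx([1.0] * 9)

    def test_zcurve_balanced_is_zero(self):
        assert zcurve("ACGT" * 3) == pytest.approx([0.0] * 9, abs=1e-12)

    def test_zcurve_inverts_to_base_counts(self):
        """(n, x, y, z) per phase determines the base counts exactly:
        a = n (1+x+y+z)/4 etc."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            s = random_dna(rng, int(rng.integers(9, 60)))
            v = zcurve(s, "phase_9")
            for ph in range(3):
                sub = s[ph::3]
                n = len(sub)
                x, y, z = v[3 * ph : 3 * ph + 3]
                assert n * (1 + x + y + z) / 4 == pytest.approx(sub.count("A"))
                assert n * (1 - x + y - z) / 4 == pytest.approx(sub.count("C"))
                assert n * (1 + x - y - z) / 4 == pytest.approx(sub.count("G"))
                assert n * (1 - x - y + z) / 4 == pytest.approx(sub.count("T"))


class TestBruteForceEquivalence:
    """Every descriptor agrees with an independent naive recomputation."""

    def test_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            s = random_dna(rng, int(rng.integers(15, 80)))
            assert kmer(s, 3, 1) == pytest.approx(brute_kmer(s, 3), abs=1e-12)
            assert kmer(s, 3, 2) == pytest.approx(brute_kmer(s, 3, False), abs=1e-12)
            assert rckmer(s, 3, 1) == pytest.approx(brute_rckmer(s, 3), abs=1e-12)
            assert nmbroto(s, nlag=3) == pytest.approx(brute_nmbroto(s, 3), abs=1e-12)
            assert zcurve(s) == pytest.approx(brute_zcurve9(s), abs=1e-12)
            assert mismatch_profile(s, 3, 1) == pytest.approx(
                brute_mismatch(s, 3, 1), abs=1e-12
            )

    def test_n_windows_excluded(self):
        s = "ACGTNNACGT"
        assert kmer(s, 3, 1) == pytest.approx(brute_kmer(s, 3), abs=1e-12)


class TestInvariants:
    @given(dna)
    def test_kmer_type1_sums_to_one(self, s):
        assert kmer(s, 3, 1).sum() == pytest.approx(1.0)

    @given(dna)
    def test_frequencies_bounded(self, s):
        assert ((kmer(s, 3, 1) >= 0) & (kmer(s, 3, 1) <= 1)).all()
        assert ((zcurve(s) >= -1) & (zcurve(s) <= 1)).all()

    def test_rckmer_reverse_complement_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            s = random_dna(rng, int(rng.integers(12, 100)))
            assert rckmer(s, 3) == pytest.approx(
                rckmer(reverse_complement(s), 3), abs=1e-12
            )


class TestAssemble:
    def test_default_column_count(self):
        """4 + 64 + 64 + 32 + 32 + 18 + 9 + 64 = 287 columns."""
        names, groups = feature_names(DescriptorConfig())
        assert len(names) == 287
        df, g = assemble_features(["ACGTACGTACGTACGT"])
        assert df.shape == (1, 287)
        assert list(df.columns) == names

    def test_deterministic(self):
        seqs = ["ACGTACGTACGTA", "GGGCCCAAATTTG"]
        a, _ = assemble_features(seqs)
        b, _ = assemble_features(seqs)
        assert a.equals(b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            assemble_features([""])
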