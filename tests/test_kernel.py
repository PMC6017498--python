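"""Derived-kernel correctness against brute-force dense oracles.

The oracles materialize the full template set A^k as a dense vector and
compute counts / inner products naively, independently of the sparse
implementation they check.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rpilearn as rp
from rpilearn.kernel import cross_kernel_matrix, sequence_kernel_matrix
from rpilearn.seqio import PROTEIN20, RNA4, Sequence, SequenceError


def dense_response_oracle(residues: str, k: int, alphabet: str) -> np.ndarray:
    """Naive window-count frequency vector over the full template set."""
    templates = ["".join(t) for t in itertools.product(alphabet, repeat=k)]
    counts = np.array(
        [sum(residues[i : i + k] == t for i in range(len(residues) - k + 1)) for t in templates],
        dtype=float,
    )
    return counts / (len(residues) - k + 1)


def dense_normalized_oracle(a: str, b: str, k: int, alphabet: str) -> float:
    va = dense_response_oracle(a, k, alphabet)
    vb = dense_response_oracle(b, k, alphabet)
    return float(va @ vb / math.sqrt((va @ va) * (vb @ vb)))


def _rna(s, sid="x"):
    return Sequence(sid, s, RNA4)


class TestNeuralResponse:
    @pytest.mark.parametrize(
        "seq,k,expected,n_windows",
        [
            ("ACGU", 2, {"AC": 1 / 3, "CG": 1 / 3, "GU": 1 / 3}, 3),
            ("ACAC", 2, {"AC": 2 / 3, "CA": 1 / 3}, 3),
            ("AAAA", 1, {"A": 1.0}, 4),
        ],
    )
    def test_hand_enumerated_windows(self, seq, k, expected, n_windows):
        resp = rp.neural_response(_rna(seq), k)
        assert resp.n_windows == n_windows
        assert resp.entries == pytest.approx(expected)

    def test_entries_sum_to_one(self):
        resp = rp.neural_response(_rna("ACGUACGGUA"), 3)
        assert sum(resp.entries.values()) == pytest.approx(1.0)
        assert all(v > 0 for v in resp.entries.values())

    def test_under_length_is_an_error(self):
        with pytest.raises(SequenceError, match="length 3 < template size 4"):
            rp.neural_response(_rna("ACG"), 4)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=12),
        st.integers(min_value=1, max_value=4),
    )
    def test_matches_dense_oracle_rna(self, s, k):
        if len(s) < k:
            return
        resp = rp.neural_response(_rna(s), k)
        dense = dense_response_oracle(s, k, RNA4.symbols)
        templates = ["".join(t) for t in itertools.product(RNA4.symbols, repeat=k)]
        sparse_as_dense = np.array([resp.entries.get(t, 0.0) for t in templates])
        assert np.allclose(sparse_as_dense, dense)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.text(alphabet=PROTEIN20.symbols, min_size=3, max_size=12),
        st.integers(min_value=1, max_value=3),
    )
    def test_matches_dense_oracle_protein(self, s, k):
        resp = rp.neural_response(Sequence("p", s, PROTEIN20), k)
        total = 0.0
        for t, v in resp.entries.items():
            count = sum(s[i : i + k] == t for i in range(len(s) - k + 1))
            assert v == pytest.approx(count / (len(s) - k + 1))
            total += v
        assert total == pytest.approx(1.0)


class TestLayer2Kernel:
    def test_raw_single_template(self):
        f = rp.neural_response(_rna("AAAA"), 1)
        assert rp.k2_raw(f, f, 4) == pytest.approx(1 / 4)

    def test_raw_disjoint_support_is_zero(self):
        f = rp.neural_response(_rna("AAAA"), 1)
        g = rp.neural_response(_rna("CCCC"), 1)
        assert rp.k2_raw(f, g, 4) == 0.0

    def test_raw_hand_derived_dimers(self):
        f = rp.neural_response(_rna("ACAC"), 2)   # {AC:2/3, CA:1/3}
        g = rp.neural_response(_rna("CACA"), 2)   # {CA:2/3, AC:1/3}
        assert rp.k2_raw(f, g, 4) == pytest.approx((1 / 16) * (4 / 9))

    def test_normalized_hand_derived(self):
        f = rp.neural_response(_rna("ACAC"), 2)
        g = rp.neural_response(_rna("CACA"), 2)
        assert rp.k2_normalized(f, g, 4) == pytest.approx(0.8, abs=1e-12)

    def test_self_kernel_is_one(self):
        for s in ["ACGU", "AAAA", "ACGUACGUAC", "GUC"]:
            f = rp.neural_response(_rna(s), 2)
            assert rp.k2_normalized(f, f, 4) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_compositions(self):
        f = rp.neural_response(_rna("AAAA"), 1)
        g = rp.neural_response(_rna("CCCC"), 1)
        assert rp.k2_normalized(f, g, 4) == 0.0

    def test_template_size_mismatch(self):
        f = rp.neural_response(_rna("ACGU"), 1)
        g = rp.neural_response(_rna("ACGU"), 2)
        with pytest.raises(ValueError, match="mismatch"):
            rp.k2_raw(f, g, 4)

    def test_uniform_measure_factor_cancels(self):
        # normalized value must not depend on the alphabet-size factor
        f = rp.neural_response(_rna("ACGGUA"), 2)
        g = rp.neural_response(_rna("GGUACC"), 2)
        assert rp.k2_normalized(f, g, 4) == pytest.approx(
            rp.k2_normalized(f, g, 1000), abs=1e-12
        )

    def test_identical_kmer_profiles_give_one(self):
        # distinct strings sharing the same dimer profile are kernel-identical
        a = rp.neural_response(_rna("AACAA"), 2)  # AA:2, AC:1, CA:1
        b = rp.neural_response(_rna("AAACA"), 2)  # AA:2, AC:1, CA:1
        assert a.entries == b.entries
        assert rp.k2_normalized(a, b, 4) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.text(alphabet="ACGU", min_size=4, max_size=12),
        st.text(alphabet="ACGU", min_size=4, max_size=12),
        st.integers(min_value=1, max_value=4),
    )
    def test_normalized_equals_cosine_oracle(self, a, b, k):
        f = rp.neural_response(_rna(a), k)
        g = rp.neural_response(_rna(b), k)
        got = rp.k2_normalized(f, g, 4)
        want = dense_normalized_oracle(a, b, k, RNA4.symbols)
        assert got == pytest.approx(want, abs=1e-12)
        assert 0.0 <= got <= 1.0
        # symmetry
        assert got == pytest.approx(rp.k2_normalized(g, f, 4), abs=1e-15)

    def test_size_one_equals_composition_cosine(self):
        # closed form: template size 1 is cosine of residue compositions
        a, b = "ACCGUU", "AACGGU"
        f = rp.neural_response(_rna(a), 1)
        g = rp.neural_response(_rna(b), 1)
        ca = np.array([a.count(ch) for ch in "ACGU"], float)
        cb = np.array([b.count(ch) for ch in "ACGU"], float)
        want = ca @ cb / np.sqrt((ca @ ca) * (cb @ cb))
        assert rp.k2_normalized(f, g, 4) == pytest.approx(want, abs=1e-12)


class TestExhaustiveSmallRNA:
    def test_all_rna_sequences_up_to_length_6(self):
        """Sparse kernel equals the dense oracle on every short RNA pair."""
        rng = np.random.default_rng(0)
        for k in (1, 2, 3):
            pool = [
                "".join(t)
                for n in range(k, 7)
                for t in itertools.product("ACGU", repeat=n)
            ]
            # exhaustive responses; sampled pairs keep the quadratic cost down
            picks = rng.choice(len(pool), size=200)
            for idx in range(0, 200, 2):
                a, b = pool[picks[idx]], pool[picks[idx + 1]]
                f = rp.neural_response(_rna(a), k)
                g = rp.neural_response(_rna(b), k)
                assert rp.k2_normalized(f, g, 4) == pytest.approx(
                    dense_normalized_oracle(a, b, k, "ACGU"), abs=1e-12
                )


class TestPairKernelAndGram:
    def test_self_pair_is_one(self, small_dataset):
        prot, rna, pairs = small_dataset
        cfg = rp.KernelConfig(k=2, l=3)
        for i in [0, 5, 17]:
            pid, rid = pairs.pair_ids[i]
            p = next(s for s in prot if s.id == pid)
            r = next(s for s in rna if s.id == rid)
            assert rp.pair_kernel(r, p, r, p, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_product_structure(self):
        # the pair kernel is exactly the product of its two factors
        p1 = rp.canonicalize_protein("MKVAHELKVV" * 4, seq_id="p1")
        p2 = rp.canonicalize_protein("GGASTWYYHH" * 4, seq_id="p2")
        r1 = rp.canonicalize_rna("ACGUACGUACGUACGU", seq_id="r1")
        r2 = rp.canonicalize_rna("GGUUCCAAGGUUCCAA", seq_id="r2")
        cfg = rp.KernelConfig(k=2, l=3)
        fr1, fr2 = rp.neural_response(r1, 3), rp.neural_response(r2, 3)
        fp1, fp2 = rp.neural_response(p1, 2), rp.neural_response(p2, 2)
        krr = rp.k2_normalized(fr1, fr2, 4)
        kpp = rp.k2_normalized(fp1, fp2, 20)
        assert rp.pair_kernel(r1, p1, r2, p2, cfg) == pytest.approx(krr * kpp, abs=1e-12)

    def test_zero_factor_annihilates(self):
        pa = rp.canonicalize_protein("A" * 30, seq_id="pa")
        pb = rp.canonicalize_protein("G" * 30, seq_id="pb")
        r = rp.canonicalize_rna("ACGU" * 8, seq_id="r")
        cfg = rp.KernelConfig(k=1, l=1)
        assert rp.pair_kernel(r, pa, r, pb, cfg) == 0.0

    def test_gram_shape_symmetry_diagonal(self, small_dataset):
        prot, rna, pairs = small_dataset
        G = rp.gram(pairs, prot, rna, rp.KernelConfig(k=2, l=3))
        m = len(pairs)
        assert G.values.shape == (m, m)
        assert np.allclose(G.values, G.values.T)
        assert np.all(np.diag(G.values) == 1.0)
        assert np.all((G.values >= 0) & (G.values <= 1))

    def test_gram_psd(self, signal_dataset):
        prot, rna, pairs = signal_dataset
        G = rp.gram(pairs, prot, rna, rp.KernelConfig(k=2, l=4))
        assert G.min_eigenvalue() >= -1e-8 * G.n

    def test_gram_matches_scalar_pair_kernel(self, small_dataset):
        prot, rna, pairs = small_dataset
        cfg = rp.KernelConfig(k=2, l=3)
        G = rp.gram(pairs, prot, rna, cfg)
        prot_by = {s.id: s for s in prot}
        rna_by = {s.id: s for s in rna}
        rng = np.random.default_rng(1)
        for i, j in rng.integers(0, len(pairs), size=(10, 2)):
            pi, ri = pairs.pair_ids[i]
            pj, rj = pairs.pair_ids[j]
            want = rp.pair_kernel(rna_by[ri], prot_by[pi], rna_by[rj], prot_by[pj], cfg)
            assert G.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_under_length_sequences_reported(self):
        prot = [rp.canonicalize_protein("MKVA", seq_id="p0")]
        rna = [rp.canonicalize_rna("AC", seq_id="r0")]
        pairs = rp.PairTable([rp.PairRecord("p0", "r0", 1)])
        with pytest.raises(SequenceError, match="r0"):
            rp.gram(pairs, prot, rna, rp.KernelConfig(k=2, l=5))

    def test_cross_matrix_consistent_with_square(self, small_dataset):
        prot, rna, pairs = small_dataset
        resp = [rp.neural_response(r, 3) for r in rna[:8]]
        square = sequence_kernel_matrix(resp)
        cross = cross_kernel_matrix(resp[:4], resp[4:8])
        assert np.allclose(cross, square[:4, 4:], atol=1e-12)

    def test_reduced_alphabet_mode(self):
        # sequences identical after 7-group reduction become kernel-1 proteins
        p1 = rp.canonicalize_protein("AGVAGVAGV" * 4, seq_id="p1")
        p2 = rp.canonicalize_protein("VAGVAGVAG" * 4, seq_id="p2")  # same groups (all 1)
        cfg = rp.KernelConfig(k=2, alphabet_mode="reduced7g")
        f1 = rp.neural_response(rp.reduce_protein(p1), 2)
        f2 = rp.neural_response(rp.reduce_protein(p2), 2)
        assert rp.k2_normalized(f1, f2, 7) == pytest.approx(1.0, abs=1e-12)

    def test_gram_tsv_export(self, tmp_path, small_dataset):
        prot, rna, pairs = small_dataset
        G = rp.gram(pairs, prot, rna, rp.KernelConfig(k=2, l=3))
        path = tmp_path / "gram.tsv"
        rp.write_gram_tsv(path, G)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(pairs) + 1
        header = lines[0].split("\t")
        assert len(header) == len(pairs) + 1


class TestKernelConfig:
    def test_bounds(self):
        with pytest.raises(ValueError):
            rp.KernelConfig(k=9)
        with pytest.raises(ValueError):
            rp.KernelConfig(l=9)
        with pytest.raises(ValueError):
            rp.KernelConfig(k=5)  # full20 caps k at 4 by default
        rp.KernelConfig(k=5, allow_large_k=True)
        rp.KernelConfig(k=6, alphabet_mode="reduced7g")
        with pytest.raises(ValueError):
            rp.KernelConfig(k=7, alphabet_mode="reduced7g")
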