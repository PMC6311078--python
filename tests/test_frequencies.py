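import numpy as np
import pytest

import oracle
from conftest import make_random_msa
from tridca import (
    Alphabet,
    ConfigurationError,
    EncodedMSA,
    MemoryBudgetError,
    ReductionMap,
    build_frequency_model,
    compute_weights,
    one_point_frequencies,
    reduce_one_two_point,
    three_point_frequencies_reduced,
    two_point_frequencies,
)


class TestWeights:
    def test_identical_sequences(self):
        data = np.tile([0, 1, 2, 0], (5, 1))
        msa = EncodedMSA(data, Alphabet(("A", "C", "D")))
        w = compute_weights(msa, 0.5)
        assert np.allclose(w.w, 1 / 5)
        assert w.B_eff == pytest.approx(1.0)

    def test_all_distinct(self):
        # rows pairwise different everywhere -> singleton neighborhoods
        data = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        msa = EncodedMSA(data, Alphabet(("A", "C", "D")))
        w = compute_weights(msa, 0.2)
        assert np.allclose(w.w, 1.0)

    def test_hand_worked_neighborhoods(self):
        # N=10; seqs 1,2 differ at 1 position (0.1 <= 0.2); seq 3 differs
        # from both at 5 positions (0.5 > 0.2)
        s1 = [0] * 10
        s2 = [0] * 9 + [1]
        s3 = [1] * 5 + [0] * 5
        msa = EncodedMSA(np.array([s1, s2, s3]), Alphabet(("A", "C")))
        w = compute_weights(msa, 0.2)
        assert np.allclose(w.w, [0.5, 0.5, 1.0])
        assert w.B_eff == pytest.approx(2.0)

    def test_theta_bounds(self, tiny_msa):
        with pytest.raises(ConfigurationError):
            compute_weights(tiny_msa, 1.5)

    def test_matches_loop_oracle(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        assert np.allclose(w.w, oracle.weights(tiny_msa.data, 0.2), atol=0)


class TestOneTwoPoint:
    def test_huge_pseudocount_uniform_limit(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f1 = one_point_frequencies(tiny_msa, w, 1e9)
        assert np.allclose(f1, 1 / tiny_msa.alphabet.q, atol=1e-8)

    def test_single_sequence_indicator(self):
        msa = EncodedMSA(np.array([[0, 2, 1]]), Alphabet(("A", "C", "D")))
        w = compute_weights(msa, 0.2)
        f1 = one_point_frequencies(msa, w, 0.0)
        expected = np.zeros((3, 3))
        expected[[0, 1, 2], [0, 2, 1]] = 1.0
        assert np.allclose(f1, expected)
        f2 = two_point_frequencies(msa, w, 0.0)
        assert f2[0, 1, 0, 2] == 1.0 and f2[0, 1, 0, 0] == 0.0

    def test_f1_matches_oracle_at_reference_pseudocount(self):
        msa = make_random_msa(4, 3, 3, seed=7)
        w = compute_weights(msa, 0.2)
        f1 = one_point_frequencies(msa, w, 4.0)
        assert np.allclose(f1, oracle.f1(msa.data, w.w, 3, 4.0), atol=1e-15)

    def test_f2_matches_oracle(self):
        msa = make_random_msa(5, 3, 3, seed=11)
        w = compute_weights(msa, 0.2)
        f2 = two_point_frequencies(msa, w, 4.0)
        assert np.abs(f2 - oracle.f2(msa.data, w.w, 3, 4.0)).max() < 1e-14

    def test_independence_limit(self):
        msa = make_random_msa(4000, 3, 3, seed=13)
        w = compute_weights(msa, 0.0)
        f1 = one_point_frequencies(msa, w, 0.0)
        f2 = two_point_frequencies(msa, w, 0.0)
        prod = np.einsum("il,jm->ijlm", f1, f1)
        off = f2[0, 1] - prod[0, 1]
        assert np.abs(off).max() < 0.05  # within sampling error

    def test_marginalization_and_symmetry(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f1 = one_point_frequencies(tiny_msa, w, 4.0)
        f2 = two_point_frequencies(tiny_msa, w, 4.0)
        assert np.allclose(f1.sum(axis=1), 1.0, atol=1e-12)
        for i in range(tiny_msa.N):
            for j in range(tiny_msa.N):
                assert np.allclose(f2[i, j].sum(axis=1), f1[i], atol=1e-12)
                assert np.allclose(f2[i, j], f2[j, i].T, atol=0)


class TestReduction:
    def test_identity_map_bit_for_bit(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f1 = one_point_frequencies(tiny_msa, w, 4.0)
        f2 = two_point_frequencies(tiny_msa, w, 4.0)
        r1, r2 = reduce_one_two_point(f1, f2, ReductionMap.identity(3))
        assert np.array_equal(r1, f1) and np.array_equal(r2, f2)

    def test_constant_map_total_mass(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f1 = one_point_frequencies(tiny_msa, w, 4.0)
        f2 = two_point_frequencies(tiny_msa, w, 4.0)
        r1, r2 = reduce_one_two_point(f1, f2, ReductionMap.constant(3))
        assert np.allclose(r1, 1.0) and np.allclose(r2, 1.0)

    def test_two_class_hand_sums(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f1 = one_point_frequencies(tiny_msa, w, 4.0)
        f2 = two_point_frequencies(tiny_msa, w, 4.0)
        rmap = ReductionMap(np.array([0, 1, 0]), 2)
        r1, r2 = reduce_one_two_point(f1, f2, rmap)
        assert np.allclose(r1[:, 0], f1[:, 0] + f1[:, 2])
        assert np.allclose(
            r2[0, 2, 0, 1], f2[0, 2, 0, 1] + f2[0, 2, 2, 1]
        )


class TestThreePoint:
    def test_constant_map_all_ones(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f3 = three_point_frequencies_reduced(tiny_msa, w, 4.0, ReductionMap.constant(3))
        assert np.allclose(f3.wedge, 1.0, atol=1e-12)

    def test_single_sequence_indicator(self):
        msa = EncodedMSA(np.array([[0, 2, 1, 0]]), Alphabet(("A", "C", "D")))
        w = compute_weights(msa, 0.2)
        f3 = three_point_frequencies_reduced(msa, w, 0.0, ReductionMap.identity(3))
        block = f3.get(0, 1, 2)
        expected = np.zeros((3, 3, 3))
        expected[0, 2, 1] = 1.0
        assert np.allclose(block, expected)

    def test_matches_loop_oracle_two_class_map(self):
        msa = make_random_msa(6, 4, 3, seed=19)
        w = compute_weights(msa, 0.2)
        rmap = ReductionMap(np.array([0, 1, 1]), 2)
        f3 = three_point_frequencies_reduced(msa, w, 4.0, rmap)
        ref = oracle.f3_red(msa.data, w.w, 3, 4.0, rmap.mu, 2)
        assert np.abs(f3.dense() - ref).max() < 1e-14

    def test_index_order_resolved_by_symmetry(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        f3 = three_point_frequencies_reduced(tiny_msa, w, 4.0, ReductionMap.identity(3))
        a = f3.get(0, 2, 3)
        assert np.allclose(f3.get(2, 0, 3), a.transpose(1, 0, 2), atol=0)
        assert np.allclose(f3.get(3, 2, 0), a.transpose(2, 1, 0), atol=0)

    def test_marginalizes_to_f2_red(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        rmap = ReductionMap(np.array([0, 1, 1]), 2)
        fm = build_frequency_model(tiny_msa, w, 4.0, rmap)
        for (i, j, k) in [(0, 1, 2), (0, 1, 3), (1, 2, 3)]:
            assert np.allclose(
                fm.f3_red.get(i, j, k).sum(axis=2), fm.f2_red[i, j], atol=1e-12
            )

    def test_memory_guard(self, tiny_msa):
        w = compute_weights(tiny_msa, 0.2)
        with pytest.raises(MemoryBudgetError, match="cap"):
            three_point_frequencies_reduced(
                tiny_msa, w, 4.0, ReductionMap.identity(3), memory_cap=10
            )

    def test_worker_count_invariance(self):
        msa = make_random_msa(12, 6, 3, seed=23)
        w = compute_weights(msa, 0.2)
        rmap = ReductionMap.identity(3)
        a = three_point_frequencies_reduced(msa, w, 4.0, rmap, workers=1)
        b = three_point_frequencies_reduced(msa, w, 4.0, rmap, workers=4)
        assert np.array_equal(a.wedge, b.wedge)


def test_sequence_permutation_invariance():
    """Reordering the sequences of the MSA must not change frequencies."""
    msa = make_random_msa(10, 5, 3, seed=29)
    perm = np.random.default_rng(1).permutation(10)
    msa_p = EncodedMSA(msa.data[perm], msa.alphabet)
    for m in (msa, msa_p):
        m.weights = compute_weights(m, 0.2)
    assert np.allclose(np.sort(msa.weights.w), np.sort(msa_p.weights.w), atol=0)
    rmap = ReductionMap(np.array([0, 1, 0]), 2)
    fm = build_frequency_model(msa, msa.weights, 4.0, rmap)
    fm_p = build_frequency_model(msa_p, msa_p.weights, 4.0, rmap)
    assert np.allclose(fm.f1, fm_p.f1, rtol=1e-15, atol=1e-16)
    assert np.allclose(fm.f2, fm_p.f2, rtol=1e-15, atol=1e-16)
    assert np.allclose(fm.f3_red.wedge, fm_p.f3_red.wedge, rtol=1e-15, atol=1e-16)


def test_full_marginalization_chain_with_pseudocounts(tiny_msa):
    """sum_gamma f3 = f2_red, sum_beta f2_red = f1_red, sum f1 = 1 — the
    consequence of the lambda_c/q^k pseudocount pattern."""
    w = compute_weights(tiny_msa, 0.2)
    for rmap in (ReductionMap.identity(3), ReductionMap(np.array([0, 1, 1]), 2)):
        fm = build_frequency_model(tiny_msa, w, 4.0, rmap)
        N, qr = fm.f1_red.shape
        assert np.allclose(fm.f1_red.sum(axis=1), 1.0, atol=1e-12)
        expected_f1 = np.broadcast_to(fm.f1_red[:, None, :], (N, N, qr))
        assert np.abs(fm.f2_red.sum(axis=3) - expected_f1).max() < 1e-12
        dense = fm.f3_red.dense()
        expected_f2 = np.broadcast_to(fm.f2_red[:, :, None, :, :], (N, N, N, qr, qr))
        assert np.abs(dense.sum(axis=5) - expected_f2).max() < 1e-12
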