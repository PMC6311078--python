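"""Sequence reweighting and pseudocounted frequency estimation.

Near-duplicate sequences are down-weighted to reduce phylogenetic bias:
sequence b gets weight w_b = 1/|{a : hamming_fraction(a, b) <= theta}|
(the neighborhood always contains b itself), and B_eff = sum(w).

Frequencies carry a pseudocount mass lambda_c = pseudocount_ratio * B_eff
spread uniformly: lambda_c/q per state for one-point, lambda_c/q^2 per
state pair for two-point, lambda_c/q^3 per triplet — the pattern that
makes the marginalization chain (sum_gamma f3 = f2, sum_beta f2 = f1,
sum_alpha f1 = 1) hold exactly with pseudocounts.  Diagonal blocks are
delta-collapsed: f2[i,i,l,m] = delta_lm f1[i,l], and triplet entries
with repeated positions collapse onto the corresponding lower-order
tensor; this is the convention that keeps the joint covariance matrix
positive definite.

Reduced-alphabet tensors are class sums over a :class:`ReductionMap`;
three-point frequencies are computed directly in reduced space, with the
pseudocount picking up the class-size multiplicity
c_abc = |mu^-1(a)| |mu^-1(b)| |mu^-1(c)|.

Three-point frequencies are stored only on the strict wedge i < j < k
(a six-fold memory saving); other index orders are resolved by symmetry
and repeated indices by the collapse rule.  The wedge computation is
distributed over the first position index across worker threads, each
worker writing disjoint output slices, so the result is bit-identical
for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .alphabet import ReductionMap
from .errors import ConfigurationError, MemoryBudgetError
from .msa_io import EncodedMSA

#: Refuse three-point tensors larger than this (bytes); override per call.
DEFAULT_MEMORY_CAP = 2 * 1024**3


@dataclass(frozen=True)
class SequenceWeights:
    w: np.ndarray
    theta: float

    @property
    def B_eff(self) -> float:
        # summed in sorted-value order: bit-identical under any permutation
        # of the input sequences
        return float(np.sort(self.w).sum())

    @property
    def B(self) -> int:
        return int(self.w.size)


def compute_weights(msa: EncodedMSA, theta: float) -> SequenceWeights:
    """Reweight sequences by inverse similarity-neighborhood size.

    Two sequences are neighbors when their Hamming distance, as a
    fraction of N, is <= theta.  Gaps count as ordinary states in the
    distance.
    """
    if not 0.0 <= theta <= 1.0:
        raise ConfigurationError(f"theta must be in [0, 1], got {theta}")
    data = msa.data
    B, N = data.shape
    cutoff = theta * N + 1e-9  # tolerate exact-boundary float arithmetic
    counts = np.zeros(B, dtype=np.intp)
    chunk = max(1, int(2**24 // max(1, B * N)))
    for lo in range(0, B, chunk):
        hi = min(B, lo + chunk)
        d = (data[lo:hi, None, :] != data[None, :, :]).sum(axis=2)
        counts[lo:hi] = (d <= cutoff).sum(axis=1)
    return SequenceWeights(1.0 / counts, theta)


def _canonical_rows(msa: EncodedMSA, weights: SequenceWeights) -> tuple[np.ndarray, np.ndarray]:
    """Sequences and weights in lexicographic row order.

    Accumulating counts in this canonical order makes every frequency
    tensor bit-identical under permutation of the input sequences
    (duplicate rows carry identical weights, so ties are harmless).
    """
    order = np.lexsort(msa.data.T[::-1])
    return msa.data[order], weights.w[order]


def _weighted_onehot(data: np.ndarray, q: int) -> np.ndarray:
    B, N = data.shape
    x = np.zeros((B, N, q))
    b = np.arange(B)[:, None]
    i = np.arange(N)[None, :]
    x[b, i, data] = 1.0
    return x


def one_point_frequencies(
    msa: EncodedMSA, weights: SequenceWeights, pseudocount_ratio: float
) -> np.ndarray:
    """Pseudocounted single-site frequencies f1[i, l], shape (N, q)."""
    q = msa.alphabet.q
    lam = pseudocount_ratio * weights.B_eff
    data, w = _canonical_rows(msa, weights)
    x = _weighted_onehot(data, q)
    counts = np.einsum("b,bil->il", w, x)
    return (lam / q + counts) / (lam + weights.B_eff)


def two_point_frequencies(
    msa: EncodedMSA, weights: SequenceWeights, pseudocount_ratio: float
) -> np.ndarray:
    """Pseudocounted pair frequencies f2[i, j, l, m], shape (N, N, q, q).

    Off-diagonal blocks follow the lambda_c/q^2 pseudocount; the i == j
    blocks are delta_lm * f1[i, l].
    """
    q = msa.alphabet.q
    N = msa.N
    lam = pseudocount_ratio * weights.B_eff
    data, w = _canonical_rows(msa, weights)
    x = _weighted_onehot(data, q)
    wx = w[:, None, None] * x
    counts = np.einsum("bil,bjm->ijlm", wx, x, optimize=True)
    f2 = (lam / q**2 + counts) / (lam + weights.B_eff)
    f1 = one_point_frequencies(msa, weights, pseudocount_ratio)
    ii = np.arange(N)
    f2[ii, ii] = 0.0
    for l in range(q):
        f2[ii, ii, l, l] = f1[:, l]
    return f2


def reduce_one_two_point(
    f1: np.ndarray, f2: np.ndarray, rmap: ReductionMap
) -> tuple[np.ndarray, np.ndarray]:
    """Class-sum f1 and f2 onto the reduced alphabet."""
    qr = rmap.q_red
    N, q = f1.shape
    sel = np.zeros((q, qr))
    sel[np.arange(q), rmap.mu] = 1.0
    f1_red = f1 @ sel
    f2_red = np.einsum("ijlm,la,mb->ijab", f2, sel, sel, optimize=True)
    return f1_red, f2_red


def _triplet_index(N: int) -> tuple[np.ndarray, dict[tuple[int, int, int], int]]:
    tri = np.array(
        [(i, j, k) for i in range(N) for j in range(i + 1, N) for k in range(j + 1, N)],
        dtype=np.intp,
    ).reshape(-1, 3)
    lookup = {tuple(t): n for n, t in enumerate(map(tuple, tri))}
    return tri, lookup


class ThreePointFrequencies:
    """Reduced three-point frequencies, stored on the strict wedge i<j<k.

    ``get(i, j, k)`` serves any index order via symmetry; repeated
    positions collapse onto f2_red / f1_red with Kronecker deltas.
    """

    def __init__(
        self,
        wedge: np.ndarray,
        triplets: np.ndarray,
        f1_red: np.ndarray,
        f2_red: np.ndarray,
    ):
        self.wedge = wedge
        self.triplets = triplets
        self.f1_red = f1_red
        self.f2_red = f2_red
        self.N = f1_red.shape[0]
        self.q_red = f1_red.shape[1]
        _, self._lookup = _triplet_index(self.N)

    def get(self, i: int, j: int, k: int) -> np.ndarray:
        """f3_red[i, j, k] as a (q_red, q_red, q_red) block."""
        qr = self.q_red
        eye = np.eye(qr)
        if i == j == k:
            return np.einsum("a,ab,ac->abc", self.f1_red[i], eye, eye)
        if i == j:
            return np.einsum("ab,ac->abc", eye, self.f2_red[i, k])
        if i == k:
            return np.einsum("ac,ab->abc", eye, self.f2_red[i, j])
        if j == k:
            return np.einsum("bc,ab->abc", eye, self.f2_red[i, j])
        order = np.argsort([i, j, k], kind="stable")
        si, sj, sk = sorted((i, j, k))
        block = self.wedge[self._lookup[(si, sj, sk)]]
        # move sorted state axes back to the caller's index order
        inv = np.argsort(order)
        return np.ascontiguousarray(np.transpose(block, axes=tuple(inv)))

    def dense(self, truncate: int | None = None) -> np.ndarray:
        """Materialize the full (N, N, N, t, t, t) tensor.

        ``truncate`` keeps only the first ``truncate`` reduced states
        (used for covariance work over states 1..q_red-1).
        """
        t = self.q_red if truncate is None else truncate
        N = self.N
        out = np.empty((N, N, N, t, t, t))
        for i in range(N):
            for j in range(N):
                for k in range(N):
                    out[i, j, k] = self.get(i, j, k)[:t, :t, :t]
        return out


def three_point_frequencies_reduced(
    msa: EncodedMSA,
    weights: SequenceWeights,
    pseudocount_ratio: float,
    rmap: ReductionMap,
    workers: int = 1,
    memory_cap: int = DEFAULT_MEMORY_CAP,
) -> ThreePointFrequencies:
    """Pseudocounted reduced triplet frequencies f3_red on the i<j<k wedge.

    The pseudocount term for a distinct triplet is
    lambda_c * c_a * c_b * c_c / q^3 with c the class sizes, i.e. the
    class sum of a uniform lambda_c/q^3 full-alphabet pseudocount.
    """
    N = msa.N
    qr = rmap.q_red
    n_tri = N * (N - 1) * (N - 2) // 6
    need = n_tri * qr**3 * 8
    if need > memory_cap:
        raise MemoryBudgetError(
            f"three-point tensor needs {need / 1e9:.2f} GB "
            f"(N={N}, q_red={qr}), exceeding the cap of {memory_cap / 1e9:.2f} GB; "
            "raise memory_cap or use a smaller reduced alphabet"
        )
    q = msa.alphabet.q
    lam = pseudocount_ratio * weights.B_eff
    sizes = rmap.class_sizes().astype(float)
    pc = lam * np.einsum("a,b,c->abc", sizes, sizes, sizes) / q**3
    denom = lam + weights.B_eff

    # reduced one-hot, with the weights folded into one factor
    data, w = _canonical_rows(msa, weights)
    xr = np.zeros((msa.B, N, qr))
    b = np.arange(msa.B)[:, None]
    i_idx = np.arange(N)[None, :]
    xr[b, i_idx, rmap.mu[data]] = 1.0
    wxr = w[:, None, None] * xr

    triplets, lookup = _triplet_index(N)
    wedge = np.empty((n_tri, qr, qr, qr))

    def fill_i(i: int) -> None:
        for j in range(i + 1, N - 1):
            # counts for all k > j at once
            pair = np.einsum("ba,bc->bac", wxr[:, i, :], xr[:, j, :])
            blocks = np.einsum("bac,bkg->kacg", pair, xr[:, j + 1 :, :], optimize=True)
            for dk, k in enumerate(range(j + 1, N)):
                wedge[lookup[(i, j, k)]] = (pc + blocks[dk]) / denom

    rows = [i for i in range(N - 2)]
    if workers <= 1 or len(rows) <= 1:
        for i in rows:
            fill_i(i)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(fill_i, rows))

    f1 = one_point_frequencies(msa, weights, pseudocount_ratio)
    f2 = two_point_frequencies(msa, weights, pseudocount_ratio)
    f1_red, f2_red = reduce_one_two_point(f1, f2, rmap)
    return ThreePointFrequencies(wedge, triplets, f1_red, f2_red)


@dataclass
class FrequencyModel:
    """All frequency tensors one run needs, full and reduced alphabet."""

    f1: np.ndarray
    f2: np.ndarray
    f1_red: np.ndarray
    f2_red: np.ndarray
    f3_red: ThreePointFrequencies | None
    rmap: ReductionMap
    lambda_c: float
    pseudocount_ratio: float

    @property
    def N(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]

    @property
    def q_red(self) -> int:
        return self.rmap.q_red


def build_frequency_model(
    msa: EncodedMSA,
    weights: SequenceWeights,
    pseudocount_ratio: float,
    rmap: ReductionMap,
    workers: int = 1,
    with_triplets: bool = True,
    memory_cap: int = DEFAULT_MEMORY_CAP,
) -> FrequencyModel:
    """Estimate every frequency tensor for one analysis run."""
    if pseudocount_ratio < 0:
        raise ConfigurationError("pseudocount ratio must be >= 0")
    if rmap.q != msa.alphabet.q:
        raise ConfigurationError(
            f"reduction map covers {rmap.q} states but the alphabet has {msa.alphabet.q}"
        )
    f1 = one_point_frequencies(msa, weights, pseudocount_ratio)
    f2 = two_point_frequencies(msa, weights, pseudocount_ratio)
    f1_red, f2_red = reduce_one_two_point(f1, f2, rmap)
    f3 = None
    if with_triplets and rmap.q_red >= 2 and msa.N >= 3:
        f3 = three_point_frequencies_reduced(
            msa, weights, pseudocount_ratio, rmap, workers=workers, memory_cap=memory_cap
        )
    return FrequencyModel(
        f1, f2, f1_red, f2_red, f3, rmap,
        lambda_c=pseudocount_ratio * weights.B_eff,
        pseudocount_ratio=pseudocount_ratio,
    )
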