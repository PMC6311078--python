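"""Mean-field inversion with a three-body correction.

Plain mean-field DCA estimates pairwise couplings as J = -g, where g is
the inverse of the connected two-point covariance matrix
e_ij(l,m) = f_ij(l,m) - f_i(l) f_j(m) built over the truncated state
range 1..q-1 (the last state is the gauge reference; its coupling rows
are zero-filled).  The three-body extension adds a correction assembled
from the connected three-point covariance over the reduced alphabet:

    J_ij(l,m) = -g_ij(l,m)
                + sum_{k != i,j} sum_{n <= q-1}
                  g3_red[i,j,k](mu(l), mu(m), mu(n)) * f_k(n),

where g3_red is the triple contraction of the reduced three-point
covariance e3_red with three copies of the reduced two-point inverse
(one per position/state leg).  g3_red entries whose class argument is
the dropped reduced class are zero by the same truncation convention.

The 6-index g3_red tensor is never materialized for all triplets: the
sum over (k, n) and the third inverse factor are contracted first, so
the working memory beyond e3_red itself is O(N^2 q_red^2).  All
contractions use fixed summation orders, making results bit-stable
across runs and worker counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ReductionMap
from .errors import InversionError, MemoryBudgetError
from .frequencies import DEFAULT_MEMORY_CAP, FrequencyModel


@dataclass
class CovariancePair:
    """Connected two-point covariance e and its inverse g.

    Both are stored as (N, N, t, t) block tensors over the truncated
    state range t = q-1 (or q_red-1 for the reduced variant); ``matrix``
    views reshape them to the joint (N*t, N*t) form.
    """

    e: np.ndarray
    g: np.ndarray

    @property
    def N(self) -> int:
        return self.e.shape[0]

    @property
    def t(self) -> int:
        return self.e.shape[2]

    def e_matrix(self) -> np.ndarray:
        return _blocks_to_matrix(self.e)

    def g_matrix(self) -> np.ndarray:
        return _blocks_to_matrix(self.g)


@dataclass
class CovarianceTriplet:
    """Connected three-point covariance over truncated reduced states."""

    e3: np.ndarray  # (N, N, N, t, t, t), t = q_red - 1


@dataclass
class CouplingSet:
    """Pairwise couplings plus the contracted three-body terms.

    ``J`` is (N, N, q, q) over the full alphabet with the dropped-state
    rows/columns zero-filled.  ``vb`` holds the eta-summed, k-summed
    three-body inverse terms sum_{k != i,j} sum_eta V_ijk^red(a, b, eta)
    with V = -g3_red, needed by the zero-sum gauge; None when no
    three-body correction was computed.
    """

    J: np.ndarray
    vb: np.ndarray | None
    rmap: ReductionMap


def _blocks_to_matrix(blocks: np.ndarray) -> np.ndarray:
    N, _, t, _ = blocks.shape
    return blocks.transpose(0, 2, 1, 3).reshape(N * t, N * t)


def _matrix_to_blocks(mat: np.ndarray, N: int, t: int) -> np.ndarray:
    return mat.reshape(N, t, N, t).transpose(0, 2, 1, 3)


def build_pair_covariance(fm: FrequencyModel, reduced: bool = False) -> CovariancePair:
    """Covariance over truncated states and its joint matrix inverse.

    ``reduced`` selects the reduced-alphabet frequencies; the matrix is
    inverted as one dense N*(q-1)-dimensional symmetric system.
    """
    f1, f2 = (fm.f1_red, fm.f2_red) if reduced else (fm.f1, fm.f2)
    q = f1.shape[1]
    if q < 2:
        raise InversionError("covariance needs at least 2 states")
    t = q - 1
    e = f2[:, :, :t, :t] - np.einsum("il,jm->ijlm", f1[:, :t], f1[:, :t])
    mat = _blocks_to_matrix(e)
    mat = 0.5 * (mat + mat.T)
    try:
        ginv = np.linalg.inv(mat)
    except np.linalg.LinAlgError as exc:
        raise InversionError(
            "covariance matrix is singular; increase the pseudocount ratio"
        ) from exc
    if not np.all(np.isfinite(ginv)):
        raise InversionError(
            "covariance inversion produced non-finite values; "
            "increase the pseudocount ratio"
        )
    return CovariancePair(_matrix_to_blocks(mat, f1.shape[0], t), _matrix_to_blocks(ginv, f1.shape[0], t))


def build_triplet_covariance(
    fm: FrequencyModel, memory_cap: int = DEFAULT_MEMORY_CAP
) -> CovarianceTriplet:
    """Connected three-point covariance e3_red over truncated reduced states:

    e3[i,j,k](a,b,c) = f3[i,j,k](a,b,c) + 2 f1[i,a] f1[j,b] f1[k,c]
                       - f2[i,j,a,b] f1[k,c] - f2[i,k,a,c] f1[j,b]
                       - f2[j,k,b,c] f1[i,a]

    for all (i, j, k) including repeated positions (where f3 and f2
    delta-collapse onto lower-order tensors).
    """
    if fm.f3_red is None:
        raise ValueError("frequency model has no three-point tensor")
    t = fm.q_red - 1
    N = fm.N
    need = N**3 * t**3 * 8
    if need > memory_cap:
        raise MemoryBudgetError(
            f"dense e3 tensor needs {need / 1e9:.2f} GB, over the cap of "
            f"{memory_cap / 1e9:.2f} GB"
        )
    f1 = fm.f1_red[:, :t]
    f2 = fm.f2_red[:, :, :t, :t]
    e3 = fm.f3_red.dense(truncate=t)
    e3 += 2.0 * np.einsum("ia,jb,kc->ijkabc", f1, f1, f1)
    e3 -= np.einsum("ijab,kc->ijkabc", f2, f1)
    e3 -= np.einsum("ikac,jb->ijkabc", f2, f1)
    e3 -= np.einsum("jkbc,ia->ijkabc", f2, f1)
    return CovarianceTriplet(e3)


def _triplet_contraction(e3: np.ndarray, G: np.ndarray, X: np.ndarray) -> np.ndarray:
    """T[i,j,a,b] = sum_{k != i,j} sum_c g3_red[i,j,k](a,b,c) X[k,c], where

    g3_red[i,j,k](a,b,c) = - sum_{p,r,s} sum_{x,y,z}
        e3[p,r,s](x,y,z) G[i,p,a,x] G[j,r,b,y] G[k,s,c,z]

    (the position sums run over all N sites, self-terms included, as the
    inverse relation prescribes).  The 6-index g3_red is never formed:
    the (k, c) sum is folded in first, then the remaining two inverse
    legs, and the k = i, k = j terms are subtracted at the end.
    """
    N = G.shape[0]
    # sum over c for every candidate k:  H[k,s,z] = sum_c G[k,s,c,z] X[k,c]
    H = np.einsum("kscz,kc->ksz", G, X)
    # fold the third leg into e3:  Q[p,r,x,y,k] = sum_{s,z} e3[p,r,s,x,y,z] H[k,s,z]
    Q = np.einsum("prsxyz,ksz->prxyk", e3, H, optimize=True)
    Qs = Q.sum(axis=4)
    # full sum over k, then remove k = i and k = j
    A = np.einsum("prxy,ipax->iray", Qs, G, optimize=True)
    T_all = np.einsum("iray,jrby->ijab", A, G, optimize=True)
    U = np.einsum("prxyi,ipax->iray", Q, G, optimize=True)
    R_i = np.einsum("iray,jrby->ijab", U, G, optimize=True)
    W = np.einsum("prxyj,jrby->prxjb", Q, G, optimize=True)
    R_j = np.einsum("prxjb,ipax->ijab", W, G, optimize=True)
    return -(T_all - R_i - R_j)


def three_body_inverse_contraction(
    e3: CovarianceTriplet,
    g_red: CovariancePair,
    f1: np.ndarray,
    rmap: ReductionMap,
) -> np.ndarray:
    """Eq.-style correction C[i,j,a,b] = sum_{k != i,j} sum_{n <= q-1}
    g3_red[i,j,k](a, b, mu(n)) * f1[k,n], over truncated reduced classes.

    Full states n whose class is the dropped reduced class contribute
    nothing (their g3_red entry is zero by convention).
    """
    t = g_red.t
    q = f1.shape[1]
    N = f1.shape[0]
    # phi[k, c] = sum of f1[k, n] over full states n <= q-2 in class c < t
    phi = np.zeros((N, t))
    for n in range(q - 1):
        c = rmap.mu[n]
        if c < t:
            phi[:, c] += f1[:, n]
    C = _triplet_contraction(e3.e3, g_red.g, phi)
    ii = np.arange(N)
    C[ii, ii] = 0.0
    return C


def gauge_three_body_term(
    e3: CovarianceTriplet, g_red: CovariancePair
) -> np.ndarray:
    """vb[i,j,a,b] = sum_{k != i,j} sum_{eta <= q_red} V_ijk^red(a, b, eta)
    with V = -g3_red (zero at the dropped class), used by the zero-sum
    gauge; truncated reduced classes a, b < q_red - 1."""
    N = g_red.N
    t = g_red.t
    vb = -_triplet_contraction(e3.e3, g_red.g, np.ones((N, t)))
    ii = np.arange(N)
    vb[ii, ii] = 0.0
    return vb


def couplings(
    g_full: CovariancePair,
    C: np.ndarray | None,
    rmap: ReductionMap,
    vb: np.ndarray | None = None,
) -> CouplingSet:
    """Assemble J[i,j,l,m] = -g_ij(l,m) + C[i,j,mu(l),mu(m)] over the full
    alphabet; rows/columns of the dropped state q are zero, and the
    diagonal i == j is zeroed (self-couplings carry no contact signal).
    """
    N, _, t, _ = g_full.g.shape
    q = t + 1
    J = np.zeros((N, N, q, q))
    J[:, :, :t, :t] = -g_full.g
    if C is not None and rmap.q_red >= 2:
        tr = rmap.q_red - 1
        Cpad = np.zeros((N, N, rmap.q_red, rmap.q_red))
        Cpad[:, :, :tr, :tr] = C
        lift = Cpad[:, :, rmap.mu[:, None], rmap.mu[None, :]]
        J[:, :, :t, :t] += lift[:, :, :t, :t]
    ii = np.arange(N)
    J[ii, ii] = 0.0
    return CouplingSet(J, vb, rmap)
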