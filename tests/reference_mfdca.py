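"""Independently coded plain mean-field DCA, used as a cross-check.

Implements classical two-body mfDCA with the same conventions as the
package (reweighting at a Hamming-fraction threshold, uniform
pseudocount lambda_c = ratio * B_eff, delta-collapsed diagonal blocks,
joint truncated-state covariance inversion, J = -g, zero-sum gauge by
double centering, Frobenius norm including the gap state, APC over the
|i - j| >= 2 pair set) — but sharing no code with it.  The three-body
pipeline run with the constant (q_red = 1) reduction map must reproduce
these scores exactly.
"""

from __future__ import annotations

import numpy as np


def mfdca_scores(data: np.ndarray, q: int, theta: float, pc_ratio: float) -> np.ndarray:
    """Symmetric APC-corrected contact score matrix (gap state included)."""
    B, N = data.shape
    # reweighting
    neigh = np.zeros(B)
    for b in range(B):
        d = (data != data[b]).sum(axis=1) / N
        neigh[b] = (d <= theta + 1e-12).sum()
    w = 1.0 / neigh
    beff = w.sum()
    lam = pc_ratio * beff

    # frequencies
    one = np.full((N, q), lam / q)
    for b in range(B):
        for i in range(N):
            one[i, data[b, i]] += w[b]
    one /= lam + beff
    t = q - 1
    cov = np.zeros((N * t, N * t))
    for i in range(N):
        for j in range(N):
            if i == j:
                blk = np.diag(one[i, :t]) - np.outer(one[i, :t], one[i, :t])
            else:
                two = np.full((q, q), lam / q**2)
                for b in range(B):
                    two[data[b, i], data[b, j]] += w[b]
                two /= lam + beff
                blk = two[:t, :t] - np.outer(one[i, :t], one[j, :t])
            cov[i * t : (i + 1) * t, j * t : (j + 1) * t] = blk
    cov = 0.5 * (cov + cov.T)
    g = np.linalg.inv(cov)

    # couplings, gauge, Frobenius
    F = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            J = np.zeros((q, q))
            J[:t, :t] = -g[i * t : (i + 1) * t, j * t : (j + 1) * t]
            J = J - J.mean(axis=0) - J.mean(axis=1)[:, None] + J.mean()
            F[i, j] = np.sqrt((J**2).sum())

    # APC over the reported pair set
    mask = np.abs(np.subtract.outer(np.arange(N), np.arange(N))) >= 2
    mi = (F * mask).sum(axis=1) / mask.sum(axis=1)
    tot = (F * mask).sum() / mask.sum()
    S = F - np.outer(mi, mi) / tot
    return np.where(mask, S, 0.0)
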