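"""Brute-force reference implementations used only by the test suite.

Everything here is written as naive nested loops, directly off the
defining formulas, deliberately sharing no code with the package: these
are the independent oracles the fast vectorized implementation is
checked against on tiny fixtures.
"""

from __future__ import annotations

import numpy as np


def weights(data: np.ndarray, theta: float) -> np.ndarray:
    B, N = data.shape
    w = np.empty(B)
    for b in range(B):
        nb = 0
        for a in range(B):
            d = sum(int(data[a, i] != data[b, i]) for i in range(N)) / N
            if d <= theta + 1e-12:
                nb += 1
        w[b] = 1.0 / nb
    return w


def f1(data, w, q, pc):
    B, N = data.shape
    beff = w.sum()
    lam = pc * beff
    out = np.empty((N, q))
    for i in range(N):
        for l in range(q):
            s = sum(w[b] for b in range(B) if data[b, i] == l)
            out[i, l] = (lam / q + s) / (lam + beff)
    return out


def f2(data, w, q, pc):
    B, N = data.shape
    beff = w.sum()
    lam = pc * beff
    out = np.empty((N, N, q, q))
    one = f1(data, w, q, pc)
    for i in range(N):
        for j in range(N):
            for l in range(q):
                for m in range(q):
                    if i == j:
                        out[i, j, l, m] = one[i, l] if l == m else 0.0
                    else:
                        s = sum(
                            w[b]
                            for b in range(B)
                            if data[b, i] == l and data[b, j] == m
                        )
                        out[i, j, l, m] = (lam / q**2 + s) / (lam + beff)
    return out


def reduce12(one, two, mu, qr):
    N, q = one.shape
    f1r = np.zeros((N, qr))
    f2r = np.zeros((N, N, qr, qr))
    for i in range(N):
        for l in range(q):
            f1r[i, mu[l]] += one[i, l]
    for i in range(N):
        for j in range(N):
            for l in range(q):
                for m in range(q):
                    f2r[i, j, mu[l], mu[m]] += two[i, j, l, m]
    return f1r, f2r


def f3_red(data, w, q, pc, mu, qr):
    """Dense (N,N,N,qr,qr,qr) reduced triplet frequencies, all index
    orders, repeated positions delta-collapsed onto lower orders."""
    B, N = data.shape
    beff = w.sum()
    lam = pc * beff
    sizes = np.bincount(mu, minlength=qr).astype(float)
    f1r, f2r = reduce12(f1(data, w, q, pc), f2(data, w, q, pc), mu, qr)
    out = np.zeros((N, N, N, qr, qr, qr))
    red = mu[data]
    for i in range(N):
        for j in range(N):
            for k in range(N):
                for a in range(qr):
                    for b2 in range(qr):
                        for c in range(qr):
                            if i == j and j == k:
                                v = f1r[i, a] if a == b2 == c else 0.0
                            elif i == j:
                                v = f2r[i, k, a, c] if a == b2 else 0.0
                            elif i == k:
                                v = f2r[i, j, a, b2] if a == c else 0.0
                            elif j == k:
                                v = f2r[i, j, a, b2] if b2 == c else 0.0
                            else:
                                s = sum(
                                    w[b]
                                    for b in range(B)
                                    if red[b, i] == a
                                    and red[b, j] == b2
                                    and red[b, k] == c
                                )
                                v = (lam * sizes[a] * sizes[b2] * sizes[c] / q**3 + s) / (
                                    lam + beff
                                )
                            out[i, j, k, a, b2, c] = v
    return out


def pair_covariance(one, two):
    """Connected covariance over truncated states and its inverse, as
    (N,N,t,t) blocks."""
    N, q = one.shape
    t = q - 1
    mat = np.empty((N * t, N * t))
    for i in range(N):
        for j in range(N):
            for l in range(t):
                for m in range(t):
                    mat[i * t + l, j * t + m] = two[i, j, l, m] - one[i, l] * one[j, m]
    mat = 0.5 * (mat + mat.T)
    inv = np.linalg.inv(mat)
    e = np.empty((N, N, t, t))
    g = np.empty((N, N, t, t))
    for i in range(N):
        for j in range(N):
            for l in range(t):
                for m in range(t):
                    e[i, j, l, m] = mat[i * t + l, j * t + m]
                    g[i, j, l, m] = inv[i * t + l, j * t + m]
    return e, g


def e3_red(f3d, f1r, f2r, t):
    N = f1r.shape[0]
    out = np.empty((N, N, N, t, t, t))
    for i in range(N):
        for j in range(N):
            for k in range(N):
                for a in range(t):
                    for b in range(t):
                        for c in range(t):
                            out[i, j, k, a, b, c] = (
                                f3d[i, j, k, a, b, c]
                                + 2 * f1r[i, a] * f1r[j, b] * f1r[k, c]
                                - f2r[i, j, a, b] * f1r[k, c]
                                - f2r[i, k, a, c] * f1r[j, b]
                                - f2r[j, k, b, c] * f1r[i, a]
                            )
    return out


def g3_red(e3, g_red):
    """Naive six-nested-loop inverse relation: the position sums run
    over all sites, self-terms included."""
    N, _, t, _ = g_red.shape
    out = np.zeros((N, N, N, t, t, t))
    for i in range(N):
        for j in range(N):
            for k in range(N):
                for a in range(t):
                    for b in range(t):
                        for c in range(t):
                            s = 0.0
                            for a1 in range(N):
                                for b1 in range(N):
                                    for c1 in range(N):
                                        for a2 in range(t):
                                            for b2 in range(t):
                                                for c2 in range(t):
                                                    s += (
                                                        e3[a1, b1, c1, a2, b2, c2]
                                                        * g_red[i, a1, a, a2]
                                                        * g_red[j, b1, b, b2]
                                                        * g_red[k, c1, c, c2]
                                                    )
                            out[i, j, k, a, b, c] = -s
    return out


def correction(g3, one, mu, qr):
    """C[i,j,a,b] = sum_{k != i,j} sum_{n <= q-2} g3[i,j,k,a,b,mu(n)] f1[k,n],
    entries at the dropped reduced class taken as zero."""
    N, q = one.shape
    t = qr - 1
    out = np.zeros((N, N, t, t))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            for a in range(t):
                for b in range(t):
                    s = 0.0
                    for k in range(N):
                        if k in (i, j):
                            continue
                        for n in range(q - 1):
                            c = mu[n]
                            if c < t:
                                s += g3[i, j, k, a, b, c] * one[k, n]
                    out[i, j, a, b] = s
    return out


def couplings(g_full, corr, mu, qr):
    N, _, t, _ = g_full.shape
    q = t + 1
    tr = qr - 1
    J = np.zeros((N, N, q, q))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            for l in range(t):
                for m in range(t):
                    J[i, j, l, m] = -g_full[i, j, l, m]
                    if corr is not None and mu[l] < tr and mu[m] < tr:
                        J[i, j, l, m] += corr[i, j, mu[l], mu[m]]
    return J


def gauge(J, g3, mu, qr):
    """Literal evaluation of the zero-sum gauge expression, with
    V = -g3_red (zero whenever an argument is the dropped class) and all
    first-two V arguments mapped."""
    N, _, q, _ = J.shape
    tr = qr - 1

    def V(i, j, k, a, b, c):
        if g3 is None or a >= tr or b >= tr or c >= tr:
            return 0.0
        return -g3[i, j, k, a, b, c]

    out = np.empty_like(J)
    for i in range(N):
        for j in range(N):
            blk = J[i, j]
            for l in range(q):
                for m in range(q):
                    v = blk[l, m]
                    for r in range(q):
                        v += (1 / q) * (
                            -blk[r, m] - blk[l, r] + (1 / q) * sum(blk[r, s] for s in range(q))
                        )
                    if g3 is not None and i != j:
                        for k in range(N):
                            if k in (i, j):
                                continue
                            for eta in range(qr):
                                term = V(i, j, k, mu[l], mu[m], eta)
                                for r in range(q):
                                    term += (1 / q) * (
                                        -V(i, j, k, mu[r], mu[m], eta)
                                        - V(i, j, k, mu[l], mu[r], eta)
                                        + (1 / q)
                                        * sum(V(i, j, k, mu[r], mu[s], eta) for s in range(q))
                                    )
                                v += term / qr
                    out[i, j, l, m] = v
    return out


def frobenius(J_hat, ignore_last=False):
    N, _, q, _ = J_hat.shape
    hi = q - 1 if ignore_last else q
    F = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            F[i, j] = np.sqrt(
                sum(J_hat[i, j, l, m] ** 2 for l in range(hi) for m in range(hi))
            )
    return F


def apc(raw):
    """APC with means over the |i-j| >= 2 pair set; returns the
    corrected matrix (only |i-j| >= 2 entries meaningful)."""
    N = raw.shape[0]
    pairs = [(i, j) for i in range(N) for j in range(N) if abs(i - j) >= 2]
    mean_i = {}
    for i in range(N):
        vals = [raw[i, j] for j in range(N) if abs(i - j) >= 2]
        mean_i[i] = sum(vals) / len(vals)
    total = sum(raw[i, j] for i, j in pairs) / len(pairs)
    out = np.zeros((N, N))
    for i, j in pairs:
        out[i, j] = raw[i, j] - mean_i[i] * mean_i[j] / total
    return out
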