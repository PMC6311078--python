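"""From couplings to ranked contact scores, and their evaluation.

Couplings are first moved to the zero-sum gauge (every coupling table
sums to zero over each state index), which shifts single-site bias out
of the pair terms.  With three-body terms present, the gauge also folds
in the class-averaged three-body inverse contributions, lifted back to
the full alphabet through the reduction map — double-centering the
augmented table satisfies the zero-sum identity exactly.

Raw scores are Frobenius norms of the gauged q x q coupling blocks; by
default the gap state contributes (reduced-alphabet classes mix gaps
with residues), which ``ignore_last`` disables.  The average product
correction (APC) then subtracts the entropic/phylogenetic background:

    S_ij = F_ij - mean(F_i.) * mean(F_.j) / mean(F_..)

with all means taken over the reported pair set |i - j| >= 2.

The area under the precision curve, A = (1/C) * sum_{i=1..C} p_i / i,
summarizes ranking quality against a known contact list (C true
contacts, p_i true positives among the first i predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import CouplingSet
from .msa_io import ScoreTable


@dataclass
class GaugedCouplings:
    """Couplings in zero-sum gauge: (N, N, q, q), rows/cols sum to zero."""

    J_hat: np.ndarray


def _double_center(blocks: np.ndarray) -> np.ndarray:
    """Remove per-state row/column means from every (i, j) coupling block."""
    row = blocks.mean(axis=2, keepdims=True)
    col = blocks.mean(axis=3, keepdims=True)
    tot = blocks.mean(axis=(2, 3), keepdims=True)
    return blocks - row - col + tot


def zero_sum_gauge(cs: CouplingSet) -> GaugedCouplings:
    """Transform couplings into the zero-sum gauge.

    The three-body part enters as the class-averaged, k-summed inverse
    terms (``cs.vb``, with V = -g3_red), lifted to full states through
    the reduction map and divided by q_red; the combined table is then
    double-centered, which enforces the zero-sum identity exactly.
    """
    J = cs.J
    if cs.vb is not None and cs.rmap.q_red >= 2:
        N, _, q, _ = J.shape
        qr = cs.rmap.q_red
        vpad = np.zeros((N, N, qr, qr))
        vpad[:, :, : qr - 1, : qr - 1] = cs.vb
        lift = vpad[:, :, cs.rmap.mu[:, None], cs.rmap.mu[None, :]]
        J = J + lift / qr
    return GaugedCouplings(_double_center(J))


def frobenius_scores(gc: GaugedCouplings, ignore_last: bool = False) -> np.ndarray:
    """Frobenius norm of each gauged coupling block; diagonal zero.

    ``ignore_last`` drops the last alphabet state (the gap, in the
    traditional DCA convention) from both state axes of the norm.
    """
    J = gc.J_hat
    if ignore_last:
        J = J[:, :, :-1, :-1]
    F = np.sqrt(np.einsum("ijlm,ijlm->ij", J, J))
    np.fill_diagonal(F, 0.0)
    return F


def apc(raw: np.ndarray) -> ScoreTable:
    """Average product correction over the reported pair set.

    Row/column/overall means are taken over pairs with |i - j| >= 2
    only, so the correction is consistent with what is reported.  An
    all-zero input would make the correction 0/0; the raw scores are
    then returned unchanged with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    denom_counts = mask.sum(axis=1)
    row_mean = np.where(denom_counts > 0, (raw * mask).sum(axis=1) / np.maximum(denom_counts, 1), 0.0)
    total = (raw * mask).sum() / max(mask.sum(), 1)
    if total == 0.0:
        warnings.warn("all raw scores are zero; APC skipped", stacklevel=2)
        return ScoreTable.from_matrix(raw)
    corrected = raw - np.outer(row_mean, row_mean) / total
    return ScoreTable.from_matrix(corrected)


@dataclass
class PrecisionInput:
    """A ranked prediction list against a truth contact set."""

    ranked: list[tuple[int, int]]
    truth: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.ranked)) != len(self.ranked):
            raise ValueError("ranked predictions contain duplicates")
        if not self.truth:
            raise ValueError("truth contact set is empty")


def area_under_precision(pin: PrecisionInput, n_contacts: int | None = None) -> float:
    """Area under the precision curve over the top C predictions:
    A = (1/C) sum_{i=1..C} p_i / i, in [0, 1]."""
    C = len(pin.truth) if n_contacts is None else n_contacts
    if C < 1:
        raise ValueError("need at least one true contact")
    if len(pin.ranked) < C:
        raise ValueError(
            f"only {len(pin.ranked)} ranked predictions for C={C} contacts"
        )
    truth = {(min(i, j), max(i, j)) for i, j in pin.truth}
    hits = 0
    acc = 0.0
    for rank, (i, j) in enumerate(pin.ranked[:C], start=1):
        if (min(i, j), max(i, j)) in truth:
            hits += 1
        acc += hits / rank
    return acc / C


def precision_at(ranked: list[tuple[int, int]], truth: set[tuple[int, int]], n: int) -> float:
    """Fraction of the top-n predictions that are true contacts."""
    t = {(min(i, j), max(i, j)) for i, j in truth}
    top = ranked[:n]
    return sum((min(i, j), max(i, j)) in t for i, j in top) / n
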