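"""Synthetic alignments from Potts models with planted interactions.

A :class:`PottsModel` defines P(sigma) proportional to exp(-H(sigma))
with H = -sum_i h_i(sigma_i) - sum_{i<j} J_ij(sigma_i, sigma_j)
- sum_{i<j<k} V_ijk(sigma_i, sigma_j, sigma_k), over sparse sets of
planted pair and triplet interactions.  Sampling such a model and
running the inference pipeline on the sample gives a fully controlled
parameter-recovery experiment: the planted pairs are the "true
contacts" and every planted index tuple keeps a separation of at least
two positions so the pairs are scoreable.

Interaction tables are drawn zero-mean (each table is double/triple
centered) so the zero-sum gauge is exercised nontrivially, and sparse,
so top-n precision is a meaningful recovery metric — mirroring the
sparsity of real contact maps.

Sequences are drawn by single-site Metropolis updates in systematic
site sweeps, recording one sequence every ``n_sweeps`` sweeps after a
burn-in; a fixed seed reproduces the MSA exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, Alphabet
from .errors import ConfigurationError
from .msa_io import EncodedMSA


@dataclass
class PottsModel:
    """Sparse Potts Hamiltonian with known planted interactions."""

    n_sites: int
    n_states: int
    h: np.ndarray  # (N, q) local fields
    pairs: dict[tuple[int, int], np.ndarray]  # (i, j) -> (q, q), i < j
    triplets: dict[tuple[int, int, int], np.ndarray]  # (i, j, k) -> (q, q, q)

    def __post_init__(self) -> None:
        for idx in itertools.chain(self.pairs, self.triplets):
            if list(idx) != sorted(set(idx)):
                raise ConfigurationError(f"interaction index {idx} not strictly increasing")

    @property
    def planted_pairs(self) -> set[tuple[int, int]]:
        """All (i, j), 0-based, carrying direct or triplet-mediated signal."""
        out = set(self.pairs)
        for (i, j, k) in self.triplets:
            out |= {(i, j), (i, k), (j, k)}
        return out

    def energy(self, seq: np.ndarray) -> float:
        e = -sum(self.h[i, seq[i]] for i in range(self.n_sites))
        for (i, j), tab in self.pairs.items():
            e -= tab[seq[i], seq[j]]
        for (i, j, k), tab in self.triplets.items():
            e -= tab[seq[i], seq[j], seq[k]]
        return float(e)


def _centered(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    tab = rng.normal(0.0, scale, size=shape)
    for ax in range(tab.ndim):
        tab -= tab.mean(axis=ax, keepdims=True)
    return tab


def make_model(
    n_sites: int,
    n_states: int,
    n_pairs: int,
    n_triplets: int = 0,
    coupling_strength: float = 1.0,
    field_strength: float = 0.0,
    seed: int = 0,
) -> PottsModel:
    """Draw a random sparse model; reproducible for a fixed seed.

    Planted pairs satisfy j >= i+2 and triplets (i, j, k) satisfy
    j >= i+2, k >= j+2, so every planted edge is scoreable.
    """
    rng = np.random.default_rng(seed)
    candidates = [(i, j) for i in range(n_sites) for j in range(i + 2, n_sites)]
    if n_pairs > len(candidates):
        raise ConfigurationError(
            f"cannot place {n_pairs} pairs with separation >= 2 in {n_sites} sites"
        )
    tri_candidates = [
        (i, j, k)
        for i in range(n_sites)
        for j in range(i + 2, n_sites)
        for k in range(j + 2, n_sites)
    ]
    if n_triplets > len(tri_candidates):
        raise ConfigurationError(
            f"cannot place {n_triplets} triplets with separation >= 2 in {n_sites} sites"
        )
    pair_idx = rng.choice(len(candidates), size=n_pairs, replace=False) if n_pairs else []
    tri_idx = (
        rng.choice(len(tri_candidates), size=n_triplets, replace=False) if n_triplets else []
    )
    q = n_states
    h = (
        _centered(rng, (n_sites, q), field_strength)
        if field_strength > 0
        else np.zeros((n_sites, q))
    )
    pairs = {
        candidates[int(p)]: _centered(rng, (q, q), coupling_strength) for p in pair_idx
    }
    triplets = {
        tri_candidates[int(t)]: _centered(rng, (q, q, q), coupling_strength)
        for t in tri_idx
    }
    return PottsModel(n_sites, n_states, h, pairs, triplets)


def _site_terms(model: PottsModel):
    """For each site, the interactions touching it and the site's slot."""
    touching: list[list[tuple[tuple[int, ...], np.ndarray, int]]] = [
        [] for _ in range(model.n_sites)
    ]
    for idx, tab in itertools.chain(model.pairs.items(), model.triplets.items()):
        for slot, site in enumerate(idx):
            touching[site].append((idx, tab, slot))
    return touching


def _local_energy(model, touching, seq: np.ndarray, site: int, state: int) -> float:
    e = -model.h[site, state]
    for idx, tab, slot in touching[site]:
        states = tuple(state if s == site else seq[s] for s in idx)
        e -= tab[states]
    return e


def sample_msa(
    model: PottsModel,
    n_sequences: int,
    n_sweeps: int = 10,
    burn_in: int = 500,
    seed: int = 0,
) -> EncodedMSA:
    """Metropolis-sample an MSA of ``n_sequences`` from the model.

    One full systematic site sweep per Metropolis pass; a sequence is
    recorded every ``n_sweeps`` sweeps after ``burn_in`` sweeps.  States
    are encoded over the first q amino-acid symbols (no gaps).
    """
    if n_sweeps < 1 or burn_in < 1:
        raise ConfigurationError("n_sweeps and burn_in must be >= 1")
    if model.n_states > len(AMINO_ACIDS):
        raise ConfigurationError("too many states to encode as amino acids")
    rng = np.random.default_rng(seed)
    N, q = model.n_sites, model.n_states
    touching = _site_terms(model)
    seq = rng.integers(0, q, size=N)
    out = np.empty((n_sequences, N), dtype=np.intp)
    total_sweeps = burn_in + n_sequences * n_sweeps
    recorded = 0
    for sweep in range(total_sweeps):
        # propose uniformly over all q states (current included): keeps the
        # chain aperiodic even for field-free binary sites, where a
        # flip-only proposal would be accepted deterministically
        props = rng.integers(0, q, size=N)
        us = rng.random(N)
        for site in range(N):
            cur = seq[site]
            new = props[site]
            if new == cur:
                continue
            de = _local_energy(model, touching, seq, site, new) - _local_energy(
                model, touching, seq, site, cur
            )
            if de <= 0.0 or us[site] < np.exp(-de):
                seq[site] = new
        if sweep >= burn_in and (sweep - burn_in + 1) % n_sweeps == 0:
            out[recorded] = seq
            recorded += 1
            if recorded == n_sequences:
                break
    alphabet = Alphabet(tuple(AMINO_ACIDS[:q]))
    return EncodedMSA(out, alphabet)


def enumerate_boltzmann(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact Boltzmann distribution by exhaustive enumeration.

    Returns (sequences, probabilities); feasible only for tiny q**N.
    Serves as the independent reference for sampler validation.
    """
    N, q = model.n_sites, model.n_states
    if q**N > 200_000:
        raise ConfigurationError(f"enumeration of q^N = {q**N} states refused")
    seqs = np.array(list(itertools.product(range(q), repeat=N)), dtype=np.intp)
    energies = np.array([model.energy(s) for s in seqs])
    w = np.exp(-(energies - energies.min()))
    return seqs, w / w.sum()
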