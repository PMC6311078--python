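"""Reading and writing alignments, score tables and contact lists.

Input alignments are aligned FASTA (protein, gap ``-``; ``.`` accepted
and normalized to ``-``).  Sequences whose gap fraction strictly exceeds
a threshold are dropped before encoding; the alphabet is then shrunk to
the symbols actually present.  Score tables are headerless CSV rows
``i,j,score`` with 1-based positions and j >= i+2 (pairs separated by at
least one residue along the backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, Alphabet, build_alphabet, normalize_symbol
from .errors import EmptyMSAError, InvalidMSAError


@dataclass
class EncodedMSA:
    """Integer-encoded alignment: B sequences x N positions.

    ``data[b, i]`` is the 0-based state of sequence b at position i,
    valid in ``alphabet``.
    """

    data: np.ndarray
    alphabet: Alphabet
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.intp)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise InvalidMSAError(
                f"MSA must be B>=1 sequences of length N>=2, got shape {self.data.shape}"
            )
        if self.data.min() < 0 or self.data.max() >= self.alphabet.q:
            raise InvalidMSAError("MSA contains states outside its alphabet")
        if not self.ids:
            self.ids = [f"seq{b + 1}" for b in range(self.data.shape[0])]

    @property
    def B(self) -> int:
        return int(self.data.shape[0])

    @property
    def N(self) -> int:
        return int(self.data.shape[1])

    def sequences(self) -> list[str]:
        """Decode back to aligned strings."""
        syms = np.array(self.alphabet.symbols)
        return ["".join(row) for row in syms[self.data]]


@dataclass
class ScoreTable:
    """Pairwise contact scores for position pairs with j >= i+2 (1-based)."""

    entries: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, _ in self.entries:
            if j < i + 2:
                raise ValueError(f"pair ({i},{j}) not separated by at least one residue")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i},{j})")
            seen.add((i, j))
        self.entries = sorted(self.entries, key=lambda e: (e[0], e[1]))

    @classmethod
    def from_matrix(cls, scores: np.ndarray) -> "ScoreTable":
        """Collect the j >= i+2 upper triangle of a symmetric score matrix."""
        scores = np.asarray(scores)
        n = scores.shape[0]
        entries = [
            (i + 1, j + 1, float(scores[i, j]))
            for i in range(n)
            for j in range(i + 2, n)
        ]
        return cls(entries)

    def ranked_pairs(self) -> list[tuple[int, int]]:
        """Pairs ordered by decreasing score (ties broken by position)."""
        order = sorted(self.entries, key=lambda e: (-e[2], e[0], e[1]))
        return [(i, j) for i, j, _ in order]


def read_msa_fasta(path, max_gap_fraction: float = 0.9) -> EncodedMSA:
    """Read an aligned FASTA file into an :class:`EncodedMSA`.

    Sequences are normalized (``.`` and ambiguous residues to ``-``);
    those whose gap fraction is *strictly greater* than
    ``max_gap_fraction`` are dropped.  The alphabet is shrunk to the
    symbols present in the surviving sequences.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidMSAError(f"no FASTA records in {path}")
    seqs = []
    ids = []
    length = None
    for rec in records:
        s = "".join(normalize_symbol(c) for c in str(rec.seq))
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise InvalidMSAError(
                f"ragged alignment: record {rec.id!r} has length {len(s)}, expected {length}"
            )
        if s.count(GAP) / len(s) > max_gap_fraction:
            continue
        seqs.append(s)
        ids.append(rec.id)
    if not seqs:
        raise EmptyMSAError(
            f"no sequences survive the gap filter (max_gap_fraction={max_gap_fraction})"
        )
    alphabet = build_alphabet("".join(seqs))
    lut = {s: i for i, s in enumerate(alphabet.symbols)}
    data = np.array([[lut[c] for c in s] for s in seqs], dtype=np.intp)
    return EncodedMSA(data, alphabet, ids)


def write_msa_fasta(msa: EncodedMSA, path) -> None:
    """Write an encoded MSA back to aligned FASTA."""
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for s, i in zip(msa.sequences(), msa.ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_scores_csv(table: ScoreTable, path) -> None:
    """Write ``i,j,score`` rows (1-based, sorted, full float precision)."""
    with open(path, "w") as fh:
        for i, j, s in table.entries:
            fh.write(f"{i},{j},{s!r}\n")


def read_scores_csv(path) -> ScoreTable:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i, j, s = line.split(",")
            entries.append((int(i), int(j), float(s)))
    return ScoreTable(entries)


def write_truth_csv(pairs, path) -> None:
    """Write a truth-contact list as two-column CSV of 1-based pairs."""
    with open(path, "w") as fh:
        for i, j in sorted(pairs):
            fh.write(f"{i},{j}\n")


def read_truth_csv(path) -> set[tuple[int, int]]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i, j = (int(x) for x in line.split(",")[:2])
            pairs.add((min(i, j), max(i, j)))
    return pairs


def gap_gap_frequencies(msa: EncodedMSA) -> np.ndarray:
    """Raw two-point gap-gap frequencies of the unpreprocessed MSA.

    Entry (i, j) is the plain fraction of sequences carrying a gap at
    both positions — no reweighting, no pseudocount.  Useful as a
    diagnostic for correlated gap regions (gap-padded termini), a known
    source of false-positive contact predictions.
    """
    gap_state = msa.alphabet.gap_state
    if gap_state is None:
        return np.zeros((msa.N, msa.N))
    g = (msa.data == gap_state).astype(float)
    return (g.T @ g) / msa.B
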