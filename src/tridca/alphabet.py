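"""Alphabets and reduced-alphabet maps.

The full alphabet is the 20 standard amino acids (one-letter codes, in
alphabetical order) followed by the gap character ``-``, giving q = 21
states.  An MSA may use only a subset of those symbols; the alphabet is
then *shrunk* to the states actually present, so every downstream tensor
is as small as possible and every state has nonzero support.

A :class:`ReductionMap` is a surjection mu from the q full states onto
q_red classes.  Grouping amino acids into biochemical classes (polarity,
hydrophobicity, ...) tames the q^3 state space of three-body couplings;
the identity map (q_red = q) and the constant map (q_red = 1, which turns
the method into plain mean-field DCA) are both representable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidMSAError

#: Canonical full alphabet: the 20 amino acids, then the gap.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
CANONICAL_SYMBOLS: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP,)

#: Ambiguous / non-standard residue codes normalized to gap before encoding.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BJOUXZ")


def normalize_symbol(c: str) -> str:
    """Map a raw alignment character onto the canonical alphabet.

    Uppercases, turns ``.`` into ``-`` and ambiguous residue codes
    (B, J, O, U, X, Z) into gaps.  Any other character raises
    :class:`InvalidMSAError`.
    """
    c = c.upper()
    if c == ".":
        return GAP
    if c in AMBIGUOUS_RESIDUES:
        return GAP
    if c == GAP or c in AMINO_ACIDS:
        return c
    raise InvalidMSAError(f"illegal alignment character {c!r}")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of states over which an MSA is encoded.

    ``symbols`` follow canonical order (amino acids, then gap); states are
    encoded internally as 0-based integers in the same order.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 1:
            raise InvalidMSAError("empty alphabet")
        order = {s: i for i, s in enumerate(CANONICAL_SYMBOLS)}
        idx = [order[s] for s in self.symbols]
        if idx != sorted(idx):
            raise ValueError("alphabet symbols must follow canonical order")

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def last_is_gap(self) -> bool:
        return self.symbols[-1] == GAP

    def index(self, symbol: str) -> int:
        """0-based state index of a (normalized) symbol."""
        return self.symbols.index(symbol)

    @property
    def gap_state(self) -> int | None:
        """0-based index of the gap state, or None if the MSA has no gaps."""
        return self.q - 1 if self.last_is_gap else None


#: The unshrunk 21-state alphabet.
FULL_ALPHABET = Alphabet(CANONICAL_SYMBOLS)


def build_alphabet(raw_symbols) -> Alphabet:
    """Shrink the canonical alphabet to the states present in an MSA.

    ``raw_symbols`` is any iterable of alignment characters.  Characters
    are normalized first (unknown residues become gaps), then the distinct
    states are kept in canonical order.
    """
    seen: set[str] = set()
    n = 0
    for c in raw_symbols:
        seen.add(normalize_symbol(c))
        n += 1
    if n == 0:
        raise InvalidMSAError("cannot build an alphabet from an empty MSA")
    return Alphabet(tuple(s for s in CANONICAL_SYMBOLS if s in seen))


@dataclass(frozen=True)
class ReductionMap:
    """Surjection mu from full-alphabet states onto q_red classes.

    ``mu[l]`` is the 0-based class of 0-based state ``l``; classes are
    numbered compactly, 0..q_red-1, in order of first appearance.
    """

    mu: np.ndarray = field(compare=False)
    q_red: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=np.intp)
        object.__setattr__(self, "mu", mu)
        if mu.ndim != 1 or mu.size < 1:
            raise ConfigurationError("reduction map must be a non-empty vector")
        if set(np.unique(mu)) != set(range(self.q_red)):
            raise ConfigurationError(
                f"reduction map is not surjective onto 0..{self.q_red - 1}"
            )

    @property
    def q(self) -> int:
        return int(self.mu.size)

    @property
    def is_identity(self) -> bool:
        return self.q_red == self.q

    def class_sizes(self) -> np.ndarray:
        """|mu^-1(alpha)| for each class alpha."""
        return np.bincount(self.mu, minlength=self.q_red)

    @classmethod
    def identity(cls, q: int) -> "ReductionMap":
        return cls(np.arange(q), q)

    @classmethod
    def constant(cls, q: int) -> "ReductionMap":
        return cls(np.zeros(q, dtype=np.intp), 1)

    @classmethod
    def from_labels(cls, labels) -> "ReductionMap":
        """Build a map from arbitrary integer class labels, compacting them
        to 0..q_red-1 in first-appearance order."""
        labels = list(labels)
        relabel: dict[int, int] = {}
        mu = np.empty(len(labels), dtype=np.intp)
        for i, lab in enumerate(labels):
            mu[i] = relabel.setdefault(lab, len(relabel))
        return cls(mu, len(relabel))


def reduce_state(l: int, rmap: ReductionMap) -> int:
    """Class of full-alphabet state ``l`` (both 0-based)."""
    if not 0 <= l < rmap.q:
        raise ValueError(f"state {l} outside 0..{rmap.q - 1}")
    return int(rmap.mu[l])


def load_reduction_map(path, row_index: int, alphabet: Alphabet) -> ReductionMap:
    """Load one row of a reduction-map CSV, restricted to ``alphabet``.

    The file has no header; each row carries one positive-integer class
    label per canonical full-alphabet symbol (21 columns, amino acids
    then gap).  ``row_index`` is 1-based.  The row is restricted to the
    symbols of the (possibly shrunken) alphabet and classes that become
    empty are compacted away, renumbered in first-appearance order.
    """
    if row_index < 1:
        raise ConfigurationError(f"map row index must be >= 1, got {row_index}")
    try:
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r]
    except OSError as exc:
        raise ConfigurationError(f"cannot read reduction map file {path}: {exc}") from exc
    if row_index > len(rows):
        raise ConfigurationError(
            f"map row {row_index} requested but {path} has only {len(rows)} rows"
        )
    row = [cell.strip() for cell in rows[row_index - 1]]
    if len(row) != len(CANONICAL_SYMBOLS):
        raise ConfigurationError(
            f"map row {row_index} has {len(row)} columns, expected "
            f"{len(CANONICAL_SYMBOLS)} (one per canonical symbol)"
        )
    labels = []
    for col, cell in enumerate(row, start=1):
        try:
            labels.append(int(cell))
        except ValueError:
            raise ConfigurationError(
                f"map row {row_index}, column {col}: non-integer class label {cell!r}"
            ) from None
        if labels[-1] < 1:
            raise ConfigurationError(
                f"map row {row_index}, column {col}: class labels must be positive"
            )
    canonical_pos = {s: i for i, s in enumerate(CANONICAL_SYMBOLS)}
    restricted = [labels[canonical_pos[s]] for s in alphabet.symbols]
    return ReductionMap.from_labels(restricted)
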