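"""Core sequence containers: alphabet, scaffold, alignments, frequency matrices.

Everything downstream (Potts fitting, Monte Carlo generation, affinity
regression) operates on fixed-length, ungapped peptide alignments that conform
to a *scaffold*: a template that pins certain positions (the three cysteines
and terminal residues of a bicyclic peptide) and leaves the loop positions
free. Positions are 1-based in every public interface, matching the residue
numbering used when discussing peptide variants (e.g. "Pro in position 15");
all arrays are 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("pepevo")

#: The 20 canonical amino acids, alphabetical one-letter order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet.

    Defaults to the 20 canonical amino acids; reduced alphabets (prefixes of
    the canonical order) are used by the synthetic benchmarks so that exact
    enumeration oracles stay tractable.
    """

    symbols: str = CANONICAL_AA

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if not self.symbols:
            raise ValueError("alphabet must be non-empty")

    @property
    def q(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        idx = self.symbols.find(symbol)
        if idx < 0:
            raise ValueError(f"symbol {symbol!r} not in alphabet")
        return idx

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence string to an int array of alphabet indices."""
        try:
            return np.array([self.index(s) for s in sequence], dtype=np.int64)
        except ValueError as exc:
            # re-raise with position information
            for pos, s in enumerate(sequence, start=1):
                if s not in self.symbols:
                    raise ValueError(
                        f"invalid symbol {s!r} at position {pos}"
                    ) from exc
            raise

    def decode(self, indices: Iterable[int]) -> str:
        return "".join(self.symbols[int(i)] for i in indices)


@dataclass(frozen=True)
class Scaffold:
    """Fixed-length peptide template with immutable positions.

    ``fixed`` maps 1-based positions to the residue pinned there. A bicyclic
    scaffold typically pins the three cysteines plus terminal residues; the
    remaining *variable* positions form the two loops the design explores.
    """

    L: int
    fixed: Mapping[int, str] = field(default_factory=dict)
    name: str = "scaffold"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("scaffold length must be >= 1")
        for pos, sym in self.fixed.items():
            if not (1 <= pos <= self.L):
                raise ValueError(f"fixed position {pos} outside [1, {self.L}]")
            if sym not in CANONICAL_AA:
                raise ValueError(f"fixed residue {sym!r} is not an amino acid")
        if len(self.fixed) >= self.L:
            raise ValueError("scaffold must have at least one variable position")
        object.__setattr__(self, "fixed", dict(self.fixed))

    @property
    def variable_positions(self) -> list[int]:
        """1-based positions free to mutate."""
        return [i for i in range(1, self.L + 1) if i not in self.fixed]

    @property
    def n_variable(self) -> int:
        return self.L - len(self.fixed)

    def conforms(self, sequence: str) -> bool:
        if len(sequence) != self.L:
            return False
        return all(sequence[pos - 1] == sym for pos, sym in self.fixed.items())

    def check(self, sequence: str) -> None:
        """Raise ValueError naming the first violation, if any."""
        if len(sequence) != self.L:
            raise ValueError(
                f"sequence length {len(sequence)} != scaffold length {self.L}"
            )
        for pos, sym in self.fixed.items():
            if sequence[pos - 1] != sym:
                raise ValueError(
                    f"position {pos} must be {sym!r}, got {sequence[pos - 1]!r}"
                )

    def random_conformant(self, rng: np.random.Generator, alphabet: Alphabet) -> str:
        chars = [alphabet.symbols[rng.integers(alphabet.q)] for _ in range(self.L)]
        for pos, sym in self.fixed.items():
            chars[pos - 1] = sym
        return "".join(chars)

    def to_dict(self) -> dict:
        return {"L": self.L, "fixed": {str(k): v for k, v in self.fixed.items()},
                "name": self.name}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaffold":
        return cls(L=int(d["L"]),
                   fixed={int(k): v for k, v in d.get("fixed", {}).items()},
                   name=d.get("name", "scaffold"))


@dataclass
class MSA:
    """Encoded alignment of equal-length scaffold-conformant sequences."""

    ids: list[str]
    matrix: np.ndarray  # (n, L) alphabet indices
    scaffold: Scaffold
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("MSA matrix must be 2-dimensional")
        n, L = self.matrix.shape
        if n < 1:
            raise ValueError("MSA must contain at least one sequence")
        if L != self.scaffold.L:
            raise ValueError(f"MSA width {L} != scaffold length {self.scaffold.L}")
        if len(self.ids) != n:
            raise ValueError("number of ids != number of rows")
        if len(set(self.ids)) != n:
            raise ValueError("sequence ids must be unique")
        if self.matrix.min() < 0 or self.matrix.max() >= self.alphabet.q:
            raise ValueError("matrix entries outside alphabet range")
        for row, seq_id in zip(self.matrix, self.ids):
            seq = self.alphabet.decode(row)
            if not self.scaffold.conforms(seq):
                raise ValueError(f"sequence {seq_id!r} violates scaffold")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return [self.alphabet.decode(row) for row in self.matrix]

    @classmethod
    def from_sequences(cls, ids: Sequence[str], sequences: Sequence[str],
                       scaffold: Scaffold,
                       alphabet: Alphabet | None = None) -> "MSA":
        alphabet = alphabet or Alphabet()
        matrix = np.stack([alphabet.encode(s) for s in sequences])
        return cls(ids=list(ids), matrix=matrix, scaffold=scaffold,
                   alphabet=alphabet)


@dataclass
class FrequencyMatrix:
    """Per-position residue frequencies of an alignment (L x q, rows sum to 1)."""

    freqs: np.ndarray
    pseudocount: float
    n_sequences: int
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")

    @property
    def L(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class AffinityRecord:
    """A peptide sequence paired with its measured (or predicted) Ki in molar."""

    id: str
    sequence: str
    ki: float  # molar
    family: str = ""

    def __post_init__(self) -> None:
        if not self.ki > 0:
            raise ValueError(f"Ki must be > 0, got {self.ki} for {self.id!r}")


def frequency_matrix(msa: MSA, pseudocount: float = 0.0,
                     weights: np.ndarray | None = None) -> FrequencyMatrix:
    """Weighted position-frequency matrix with a symmetric pseudocount.

    ``freqs[i, a] = (pc + sum_m w_m [sigma_mi == a]) / (q*pc + sum_m w_m)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n, L = msa.matrix.shape
    q = msa.alphabet.q
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,):
            raise ValueError("weights must have one entry per sequence")
        if (weights <= 0).any():
            raise ValueError("weights must be positive")
    counts = np.zeros((L, q))
    for i in range(L):
        np.add.at(counts[i], msa.matrix[:, i], weights)
    freqs = (pseudocount + counts) / (q * pseudocount + weights.sum())
    return FrequencyMatrix(freqs=freqs, pseudocount=pseudocount,
                           n_sequences=n, alphabet=msa.alphabet)


def information_content(fm: FrequencyMatrix, small_sample_correction: bool = False
                        ) -> np.ndarray:
    """Per-position information content in bits: ``log2(q) - H_i``.

    These are the column heights of a sequence logo. The small-sample
    correction is off by default: for families of n ~ 30-60 sequences the
    correction term (q-1)/(2n ln 2) would dominate the signal.
    """
    q = fm.alphabet.q
    f = fm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -terms.sum(axis=1)
    ic = np.log2(q) - entropy
    if small_sample_correction:
        ic = ic - (q - 1) / (2 * np.log(2) * max(fm.n_sequences, 1))
    return np.clip(ic, 0.0, np.log2(q))


def hamming_identity(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if isinstance(a, np.ndarray):
        return float(np.mean(np.asarray(a) == np.asarray(b)))
    return sum(x == y for x, y in zip(a, b)) / len(a)
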