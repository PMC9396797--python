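"""Hard pairing rules and the binary filter matrix M.

Four rules govern which base pairs a predicted structure may contain:

1. only canonical pairs (Watson-Crick A-U, G-C, and wobble G-U);
2. no base pairs with itself;
3. partners are at least four positions apart (|i - j| < 4 is forbidden);
4. each base has at most one partner.

Rules 1-3 depend only on the sequence and are captured by the L x L binary
mask M: ``M[i, j] == 1`` iff pairing i with j is permitted.  Rule 4 is a
row-sum constraint handled by the projection layer and checked by
:func:`validate_structure`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ALPHABET, RnaSequence

CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
MIN_LOOP_SEPARATION = 4  # |i-j| < 4 is disallowed

__all__ = [
    "CANONICAL_PAIRS",
    "MIN_LOOP_SEPARATION",
    "is_canonical_pair",
    "build_constraint_matrix",
    "validate_structure",
    "Violation",
]


def is_canonical_pair(a: str, b: str) -> bool:
    if a not in ALPHABET or b not in ALPHABET:
        raise ValueError(f"residue outside A/C/G/U alphabet: {a!r}, {b!r}")
    return (a, b) in CANONICAL_PAIRS


def build_constraint_matrix(seq: RnaSequence, padded_length: int | None = None) -> np.ndarray:
    """Binary mask of permitted pairs; padding rows/columns are all zero."""
    n = len(seq)
    total = padded_length if padded_length is not None else n
    if total < n:
        raise ValueError("padded length smaller than sequence")
    res = np.frombuffer(seq.residues.encode(), dtype="S1").astype("U1")
    canon = np.zeros((n, n), dtype=bool)
    for a, b in CANONICAL_PAIRS:
        canon |= (res[:, None] == a) & (res[None, :] == b)
    idx = np.arange(n)
    canon &= np.abs(idx[:, None] - idx[None, :]) >= MIN_LOOP_SEPARATION
    m = np.zeros((total, total), dtype=np.int8)
    m[:n, :n] = canon
    return m


@dataclass(frozen=True)
class Violation:
    rule: int
    position: tuple[int, int]
    detail: str

    def __str__(self) -> str:
        return f"rule {self.rule} at {self.position}: {self.detail}"


def validate_structure(p: np.ndarray, m: np.ndarray) -> list[Violation]:
    """All rule violations of prediction ``p`` against mask ``m`` (empty = valid)."""
    p = np.asarray(p)
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape}, mask {m.shape}")
    out: list[Violation] = []
    if not np.array_equal(p, p.T):
        for i, j in zip(*np.nonzero(p != p.T)):
            if i < j:
                out.append(Violation(0, (int(i), int(j)), "pair matrix not symmetric"))
    for i in np.nonzero(np.diag(p))[0]:
        out.append(Violation(2, (int(i), int(i)), "base paired with itself"))
    idx = np.arange(p.shape[0])
    for i, j in zip(*np.nonzero(p)):
        if i >= j or (i == j):
            continue
        if abs(int(i) - int(j)) < MIN_LOOP_SEPARATION:
            out.append(Violation(3, (int(i), int(j)),
                                 f"partners only {abs(int(i) - int(j))} apart"))
        elif not m[i, j]:
            out.append(Violation(1, (int(i), int(j)), "pair not permitted by the mask"))
    for i in np.nonzero(p.sum(axis=1) > 1)[0]:
        out.append(Violation(4, (int(i), int(i)),
                             f"base has {int(p[i].sum())} partners"))
    return out
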