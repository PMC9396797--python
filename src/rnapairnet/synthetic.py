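"""Synthetic fixture generator: constraint-valid structures with sequences.

Structures are built by stem sampling: helical stems (blocks of consecutive
pairs, geometric length) are placed on unpaired stretches subject to the
hard rules (one partner per base, partners at least four apart).  With
probability ``pseudoknot_prob`` a crossing stem is planted explicitly, so
the generated corpus exercises the non-nested case end to end.  Sequences
are then assigned so every labelled pair is canonical (A-U/G-C/G-U, with
the wobble pair sampled at a lower rate to resemble natural composition),
which guarantees the hard-rule mask admits the full label — the
learnability precondition for every training test downstream.

These fixtures test machinery, not biology: there is no energy model, no
family structure beyond what the sampling imposes, and no non-canonical
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constraints import MIN_LOOP_SEPARATION
from .io import RnaSequence, SecondaryStructure, write_bpseq, write_fasta

__all__ = ["SyntheticConfig", "generate_structure", "assign_sequence",
           "generate_dataset", "write_fixtures"]

PAIR_TYPES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
# AU/GC pairs dominate; GU wobble is rarer in natural helices
PAIR_WEIGHTS = np.array([0.23, 0.23, 0.23, 0.23, 0.04, 0.04])


@dataclass
class SyntheticConfig:
    n: int = 100
    length_range: tuple[int, int] = (20, 120)
    pseudoknot_prob: float = 0.3
    pairing_density: float = 0.4
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 9:
            raise ValueError("minimum length is 9 (room for one legal pair)")
        if hi > 512:
            raise ValueError("maximum length is 512")
        if not 0 <= self.pseudoknot_prob <= 1:
            raise ValueError("pseudoknot_prob must lie in [0, 1]")
        if not 0 < self.pairing_density < 1:
            raise ValueError("pairing_density must lie in (0, 1)")


def _place_stem(partner: list[int], i: int, j: int, k: int) -> None:
    """Pair (i+d, j-d) for d in 0..k-1."""
    for d in range(k):
        partner[i + d], partner[j - d] = j - d, i + d


def _stem_fits(partner: list[int], i: int, j: int, k: int) -> bool:
    if i + k - 1 >= j - k + 1 - (MIN_LOOP_SEPARATION - 1):
        return False
    if j >= len(partner):
        return False
    for d in range(k):
        if partner[i + d] != -1 or partner[j - d] != -1:
            return False
        if abs((j - d) - (i + d)) < MIN_LOOP_SEPARATION:
            return False
    return True


def _crosses_existing(partner: list[int], i: int, j: int, k: int) -> bool:
    """Would the stem pairing (i+d, j-d) cross any existing pair?"""
    existing = [(a, b) for a, b in enumerate(partner) if b > a]
    for d in range(k):
        x, y = i + d, j - d
        for a, b in existing:
            if x < a < y < b or a < x < b < y:
                return True
    return False


def generate_structure(length: int, pseudoknot_prob: float, density: float,
                       rng: np.random.Generator) -> SecondaryStructure:
    """Sample a structure with ~``density`` of positions paired."""
    if length < 9:
        raise ValueError("length must be at least 9")
    partner = [-1] * length
    target = int(density * length)
    want_pk = rng.random() < pseudoknot_prob and length >= 20

    if want_pk:  # plant two crossing stems: i1 < i2 < j1 < j2
        for _ in range(200):
            k = 2
            i1 = int(rng.integers(0, length - 4 * k - 2 * MIN_LOOP_SEPARATION))
            i2 = i1 + k + int(rng.integers(1, 4))
            j1 = i2 + k + int(rng.integers(MIN_LOOP_SEPARATION, MIN_LOOP_SEPARATION + 4))
            j2 = j1 + k + int(rng.integers(1, 4))
            if j2 + k - 1 >= length:
                continue
            ok = (_stem_fits(partner, i1, j1 + k - 1, k)
                  and j1 - k + 1 - (i1 + k - 1) >= MIN_LOOP_SEPARATION)
            if not ok:
                continue
            _place_stem(partner, i1, j1 + k - 1, k)
            if _stem_fits(partner, i2, j2 + k - 1, k):
                _place_stem(partner, i2, j2 + k - 1, k)
                break
            _place_stem_undo(partner, i1, j1 + k - 1, k)

    attempts = 0
    while sum(p != -1 for p in partner) < target and attempts < 50 * length:
        attempts += 1
        k = 1 + int(rng.geometric(0.5))
        min_span = MIN_LOOP_SEPARATION + 2 * k - 2
        if min_span >= length:
            continue
        i = int(rng.integers(0, length - 1))
        span = int(rng.integers(min_span, length))
        j = i + span
        if j >= length or not _stem_fits(partner, i, j, k):
            continue
        # random filling never introduces crossings; they come only from the
        # planted crossing stem above
        if _crosses_existing(partner, i, j, k):
            continue
        _place_stem(partner, i, j, k)
    return SecondaryStructure(tuple(partner))


def _place_stem_undo(partner: list[int], i: int, j: int, k: int) -> None:
    for d in range(k):
        partner[i + d] = partner[j - d] = -1


def assign_sequence(structure: SecondaryStructure, rng: np.random.Generator,
                    seq_id: str = "synthetic") -> RnaSequence:
    """Residues such that every labelled pair is canonical."""
    n = len(structure)
    residues = [""] * n
    for i, j in structure.pairs:
        a, b = PAIR_TYPES[rng.choice(len(PAIR_TYPES), p=PAIR_WEIGHTS / PAIR_WEIGHTS.sum())]
        residues[i], residues[j] = a, b
    for i in range(n):
        if not residues[i]:
            residues[i] = "ACGU"[rng.integers(0, 4)]
    return RnaSequence(id=seq_id, residues="".join(residues))


def generate_dataset(cfg: SyntheticConfig) -> list[tuple[RnaSequence, SecondaryStructure]]:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    out = []
    for idx in range(cfg.n):
        length = int(rng.integers(lo, hi + 1))
        structure = generate_structure(length, cfg.pseudoknot_prob, cfg.pairing_density, rng)
        seq = assign_sequence(structure, rng, seq_id=f"syn{idx:04d}")
        out.append((seq, structure))
    return out


def write_fixtures(records, out_dir) -> None:
    """bpseq per record plus one FASTA of all sequences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for seq, structure in records:
        (out / f"{seq.id}.bpseq").write_text(write_bpseq(seq, structure))
    write_fasta(out / "sequences.fasta", [seq for seq, _ in records])
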