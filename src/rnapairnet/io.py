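"""Sequence and structure I/O.

Internal convention: positions are 0-based; bpseq/ct files are 1-based and
converted at the boundary.  A structure is a partner assignment
(``partner[i] == j`` iff bases i and j pair, ``-1`` for unpaired), which is
equivalent to a binary symmetric adjacency ("pair") matrix with zero
diagonal and row sums at most one.  Pseudoknots are supported everywhere:
dot-bracket serialization uses extra bracket layers assigned by greedy
coloring of the pair-crossing graph.

Base encoding for the network: A→1, U→2, G→3, C→4, padding '#'→0; T is
normalized to U and lowercase to uppercase; any other letter is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGU"
CODES = {"#": 0, "A": 1, "U": 2, "G": 3, "C": 4}
DECODES = {v: k for k, v in CODES.items()}

BRACKET_LAYERS = ["()", "[]", "{}", "<>"] + [chr(65 + i) + chr(97 + i) for i in range(8)]

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "EncodedSequence",
    "DatasetSplit",
    "normalize_residues",
    "parse_dotbracket",
    "write_dotbracket",
    "parse_bpseq",
    "write_bpseq",
    "parse_ct",
    "write_ct",
    "read_fasta",
    "write_fasta",
    "structure_to_pair_matrix",
    "pair_matrix_to_structure",
    "encode_sequence",
    "decode_codes",
    "bucket_by_length",
    "split_dataset",
    "crossing_pairs",
]


class FormatError(ValueError):
    """Malformed structure/sequence file."""


def normalize_residues(residues: str) -> str:
    """Uppercase, T→U; reject anything outside {A,C,G,U}."""
    s = residues.upper().replace("T", "U")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise ValueError(f"residues outside A/C/G/U alphabet: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class RnaSequence:
    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """Partner assignment; partner[i] == -1 means unpaired."""

    partner: tuple

    def __post_init__(self):
        p = tuple(int(x) for x in self.partner)
        object.__setattr__(self, "partner", p)
        for i, j in enumerate(p):
            if j == -1:
                continue
            if j == i:
                raise ValueError(f"position {i} paired with itself")
            if not (0 <= j < len(p)) or p[j] != i:
                raise ValueError(f"asymmetric pairing at position {i} -> {j}")

    def __len__(self) -> int:
        return len(self.partner)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j > i]

    @classmethod
    def from_pairs(cls, length: int, pairs) -> "SecondaryStructure":
        partner = [-1] * length
        for i, j in pairs:
            if partner[i] != -1 or partner[j] != -1:
                raise ValueError(f"position in more than one pair: {(i, j)}")
            partner[i], partner[j] = j, i
        return cls(tuple(partner))


@dataclass(frozen=True)
class EncodedSequence:
    codes: np.ndarray
    true_length: int

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=np.int64))


def crossing_pairs(s: SecondaryStructure) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All crossing ((i,j),(k,l)) with i<k<j<l — the pseudoknot signature."""
    out = []
    ps = s.pairs
    for a in range(len(ps)):
        for b in range(a + 1, len(ps)):
            (i, j), (k, l) = sorted([ps[a], ps[b]])
            if i < k < j < l:
                out.append(((i, j), (k, l)))
    return out


# ----------------------------------------------------------------- dot-bracket
def parse_dotbracket(text: str) -> SecondaryStructure:
    text = text.strip()
    openers = {layer[0]: layer for layer in BRACKET_LAYERS}
    closers = {layer[1]: layer for layer in BRACKET_LAYERS}
    stacks: dict[str, list[int]] = {layer: [] for layer in BRACKET_LAYERS}
    partner = [-1] * len(text)
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in openers:
            stacks[openers[ch]].append(pos)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise FormatError(f"unmatched '{ch}' at position {pos}")
            i = stack.pop()
            partner[i], partner[pos] = pos, i
        else:
            raise FormatError(f"unknown character '{ch}' at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise FormatError(f"unmatched '{layer[0]}' at position {stack[-1]}")
    return SecondaryStructure(tuple(partner))


def write_dotbracket(s: SecondaryStructure) -> str:
    """Serialize with layered brackets via greedy coloring of the crossing graph."""
    pairs = s.pairs
    layer_of: dict[tuple[int, int], int] = {}
    for p in pairs:  # pairs are sorted by opening position
        used = set()
        i, j = p
        for q, lq in layer_of.items():
            k, l = q
            a, b = sorted([p, q])
            if a[0] < b[0] < a[1] < b[1]:
                used.add(lq)
        layer = 0
        while layer in used:
            layer += 1
        if layer >= len(BRACKET_LAYERS):
            raise ValueError("crossing number exceeds available bracket layers")
        layer_of[p] = layer
    chars = ["."] * len(s)
    for (i, j), layer in layer_of.items():
        chars[i], chars[j] = BRACKET_LAYERS[layer][0], BRACKET_LAYERS[layer][1]
    return "".join(chars)


# ----------------------------------------------------------------- bpseq / ct
def parse_bpseq(text: str) -> tuple[RnaSequence, SecondaryStructure]:
    residues, partner = [], []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise FormatError(f"bpseq line needs 3 fields: {line!r}")
        idx, res, par = int(fields[0]), fields[1], int(fields[2])
        if idx != len(residues) + 1:
            raise FormatError(f"gap or disorder in bpseq indices at line {line!r}")
        residues.append(res)
        partner.append(par - 1)  # 1-based file, 0-based here; 0 -> -1 unpaired
    for i, j in enumerate(partner):
        if j != -1 and (not 0 <= j < len(partner) or partner[j] != i):
            raise FormatError(f"asymmetric pairing record: {i + 1} -> {j + 1}")
    seq = RnaSequence(id="bpseq", residues="".join(residues))
    return seq, SecondaryStructure(tuple(partner))


def write_bpseq(seq: RnaSequence, s: SecondaryStructure) -> str:
    lines = [f"{i + 1} {res} {s.partner[i] + 1}" for i, res in enumerate(seq.residues)]
    return "\n".join(lines) + "\n"


def parse_ct(text: str) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    name = header[1] if len(header) > 1 else "ct"
    residues, partner = [], []
    for line in lines[1 : n + 1]:
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"ct line needs 6 fields: {line!r}")
        idx, res, par = int(fields[0]), fields[1], int(fields[4])
        if idx != len(residues) + 1:
            raise FormatError(f"gap or disorder in ct indices at line {line!r}")
        residues.append(res)
        partner.append(par - 1)
    for i, j in enumerate(partner):
        if j != -1 and (not 0 <= j < len(partner) or partner[j] != i):
            raise FormatError(f"asymmetric pairing record: {i + 1} -> {j + 1}")
    return RnaSequence(id=name, residues="".join(residues)), SecondaryStructure(tuple(partner))


def write_ct(seq: RnaSequence, s: SecondaryStructure) -> str:
    n = len(seq)
    lines = [f"{n} {seq.id}"]
    for i, res in enumerate(seq.residues):
        lines.append(f"{i + 1} {res} {i} {i + 2 if i + 1 < n else 0} {s.partner[i] + 1} {i + 1}")
    return "\n".join(lines) + "\n"


def read_fasta(path) -> list[RnaSequence]:
    return [RnaSequence(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, seqs) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ------------------------------------------------------------- matrices/codes
def structure_to_pair_matrix(s: SecondaryStructure, padded_length: int | None = None) -> np.ndarray:
    n = padded_length if padded_length is not None else len(s)
    if n < len(s):
        raise ValueError("padded length smaller than structure")
    m = np.zeros((n, n), dtype=np.int8)
    for i, j in enumerate(s.partner):
        if j != -1:
            m[i, j] = 1
    return m


def pair_matrix_to_structure(m: np.ndarray, true_length: int | None = None) -> SecondaryStructure:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pair matrix must be square")
    if not np.array_equal(m, m.T):
        raise ValueError("pair matrix must be symmetric")
    if np.any(np.diag(m)):
        raise ValueError("pair matrix has a nonzero diagonal")
    if np.any(m.sum(axis=1) > 1):
        raise ValueError("pair matrix row sum exceeds 1")
    n = true_length if true_length is not None else m.shape[0]
    partner = [-1] * n
    for i, j in zip(*np.nonzero(m)):
        if i < n:
            partner[i] = int(j)
    return SecondaryStructure(tuple(partner))


def encode_sequence(seq: RnaSequence, encoding_length: int) -> EncodedSequence:
    if len(seq) > encoding_length:
        raise ValueError(f"sequence length {len(seq)} exceeds encoding length {encoding_length}")
    codes = np.zeros(encoding_length, dtype=np.int64)
    for i, res in enumerate(seq.residues):
        codes[i] = CODES[res]
    return EncodedSequence(codes=codes, true_length=len(seq))


def decode_codes(enc: EncodedSequence) -> str:
    return "".join(DECODES[int(c)] for c in enc.codes[: enc.true_length])


def bucket_by_length(records: list) -> tuple[list, list, list]:
    """Split records into the two encoding-length buckets (<=128 and 129..512).

    Records may be RnaSequence or (RnaSequence, SecondaryStructure) tuples;
    the sequence length decides the bucket.  Lengths above 512 are rejected
    (returned with a reason, not raised).
    """
    bucket_128, bucket_512, rejected = [], [], []
    for rec in records:
        seq = rec[0] if isinstance(rec, tuple) else rec
        n = len(seq)
        if n <= 128:
            bucket_128.append(rec)
        elif n <= 512:
            bucket_512.append(rec)
        else:
            rejected.append((rec, f"length {n} exceeds the 512 encoding limit"))
    return bucket_128, bucket_512, rejected


@dataclass
class DatasetSplit:
    train: list
    test: list
    validate: list
    seed: int

    @property
    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "test": len(self.test), "validate": len(self.validate)}

    def manifest(self, ids: dict[str, list[str]] | None = None) -> dict:
        return {"seed": self.seed, "counts": self.counts, **({"ids": ids} if ids else {})}


def split_dataset(records: list, seed: int) -> DatasetSplit:
    """Shuffle with the given seed, then partition 80/10/10.

    Rounding rule: train takes floor(0.8 n); the remainder is split evenly
    between test and validate, with any odd record going to test (so 37
    records give 29/4/4).  Below 10 records each partition still receives
    at least one record.
    """
    records = list(records)
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [records[i] for i in order]
    n_train = max(1, (8 * n) // 10)
    rest = n - n_train
    n_test = max(1, (rest + 1) // 2)
    n_val = max(1, rest - n_test)
    n_train = n - n_test - n_val
    return DatasetSplit(
        train=shuffled[:n_train],
        test=shuffled[n_train : n_train + n_test],
        validate=shuffled[n_train + n_test :],
        seed=seed,
    )


def save_split_manifest(split: DatasetSplit, path, ids: dict | None = None) -> None:
    Path(path).write_text(json.dumps(split.manifest(ids), indent=2))
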