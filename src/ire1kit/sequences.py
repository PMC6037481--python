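"""Sequence and tabular I/O.

External representations handled here: FASTA (sequences, via Biopython),
Vienna dot-bracket and CT (secondary structures), TSV (per-base DMS
reactivity) and CSV (cleavage time courses).  All coordinates are 1-based
and inclusive; a scissile bond is identified by the index ``i`` of the
nucleotide 5' of the cut (the bond between ``i`` and ``i+1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

class SequenceAlphabetError(ValueError):
    """A residue outside {A, C, G, U} survived canonicalization."""


def _canonicalize(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U; whitespace is stripped."""
    return "".join(raw.split()).upper().replace("T", "U")


class RnaSequence:
    """An identified RNA string over {A, C, G, U}, positions 1-based.

    Input is canonicalized (lowercase -> uppercase, T -> U); any other
    letter raises :class:`SequenceAlphabetError` naming the offending
    1-based position.
    """

    __slots__ = ("id", "residues")

    def __init__(self, id: str, residues: str):
        residues = _canonicalize(residues)
        for pos, ch in enumerate(residues, start=1):
            if ch not in RNA_ALPHABET:
                raise SequenceAlphabetError(
                    f"{id!r}: invalid residue {ch!r} at position {pos}"
                )
        self.id = id
        self.residues = residues

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]

    def subseq(self, start: int, end: int, id: Optional[str] = None) -> "RnaSequence":
        """Inclusive 1-based slice ``start..end`` as a new sequence."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"window {start}..{end} outside 1..{len(self.residues)}")
        return RnaSequence(id or f"{self.id}:{start}-{end}", self.residues[start - 1 : end])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RnaSequence)
            and self.id == other.id
            and self.residues == other.residues
        )

    def __hash__(self) -> int:
        return hash((self.id, self.residues))

    def __repr__(self) -> str:
        return f"RnaSequence(id={self.id!r}, residues={self.residues!r})"


@dataclass(frozen=True)
class ReactivityRecord:
    """Per-base DMS modification signal.

    ``raw_signal`` is in arbitrary units (any non-negative per-base score;
    normalization is scale-invariant).  ``normalized_signal`` is set by
    max-normalization over a window and lies in [0, 1] when present.
    """

    position: int
    base: str
    raw_signal: float
    normalized_signal: Optional[float] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.base not in RNA_ALPHABET:
            raise ValueError(f"base must be one of A/C/G/U, got {self.base!r}")
        if self.raw_signal < 0 or not math.isfinite(self.raw_signal):
            raise ValueError(f"raw_signal must be finite and >= 0, got {self.raw_signal}")
        if self.normalized_signal is not None and not 0.0 <= self.normalized_signal <= 1.0:
            raise ValueError(
                f"normalized_signal must lie in [0, 1], got {self.normalized_signal}"
            )


@dataclass(frozen=True)
class TimeCourse:
    """A cleavage time course: fraction cleaved versus time (seconds)."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)
        if times.ndim != 1 or fractions.shape != times.shape:
            raise ValueError("times and fractions must be 1-D and the same length")
        if len(times) and times[0] < 0:
            raise ValueError("times must start at >= 0 s")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((fractions < 0) | (fractions > 1)):
            raise ValueError("cleaved fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[RnaSequence]:
    """Read FASTA records, canonicalizing DNA letters to RNA.

    Record ids are the header up to the first whitespace.  An empty file
    yields an empty list; a residue outside A/C/G/U (after T->U) is a hard
    error naming the position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(RnaSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(seqs: Iterable[RnaSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# Dot-bracket and CT

class PseudoknotError(ValueError):
    """A crossing pair table cannot be serialized as dot-bracket."""


def dotbracket_string(pair_table: Sequence[int]) -> str:
    """Render a 1-based pair table (index 0 unused) as dot-bracket.

    Raises :class:`PseudoknotError` for crossing pairs.
    """
    n = len(pair_table) - 1
    chars = ["."] * n
    open_stack: list[int] = []
    for i in range(1, n + 1):
        j = pair_table[i]
        if j == 0:
            continue
        if j > i:
            open_stack.append(j)
            chars[i - 1] = "("
        else:
            if not open_stack or open_stack[-1] != i:
                raise PseudoknotError(f"crossing pair ({j}, {i}) cannot be serialized")
            open_stack.pop()
            chars[i - 1] = ")"
    return "".join(chars)


def pair_table_from_dotbracket(db: str) -> np.ndarray:
    pt = np.zeros(len(db) + 1, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[-1]}")
    return pt


def write_dotbracket(seq: RnaSequence, structure) -> str:
    """Three-line Vienna-style record: header, residues, dot-bracket (energy)."""
    if structure.length != len(seq):
        raise ValueError(
            f"structure length {structure.length} != sequence length {len(seq)}"
        )
    db = dotbracket_string(structure.pair_table)
    return f">{seq.id}\n{seq.residues}\n{db} ({structure.energy:.2f})\n"


def parse_dotbracket(text: str):
    """Inverse of :func:`write_dotbracket`; returns (RnaSequence, SecondaryStructure)."""
    from .folding import SecondaryStructure  # local import to avoid a cycle

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 3 or not lines[0].startswith(">"):
        raise ValueError("expected three lines: >header, residues, dot-bracket")
    seq = RnaSequence(lines[0][1:].split()[0], lines[1].strip())
    field = lines[2].strip()
    energy = 0.0
    if "(" in field and field.endswith(")") and " " in field:
        db, _, en = field.rpartition(" ")
        energy = float(en.strip("()"))
        db = db.strip()
    else:
        db = field
    if len(db) != len(seq):
        raise ValueError("dot-bracket length does not match sequence length")
    pt = pair_table_from_dotbracket(db)
    return seq, SecondaryStructure(pair_table=pt, energy=energy)


def write_ct(seq: RnaSequence, structure) -> str:
    """Connectivity-table (CT) text for a structure."""
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence length")
    n = len(seq)
    lines = [f"{n} {seq.id} dG = {structure.energy:.2f}"]
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else 0
        lines.append(
            f"{i} {seq.base(i)} {i - 1} {nxt} {structure.pair_table[i]} {i}"
        )
    return "\n".join(lines) + "\n"


def parse_ct(text: str):
    from .folding import SecondaryStructure

    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = lines[0].split()
    n = int(head[0])
    name = head[1] if len(head) > 1 else "ct"
    energy = 0.0
    if "=" in lines[0]:
        energy = float(lines[0].split("=")[1].split()[0])
    bases = []
    pt = np.zeros(n + 1, dtype=int)
    for ln in lines[1 : n + 1]:
        f = ln.split()
        i, b, partner = int(f[0]), f[1], int(f[4])
        bases.append(b)
        pt[i] = partner
    seq = RnaSequence(name, "".join(bases))
    return seq, SecondaryStructure(pair_table=pt, energy=energy)


# ---------------------------------------------------------------------------
# Tabular formats


def read_reactivity_tsv(path) -> list[ReactivityRecord]:
    """Read a headered TSV with columns position, base, raw_signal
    [, normalized_signal]; records are returned ordered by position.
    Duplicate positions are a hard error."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "base", "raw_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reactivity TSV missing columns: {sorted(missing)}")
    if df["position"].duplicated().any():
        dupes = df.loc[df["position"].duplicated(), "position"].tolist()
        raise ValueError(f"duplicate positions in reactivity TSV: {dupes}")
    df = df.sort_values("position")
    has_norm = "normalized_signal" in df.columns
    records = []
    for row in df.itertuples(index=False):
        norm = None
        if has_norm:
            val = getattr(row, "normalized_signal")
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                norm = float(val)
        records.append(
            ReactivityRecord(
                position=int(row.position),
                base=str(row.base).upper().replace("T", "U"),
                raw_signal=float(row.raw_signal),
                normalized_signal=norm,
            )
        )
    return records


def write_reactivity_tsv(records: Iterable[ReactivityRecord], path) -> None:
    rows = [
        {
            "position": r.position,
            "base": r.base,
            "raw_signal": r.raw_signal,
            "normalized_signal": r.normalized_signal,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_timecourse_csv(path) -> TimeCourse:
    """Read a headered CSV with columns time_s, fraction_cleaved."""
    df = pd.read_csv(path)
    required = {"time_s", "fraction_cleaved"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV missing columns: {sorted(missing)}")
    return TimeCourse(
        times=df["time_s"].to_numpy(dtype=float),
        fractions=df["fraction_cleaved"].to_numpy(dtype=float),
    )


def write_timecourse_csv(tc: TimeCourse, path) -> None:
    pd.DataFrame({"time_s": tc.times, "fraction_cleaved": tc.fractions}).to_csv(
        path, index=False
    )


__all__ = [
    "RnaSequence",
    "ReactivityRecord",
    "TimeCourse",
    "SequenceAlphabetError",
    "PseudoknotError",
    "read_fasta",
    "write_fasta",
    "write_dotbracket",
    "parse_dotbracket",
    "dotbracket_string",
    "pair_table_from_dotbracket",
    "write_ct",
    "parse_ct",
    "read_reactivity_tsv",
    "write_reactivity_tsv",
    "read_timecourse_csv",
    "write_timecourse_csv",
]
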