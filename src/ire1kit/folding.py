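"""Constrained minimum-free-energy RNA secondary-structure prediction.

The predictor is a Zuker-style dynamic program over the nearest-neighbour
model in :mod:`ire1kit.energies`: hairpin, stack/bulge/internal and affine
multibranch loop terms, Watson-Crick + G.U wobble pairs, minimum hairpin
loop of 3 nt, and hard "force unpaired" constraints (a constrained
position is excluded from every pair, as with mfold's force-unpaired
annotation).  A Nussinov-style base-pair-maximization mode is provided as
a testing oracle only.

Traceback is deterministic: among co-optimal branches it prefers the one
that adds a pair (interior loop, then multibranch, then hairpin) and,
within a branch, the candidate with the smallest 5' index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .energies import (
    DEFAULT_MODEL,
    INF,
    PAIR_MATRIX,
    EnergyModel,
    encode_sequence,
)
from .sequences import RnaSequence

_EPS = 1e-9
MIN_HAIRPIN = 3  # unpaired nt; standard steric bound


@dataclass(frozen=True)
class FoldConstraints:
    """Positions forced single-stranded (1-based)."""

    forced_single_stranded: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "forced_single_stranded", frozenset(self.forced_single_stranded)
        )
        for p in self.forced_single_stranded:
            if p < 1:
                raise ValueError(f"constraint position {p} is not a 1-based index")

    def check_range(self, length: int) -> None:
        bad = [p for p in self.forced_single_stranded if p > length]
        if bad:
            raise ValueError(f"constraint positions {sorted(bad)} exceed length {length}")

    def shifted(self, offset: int) -> "FoldConstraints":
        return FoldConstraints(
            frozenset(p + offset for p in self.forced_single_stranded)
        )


class SecondaryStructure:
    """Nested pair table (1-based; entry 0 unused) plus free energy.

    Invariants enforced on construction: involution, nestedness (no
    pseudoknots) and a minimum hairpin loop of 3 unpaired nt.
    """

    __slots__ = ("pair_table", "energy")

    def __init__(self, pair_table, energy: float = 0.0):
        pt = np.asarray(pair_table, dtype=int)
        if pt.ndim != 1 or len(pt) < 1 or pt[0] != 0:
            raise ValueError("pair table must be 1-based with entry 0 == 0")
        n = len(pt) - 1
        open_stack = []
        for i in range(1, n + 1):
            j = pt[i]
            if j == 0:
                continue
            if not 1 <= j <= n or pt[j] != i or j == i:
                raise ValueError(f"pair table is not an involution at position {i}")
            if j > i:
                if abs(j - i) < MIN_HAIRPIN + 1:
                    raise ValueError(f"pair ({i}, {j}) violates the minimum hairpin loop")
                open_stack.append(j)
            else:
                if not open_stack or open_stack[-1] != i:
                    raise ValueError(f"crossing pair ({j}, {i}): pseudoknots not supported")
                open_stack.pop()
        self.pair_table = pt
        self.energy = float(energy)

    @property
    def length(self) -> int:
        return len(self.pair_table) - 1

    def partner(self, i: int) -> int:
        return int(self.pair_table[i])

    def is_paired(self, i: int) -> bool:
        return self.pair_table[i] != 0

    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, int(self.pair_table[i]))
            for i in range(1, self.length + 1)
            if self.pair_table[i] > i
        ]

    def n_pairs(self) -> int:
        return len(self.pairs())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and np.array_equal(self.pair_table, other.pair_table)
            and abs(self.energy - other.energy) < 1e-9
        )

    def __repr__(self) -> str:
        from .sequences import dotbracket_string

        return (
            f"SecondaryStructure({dotbracket_string(self.pair_table)!r}, "
            f"energy={self.energy:.2f})"
        )


@dataclass(frozen=True)
class HairpinLoop:
    """A hairpin loop: closing pair (i, j) and unpaired positions i+1..j-1."""

    closing_pair: tuple[int, int]
    size: int

    @property
    def loop_positions(self) -> range:
        i, j = self.closing_pair
        return range(i + 1, j)

    @property
    def start(self) -> int:
        return self.closing_pair[0] + 1

    @property
    def end(self) -> int:
        return self.closing_pair[1] - 1


@dataclass(frozen=True)
class BondContext:
    """Placement of a scissile bond relative to a hairpin loop.

    ``ordinal`` is the bond's 1-based rank among the loop's L-1 internal
    bonds; ``offset`` = \\|ordinal - L/2\\| in bond units (0.5 = the two
    central bonds of an odd loop).  Both are None when the bond is not
    between two unpaired positions of the same hairpin loop.
    """

    loop: Optional[HairpinLoop]
    ordinal: Optional[int]
    offset: Optional[float]

    @property
    def in_loop(self) -> bool:
        return self.loop is not None


def validate_pairing_alphabet(seq: RnaSequence, structure: SecondaryStructure) -> None:
    """Assert every pair is Watson-Crick or wobble for this sequence."""
    enc = encode_sequence(seq.residues)
    for i, j in structure.pairs():
        if not PAIR_MATRIX[enc[i - 1], enc[j - 1]]:
            raise ValueError(f"pair ({i}, {j}) = {seq.base(i)}-{seq.base(j)} is not canonical")


# ---------------------------------------------------------------------------
# MFE dynamic program


def _two_loop_energy(enc, model: EnergyModel, i: int, j: int, k: int, l: int) -> float:
    """Energy of the loop between closing pair (i, j) and interior pair (k, l).

    Stacked pair, bulge, or internal loop; 1-based indices into ``enc``
    shifted down by one.  No stacking term is carried across a bulge.
    """
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 and n2 == 0:
        return float(model.stack[enc[i - 1], enc[j - 1], enc[k - 1], enc[l - 1]])
    pen = model.closure_penalty(enc[i - 1], enc[j - 1]) + model.closure_penalty(
        enc[k - 1], enc[l - 1]
    )
    if n1 == 0 or n2 == 0:
        return model.bulge(n1 + n2) + pen
    return model.internal(n1 + n2) + pen


def _hairpin_energy(enc, model: EnergyModel, i: int, j: int) -> float:
    return model.hairpin(j - i - 1) + model.closure_penalty(enc[i - 1], enc[j - 1])


def fold_mfe(
    seq: RnaSequence,
    constraints: Optional[FoldConstraints] = None,
    model: Optional[EnergyModel] = None,
) -> SecondaryStructure:
    """Minimum-free-energy nested structure under hard unpaired constraints.

    Sequences shorter than 5 nt fold trivially (all unpaired, energy 0).
    Deterministic: repeated calls give identical pair tables.
    """
    model = model or DEFAULT_MODEL
    constraints = constraints or FoldConstraints()
    n = len(seq)
    if n > 2000:
        raise ValueError("practical DP bound is 2000 nt")
    constraints.check_range(n)
    if n < 5:
        return SecondaryStructure(np.zeros(n + 1, dtype=int), 0.0)

    enc = encode_sequence(seq.residues)
    blocked = np.zeros(n + 1, dtype=bool)
    for p in constraints.forced_single_stranded:
        blocked[p] = True

    pairable = np.zeros((n + 1, n + 1), dtype=bool)
    for i in range(1, n + 1):
        if blocked[i]:
            continue
        for j in range(i + MIN_HAIRPIN + 1, n + 1):
            if not blocked[j] and PAIR_MATRIX[enc[i - 1], enc[j - 1]]:
                pairable[i, j] = True

    V = np.full((n + 2, n + 2), INF)
    WM = np.full((n + 2, n + 2), INF)
    mb_a, mb_b, mb_c = model.multibranch_a, model.multibranch_b, model.multibranch_c
    max_int = model.max_interior

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            # V(i, j): energy given (i, j) paired
            if pairable[i, j]:
                best = _hairpin_energy(enc, model, i, j)
                kmax = min(i + max_int + 1, j - MIN_HAIRPIN - 1)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if V[k, l] >= INF or not pairable[k, l]:
                            continue
                        e = _two_loop_energy(enc, model, i, j, k, l) + V[k, l]
                        if e < best:
                            best = e
                # multibranch closing: a + b (closing branch) + two WM segments
                if j - i >= 6:
                    base = mb_a + mb_b
                    for m in range(i + 1, j - 1):
                        e = base + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM(i, j): multiloop segment with >= 1 branch
            best = V[i, j] + mb_b if V[i, j] < INF else INF
            e = WM[i + 1, j] + mb_c
            if e < best:
                best = e
            e = WM[i, j - 1] + mb_c
            if e < best:
                best = e
            for m in range(i + 1, j):
                e = WM[i, m] + WM[m + 1, j]
                if e < best:
                    best = e
            WM[i, j] = best

    # external loop
    W = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for k in range(1, j - MIN_HAIRPIN):
            if V[k, j] < INF:
                e = W[k - 1] + V[k, j]
                if e < best:
                    best = e
        W[j] = best

    pt = np.zeros(n + 1, dtype=int)
    _traceback(enc, model, pairable, V, WM, W, n, pt)
    energy = float(W[n])
    return SecondaryStructure(pt, 0.0 if abs(energy) < _EPS else energy)


def _traceback(enc, model, pairable, V, WM, W, n, pt) -> None:
    mb_a, mb_b, mb_c = model.multibranch_a, model.multibranch_b, model.multibranch_c
    max_int = model.max_interior
    stack: list[tuple[str, int, int]] = [("W", 1, n)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            # external segment 1..j (i unused beyond start bound)
            while j >= i:
                target = W[j]
                hit = False
                for k in range(i, j - MIN_HAIRPIN):
                    if V[k, j] < INF and abs(W[k - 1] + V[k, j] - target) < _EPS:
                        stack.append(("V", k, j))
                        j = k - 1
                        hit = True
                        break
                if not hit:
                    if abs(W[j - 1] - target) > _EPS:  # pragma: no cover - safety
                        raise AssertionError("external traceback failed")
                    j -= 1
        elif kind == "V":
            pt[i], pt[j] = j, i
            target = V[i, j]
            # interior two-loops first (adds a pair), 5'-most candidate wins
            found = False
            kmax = min(i + max_int + 1, j - MIN_HAIRPIN - 1)
            for k in range(i + 1, kmax + 1):
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (max_int - (k - i - 1)))
                for l in range(j - 1, lmin - 1, -1):
                    if V[k, l] >= INF or not pairable[k, l]:
                        continue
                    if abs(_two_loop_energy(enc, model, i, j, k, l) + V[k, l] - target) < _EPS:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            if j - i >= 6:
                base = mb_a + mb_b
                for m in range(i + 1, j - 1):
                    if abs(base + WM[i + 1, m] + WM[m + 1, j - 1] - target) < _EPS:
                        stack.append(("M", i + 1, m))
                        stack.append(("M", m + 1, j - 1))
                        found = True
                        break
            if found:
                continue
            if abs(_hairpin_energy(enc, model, i, j) - target) > _EPS:  # pragma: no cover
                raise AssertionError(f"V traceback failed at ({i}, {j})")
        else:  # WM segment
            target = WM[i, j]
            if V[i, j] < INF and abs(V[i, j] + mb_b - target) < _EPS:
                stack.append(("V", i, j))
                continue
            found = False
            for m in range(i + 1, j):
                if abs(WM[i, m] + WM[m + 1, j] - target) < _EPS:
                    stack.append(("M", i, m))
                    stack.append(("M", m + 1, j))
                    found = True
                    break
            if found:
                continue
            if abs(WM[i + 1, j] + mb_c - target) < _EPS:
                stack.append(("M", i + 1, j))
            elif abs(WM[i, j - 1] + mb_c - target) < _EPS:
                stack.append(("M", i, j - 1))
            else:  # pragma: no cover - safety
                raise AssertionError(f"WM traceback failed at ({i}, {j})")


def structure_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    model: Optional[EnergyModel] = None,
) -> float:
    """Recompute a structure's free energy from its loop decomposition.

    Sums one term per loop (hairpin / two-loop / multibranch); the external
    loop contributes 0.  For a structure returned by :func:`fold_mfe` this
    reproduces the DP's reported energy.
    """
    model = model or DEFAULT_MODEL
    enc = encode_sequence(seq.residues)
    pt = structure.pair_table
    total = 0.0
    for i, j in structure.pairs():
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if pt[k] > k:
                children.append((k, int(pt[k])))
                k = int(pt[k]) + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += _hairpin_energy(enc, model, i, j)
        elif len(children) == 1:
            k, l = children[0]
            total += _two_loop_energy(enc, model, i, j, k, l)
        else:
            total += (
                model.multibranch_a
                + model.multibranch_b * (len(children) + 1)
                + model.multibranch_c * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# Nussinov oracle mode


def fold_maxpair(
    seq: RnaSequence, constraints: Optional[FoldConstraints] = None
) -> SecondaryStructure:
    """Maximize base-pair count under the same pairing rules and constraints.

    Cross-check oracle only (pure pair maximization over-pairs real
    hairpins); the reported ``energy`` is the negated pair count.
    """
    constraints = constraints or FoldConstraints()
    n = len(seq)
    constraints.check_range(n)
    if n < 5:
        return SecondaryStructure(np.zeros(n + 1, dtype=int), 0.0)
    enc = encode_sequence(seq.residues)
    blocked = np.zeros(n + 1, dtype=bool)
    for p in constraints.forced_single_stranded:
        blocked[p] = True

    N = np.zeros((n + 2, n + 2), dtype=int)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = N[i + 1, j]
            if not blocked[i]:
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    if blocked[k] or not PAIR_MATRIX[enc[i - 1], enc[k - 1]]:
                        continue
                    cand = 1 + N[i + 1, k - 1] + N[k + 1, j]
                    if cand > best:
                        best = cand
            N[i, j] = best

    pt = np.zeros(n + 1, dtype=int)
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_HAIRPIN + 1:
            continue
        target = N[i, j]
        paired = False
        if not blocked[i]:
            # prefer pairing i, smallest partner index first
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if blocked[k] or not PAIR_MATRIX[enc[i - 1], enc[k - 1]]:
                    continue
                if 1 + N[i + 1, k - 1] + N[k + 1, j] == target:
                    pt[i], pt[k] = k, i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(pt, -float(N[1, n]))


# ---------------------------------------------------------------------------
# Loop geometry queries


def hairpin_loops(structure: SecondaryStructure) -> list[HairpinLoop]:
    """All hairpin loops, ordered by closing-pair 5' position."""
    loops = []
    pt = structure.pair_table
    for i, j in structure.pairs():
        if all(pt[k] == 0 for k in range(i + 1, j)):
            loops.append(HairpinLoop(closing_pair=(i, j), size=j - i - 1))
    loops.sort(key=lambda lp: lp.closing_pair[0])
    return loops


def scissile_bond_context(structure: SecondaryStructure, bond_index: int) -> BondContext:
    """Loop placement of the bond between positions ``bond_index`` and +1."""
    i = bond_index
    if not 1 <= i < structure.length:
        raise IndexError(f"bond index {i} outside 1..{structure.length - 1}")
    for loop in hairpin_loops(structure):
        if loop.start <= i and i + 1 <= loop.end:
            ordinal = i - loop.start + 1
            return BondContext(
                loop=loop, ordinal=ordinal, offset=abs(ordinal - loop.size / 2.0)
            )
    return BondContext(loop=None, ordinal=None, offset=None)


__all__ = [
    "FoldConstraints",
    "SecondaryStructure",
    "HairpinLoop",
    "BondContext",
    "fold_mfe",
    "fold_maxpair",
    "structure_energy",
    "hairpin_loops",
    "scissile_bond_context",
    "validate_pairing_alphabet",
    "MIN_HAIRPIN",
]
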