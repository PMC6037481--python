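"""Nearest-neighbour free-energy parameters for RNA secondary structure.

A Turner-style parameter set at 37 degC, embedded as a versioned table:
Watson-Crick stack free energies (Xia et al. style values), approximate
G.U wobble stacks, length-dependent hairpin/bulge/internal-loop
initiation terms with logarithmic extrapolation beyond 30 nt, an affine
multibranch-loop penalty and a +0.5 kcal/mol closure penalty for
AU/UA/GU/UG pairs closing a loop.

Deliberately omitted refinements: dangling ends, coaxial stacking,
special tetraloop bonuses, and the stacking term across a 1-nt bulge.
Absolute energies therefore differ from mfold/ViennaRNA values; the
discriminating surface of this model is loop geometry (which pairs form),
not the printed free energy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: base encoding used throughout the folding DP
BASES = "ACGU"
A, C, G, U = range(4)
ENCODE = {b: i for i, b in enumerate(BASES)}

#: canonical pairs: Watson-Crick plus G.U wobble
_PAIRS = {(A, U), (U, A), (G, C), (C, G), (G, U), (U, G)}

#: gas constant x 310.15 K, kcal/mol
RT37 = 0.0019872 * 310.15

INF = 1e9

# Stack free energies, ΔG°37 kcal/mol, keyed by ((i, j), (i+1, j-1)) where
# (i, j) is the outer (5'-closer) pair.  Watson-Crick values follow
# Xia et al. 1998; wobble values are representative Turner-style numbers.
_STACKS_SEED = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    # wobble-containing stacks
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("U", "A"), ("G", "U")): -1.27,
    (("U", "A"), ("U", "G")): -1.00,
    (("G", "U"), ("G", "U")): -0.50,
    (("G", "U"), ("U", "G")): +0.50,
    (("U", "G"), ("G", "U")): -0.60,
}

# Loop initiation ΔG°37 by loop length (unpaired nt).
_HAIRPIN_INIT = {
    3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4, 10: 6.5,
    11: 6.6, 12: 6.7, 13: 6.8, 14: 6.9, 15: 6.9, 16: 7.0, 17: 7.1,
    18: 7.1, 19: 7.2, 20: 7.2, 21: 7.3, 22: 7.3, 23: 7.4, 24: 7.4,
    25: 7.5, 26: 7.5, 27: 7.5, 28: 7.6, 29: 7.6, 30: 7.7,
}
_BULGE_INIT = {
    1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.7,
    9: 4.8, 10: 4.9, 11: 5.0, 12: 5.1, 13: 5.2, 14: 5.3, 15: 5.4,
    16: 5.4, 17: 5.5, 18: 5.5, 19: 5.6, 20: 5.7, 21: 5.7, 22: 5.8,
    23: 5.8, 24: 5.8, 25: 5.9, 26: 5.9, 27: 6.0, 28: 6.0, 29: 6.0,
    30: 6.1,
}
_INTERNAL_INIT = {
    2: 1.7, 3: 1.8, 4: 1.1, 5: 2.0, 6: 1.9, 7: 2.1, 8: 2.3, 9: 2.4,
    10: 2.5, 11: 2.6, 12: 2.7, 13: 2.8, 14: 2.9, 15: 2.9, 16: 3.0,
    17: 3.1, 18: 3.1, 19: 3.2, 20: 3.3, 21: 3.3, 22: 3.4, 23: 3.4,
    24: 3.5, 25: 3.5, 26: 3.5, 27: 3.6, 28: 3.6, 29: 3.7, 30: 3.7,
}


def _build_stack_array() -> np.ndarray:
    """4x4x4x4 array stack[a, b, c, d] for pair (a,b) on interior pair (c,d).

    The seed table is completed by the helix-reversal symmetry
    stack[(a,b),(c,d)] == stack[(d,c),(b,a)].
    """
    arr = np.full((4, 4, 4, 4), INF)
    seed = {}
    for ((a1, b1), (c1, d1)), v in _STACKS_SEED.items():
        k = (ENCODE[a1], ENCODE[b1], ENCODE[c1], ENCODE[d1])
        seed[k] = v
        seed.setdefault((k[3], k[2], k[1], k[0]), v)
    for (a1, b1) in _PAIRS:
        for (c1, d1) in _PAIRS:
            k = (a1, b1, c1, d1)
            if k in seed:
                arr[k] = seed[k]
            else:  # only reachable if the seed table were incomplete
                arr[k] = -0.5
    return arr


def _init_array(table: dict[int, float], min_len: int) -> np.ndarray:
    arr = np.full(31, INF)
    for n, v in table.items():
        arr[n] = v
    assert all(np.isfinite(arr[min_len:31]))
    return arr


@dataclass(frozen=True)
class EnergyModel:
    """Versioned nearest-neighbour parameter set (37 degC)."""

    stack: np.ndarray = field(repr=False)
    hairpin_init: np.ndarray = field(repr=False)
    bulge_init: np.ndarray = field(repr=False)
    internal_init: np.ndarray = field(repr=False)
    multibranch_a: float = 3.4   # closing offset
    multibranch_b: float = 0.4   # per branch
    multibranch_c: float = 0.0   # per unpaired nt
    terminal_au_gu: float = 0.5  # loop-closure penalty for AU/UA/GU/UG
    max_interior: int = 30       # cap on unpaired nt in a two-loop during the DP
    temperature_label: str = "37C"
    version: str = "ire1kit-nn-1"

    @classmethod
    def default(cls) -> "EnergyModel":
        return cls(
            stack=_build_stack_array(),
            hairpin_init=_init_array(_HAIRPIN_INIT, 3),
            bulge_init=_init_array(_BULGE_INIT, 1),
            internal_init=_init_array(_INTERNAL_INIT, 2),
        )

    # -- loop terms -------------------------------------------------------

    def _extrapolate(self, table: np.ndarray, n: int) -> float:
        if n <= 30:
            return float(table[n])
        return float(table[30]) + 1.75 * RT37 * math.log(n / 30.0)

    def hairpin(self, n: int) -> float:
        """Hairpin-loop initiation for n unpaired nt (n >= 3)."""
        return self._extrapolate(self.hairpin_init, n)

    def bulge(self, n: int) -> float:
        return self._extrapolate(self.bulge_init, n)

    def internal(self, n: int) -> float:
        return self._extrapolate(self.internal_init, n)

    def closure_penalty(self, a: int, b: int) -> float:
        """Penalty for an AU/UA/GU/UG pair closing a hairpin/bulge/internal loop."""
        if (a, b) in ((G, C), (C, G)):
            return 0.0
        return self.terminal_au_gu

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "temperature_label": self.temperature_label,
            "stack": {
                f"{BASES[a]}{BASES[b]}/{BASES[c]}{BASES[d]}": self.stack[a, b, c, d]
                for (a, b) in _PAIRS
                for (c, d) in _PAIRS
            },
            "hairpin_init": {str(n): self.hairpin_init[n] for n in range(3, 31)},
            "bulge_init": {str(n): self.bulge_init[n] for n in range(1, 31)},
            "internal_init": {str(n): self.internal_init[n] for n in range(2, 31)},
            "multibranch": [self.multibranch_a, self.multibranch_b, self.multibranch_c],
            "terminal_au_gu": self.terminal_au_gu,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnergyModel":
        with open(path) as fh:
            payload = json.load(fh)
        stack = np.full((4, 4, 4, 4), INF)
        for key, v in payload["stack"].items():
            outer, inner = key.split("/")
            stack[
                ENCODE[outer[0]], ENCODE[outer[1]], ENCODE[inner[0]], ENCODE[inner[1]]
            ] = v
        def arr(d, lo):
            out = np.full(31, INF)
            for n, v in d.items():
                out[int(n)] = v
            return out
        a, b, c = payload["multibranch"]
        return cls(
            stack=stack,
            hairpin_init=arr(payload["hairpin_init"], 3),
            bulge_init=arr(payload["bulge_init"], 1),
            internal_init=arr(payload["internal_init"], 2),
            multibranch_a=a,
            multibranch_b=b,
            multibranch_c=c,
            terminal_au_gu=payload["terminal_au_gu"],
            temperature_label=payload["temperature_label"],
            version=payload["version"],
        )


def encode_sequence(residues: str) -> np.ndarray:
    return np.fromiter((ENCODE[b] for b in residues), dtype=np.int8, count=len(residues))


def can_pair(a: int, b: int) -> bool:
    return (a, b) in _PAIRS


#: module-level pairing matrix, indexed by encoded bases
PAIR_MATRIX = np.zeros((4, 4), dtype=bool)
for _a, _b in _PAIRS:
    PAIR_MATRIX[_a, _b] = True

DEFAULT_MODEL = EnergyModel.default()

__all__ = [
    "EnergyModel",
    "DEFAULT_MODEL",
    "encode_sequence",
    "can_pair",
    "PAIR_MATRIX",
    "BASES",
    "ENCODE",
    "RT37",
    "INF",
]
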