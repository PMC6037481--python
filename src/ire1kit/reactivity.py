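"""DMS reactivity normalization and folding-constraint derivation.

DMS methylates solvent-exposed, unpaired adenine and cytosine; guanine
and uracil are not informative.  Within a window centred on a scissile
bond, signals are max-normalized (the most reactive base is set to 1 and
the rest scaled proportionally) and A/C positions whose normalized
signal exceeds a threshold (default 0.2, strict inequality) are forced
single-stranded in the fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .energies import EnergyModel
from .folding import FoldConstraints, SecondaryStructure, fold_mfe
from .sequences import ReactivityRecord, RnaSequence

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.2
DEFAULT_HALFWIDTH = 19
MIN_WINDOW = 10


class NotNormalizedError(ValueError):
    """Constraints were requested from a profile that is not normalized."""


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-base DMS signals over a window anchored on a scissile bond.

    The window spans ``anchor_bond - (halfwidth - 1) .. anchor_bond +
    halfwidth`` (38 nt at the default halfwidth of 19), clipped to the
    sequence bounds.
    """

    records: tuple
    anchor_bond: int
    window_halfwidth: int = DEFAULT_HALFWIDTH

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        positions = [r.position for r in self.records]
        if positions != sorted(set(positions)):
            raise ValueError("records must be ordered by unique position")

    @property
    def is_normalized(self) -> bool:
        return bool(self.records) and all(
            r.normalized_signal is not None for r in self.records
        )

    def window_bounds(self, length: int) -> tuple[int, int]:
        lo = max(1, self.anchor_bond - (self.window_halfwidth - 1))
        hi = min(length, self.anchor_bond + self.window_halfwidth)
        return lo, hi


def window_records(
    records: Sequence[ReactivityRecord],
    anchor_bond: int,
    length: int,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> ReactivityProfile:
    """Clip a full-transcript record list to the window around a bond."""
    lo = max(1, anchor_bond - (halfwidth - 1))
    hi = min(length, anchor_bond + halfwidth)
    if lo > anchor_bond - (halfwidth - 1) or hi < anchor_bond + halfwidth:
        logger.warning(
            "reactivity window around bond %d clipped to %d..%d", anchor_bond, lo, hi
        )
    inside = tuple(r for r in records if lo <= r.position <= hi)
    return ReactivityProfile(inside, anchor_bond, halfwidth)


def normalize_window(profile: ReactivityProfile) -> ReactivityProfile:
    """Max-normalize raw signals over the window.

    The most reactive base gets normalized signal 1; others scale
    proportionally.  An all-zero window normalizes to all zeros.
    """
    if not profile.records:
        raise ValueError("cannot normalize an empty profile")
    peak = max(r.raw_signal for r in profile.records)
    if peak <= 0:
        new = tuple(replace(r, normalized_signal=0.0) for r in profile.records)
    else:
        new = tuple(
            replace(r, normalized_signal=r.raw_signal / peak) for r in profile.records
        )
    return replace(profile, records=new)


def derive_constraints(
    profile: ReactivityProfile,
    seq: RnaSequence,
    threshold: float = DEFAULT_THRESHOLD,
) -> FoldConstraints:
    """Force single-stranded every A/C above the normalization threshold.

    Strict inequality (a base at exactly the threshold is unconstrained);
    G and U are never constrained regardless of signal, since DMS does
    not report on them.
    """
    if not profile.is_normalized:
        raise NotNormalizedError("profile must be normalized before deriving constraints")
    forced = set()
    for r in profile.records:
        if r.position > len(seq):
            raise ValueError(f"record position {r.position} beyond sequence end")
        if r.base != seq.base(r.position):
            raise ValueError(
                f"record base {r.base} at {r.position} does not match sequence "
                f"{seq.base(r.position)}"
            )
        if r.base in ("A", "C") and r.normalized_signal > threshold:
            forced.add(r.position)
    return FoldConstraints(frozenset(forced))


def probe_and_fold(
    seq: RnaSequence,
    records: Sequence[ReactivityRecord],
    bond_index: int,
    model: Optional[EnergyModel] = None,
    threshold: float = DEFAULT_THRESHOLD,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> tuple[SecondaryStructure, int]:
    """Window -> normalize -> constrain -> fold around a scissile bond.

    Returns the window-local structure and the offset such that
    ``global_position = local_position + offset``.
    """
    if not 1 <= bond_index < len(seq):
        raise IndexError(f"bond index {bond_index} outside 1..{len(seq) - 1}")
    lo = max(1, bond_index - (halfwidth - 1))
    hi = min(len(seq), bond_index + halfwidth)
    if hi - lo + 1 < MIN_WINDOW:
        raise ValueError(f"window {lo}..{hi} shorter than {MIN_WINDOW} nt after clipping")
    profile = normalize_window(window_records(records, bond_index, len(seq), halfwidth))
    constraints = derive_constraints(profile, seq, threshold)
    offset = lo - 1
    local = FoldConstraints(
        frozenset(p - offset for p in constraints.forced_single_stranded)
    )
    window_seq = seq.subseq(lo, hi)
    structure = fold_mfe(window_seq, local, model)
    return structure, offset


__all__ = [
    "ReactivityProfile",
    "NotNormalizedError",
    "window_records",
    "normalize_window",
    "derive_constraints",
    "probe_and_fold",
    "DEFAULT_THRESHOLD",
    "DEFAULT_HALFWIDTH",
]
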