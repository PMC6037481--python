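"""Species-specific Ire1 cleavage-site classification.

Ire1 selects its substrates by both sequence and stem-loop geometry:

* *S. cerevisiae* Ire1 requires CNG|CNGN or CNG|ANGN ('|' marks the
  scissile bond) inside a strictly conserved 7-membered loop, with the
  consensus occupying the whole loop (bond between loop positions 3
  and 4).
* *S. pombe* Ire1 requires the trinucleotide UG|C near the centre of a
  hairpin loop and tolerates loop sizes from 3 to 9 nt.

"Near the centre" is formalized as a bond offset |b - L/2| <= 1 bond,
where b is the bond's ordinal among the loop's L-1 internal bonds; all
verifiable substrate hairpins (XBP1 7-loop, SPAC4G9.15 3-loop, BIP1
9-loop) sit at offset 0.5.  Wobble-closed loops count as loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .folding import BondContext, SecondaryStructure, scissile_bond_context
from .sequences import RnaSequence

_WILDCARD = "N"


def _split_motif(motif: str) -> tuple[str, str]:
    if motif.count("|") != 1:
        raise ValueError(f"motif {motif!r} must contain exactly one scissile-bond '|'")
    up, down = motif.split("|")
    if not up or not down:
        raise ValueError(f"motif {motif!r} must have bases on both sides of the bond")
    return up, down


@dataclass(frozen=True)
class SpeciesRule:
    """Sequence + geometry rule for one Ire1 ortholog.

    ``register`` pins the bond to a fixed ordinal within the loop (the
    S. cerevisiae consensus spans exactly the 7-nt loop); ``None`` leaves
    the register free, in which case ``center_tolerance`` bounds the
    bond's distance from the loop centre.
    """

    species: str
    motifs: tuple[str, ...]
    loop_size_range: tuple[int, int]
    center_tolerance: Optional[float] = None
    register: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "motifs", tuple(self.motifs))
        for m in self.motifs:
            _split_motif(m)
        lo, hi = self.loop_size_range
        if not (3 <= lo <= hi):
            raise ValueError(f"invalid loop size range {self.loop_size_range}")


S_CEREVISIAE = SpeciesRule(
    species="S_cerevisiae",
    motifs=("CNG|CNGN", "CNG|ANGN"),
    loop_size_range=(7, 7),
    register=3,
)

S_POMBE = SpeciesRule(
    species="S_pombe",
    motifs=("UG|C",),
    loop_size_range=(3, 9),
    center_tolerance=1.0,
)

DEFAULT_RULES = (S_CEREVISIAE, S_POMBE)


def _match_motif_at(seq: RnaSequence, bond: int, motif: str) -> Optional[str]:
    """Literal substring matched when ``motif`` sits on bond ``bond``, else None."""
    up, down = _split_motif(motif)
    start = bond - len(up) + 1
    end = bond + len(down)
    if start < 1 or end > len(seq):
        return None
    window = seq.residues[start - 1 : end]
    pattern = up + down
    for got, want in zip(window, pattern):
        if want != _WILDCARD and got != want:
            return None
    return window


def matched_motif(seq: RnaSequence, bond: int, rule: SpeciesRule) -> Optional[str]:
    for m in rule.motifs:
        hit = _match_motif_at(seq, bond, m)
        if hit is not None:
            return hit
    return None


def scan_motifs(seq: RnaSequence, rule: SpeciesRule) -> list[int]:
    """All scissile-bond indices whose flanks match the rule's motif.

    Pure sequence scan; no structural filtering.
    """
    return [i for i in range(1, len(seq)) if matched_motif(seq, i, rule) is not None]


@dataclass(frozen=True)
class SiteVerdict:
    """One species' verdict on one bond, with per-check reasons.

    ``reasons`` maps check name (motif, in_loop, loop_size, placement) to
    "pass" or a failure description; ``substrate`` is True iff every
    check passed.
    """

    species: str
    substrate: bool
    reasons: dict
    matched_motif: Optional[str]


@dataclass(frozen=True)
class CleavageSiteCall:
    """A candidate scissile bond with loop context and per-species verdicts."""

    bond_index: int
    context: BondContext
    verdicts: dict  # species name -> SiteVerdict

    def substrate_species(self) -> set[str]:
        return {sp for sp, v in self.verdicts.items() if v.substrate}


def classify_site(
    seq: RnaSequence,
    structure: SecondaryStructure,
    bond_index: int,
    rule: SpeciesRule,
) -> SiteVerdict:
    """Apply one species rule to one bond given a folded structure.

    Substrate iff: motif matches, both bond-flanking nucleotides are
    unpaired in the same hairpin loop, the loop size is in range, and
    the bond satisfies the register (or sits within the centre
    tolerance).
    """
    reasons: dict[str, str] = {}
    motif = matched_motif(seq, bond_index, rule)
    reasons["motif"] = "pass" if motif else f"no {'/'.join(rule.motifs)} at bond"

    ctx = scissile_bond_context(structure, bond_index)
    if ctx.in_loop:
        reasons["in_loop"] = "pass"
        lo, hi = rule.loop_size_range
        L = ctx.loop.size
        reasons["loop_size"] = (
            "pass" if lo <= L <= hi else f"loop size {L} outside [{lo}, {hi}]"
        )
        if rule.register is not None:
            reasons["placement"] = (
                "pass"
                if ctx.ordinal == rule.register
                else f"bond at loop register {ctx.ordinal}, requires {rule.register}"
            )
        elif rule.center_tolerance is not None:
            reasons["placement"] = (
                "pass"
                if ctx.offset <= rule.center_tolerance
                else f"offset {ctx.offset} from loop centre exceeds {rule.center_tolerance}"
            )
        else:
            reasons["placement"] = "pass"
    else:
        reasons["in_loop"] = "not in loop"
        reasons["loop_size"] = "not in loop"
        reasons["placement"] = "not in loop"

    return SiteVerdict(
        species=rule.species,
        substrate=all(v == "pass" for v in reasons.values()),
        reasons=reasons,
        matched_motif=motif,
    )


def classify_bond(
    seq: RnaSequence,
    structure: SecondaryStructure,
    bond_index: int,
    rules: Sequence[SpeciesRule] = DEFAULT_RULES,
) -> CleavageSiteCall:
    """Per-species verdicts for one bond."""
    return CleavageSiteCall(
        bond_index=bond_index,
        context=scissile_bond_context(structure, bond_index),
        verdicts={r.species: classify_site(seq, structure, bond_index, r) for r in rules},
    )


def dual_specificity(
    seq: RnaSequence, structure: SecondaryStructure, bond_index: int
) -> set[str]:
    """Which of the default species rules call this bond a substrate."""
    return classify_bond(seq, structure, bond_index).substrate_species()


@dataclass(frozen=True)
class Substitution:
    position: int
    old: str
    new: str


def apply_substitutions(seq: RnaSequence, subs: Iterable[Substitution]) -> RnaSequence:
    residues = list(seq.residues)
    for s in subs:
        if residues[s.position - 1] != s.old:
            raise ValueError(
                f"substitution at {s.position} expects {s.old}, found {residues[s.position - 1]}"
            )
        residues[s.position - 1] = s.new
    return RnaSequence(seq.id, "".join(residues))


def mutate_to_motif(
    seq: RnaSequence, bond_index: int, rule: SpeciesRule
) -> list[Substitution]:
    """Smallest set of point substitutions making the motif match at the bond.

    Already-matching sites return an empty list.  Among the rule's motif
    alternatives the one needing fewest edits wins (first listed on
    ties); within a motif the edit set is determined by the mismatching
    literal positions, so ties break 5'-first by construction.
    """
    if matched_motif(seq, bond_index, rule) is not None:
        return []
    best: Optional[list[Substitution]] = None
    for motif in rule.motifs:
        up, down = _split_motif(motif)
        start = bond_index - len(up) + 1
        end = bond_index + len(down)
        if start < 1 or end > len(seq):
            continue
        pattern = up + down
        subs = [
            Substitution(position=start + k, old=seq.base(start + k), new=want)
            for k, want in enumerate(pattern)
            if want != _WILDCARD and seq.base(start + k) != want
        ]
        if best is None or len(subs) < len(best):
            best = subs
    if best is None:
        raise ValueError(
            f"no motif of {rule.species} fits around bond {bond_index} within the sequence"
        )
    return best


__all__ = [
    "SpeciesRule",
    "SiteVerdict",
    "CleavageSiteCall",
    "Substitution",
    "S_CEREVISIAE",
    "S_POMBE",
    "DEFAULT_RULES",
    "scan_motifs",
    "matched_motif",
    "classify_site",
    "classify_bond",
    "dual_specificity",
    "mutate_to_motif",
    "apply_substitutions",
]
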