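"""Splicing-cassette engineering and splice-product prediction.

A splicing cassette is two Ire1-cleavable stem-loops flanking a short
intron: Ire1 cuts both loops, the intron falls out, and tRNA ligase
joins the exons.  The cassette built here is optimized for S. pombe
Ire1 (UG|C in a 7-membered loop at both junctions) around a 30-nt
intron — the pruned-intron architecture.  Both scissile bonds sit
exactly on the exon/intron boundaries, so the excised segment equals
the intron field.

The default cassette nucleotide sequence is a design artifact of this
package (validated at run time by folding and classification), not a
published sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .energies import EnergyModel
from .folding import fold_mfe
from .reactivity import DEFAULT_HALFWIDTH
from .rules import S_POMBE, SiteVerdict, SpeciesRule, classify_site
from .sequences import RnaSequence

INTRON_LENGTH = 30


@dataclass(frozen=True)
class CassetteDesign:
    """Two junction stem-loops around a 30-nt intron.

    ``exon1_junction`` ends at the 5' scissile bond; ``exon2_junction``
    starts right after the 3' scissile bond; the hairpins straddle the
    boundaries (each loop's 3 nt downstream of its bond lie in the next
    segment).  ``validation`` is filled by :func:`insert_cassette`.
    """

    exon1_junction: str
    intron: str
    exon2_junction: str
    validation: Optional[dict] = None

    def __post_init__(self):
        if len(self.intron) != INTRON_LENGTH:
            raise ValueError(
                f"intron must be {INTRON_LENGTH} nt, got {len(self.intron)}"
            )

    @property
    def insert(self) -> str:
        return self.exon1_junction + self.intron + self.exon2_junction

    def bond_offsets(self) -> tuple[int, int]:
        """Scissile-bond positions within the insert (5' and 3' junctions)."""
        b1 = len(self.exon1_junction)
        return b1, b1 + len(self.intron)


# Junction architecture: 8-bp GC-rich stem, 7-nt loop CAUGCAG with the
# UG|C bond between loop positions 4 and 5 (offset 0.5 from centre).
_STEM1 = "GGGCAGGC"
_STEM2 = "GGACGGAG"
_LOOP = "CAUGCAG"
_LINKER = "AAUUAAA"


def build_cassette(
    stem1: str = _STEM1,
    stem2: str = _STEM2,
    loop: str = _LOOP,
    linker: Optional[str] = None,
) -> CassetteDesign:
    """Assemble a cassette from two stem arms and a junction loop.

    The loop must be 7 nt with the scissile bond between loop positions
    4 and 5; the linker length is chosen (or checked) so the intron is
    exactly 30 nt.
    """
    from .simulate import reverse_complement

    if len(loop) != 7:
        raise ValueError("junction loop must be 7 nt")
    need = INTRON_LENGTH - 7 - len(stem1) - len(stem2)
    if linker is None:
        if need < 0:
            raise ValueError("stems too long for a 30-nt intron")
        linker = ("AAUUAAAUUAAUAAU" * 2)[:need]
    elif len(linker) != need:
        raise ValueError(f"linker must be {need} nt for a 30-nt intron")
    exon1 = stem1 + loop[:4]
    intron = loop[4:] + reverse_complement(stem1) + linker + stem2 + loop[:4]
    exon2 = loop[4:] + reverse_complement(stem2)
    return CassetteDesign(exon1_junction=exon1, intron=intron, exon2_junction=exon2)


def design_default_cassette() -> CassetteDesign:
    """The package's reference S. pombe-optimized cassette."""
    return build_cassette()


# ---------------------------------------------------------------------------
# Sequence surgery


def replace_site(
    host: RnaSequence, region_start: int, region_end: int, replacement: str
) -> RnaSequence:
    """Splice ``replacement`` in for positions ``region_start..region_end``.

    Downstream coordinates shift by ``len(replacement) - region length``;
    an empty replacement is a deletion.
    """
    if not (1 <= region_start <= region_end <= len(host)):
        raise IndexError(
            f"region {region_start}..{region_end} outside 1..{len(host)}"
        )
    residues = (
        host.residues[: region_start - 1] + replacement + host.residues[region_end:]
    )
    return RnaSequence(host.id, residues)


def insert_after(host: RnaSequence, position: int, insert: str) -> RnaSequence:
    """Insert after bond ``position`` (0 inserts at the 5' end)."""
    if not 0 <= position <= len(host):
        raise IndexError(f"insertion bond {position} outside 0..{len(host)}")
    return RnaSequence(
        host.id, host.residues[:position] + insert + host.residues[position:]
    )


def _validate_junction(
    engineered: RnaSequence,
    bond: int,
    rule: SpeciesRule,
    model: Optional[EnergyModel],
) -> SiteVerdict:
    lo = max(1, bond - (DEFAULT_HALFWIDTH - 1))
    hi = min(len(engineered), bond + DEFAULT_HALFWIDTH)
    window = engineered.subseq(lo, hi)
    structure = fold_mfe(window, model=model)
    return classify_site(window, structure, bond - lo + 1, rule)


def insert_cassette(
    host: RnaSequence,
    position: int,
    design: Optional[CassetteDesign] = None,
    model: Optional[EnergyModel] = None,
    rule: SpeciesRule = S_POMBE,
    utr: Optional[tuple[int, int]] = None,
) -> tuple[RnaSequence, dict]:
    """Insert the cassette after bond ``position`` and validate both junctions.

    Each junction's 38-nt window is folded in the new sequence context
    and classified under the given species rule.  Validation failure is
    reported, not raised — designs are iterated.
    """
    design = design or design_default_cassette()
    if utr is not None and not (utr[0] <= position <= utr[1]):
        raise ValueError(
            f"insertion position {position} outside annotated 3'UTR {utr[0]}..{utr[1]}"
        )
    engineered = insert_after(host, position, design.insert)
    b1_local, b2_local = design.bond_offsets()
    bond5 = position + b1_local
    bond3 = position + b2_local
    verdicts = {
        "junction1": _validate_junction(engineered, bond5, rule, model),
        "junction2": _validate_junction(engineered, bond3, rule, model),
    }
    report = {
        "valid": all(v.substrate for v in verdicts.values()),
        "species": rule.species,
        "bond5": bond5,
        "bond3": bond3,
        "intron_length": len(design.intron),
        "junctions": {
            name: {"substrate": v.substrate, "reasons": v.reasons}
            for name, v in verdicts.items()
        },
    }
    return engineered, report


# ---------------------------------------------------------------------------
# Splice product


@dataclass(frozen=True)
class SpliceProduct:
    """Result of cutting at two bonds and ligating the exons."""

    spliced: RnaSequence
    excised_intron: RnaSequence
    junction_coordinate: int  # 1-based position in the spliced sequence


def predict_splice_product(
    seq: RnaSequence, bond5: int, bond3: int, verdicts: Optional[dict] = None
) -> SpliceProduct:
    """Excise ``seq[bond5+1 .. bond3]`` and ligate the flanking exons.

    Lengths are conserved: spliced + intron == input.  If per-bond
    verdicts are supplied and either bond is not a substrate, a warning
    is emitted (the arithmetic still proceeds).
    """
    if not (1 <= bond5 < bond3 <= len(seq) - 1):
        raise ValueError(
            f"need 1 <= bond5 < bond3 <= {len(seq) - 1}, got {bond5}, {bond3}"
        )
    if verdicts is not None:
        for name, v in verdicts.items():
            substrate = v.substrate if isinstance(v, SiteVerdict) else bool(v)
            if not substrate:
                warnings.warn(
                    f"splice bond {name} is not classified as a substrate", stacklevel=2
                )
    spliced = RnaSequence(
        f"{seq.id}|spliced", seq.residues[:bond5] + seq.residues[bond3:]
    )
    intron = RnaSequence(f"{seq.id}|intron", seq.residues[bond5:bond3])
    return SpliceProduct(
        spliced=spliced, excised_intron=intron, junction_coordinate=bond5
    )


def reinsert_intron(product: SpliceProduct, original_id: str = "") -> RnaSequence:
    """Inverse of :func:`predict_splice_product` (round-trip check)."""
    j = product.junction_coordinate
    residues = (
        product.spliced.residues[:j]
        + product.excised_intron.residues
        + product.spliced.residues[j:]
    )
    return RnaSequence(original_id or product.spliced.id, residues)


__all__ = [
    "CassetteDesign",
    "SpliceProduct",
    "INTRON_LENGTH",
    "design_default_cassette",
    "replace_site",
    "insert_after",
    "insert_cassette",
    "predict_splice_product",
    "reinsert_intron",
]
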