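"""Bundled reference sequences.

The four hairpin oligos used for in vitro Ire1 cleavage assays, with the
scissile bond of each site (the index of the nucleotide 5' of the cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .sequences import RnaSequence, read_fasta


@dataclass(frozen=True)
class PaperHairpin:
    name: str
    sequence: str
    scissile_bond: int  # cut between this position and the next
    expected_loop_size: int


#: the four hairpin substrates; bonds sit at the UG|C (BIP1, SPAC4G9.15,
#: XBP1) or CNG|ANGN / CNG|CNGN (HAC1, XBP1) sites of the folded loops
PAPER_HAIRPINS = {
    "BIP1": PaperHairpin("BIP1", "CGCGAGAUAACUGGUGCUUUGUUAUCUCGCG", 16, 9),
    "SPAC4G9.15": PaperHairpin("SPAC4G9.15", "CCACCACCGAGUAUGCUACUCGGUGGUGG", 15, 3),
    "HAC1_3SS": PaperHairpin("HAC1_3SS", "GCGCGGACUGUCCGAAGCGCAGUCCGCGC", 14, 7),
    "XBP1": PaperHairpin("XBP1", "UGCACCUCUGCAGCAGGUGCA", 10, 7),
}


def load_paper_hairpins() -> list[RnaSequence]:
    """The bundled hairpin FASTA as RnaSequence records."""
    with resources.as_file(
        resources.files("ire1kit.data").joinpath("hairpins.fasta")
    ) as path:
        return read_fasta(path)
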