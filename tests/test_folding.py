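"""MFE folding, the pair-maximization oracle, and loop geometry."""

import functools
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ire1kit.energies import DEFAULT_MODEL, PAIR_MATRIX, encode_sequence
from ire1kit.folding import (
    FoldConstraints,
    SecondaryStructure,
    fold_maxpair,
    fold_mfe,
    hairpin_loops,
    scissile_bond_context,
    structure_energy,
    validate_pairing_alphabet,
)
from ire1kit.sequences import RnaSequence, dotbracket_string

rna = st.text(alphabet="ACGU", min_size=5, max_size=18)


class TestMfeReferenceHairpins:
    """The four in-vitro substrate hairpins fold to their known loop sizes."""

    @pytest.mark.parametrize(
        "name, loop_size, loop_span",
        [
            ("BIP1", 9, (12, 20)),
            ("SPAC4G9.15", 3, (14, 16)),
            ("XBP1", 7, (8, 14)),
            ("HAC1_3SS", 7, (12, 18)),
        ],
    )
    def test_loop_size_and_position(self, hairpins, name, loop_size, loop_span):
        _, structure = hairpins[name]
        loops = hairpin_loops(structure)
        assert len(loops) == 1
        (loop,) = loops
        assert loop.size == loop_size
        assert (loop.start, loop.end) == loop_span

    def test_hac1_loop_closed_by_wobble(self, hairpins):
        seq, structure = hairpins["HAC1_3SS"]
        (loop,) = hairpin_loops(structure)
        i, j = loop.closing_pair
        assert {seq.base(i), seq.base(j)} == {"U", "G"}

    def test_xbp1_rejects_bulged_extra_pair(self, hairpins):
        """Pure pair maximization shrinks the XBP1 7-loop; the energy model must not."""
        seq, structure = hairpins["XBP1"]
        maxpair = fold_maxpair(seq)
        assert maxpair.n_pairs() > structure.n_pairs()
        assert hairpin_loops(structure)[0].size == 7

    def test_pairs_are_canonical(self, hairpins):
        for seq, structure in hairpins.values():
            validate_pairing_alphabet(seq, structure)

    @pytest.mark.skipif(shutil.which("RNAfold") is None, reason="ViennaRNA not on PATH")
    def test_pair_tables_match_viennarna(self, hairpins):
        """Independent cross-check against RNAfold on the reference hairpins."""
        fasta = "".join(f">{n}\n{s.residues}\n" for n, (s, _) in hairpins.items())
        out = subprocess.run(
            ["RNAfold", "--noPS"], input=fasta, capture_output=True, text=True, check=True
        ).stdout.splitlines()
        vienna = {out[i][1:]: out[i + 2].split()[0] for i in range(0, len(out), 3)}
        for name, (seq, structure) in hairpins.items():
            assert dotbracket_string(structure.pair_table) == vienna[name]


class TestMfeBasics:
    def test_unpairable_sequence_stays_open(self):
        structure = fold_mfe(RnaSequence("a", "AAAAAAAAAA"))
        assert structure.n_pairs() == 0 and structure.energy == 0.0

    def test_short_sequence_trivial(self):
        structure = fold_mfe(RnaSequence("s", "ACGU"))
        assert structure.length == 4 and structure.n_pairs() == 0

    def test_deterministic(self, hairpins):
        for seq, structure in hairpins.values():
            again = fold_mfe(seq)
            assert np.array_equal(again.pair_table, structure.pair_table)

    def test_constrained_positions_stay_unpaired(self, hairpins):
        seq, _ = hairpins["BIP1"]
        cons = FoldConstraints(frozenset({5, 6, 7, 25}))
        structure = fold_mfe(seq, cons)
        assert all(not structure.is_paired(p) for p in (5, 6, 7, 25))

    def test_constraint_energy_monotone(self, hairpins):
        for seq, free in hairpins.values():
            cons = FoldConstraints(frozenset({len(seq) // 2}))
            assert fold_mfe(seq, cons).energy >= free.energy - 1e-9

    def test_out_of_range_constraint_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fold_mfe(RnaSequence("x", "GGGAAACCC"), FoldConstraints(frozenset({50})))


@given(rna)
def test_energy_decomposition_matches_dp(residues):
    """Recomputing the returned structure's energy loop-by-loop reproduces the DP."""
    seq = RnaSequence("r", residues)
    structure = fold_mfe(seq)
    assert structure_energy(seq, structure) == pytest.approx(
        structure.energy, abs=1e-6
    )


@given(rna, st.integers(min_value=1, max_value=18))
def test_constrained_position_never_paired(residues, pos):
    seq = RnaSequence("r", residues)
    if pos > len(seq):
        pos = 1 + (pos - 1) % len(seq)
    structure = fold_mfe(seq, FoldConstraints(frozenset({pos})))
    assert not structure.is_paired(pos)


def test_energy_model_json_roundtrip(tmp_path, hairpins):
    """A model exported to JSON folds identically when loaded back."""
    from ire1kit.energies import EnergyModel

    path = tmp_path / "nn.json"
    DEFAULT_MODEL.to_json(path)
    model = EnergyModel.from_json(path)
    for seq, structure in hairpins.values():
        again = fold_mfe(seq, model=model)
        assert np.array_equal(again.pair_table, structure.pair_table)
        assert again.energy == pytest.approx(structure.energy)


# ---------------------------------------------------------------------------
# Nussinov oracle


def _enumerate_max_pairs(residues: str) -> int:
    """Independent brute-force recursion over all nested pairings."""
    enc = encode_sequence(residues)
    n = len(residues)

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:  # 0-based, inclusive
        if j - i < 4:
            return 0
        out = best(i + 1, j)
        for k in range(i + 4, j + 1):
            if PAIR_MATRIX[enc[i], enc[k]]:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, n - 1)


def _enumerate_structures(residues: str):
    """Yield every nested pairing (as frozensets of 0-based pairs)."""
    enc = encode_sequence(residues)

    def gen(i, j):
        if i > j:
            yield frozenset()
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + 4, j + 1):
            if PAIR_MATRIX[enc[i], enc[k]]:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield inner | outer | {(i, k)}

    yield from gen(0, len(residues) - 1)


class TestMaxPairOracle:
    def test_unique_maximum(self):
        structure = fold_maxpair(RnaSequence("x", "GGGAAACCC"))
        assert structure.n_pairs() == 3
        assert dotbracket_string(structure.pair_table) == "(((...)))"

    def test_constraint_removes_a_pair(self):
        structure = fold_maxpair(
            RnaSequence("x", "GGGAAACCC"), FoldConstraints(frozenset({2}))
        )
        assert structure.n_pairs() <= 2

    def test_matches_bruteforce_on_200_random_sequences(self, rng):
        """Pair count equals exhaustive interval recursion for n <= 18."""
        for _ in range(200):
            n = int(rng.integers(8, 19))
            residues = "".join(rng.choice(list("ACGU"), size=n))
            seq = RnaSequence("r", residues)
            assert fold_maxpair(seq).n_pairs() == _enumerate_max_pairs(residues)

    def test_bruteforce_recursion_matches_full_enumeration(self, rng):
        """Validate the interval recursion itself against literal enumeration."""
        for _ in range(30):
            n = int(rng.integers(6, 13))
            residues = "".join(rng.choice(list("ACGU"), size=n))
            explicit = max(
                (len(s) for s in _enumerate_structures(residues)), default=0
            )
            assert _enumerate_max_pairs(residues) == explicit

    def test_mfe_never_beats_maxpair_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 19))
            residues = "".join(rng.choice(list("ACGU"), size=n))
            seq = RnaSequence("r", residues)
            assert fold_mfe(seq).n_pairs() <= fold_maxpair(seq).n_pairs()


# ---------------------------------------------------------------------------
# Loop geometry


class TestLoopGeometry:
    def test_unpaired_structure_has_no_loops(self):
        structure = SecondaryStructure(np.zeros(11, dtype=int), 0.0)
        assert hairpin_loops(structure) == []

    @pytest.mark.parametrize(
        "name, bond, size, ordinal, offset",
        [
            ("XBP1", 10, 7, 3, 0.5),
            ("BIP1", 16, 9, 5, 0.5),
            ("SPAC4G9.15", 15, 3, 2, 0.5),
            ("HAC1_3SS", 14, 7, 3, 0.5),
        ],
    )
    def test_scissile_bonds_near_loop_centre(
        self, hairpins, name, bond, size, ordinal, offset
    ):
        _, structure = hairpins[name]
        ctx = scissile_bond_context(structure, bond)
        assert ctx.in_loop
        assert ctx.loop.size == size
        assert ctx.ordinal == ordinal
        assert ctx.offset == pytest.approx(offset)

    def test_stem_bond_not_in_loop(self, hairpins):
        _, structure = hairpins["XBP1"]
        ctx = scissile_bond_context(structure, 2)  # U1-G2|C3 sits in the stem
        assert not ctx.in_loop
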