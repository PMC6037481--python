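"""Shared fixtures: reference hairpins and generated stem-loop banks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ire1kit import (
    PAPER_HAIRPINS,
    RnaSequence,
    fold_mfe,
)
from ire1kit.simulate import HairpinSpec, make_hairpin

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def hairpins():
    """name -> (RnaSequence, MFE SecondaryStructure) for the four reference oligos."""
    out = {}
    for name, hp in PAPER_HAIRPINS.items():
        seq = RnaSequence(name, hp.sequence)
        out[name] = (seq, fold_mfe(seq))
    return out


def _loop_with_motif(loop_size: int, motif: str) -> HairpinSpec:
    """N-loop of the given size with the motif's bond at the loop centre."""
    ordinal = (loop_size + 1) // 2  # bond at offset 0.5 for odd sizes
    return HairpinSpec(
        stem_length=9,
        loop_sequence="N" * loop_size,
        flank_lengths=(5, 5),
        motif_placement=(motif, ordinal),
    )


def _hairpin_bank(motif: str, n: int, seed0: int):
    """n generated hairpins carrying `motif` at loop centre.

    Returns a list of (sequence, true structure, implanted bond index,
    loop size); loop sizes cycle over 3, 5, 7, 9.
    """
    bank = []
    sizes = (3, 5, 7, 9)
    for idx in range(n):
        L = sizes[idx % len(sizes)]
        spec = _loop_with_motif(L, motif)
        seq, structure = make_hairpin(spec, seed=seed0 + idx)
        f5, stem = spec.flank_lengths[0], spec.stem_length
        bond = f5 + stem + (L + 1) // 2
        bank.append((seq, structure, bond, L))
    return bank


@pytest.fixture(scope="session")
def ugc_hairpins():
    """200 stem-loops with UG|C implanted at the loop centre."""
    return _hairpin_bank("UG|C", 200, seed0=10_000)


@pytest.fixture(scope="session")
def agc_hairpins():
    """200 stem-loops with the non-cognate AG|C at the loop centre."""
    return _hairpin_bank("AG|C", 200, seed0=20_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
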