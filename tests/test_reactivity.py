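"""DMS normalization, constraint derivation, and constrained window folding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ire1kit.folding import hairpin_loops
from ire1kit.reactivity import (
    NotNormalizedError,
    ReactivityProfile,
    derive_constraints,
    normalize_window,
    probe_and_fold,
    window_records,
)
from ire1kit.sequences import ReactivityRecord, RnaSequence
from ire1kit.simulate import simulate_dms


def _profile(signals, bases=None, anchor=1):
    bases = bases or ["A"] * len(signals)
    records = [
        ReactivityRecord(position=i + 1, base=b, raw_signal=s)
        for i, (b, s) in enumerate(zip(bases, signals))
    ]
    return ReactivityProfile(records, anchor_bond=anchor)


class TestNormalizeWindow:
    def test_proportional_scaling(self):
        out = normalize_window(_profile([10.0, 50.0, 25.0]))
        assert [r.normalized_signal for r in out.records] == [0.2, 1.0, 0.5]

    def test_all_zero_window(self):
        out = normalize_window(_profile([0.0, 0.0]))
        assert all(r.normalized_signal == 0.0 for r in out.records)

    def test_single_record_normalizes_to_one(self):
        out = normalize_window(_profile([7.0]))
        assert out.records[0].normalized_signal == 1.0

    def test_max_is_one_whenever_any_signal_positive(self):
        out = normalize_window(_profile([0.0, 3.0, 1.0]))
        assert max(r.normalized_signal for r in out.records) == 1.0


class TestDeriveConstraints:
    def test_reactive_adenine_constrained(self):
        seq = RnaSequence("s", "AGCU")
        prof = normalize_window(_profile([0.25, 1.0, 0.1, 0.0], list("AGCU")))
        assert 1 in derive_constraints(prof, seq).forced_single_stranded

    def test_threshold_is_strict(self):
        seq = RnaSequence("s", "AA")
        prof = normalize_window(_profile([0.20, 1.0], ["A", "A"]))
        assert 1 not in derive_constraints(prof, seq).forced_single_stranded

    def test_guanine_never_constrained(self):
        seq = RnaSequence("s", "GA")
        prof = normalize_window(_profile([0.9, 1.0], ["G", "A"]))
        forced = derive_constraints(prof, seq).forced_single_stranded
        assert 1 not in forced and 2 in forced

    def test_unnormalized_profile_is_hard_error(self):
        seq = RnaSequence("s", "AA")
        with pytest.raises(NotNormalizedError):
            derive_constraints(_profile([1.0, 2.0]), seq)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        """Multiplying all raw signals by c > 0 leaves constraints unchanged."""
        seq = RnaSequence("s", "ACAU")
        raws = [5.0, 30.0, 1.0, 8.0]
        base = derive_constraints(
            normalize_window(_profile(raws, list("ACAU"))), seq
        )
        scaled = derive_constraints(
            normalize_window(_profile([c * r for r in raws], list("ACAU"))), seq
        )
        assert base.forced_single_stranded == scaled.forced_single_stranded


class TestProbeAndFold:
    def test_zero_signal_equals_unconstrained_fold(self, hairpins):
        seq, free = hairpins["BIP1"]
        records = [
            ReactivityRecord(i, seq.base(i), 0.0) for i in range(1, len(seq) + 1)
        ]
        structure, offset = probe_and_fold(seq, records, bond_index=16)
        assert offset == 0  # 31-mer: window covers everything
        assert np.array_equal(structure.pair_table, free.pair_table)

    def test_everything_reactive_folds_open(self, hairpins):
        seq, _ = hairpins["BIP1"]
        records = [
            ReactivityRecord(i, seq.base(i), 100.0) for i in range(1, len(seq) + 1)
        ]
        structure, _ = probe_and_fold(seq, records, bond_index=16)
        # every A/C is forced open; remaining G/U cannot form the stems
        assert structure.n_pairs() <= 2

    def test_window_too_short_is_error(self):
        seq = RnaSequence("s", "ACGUACGUA")
        records = [ReactivityRecord(i, seq.base(i), 1.0) for i in range(1, 10)]
        with pytest.raises(ValueError, match="shorter"):
            probe_and_fold(seq, records, bond_index=4, halfwidth=4)

    def test_synthetic_window_recovers_implanted_loop(self, ugc_hairpins):
        seq, truth, bond, loop_size = ugc_hairpins[2]
        records = simulate_dms(seq, truth, seed=7)
        structure, offset = probe_and_fold(seq, records, bond)
        loops = hairpin_loops(structure)
        assert any(
            lp.size == loop_size and lp.start + offset == bond - (loop_size + 1) // 2 + 1
            for lp in loops
        )


class TestSyntheticRecoveryAtScale:
    """Generator-truth recovery over 100 random stem-loop windows."""

    def test_paired_ac_rarely_constrained_and_folds_match_truth(self, ugc_hairpins):
        paired_ac_total = 0
        paired_ac_constrained = 0
        positions_total = 0
        positions_correct = 0
        for idx, (seq, truth, bond, _) in enumerate(ugc_hairpins[:100]):
            records = simulate_dms(seq, truth, seed=1000 + idx)
            lo = max(1, bond - 18)
            hi = min(len(seq), bond + 19)
            prof = normalize_window(
                window_records(records, bond, len(seq))
            )
            cons = derive_constraints(prof, seq)
            for p in range(lo, hi + 1):
                if seq.base(p) in "AC" and truth.is_paired(p):
                    paired_ac_total += 1
                    if p in cons.forced_single_stranded:
                        paired_ac_constrained += 1
            structure, offset = probe_and_fold(seq, records, bond)
            for local in range(1, structure.length + 1):
                positions_total += 1
                if structure.is_paired(local) == truth.is_paired(local + offset):
                    positions_correct += 1
        assert paired_ac_constrained <= 0.05 * paired_ac_total
        assert positions_correct >= 0.90 * positions_total
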