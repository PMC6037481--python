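"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's input types:

* hairpin sequences with a designed stem-loop (and optionally an
  implanted cleavage motif) whose MFE fold is verified to reproduce the
  intended loop;
* per-base DMS modification counts drawn from a three-channel Poisson
  model (exposed A/C, protected A/C, G/U background);
* noisy first-order cleavage time courses.

All randomness is seed-controlled and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .energies import EnergyModel
from .folding import SecondaryStructure, fold_mfe, hairpin_loops
from .sequences import ReactivityRecord, RnaSequence, TimeCourse

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DmsSimParams:
    """Poisson means for the three DMS channels.

    Defaults place exposed A/C (mean 50) and protected A/C (mean 3) far
    enough apart that the 0.2 normalization threshold separates the
    pairing states at nominal coverage.
    """

    lambda_exposed: float = 50.0
    lambda_protected: float = 3.0
    lambda_gu: float = 0.5
    coverage: int = 1000

    def __post_init__(self):
        if not self.lambda_exposed > self.lambda_protected >= self.lambda_gu >= 0:
            raise ValueError(
                "require lambda_exposed > lambda_protected >= lambda_gu >= 0"
            )


@dataclass(frozen=True)
class HairpinSpec:
    """Blueprint for a synthetic stem-loop.

    ``loop_sequence`` may contain N wildcards (filled randomly from A/C,
    which cannot pair with each other); ``motif_placement`` optionally
    overwrites part of the loop with a cleavage motif such as ``"UG|C"``
    whose bond lands on the given loop-bond ordinal.
    """

    stem_length: int
    loop_sequence: str
    flank_lengths: tuple[int, int] = (5, 5)
    motif_placement: Optional[tuple[str, int]] = None

    def __post_init__(self):
        if len(self.loop_sequence) < 3:
            raise ValueError("hairpin loop must be at least 3 nt")
        if self.stem_length < 4:
            raise ValueError("stem must be at least 4 bp")
        if self.motif_placement is not None:
            motif, ordinal = self.motif_placement
            up, _, down = motif.partition("|")
            if not (1 <= ordinal <= len(self.loop_sequence) - 1):
                raise ValueError("motif bond ordinal outside the loop's bonds")
            if ordinal - len(up) < 0 or ordinal + len(down) > len(self.loop_sequence):
                raise ValueError("motif does not fit in the loop at that ordinal")


class HairpinRejectionError(RuntimeError):
    """The MFE fold refused the intended stem-loop within the attempt budget."""


def _resolve_loop(spec: HairpinSpec, rng: np.random.Generator) -> str:
    loop = list(spec.loop_sequence.upper())
    if spec.motif_placement is not None:
        motif, ordinal = spec.motif_placement
        up, _, down = motif.partition("|")
        pattern = up + down
        start = ordinal - len(up)  # 0-based index into the loop
        for k, base in enumerate(pattern):
            loop[start + k] = base
    return "".join(
        rng.choice(("A", "C")) if b == "N" else b for b in loop
    )


def make_hairpin(
    spec: HairpinSpec,
    seed: int,
    model: Optional[EnergyModel] = None,
    max_attempts: int = 100,
) -> tuple[RnaSequence, SecondaryStructure]:
    """Random flanks + perfectly complementary stem + the given loop.

    Rejection-samples stem and flank sequences until the MFE fold of the
    full sequence contains the intended hairpin loop with every intended
    stem pair formed; the returned structure is that verified MFE fold.
    """
    rng = np.random.default_rng(seed)
    f5, f3 = spec.flank_lengths
    s = spec.stem_length
    for attempt in range(max_attempts):
        loop = _resolve_loop(spec, rng)
        # GC-biased stems fold robustly; flanks avoid G to stay unstructured
        stem5 = "".join(rng.choice(["G", "C", "A", "U"], p=[0.4, 0.4, 0.1, 0.1], size=s))
        flank5 = "".join(rng.choice(["A", "C", "U"], p=[0.5, 0.3, 0.2], size=f5))
        flank3 = "".join(rng.choice(["A", "C", "U"], p=[0.5, 0.3, 0.2], size=f3))
        residues = flank5 + stem5 + loop + reverse_complement(stem5) + flank3
        seq = RnaSequence(f"hairpin-{seed}-{attempt}", residues)
        structure = fold_mfe(seq, model=model)
        closing = (f5 + s, f5 + s + len(loop) + 1)
        intended_loop_ok = any(
            lp.closing_pair == closing for lp in hairpin_loops(structure)
        )
        stem_ok = all(
            structure.partner(f5 + k) == f5 + 2 * s + len(loop) + 1 - k
            for k in range(1, s + 1)
        )
        if intended_loop_ok and stem_ok:
            return seq, structure
    raise HairpinRejectionError(
        f"no accepted hairpin in {max_attempts} attempts; try a longer stem"
    )


def simulate_dms(
    seq: RnaSequence,
    structure: SecondaryStructure,
    params: DmsSimParams = DmsSimParams(),
    seed: int = 0,
) -> list[ReactivityRecord]:
    """Per-base Poisson RT-stop counts reflecting the true pairing state.

    Raw signal is the count divided by nominal coverage; normalization
    downstream is scale-invariant so the divisor is cosmetic.
    """
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, len(seq) + 1):
        base = seq.base(i)
        if base in ("G", "U"):
            lam = params.lambda_gu
        elif structure.is_paired(i):
            lam = params.lambda_protected
        else:
            lam = params.lambda_exposed
        count = int(rng.poisson(lam))
        records.append(
            ReactivityRecord(position=i, base=base, raw_signal=count / params.coverage)
        )
    return records


def simulate_timecourse(
    k: float,
    times: Sequence[float],
    sigma: float,
    seed: int = 0,
) -> TimeCourse:
    """Noisy one-phase decay: f = clamp(1 - exp(-k t) + eps, 0, 1).

    ``eps`` is additive Gaussian noise of SD ``sigma`` (gel densitometry
    noise is approximately additive on the fraction scale).
    """
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = 1.0 - np.exp(-k * t)
    noisy = np.clip(clean + rng.normal(0.0, sigma, size=t.shape), 0.0, 1.0)
    return TimeCourse(times=t, fractions=noisy)


__all__ = [
    "DmsSimParams",
    "HairpinSpec",
    "HairpinRejectionError",
    "make_hairpin",
    "simulate_dms",
    "simulate_timecourse",
    "reverse_complement",
]
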