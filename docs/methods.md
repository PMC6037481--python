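# Methods

## Secondary-structure model

`ire1kit.folding.fold_mfe` is a Zuker-style minimum-free-energy dynamic
program over nested structures with Watson–Crick (AU, UA, GC, CG) and
wobble (GU, UG) pairs and a minimum hairpin loop of 3 unpaired nt (the
standard steric bound). The free-energy decomposition has one term per
loop:

* **Hairpin**: length-dependent initiation, tabulated for 3–30 nt and
  extrapolated as ΔG(n) = ΔG(30) + 1.75·RT·ln(n/30) beyond.
* **Stack / bulge / internal**: tabulated stack free energies for every
  ordered pair-on-pair combination (Xia-style Watson–Crick values,
  representative wobble values); bulge and internal loops pay a
  length-dependent initiation only.
* **Multibranch**: affine penalty a + b·(branches) + c·(unpaired), with
  (a, b, c) = (3.4, 0.4, 0.0) kcal/mol.
* **Closure penalty**: +0.5 kcal/mol for each AU/UA/GU/UG pair closing a
  hairpin, bulge or internal loop.

Parameters live in `ire1kit.energies` as a versioned table
(`ire1kit-nn-1`, 37 °C) and can be exported/loaded as JSON.

**Deliberate omissions**: dangling ends, coaxial stacking, tetraloop
bonuses, sequence-dependent 1×1/2×2 internal-loop terms, and the
stacking term usually carried across a 1-nt bulge. Absolute energies
therefore differ from mfold/ViennaRNA output. The quantity this model is
asked to reproduce is **loop geometry** — which pairs form and hence the
hairpin-loop sizes — not printed ΔG values. Loop penalties are essential
even for that: pure pair maximization provably over-pairs real
substrate hairpins (it buries an extra bulged pair inside the XBP1
7-loop, shrinking it), which is why the Nussinov mode
(`fold_maxpair`) exists only as a cross-check oracle for the DP
machinery and never in the analysis path. On the four bundled reference
hairpins the model's pair tables coincide with ViennaRNA 2.7 defaults
(asserted in the test suite when `RNAfold` is on PATH).

Interior two-loops are capped at 30 unpaired nt inside the DP (standard
practice); the energy-recomputation routine (`structure_energy`)
handles arbitrary sizes, and the suite asserts it reproduces the DP's
reported energy exactly on random sequences.

**Determinism and tie-breaks.** Among co-optimal branches the traceback
prefers the alternative that adds a base pair (interior loop, then
multibranch, then hairpin) and, within a branch, the smallest 5′ index.
Two invocations on identical input give identical pair tables.

**Constraints.** A forced-single-stranded position is excluded from
every pair (hard constraint, mirroring mfold's force-unpaired
annotation). Constrained MFE energy is therefore never below the
unconstrained one — property-tested.

**Degenerate inputs**: sequences shorter than 5 nt return the
all-unpaired structure at energy 0; sequences above 2000 nt are
rejected (O(n³) DP in pure Python; practical inputs here are ≤100 nt
windows).

## DMS reactivity

DMS methylates solvent-exposed unpaired A and C; G/U carry no signal.
Within the 38-nt window centred on a scissile bond (19 nt up/downstream,
clipped with a warning at transcript ends, hard error below 10 nt) the
most reactive base is set to 1 and the rest scaled proportionally.
A/C positions with normalized signal **strictly greater than 0.2**
become folding constraints; G/U are never constrained regardless of
signal. Both the threshold and the half-width are configuration
parameters with those defaults. Any non-negative per-base score works as
the raw signal, since max-normalization is scale-invariant
(property-tested).

## Cleavage-site rules

A scissile bond is indexed by the nucleotide 5′ of the cut. For a
hairpin loop of L nt, a bond between two loop positions has an ordinal
b ∈ {1, …, L−1} and an offset |b − L/2| in bond units.

* **S. cerevisiae**: motif `CNG|CNGN` or `CNG|ANGN`, loop exactly 7 nt,
  bond ordinal 3 — equivalently, the consensus occupies the whole loop.
* **S. pombe**: motif `UG|C`, loop 3–9 nt, offset ≤ 1 bond.

Design choices where the biology is underdetermined: "near the centre"
is formalized as offset ≤ 1 because every verifiable substrate
(XBP1 7-loop, SPAC4G9.15 3-loop, BIP1 9-loop) sits at offset 0.5; the
S. pombe loop ceiling of 9 nt is the largest observed size and is
config-exposed rather than hard-coded; wobble-closed loops count as
loops (the HAC1 3′ splice-site loop requires a U·G closing pair); and a
substrate call requires **both** bond-flanking nucleotides unpaired in
the same hairpin loop — the strictest reading of loop placement, since
tolerance of partially stem-buried motifs has not been characterized.

`mutate_to_motif` repairs a failing site with the fewest point
substitutions; among motif alternatives the first listed wins ties, and
within a motif the edit set is fixed by the mismatching literal
positions (5′-first by construction).

## Kinetics

`fit_kobs` fits f(t) = 1 − e^(−kt) by nonlinear least squares with the
plateau fixed at 1 (complete cleavage); a floating-plateau variant is
available for robustness studies but is not the default. When the
maximum observed cleaved fraction is below 10 % the substrate
concentration is effectively constant and a through-origin linear fit
f = kt is used instead — the two branches agree within 5 % in the
small-kt limit (tested). The nonlinear fit is initialized from a linear
fit of the first half of the course, removing initialization
sensitivity. The reported uncertainty is the standard error of the fit
(square root of the covariance diagonal); published "±" values are
treated as this quantity, since fit-SE versus replicate-SD is not
otherwise distinguishable.

## Synthetic-data generators

* **Hairpins** (`make_hairpin`): random flanks (A/C/U, unstructured by
  composition) + a perfectly complementary GC-biased stem + a given
  loop, optionally with a cleavage motif implanted at a chosen loop
  bond; N wildcards fill from {A, C}, which cannot pair with each
  other. The candidate is accepted only if the MFE fold of the full
  sequence reproduces the intended loop and every stem pair (≤100
  attempts, then a hard error advising a longer stem). The returned
  "truth" structure is that verified MFE fold.
* **DMS counts** (`simulate_dms`): per-base Poisson counts with three
  channels — exposed A/C (mean 50), paired A/C (mean 3), G/U background
  (mean 0.5) at nominal coverage 1000. The three-channel Poisson is the
  simplest generative model matching the qualitative exposed/protected
  contrast DMS provides, with means far enough apart that the 0.2
  threshold separates pairing states at default coverage.
* **Time courses** (`simulate_timecourse`): f = clamp(1 − e^(−kt) + ε,
  0, 1) with additive Gaussian ε (gel densitometry noise is
  approximately additive on the fraction scale).

All generators are reproducible byte-for-byte under a seed.

**What the generators do not emulate**: read-level artefacts (ligation
bias, RT drop-off gradients, coverage heterogeneity), protein
occlusion of unpaired bases, alternative/ensemble structure, and
correlated densitometry errors. Passing the recovery suites therefore
demonstrates the pipeline's internal consistency under the stated noise
model, not performance on real probing libraries.

**Problem sizes in the test and acceptance suites.** Recovery suites
use 100–200 generated hairpins per property, 500 simulated time
courses for the estimator bias/coverage check, and 20 seeded replicates
per published-rate recovery; the pair-maximization oracle is checked
against brute-force enumeration on 200 random sequences of up to 18 nt.
For the bias/coverage suite the time grid spans [0, 2/k] (8 points,
~86 % completion), emulating an experimenter matching assay duration to
the observed rate; with a fixed 1-h grid the slowest rates in the
k ∈ [10⁻⁵, 5·10⁻³] s⁻¹ range would sit entirely inside the noise floor,
where the clamp at 0 truncates the noise distribution and the suite
would measure that truncation rather than the estimator.

## Splicing cassettes

The cassette layout is two stem-loop junctions straddling the
exon/intron boundaries: each junction is an 8-bp GC-rich stem with the
7-nt loop `CAUGCAG`, whose `UG|C` bond (between loop positions 4 and 5,
offset 0.5) falls exactly on the boundary, so the excised segment equals
the 30-nt intron field — the pruned-intron length. The default cassette
sequence is a design artifact of this package, produced and validated by
its own folding + classification modules; only the 30-nt intron length
and the S. pombe-optimized junction requirement are externally given.
Validation folds each junction's 38-nt window **in the engineered host
context** and requires a substrate verdict at both bonds; failures are
returned as reasons, not exceptions, because designs are iterated.
Host 3′UTR annotation is a simple (start, end) interval; no feature-file
parsing in this version.

## Known limitations

* The energy model's absolute ΔG values are not comparable to
  mfold/ViennaRNA; only structures are.
* No partition-function / suboptimal-ensemble folding, no pseudoknots,
  no temperature dependence beyond the fixed 37 °C table.
* The classifier is binary; it does not predict quantitative cleavage
  rates from sequence, and oligomerization/docking effects on substrate
  choice in vivo are out of scope.
* Windowed validation (38 nt) cannot see long-range pairing into the
  rest of the transcript; an insertion context with distal
  complementarity could fold differently at full length.
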