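# Methods

This note records the models implemented in `pepevo`, the defaults that
matter, the design decisions taken where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Sequence model

Families are fixed-length, ungapped alignments of scaffold-conformant
peptides. A scaffold pins immutable positions (for a bicyclic peptide: the
three cysteines that react with the trivalent linker, plus terminal
residues) and leaves the loop positions variable. Gaps are not supported:
the families this tool targets are equal-length by construction, and a gap
symbol is treated as an input error. Positions are 1-based everywhere a
user sees them, matching how peptide variants are discussed ("Pro in
position 15"); arrays are 0-based internally.

Logo column heights are information content in bits, IC = log₂ q − H, with
no small-sample correction by default: at n ≈ 30–60 the correction term
(q−1)/(2n ln 2) ≈ 0.2–0.5 bits would dominate genuine signal. It can be
switched on.

## Potts model and pseudolikelihood fit

The score S(σ) = Σ h + Σ J is fitted by minimizing the weighted negative
log pseudolikelihood

L(h, J) = (1/Meff) Σₘ wₘ Σᵣ −log P(σₘᵣ | σₘ,∖ᵣ) + λ_h‖h‖² + λ_J‖J‖²,

with P(σᵣ | σ∖ᵣ) the softmax of h_r(·) + Σ_{j≠r} J_rj(·, σ_j). Conditional
normalizers use max-shifted log-sum-exp. The gradient is analytic (the
usual softmax-minus-indicator form; each coupling block accumulates terms
from both conditionals it appears in) and is verified against central
finite differences in the tests to better than 1e-5 relative error.

Decisions:

- **Joint (symmetric) pseudolikelihood with one shared J**, not the
  asymmetric per-site variant with post-hoc averaging. One coherent tensor
  is needed as the Monte Carlo energy, and at n of a few dozen the speed
  argument for asymmetric fitting is irrelevant.
- **λ_h = λ_J = 0.01** per parameter on the Meff-normalized objective —
  conventional magnitudes; in the small-n regime the penalty is what makes
  couplings identifiable at all.
- **Optimizer**: L-BFGS-B from the zero model, gradient max-norm tolerance
  1e-5, max 500 iterations. Deterministic given data and configuration;
  non-convergence returns the best-so-far model flagged in its metadata
  rather than raising.
- **Reweighting off by default** (threshold 0.8 when enabled). Curated
  display-selected families are intentionally similar; silently collapsing
  Meff would surprise users. The choice is logged.
- **Fixed scaffold positions are ordinary columns during fitting**; their
  fields absorb perfect conservation and, in the zero-sum gauge, perfectly
  conserved columns carry no coupling signal. They are constrained only at
  sampling time.

Couplings are reported in the zero-sum gauge (block row/column sums zero,
means absorbed into fields, fields centred); score differences are
preserved exactly, so sampling and ranking are gauge-independent. Pair
ranking uses the Frobenius norm with the average-product correction
F_ij − F_i·F_·j / F_·· (off-diagonal means), ties broken lexicographically.

## Metropolis sampler

Single-site proposals: uniform over variable positions × the q−1 other
residues (symmetric), accepted with min(1, exp(ΔS/T)). ΔS is computed
incrementally in O(L); recorded scores are exact to 1e-9 of a full rescore
over 10⁴ chained steps. Defaults: T = 1 (the score used as-is), 50 chains ×
2000 steps, burn-in 500, thinning 10 — sized so a desk run records on the
order of 10⁴ states, the scale of the published campaigns, whose exact
counts depend on unreported run lengths and are treated as scale indicators
only. Chain c is seeded with `default_rng((seed + c) mod 2³¹)` and proposal
randomness is drawn in fixed 1024-step blocks, so pools are
bitwise-reproducible within this implementation; a port using a different
generator can only match distributionally. Pools are deduplicated keeping
first occurrence, with visit counts retained so the empirical distribution
remains recoverable.

## Affinity regression and selection

The target is log₁₀(Ki / 1 nM): families span 250–750-fold Ki ranges, so an
untransformed target would be dominated by the weakest binders. Features
are a one-hot block over variable positions plus whole-sequence descriptors
(Kyte–Doolittle mean hydropathy, net charge at pH 7.4 with D/E = −1,
K/R = +1, H = 0, molecular weight, and residue-class counts) from a
versioned table shipped as package data. The descriptor set is this
package's documented surrogate for unpublished feature tables used
elsewhere; it is deliberately simple and additive. The learner is
scikit-learn's RandomForestRegressor (100 trees, fixed seed, single
thread); the bespoke surface is the featurization, the transform, the
cross-validation report (k = min(5, n) shuffled folds, RMSE in log units)
and the percentile filter.

Selection keeps sequences predicted **strictly below** the configured
percentile (default 50) of a reference distribution. The reference is
configurable — generated-pool predictions (default) or training
measurements — because a median-based filter that retains far less than
half of a pool implies an ambiguous reference set; both options are
implemented and logged.

## Generation rounds and leave-out validation

A round = fit plmDCA → sample a novel pool (training sequences excluded) →
predict Ki → threshold → select → logo → candidates. A single master seed
derives stage seeds as (master × 7919 + offset) mod 2³¹; rounds are
reproducible bit for bit and hash their manifests. Iterative campaigns are
repeated calls on an augmented record table — no special second-round path.

`suggest_holdouts` picks validation members with Ki strictly below the
family median, excluding the single most potent record, capped at
⌊max_fraction·n⌋ (default 5%), returning the most potent eligible ones.
This mirrors holding out good-but-not-best binders: the validation should
neither hand the pipeline its best answer nor an uninformative weak binder.

`design_candidates` implements only the reproducible frequency rule:
consensus first, then binary branching at positions whose runner-up
frequency is at least `runner_up_fraction` (default 0.5) of the top
frequency, positions expanded in descending runner-up-ratio order, capped
at `max_candidates` (default 8). Frequency ties break toward the
alphabetically earlier residue. Expert structural curation of candidates is
deliberately out of scope; the runner-up ratios are surfaced so a human can
reproduce that step.

## Synthetic ground truth

The synthetic module exists so every stage has an oracle without external
data:

- **Planted Potts models**: Gaussian background fields/couplings, one
  boosted residue per conserved position, one boosted (a, b) entry per
  planted pair. Planted structure involves variable positions only.
- **Exact enumeration** of P(σ) = exp(S)/Z for state spaces up to 10⁶,
  the Boltzmann oracle for the sampler (TV ≤ 0.02 at 10⁵ recorded states on
  the L = 4, q = 4 model).
- **Log-Ki landscapes**: additive per-(position, residue) effects plus
  sparse pair effects; observation noise (default sd 0.15 log₁₀ units) is
  applied only at observation time. The intercept is calibrated so the
  median random-sequence Ki is ~100 nM and the central 95% spans ≥ 250-fold,
  the range reported for real families. A landscape can be *aligned* with a
  planted model (favorable contributions on its conserved residues and
  planted pairs) because display-selected binders entangle sequence
  statistics with affinity; the tests should reflect that coupling.

Benchmark scales, chosen on detectability grounds and then frozen:

- **Coupling recovery** (L = 10, q = 8, 2 conserved, 5 planted pairs,
  n = 2000, fixed seed): background coupling sd 0.2 with the 10× boost
  (2.0). The boosted entry must clear the estimation-noise floor of
  pseudolikelihood coupling norms at n = 2000; with a much weaker
  background the single planted entry is statistically invisible to any
  correct fitter, and the benchmark would test luck, not correctness.
- **Pipeline family** (50 unique 10-mers on a mini-bicyclic scaffold with
  four pinned positions): background field sd 4.0, so members sit within
  ~3 mutations of the consensus. This matches what published campaign
  numbers imply about real family concentration — a ~50-sequence family
  whose MC resampling yields only hundreds to a few thousand unique
  sequences occupies an effective design space of order 10²–10³. The
  benchmark round samples 100 chains × 3000 steps (≈ 5 × 10⁴ recorded,
  ~6–7 × 10³ unique), the published order of magnitude.

With these conditions the leave-out validation — remove two known binders,
rerun the round, check both reappear in the selected pool — succeeds in
10/10 independently seeded rounds.

## What the synthetic benchmarks do not show

The landscapes are additive-plus-sparse-pairs with lognormal noise; real
structure–activity landscapes contain higher-order epistasis, and real
assay error is not homoscedastic in log space. The planted families are
drawn from the same model class the fitter assumes, so recovery results
demonstrate correctness of the estimation machinery, not robustness to
model misspecification. Passing tests therefore certify the pipeline's
internal consistency and its behaviour under the stated family
concentration and signal scales — not wet-lab potency of designed peptides,
which in the motivating campaigns required expert curation and synthesis.

## Degenerate inputs and numerical notes

Empty novel pools or empty selections produce warnings and empty results,
not exceptions, so campaign loops can continue. A held-out sequence
identical to a remaining training sequence is flagged as a degenerate
(trivially regenerated) case. Constant-Ki targets warn and return a
constant predictor. Percentiles use linear interpolation (pct = 50 is the
median); the selection inequality is strict, so at the median an n-element
pool keeps ⌊n/2⌋ elements (distinct values). All Ki values are stored in
molar; table I/O requires an explicit unit.
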