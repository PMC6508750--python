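# Methods

## Model and assumptions

A single cell carries one gene of interest. The division cycle is split at
the instant that gene is replicated into an early stage S1 (one template
copy) and a late stage S2 (two copies, transcribed independently with their
own telegraph kinetics). The model's assumptions:

1. Stage durations T1 and T2 are independent and exponential with rates
   κ₁, κ₂ > 0, so the stage process is a two-state Markov chain. The
   stationary stage occupancies are κ₂/(κ₁+κ₂) and κ₁/(κ₁+κ₂); these are
   also the mixture weights of the population mean and second moment.
2. Transcription restarts in the OFF state at every stage entry (gene
   duplication and division both reset the promoter), reflecting the
   displacement of polymerases during replication and chromatin
   condensation during mitosis.
3. In S1 the single copy follows telegraph kinetics (λ₁, γ₁, ν₁, δ₁); in
   S2 the two copies switch and transcribe independently with (λ₂, γ₂,
   ν₂, δ₂). The active-copy count I is 0–1 in S1 and 0–2 in S2, giving the
   copy-number multiplicities 2λ₂ (0→1 active) and 2γ₂ (2→1 active).
4. Gene duplication itself is instantaneous. The per-gene replication time
   implied by genome size, gene count and fork speed (seconds; see
   `mean_gene_duplication_time`) is negligible against stage durations.
5. At division each transcript is retained by the followed daughter with
   probability 1/2, independently — a single Binomial(M, 1/2) draw.

All rates are canonically per hour; per-minute inputs are converted by an
exact factor of 60 at the configuration boundary. Rates printed in the
literature as 4-digit decimals are accepted verbatim rather than re-derived
from durations, so worked numbers are reproducible to the digit.

## Closed forms and how they are validated

The stationary stage-conditioned means, second moments, Fano factors,
noises and the fold change r\* = m₂\*/m₁\* are evaluated literally as
derived from the moment equations, with no algebraic re-simplification.
This keeps every term traceable and makes the expressions directly
comparable against the two independent numerical routes:

* **Finite-state-projection oracle** (`cyctx.fsp`): the truncated master
  equation on {S1: (i, m), i ≤ 1} ∪ {S2: (i, m), i ≤ 2}, m ≤ N, including
  the dense lower-triangular binomial division kernel B[m, n] = C(n, m)2⁻ⁿ.
  Moments come from summation over the distribution only. Truncation is
  sized from the closed-form mean and standard deviation (mean + 10 sd
  placed below the 0.9 N tail cut) — a sizing hint that cannot bias the
  oracle's values. Mass loss and upper-tail mass above `tail_tol = 1e-8`
  raise an error with a resize recommendation. The stationary solve uses a
  direct sparse nullspace solve (one balance row replaced by the
  normalization; residual-checked) and falls back to long-time
  `expm_multiply` integration if that misbehaves; both methods are exposed
  and tested against each other.
* **Exact lineage simulation** (`cyctx.ssa`): Gillespie steps with the
  stage-dependent propensities, binomial thinning at division, following
  one daughter per division. Stationary stage-conditioned moments are
  time averages after a burn-in (default 20 completed cycles), with
  standard errors from batch means over completed cycles (default 20
  batches). Ergodicity of the lineage process — time averages equal the
  stationary mixture values whose weights are the stage occupancies — is
  an assumption of this estimator; the test suite verifies it empirically
  against the closed forms on parameter sets spanning slow and fast
  cycling. The inner loop is numba-compiled; a fixed seed reproduces the
  trajectory exactly.

The moment dynamics from the synchronized start (all cells at the start of
S1, promoter OFF, zero counts) form one 14-dimensional constant-coefficient
linear cascade: 5 stage-promoter occupancies, 2 stage first moments, 5
promoter-resolved first moments, 2 stage second moments. It is propagated
with matrix exponentials per grid interval — exact for linear systems, so
no integrator tolerance enters the comparisons. Stage-conditioned moments
are ratios mᵢ = nᵢ/Pᵢ; at t = 0 the S2 conditionals are reported as NaN
because P₂(0) = 0.

## Tunable parameters that matter

| parameter | meaning | unit | typical values used here |
|---|---|---|---|
| λᵢ | promoter activation (burst frequency) | h⁻¹ | 0.35–0.56 (mouse ES cells) |
| γᵢ | promoter inactivation | h⁻¹ | ~1.07 |
| νᵢ | synthesis per active copy | h⁻¹ | 113.4 (= 1.89 min⁻¹) |
| δᵢ | mRNA degradation | h⁻¹ | 0.14 (stable) to 17.14 (nascent) |
| κ₁, κ₂ | stage transition rates | h⁻¹ | 60/560, 60/220 (mouse ES cells) |
| N | master-equation truncation | counts | mean + 10 sd (auto) |
| burn-in | discarded initial cycles (SSA) | cycles | 20 |

The burst size is ν/γ; the mean ON fraction per copy is λ/(λ+γ).

## Homeostasis machinery

Transcription homeostasis (m₁\* = m₂\*) through a single compensating rate
has closed-form solutions: the S2 synthesis rate scales proportionally
(ν₂ → ν₁/2 in the slow-cycling limit), while degradation, activation and
inactivation compensate affinely (δ₂ → 2δ₁, γ₂ → 2γ₁ + λ in the limit).
The inactivation channel can be infeasible for fast S2 transitions and then
raises an explicit error. The signed homeostasis residual
ν₁λ₁δ₂(λ₂+γ₂+κ₂) − ν₂λ₂(2δ₁+κ₁)(λ₁+γ₁+κ₁) was re-derived from the
stationary means during implementation; it is negative exactly when
r\* > 1 (the common regime), zero iff m₁\* = m₂\*.

The volume model assumes exponential single-cell growth V(t) = exp(at)
with exact doubling over one cycle; solving E[V(T1+T2)] = 2 under the
hypoexponential cycle-length distribution fixes a and gives the volume
fold change r_v = κ₂/(κ₂ − a) ∈ (1, 2), increasing in κ₁ (a shorter S1
places more of the doubling growth inside S2). The κ₁ = κ₂ case of the
cycle-length CDF uses the analytic Erlang-2 limit, switched on below a
relative rate difference of 1e-9 to avoid catastrophic cancellation.

Concentration homeostasis r\* = r_v is solved for one free S2 rate by a
200-point log-spaced scan over [1e-6, 1e3] h⁻¹ followed by Brent's method.
Monotonicity of r\* in a single rate is plausible but not proven, so
multiple sign changes raise an explicit ambiguity error listing all roots
rather than returning one silently. The homeostasis-vs-noise comparison
sweeps an S2/S1 rate ratio (default 0.1–10), locating the homeostasis
point H by root-finding on the residual and the noise minimum Z by
golden-section refinement of the population noise η²\* on a log grid.

## Prescribed fold change

Under shared kinetics, r\* depends only on s = λ+γ, δ, κ₁, κ₂. For a
target C ≤ 1 an explicit witness exists (s = κ₁, κ₂ = 4κ₁/C,
δ = (16−12C−2C³)κ₁/C³) and is exact. For C > 1 the constructor fixes
(s, δ) within a small family of scalings of κ₁ and solves r\*(κ₂) = C by
bracketing + Brent; the family δ = κ₁ alone caps r\* below 8/3, so larger
δ/κ₁ and smaller s/κ₁ scalings are included, covering all practically
requested targets. Threshold flags for r\* > 2 and r\* < 1 are evaluated
from the exact inequalities in (s, δ, κ₁, κ₂) and cross-checked against
the sign of r\* − 2 and r\* − 1 on grids.

## Numerical choices

* Double precision throughout; no symbolic or arbitrary-precision paths.
* Root finding: Brent with rtol 1e-15; reported homeostasis solutions
  reproduce r\* = r_v to ~1e-10 relative when substituted back.
* FSP generator columns sum to zero except for the synthesis flux out of
  m = N (the truncation sink) — asserted in tests.
* SSA uses one binomial draw per division, not per-molecule Bernoulli
  loops (distributionally identical, much faster).
* Scan tables are pure functions of their spec; CSV floats are written at
  10 significant digits so re-runs are byte-identical.

## Problem sizes used in the tests

Cross-validation parameter sets are chosen at moderate stationary means
(≈ 1–30 transcripts) so the truncated state space stays at a few hundred
to a few thousand states and the full suite runs in well under a minute of
oracle time. The slow-cycling simulation check (mean ≈ 280–550 transcripts,
1/κ = 1250 h) runs ~55 cycles (~1.4×10⁵ h of simulated time, ~10⁷ events)
— enough for a 3-SE Fano-factor comparison. The baseline simulation
agreement check uses ≥ 200 completed cycles. Monte-Carlo volume checks use
10⁶ samples.

## What the tests do and do not show

The package generates its own study conditions: published kinetic-rate
sets are inputs, and the synthetic ingredients are the model itself (the
simulator and the oracle share the model's assumptions). Passing
cross-validation therefore demonstrates internal correctness — the closed
forms, the ODE cascade, the master equation and the simulator are mutually
consistent implementations of the same stochastic process — not that the
model describes any particular gene. Features of real data that the model
deliberately omits: non-exponential stage durations, cell-to-cell kinetic
variability, time-dependent or size-dependent rates within a stage,
mother–daughter correlations beyond the followed lineage, and
protein-level dynamics.

## Known limitations

* Means ≫ 10³ make the FSP oracle impractical (state space ~5N); use the
  closed forms and the simulator there.
* The lineage simulator deliberately tracks one cell, not a branching
  population; population-snapshot statistics that weight lineages by
  progeny number are out of scope.
* The constitutive limit (λ → ∞) is a separate closed form, not an
  infinite rate in the parameter containers, keeping validation simple.
* Figure-level claims about parameter maps are approximate by nature: over
  duration grids the population mean is monotone in the S2 duration and
  along the duration diagonal but can dip by a few percent as the S1
  duration alone grows, and the fold change under shared kinetics can
  leave [1, 2] slightly at extreme duration asymmetries. The tests assert
  these verified quantitative versions.
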