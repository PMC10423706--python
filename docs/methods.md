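# Methods

## The stochastic model

PCR is treated as a discrete-time, two-type branching process on strand
counts **U**ᵢ = (Xᵢ, Yᵢ). During cycle *i* each of the Y_{i−1} reverse
strands templates a new forward strand with probability p_rf = p̄R, and
each of the X_{i−1} forward strands templates a new reverse strand with
probability p_fr = p̄/R; all Bernoulli trials are independent, both draws
condition on the cycle i−1 counts (synchronous update), and no strand is
ever destroyed. The parameterization (p̄, R) — geometric mean and square
root of the ratio of the directional efficiencies — is used throughout
because p̄ is what standard-curve analyses estimate as "the" efficiency,
while R isolates directional asymmetry; R = 1 collapses the model to the
classical single-type process on N = X + Y.

Input handling distinguishes double-stranded DNA (Case D: X₀, Y₀ i.i.d.
copies of the input count I) from single-stranded RNA (Cases RF/RR), where
a reverse-transcription step thins I binomially with efficiency r and
populates only the complementary cDNA strand. X₀ ⟂ Y₀ holds in every case,
so the initial covariance matrix is diagonal; for RNA input the law of
total variance gives Var[U₀] on the cDNA strand as r²Var[I] + r(1−r)E[I].

### Moments

Means propagate by the matrix A = [[1, p̄R], [p̄/R, 1]], whose spectral
decomposition is evaluated from its closed form (x₁,₂ = (R, ±1)/√2,
z₁,₂ = (1, ±R)/(R√2), λ₁,₂ = 1 ± p̄) rather than a generic eigensolver, so
signs and scaling are deterministic. Covariance matrices satisfy the
recursion Var[Uᵢ] = A Var[U_{i−1}] Aᵀ + Σ_ℓ λ_ℓ^{i−1} K_ℓ, where the K_ℓ
collect the binomial reproduction variances resolved onto the eigenbasis.
The package ships the geometric-series closed form of this recursion
(coefficients ν_{jk} = z_jᵀVar[U₀]z_k and
η^ℓ_{jk} = z_jᵀK_ℓz_k/(λ_jλ_k − λ_ℓ)); the raw recursion is implemented
only in the test suite, as an independent oracle. The cross-covariance
Cov[Xᵢ, X₀] = (Var[X₀]/2)(λ₁ⁱ + λ₂ⁱ) closes the system needed for
background-subtracted fluorescence.

Numerical notes. All moments are double precision; cycle counts above 500
are rejected (λ₁^{2i} would overflow). The η denominators cannot vanish
for p̄ ∈ (0, 1); the boundary p̄ = 1 (perfect amplification, accepted as
the natural doubling limit) zeroes the corresponding numerators exactly,
and the implementation defines η = 0 there. Each covariance matrix is
symmetrized after evaluation (guards ~1e−16 asymmetry) and the cycle-0
slice is set to Var[U₀] exactly. Moments for cycles 0..n are computed in
one vectorized pass and cached in a `MomentTrajectory`.

### Simulator

The Monte-Carlo simulator draws the exact model (integer Poisson /
negative-binomial / fixed input; Bernoulli-thinned RT step; per-cycle
binomial updates), not an approximation. The negative binomial is
parameterized by mean m and variance χm (size m/(χ−1), success probability
1/χ). One `SeedSequence` per run spawns sub-streams for input, RT and
cycling, so partial reruns agree bit for bit. Full replicate × cycle
trajectories are kept in memory (≈50 MB at 2×10⁵ replicates × 16 cycles).
Sample moments use unbiased estimators; standard errors for variances and
covariances use fourth-central-moment formulas, which is what makes
"within 4 SE" comparisons against the analytic moments well calibrated.

## Fluorescence

Fluorescence is the Beer's-law analog F = f⁻C⁻ + f⁺C⁺ over inactive and
active probe species. For a hydrolysis probe bound to the reverse strand,
one probe is activated per forward strand synthesized, giving
F_{i,w} = b_{i,w} + d_{i,w}ΔXᵢ with b = f⁻C and d = (f⁺ − f⁻)/(V·N_A).
A configuration switch (`mode="annealing"`) supports probes that fluoresce
while annealed to the forward strand, which report X_{i−1} instead of ΔXᵢ;
the default is hydrolysis chemistry, and the probe orientation can be
mirrored by exchanging the roles of the strands in the input case.

Molar fluorescences f±(i, w) are estimated from template-free control
plates at q known concentrations by least squares through the origin,
f = ΣⱼFʲCʲ/Σⱼ(Cʲ)², with dispersion σ = ‖F − fC‖/√(q−1). With a single
plate the estimate degenerates to pointwise division and σ is reported as
missing (NaN), not zero. A QC summary flags σ/f above a configurable
threshold (default 0.022, the level above which well-specific artifacts
dominated control data in our experience with this model class).

Units are mol/L, litres, fluorescence·L/mol and fluorescence/molecule;
converters are provided for the pmol/L and µL values typical of assay
sheets (working point C = 0.125 pmol/L, V = 20 µL, at which b ≈ 1 and
d ≈ 1e−6).

## Limit of detection

Detection after n cycles requires E[F] − κ√Var[F] ≥ b, which reduces to
the well-independent criterion CV[ΔXₙ] ≤ 1/κ because d > 0 cancels. At
n in the usual 35–50 range, CV[ΔXₙ]² is indistinguishable from its
asymptote αCV[I]² + β/E[I] (the difference decays as λ₁⁻ⁱ), so with
Var[I] = χE[I] the criterion rearranges to E[I] ≥ (χα + β)κ², and
L = min{y ∈ ℕ₊ : y ≥ (χα + β)κ²}. Conventions: ℕ₊ excludes 0 (an expected
input of zero copies is never detectable, so κ → 0 gives L = 1); the
inequality is non-strict, so an exactly integral threshold is itself the
limit; an input with zero expected signal (E[ΔXₙ] = 0) is infeasible by
definition even though the κ-sigma inequality is vacuously satisfied at
zero variance. The grid scan evaluates the asymptotic criterion
(vectorized, ~10⁶ points in well under a second); `feasibility_check`
exposes the finite-n inequality with exact moments separately. Summaries
pair min-L with max-M and max-L with min-M, and the full grid mapping is
retained.

## Synthetic data

The control-plate generator emulates the statistical structure the
calibration assumes: ground truth f±(i, w) = base × (1 + well effect) ×
trend(i), observed readings F = f·C·(1 + ε) with ε ~ N(0, noise_cv²).
Multiplicative (constant-CV) noise is used because the calibration model
treats F/C across plates as i.i.d. normal at fixed cycle and well. The
cycle trend is a low-order bump peaking near cycle 2–3 times a slow
exponential decay, emulating the early background maximum and
photobleaching seen in real instruments; it is a fixture shape, not a
scientific claim. Defaults: 96 wells, 45 cycles, 1 % noise, q = 4 active
and q = 3 inactive plates.

The concentration levels bracket the working point narrowly
((0.8, 1.0, 1.25, 1.6)× active; (0.8, 1.0, 1.25)× inactive). This is a
deliberate calibration-design choice: regression through the origin
weights each plate by C², so a wide dilution series concentrates leverage
in the top plate; and since d is the *difference* f⁺ − f⁻, its propagated
relative error is roughly twice that of either fit (≈√((1.66·cv⁺)² +
(0.66·cv⁻)²)). The narrow bracket keeps the propagated CV of d near 1 %,
so the 1 %-noise defaults support ~3 % parameter recovery.

The amplification-run generator draws one independent branching-process
trajectory per well and maps it through F = b + d·ΔX. What the generator
does **not** emulate: spatially correlated drift, optical crosstalk
between wells, cycle-to-cycle noise correlation, probe degradation, or
any instrument artifact beyond i.i.d. multiplicative noise. Tests passing
on these fixtures therefore validate the estimators and moment algebra
under the model's own assumptions; they do not certify behaviour on real
instrument data that violates them.

## Problem sizes and determinism

Default study sizes — 10⁶-point detection grids, 2×10⁵ simulation
replicates over ≤15 cycles, 96 × 45 control plates — run in seconds and
were chosen as the smallest sizes at which grid extremes are exact and
Monte-Carlo checks resolve 4-SE agreement. Every stochastic entry point
takes an explicit seed; identical seed and configuration reproduce outputs
bit for bit, and CLI runs record configuration, seed and package version
beside their outputs.

## Known limitations

* No inference of p̄, R, r or E[I] from measured amplification data — the
  package computes forward from known parameters.
* No moments beyond the second; detection rests on a κ-sigma normal
  criterion, not on calibrated false-positive/negative rates.
* DNA-binding–dye chemistry is out of scope (the stoichiometry differs);
  the cycle dependence of f± is data-driven, with no mechanistic
  photobleaching model.
* E[I] is treated as a nonnegative real (e.g. a Poisson mean); it need not
  be an integer.
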