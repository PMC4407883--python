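# Methods

## Model

The package implements a differential/integral hybrid description of
fiber-reinforced soft-tissue viscoelasticity. The Helmholtz free energy is
decoupled into an elastic part, a short-term viscous part driven by the
rate of the right Cauchy-Green tensor, and a long-term part carried by
internal variables that evolve in time:

    Ψ = Ψᵉ(C, N₀) + Ψₛᵛ(C, Ċ, N₀) + Ψₗᵛ(C, Γ, N₀)

The two viscous mechanisms are assumed decoupled by time scale: during
loading only the short-term term acts (Ψₗᵛ = 0), during relaxation only the
long-term term acts (Ψₛᵛ = 0, since Ċ = 0). This split is what lets a
single parameter set capture both high-rate loading stiffness and long
relaxation tails — the classical weakness of pure differential-type
(no relaxation) and pure integral-type/QLV (weak rate sensitivity) models.

Stresses follow as S = 2∂Ψ/∂C for the elastic part and Sᵛ = 2∂Ψᵛ/∂Ċ for
the short-term part; this convention reproduces the closed-form uniaxial
expressions used for data fitting exactly. All fiber terms carry an
(I₄ − 1) factor, so the tension–compression switch at I₄ = 1 is
stress-continuous (fibers buckle under compression and carry no load).
The ligament fiber *energy* retains the constant a₂/(2a₃) at I₄ = 1 — an
artifact of the exponential form that does not affect stress; it is noted,
not altered.

## Long-term evolution law: prony vs literal

The long-term stress is built from relaxation branches. Each transition
from loading to hold at time δ spawns a branch carrying the short-term
viscous stress S_δ at that instant. Two readings of the branch evolution
are implemented:

* **prony (default)**: Sₗᵛ(t) = S_δ Σᵢ wᵢ e^{−(t−δ)/τᵢ}, weights
  dimensionless with Σwᵢ = 1. This honors stress continuity at δ (the
  branch starts exactly at S_δ as the short-term term switches off), decays
  monotonically to zero, and returns the total stress to the elastic
  equilibrium — the behavior relaxation experiments show.
* **literal**: the closed-form antiderivative of the evolution equation
  with the weights read as rates (1/s),
  Sₗᵛ(t) = S_δ Σᵢ wᵢ τᵢ (1 − e^{−(t−δ)/τᵢ}), which *grows* toward
  Σwᵢτᵢ·S_δ. It is retained behind `mode="literal"` because the governing
  equations can be read this way; it is regression-tested so the mode
  distinction cannot silently vanish.

Published weight tables for these tissues print rounded values whose sums
are 0.997 and 0.9989; `RelaxationSpectrum.from_table` renormalizes them to
satisfy Σw = 1 exactly (the constraint imposed during the original
optimization) and sorts time constants ascending.

In multi-step protocols every loading→hold handoff spawns a new branch and
existing branches keep decaying through subsequent ramps (linear
superposition). The governing equations do not prescribe multi-step
bookkeeping; superposition is the minimal assumption consistent with the
single-step law.

## Numerics

* **Simulation is closed-form.** For piecewise-linear stretch histories all
  three stress components are algebraic in time (the prony branch sum
  included), so the simulator's sampling grid controls output resolution
  only, never accuracy. The default step resolves both the fastest ramp
  (≥50 samples) and the fastest time constant (τ_min/20); very long holds
  switch to a hybrid linear+geometric grid (cap 600 points) so early
  relaxation is resolved without millions of samples. A sample falling
  exactly on a ramp→hold boundary is attributed to the ramp; the total is
  continuous there either way.
* **QLV integration** uses an exponential recurrence for the hereditary
  integrals: the kernel is treated exactly per step (unconditionally stable
  for τ spreads of 3.77 s to ~11000 s) and the elastic stress is taken
  piecewise linear within a step, for which the update is exact. Against
  smooth integrands the scheme is second-order accurate (observed error
  ratios ≈4 per step halving). Small-exponent branches of the φ-functions
  use series expansions to avoid cancellation.
* **Tangents** (∂P11/∂λ, ∂P11/∂λ̇) are analytic on the tension branch and
  verified against central finite differences to ~1e-9 relative.

## Calibration pipeline

Stages mirror how the experiments separate mechanisms; fixed parameters are
threaded forward:

1. ligament: equilibrium tension → (a₂, a₃) with a₁ fixed (default 0: the
   tissue's compressive matrix response is negligible in tensile fits; the
   near-equilibrium 1.2 %/s test is treated as λ̇ = 0, with a
   `viscous_correction` hook to subtract a known small rate term);
   single-rate ramp (25 %/s by convention) → (a₄, a₅); normalized
   relaxation → spectrum.
2. cartilage: confined compression → b₁; tensile equilibria (with b₁
   fixed) → (b₂, b₃), a non-negative linear fit; the first ramp of the
   multistep record → b₄ (linear, and free of relaxation-branch
   contamination because no branch exists yet); first relaxation phase
   normalized → spectrum. Joint refinement of b₄ with the spectrum over the
   whole record is deliberately not offered: on the study conditions the
   sequential path already recovers the generating parameters exactly.

All fits are bound-constrained trust-region least squares. The Σw = 1
equality is enforced exactly by eliminating the last weight; positivity is
enforced by bounds and candidate rejection. Because multi-exponential
fitting is ill-conditioned, the spectrum stage is multi-started (8 seeded
starts, τ initialized log-spaced over the data's time span) and judged
primarily at curve level: distinct (τ, w) sets can produce relaxation
curves identical to within measurement noise, so parameter-level agreement
is reported but not the primary criterion.

The relaxation record is normalized by the *predicted* short-term peak
S_δ (from the already-fitted viscous constants and the known ramp rate)
rather than by the single measured peak sample: the viscous excess above
equilibrium can be a small difference of large stresses (~6 % of total for
the ligament set at 16 % stretch), and dividing by one noisy sample is
unstable while the model prediction is exact in the noiseless limit.

## Confined compression

The source experiments use equilibrium confined compression to isolate the
cartilage matrix stiffness b₁, but no constitutive form for that state is
given — under uniaxial strain (F = diag(λ,1,1), J = λ) the incompressible
tensile formulation does not apply. This package's own stand-in is a
compressible Neo-Hookean with logarithmic volumetric term,

    Ψ = b1(I1 − 3 − 2 ln J) + (κ/2)(ln J)²,  P11 = 2b1(λ − 1/λ) + κ ln(λ)/λ,

with κ a configuration input (default κ = 10·b₁, mild near-
incompressibility). Fitted b₁ therefore depends on the assumed κ — a 2×
mis-specification biases b₁ by roughly half — which is why κ is an explicit,
recorded input and the sensitivity is exercised in the tests. The fibers
stay slack (I₄ ≤ 1) under lateral confinement, so no fiber term enters.

## Synthetic data

The generator emulates the published test batteries with known ground
truth: ligament — near-equilibrium tension to 16 % strain, ramps at
25/38/50 %/s, and ramp-relaxation at 16 % stretch; cartilage — equilibrium
confined compression, a 5-step 2 %-per-step tensile record at 0.15 %/s, the
per-step tensile equilibria, and the first relaxation phase. Records are
subsampled to realistic point counts (12–220) and carry multiplicative
Gaussian noise (default 2 % — load-cell error scales with signal — plus an
optional additive floor for near-zero readings), all driven by one seeded
generator.

Choices worth knowing:

* Relaxation records are truncated at 5·τ_max (a finite experiment); the
  cartilage *equilibrium* points instead carry the exact elastic values,
  matching the stated experimental condition that each hold continues to
  complete equilibrium — end-of-hold samples of the truncated record would
  retain an O(e⁻⁵) branch residual.
* What passing round trips show: the pipeline recovers parameters the model
  itself generated under the stated protocols and noise. They do not show
  that real tissue follows these energy functions, nor cover preconditioning
  cycles, instrument drift, specimen-to-specimen variability, hysteresis or
  biaxial states — all outside the generator.

## Strain-rate sensitivity of the bundled constants

Simulating 10 % ramps at 1–50 %/s with the bundled ligament constants and
normalizing by the elastic equilibrium stress gives a peak ratio of 1.154
(1.133 at 15 % strain), strictly increasing with rate but far below the
roughly three-fold ratio quoted alongside the source parameters: the rate
term 4a₄(λ²−1)λ²e^{a5(λ²−1)²}λ̇ is only ~15 % of the elastic stress at
λ̇ = 0.5/s and λ = 1.1. The generated calibration-notes report
(`tissuevisco.reports`) recomputes and documents this discrepancy. The
QLV-vs-model contrast is correspondingly weaker than the published
qualitative picture; measured as the max/min ratio of normalized peaks
(this package's spread convention), the QLV reference (1.113) is still
strictly less rate-sensitive than the internal-variable model (1.154).

## Known limitations

* One fiber family, uniaxial kinematics; no 3D boundary-value problems,
  finite-element tangent assembly, or fluid flow/biphasic transients.
* Time constants are strain-independent (quasi-linear relaxation); strain-
  dependent spectra are not formulated.
* Hysteresis/unloading and force-controlled protocols are out of scope.
* The confined-compression law is a documented stand-in (above).
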