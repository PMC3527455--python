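# Methods

## Model

The Myc/E2F/miR-17-92 network is reduced to two lumped variables: the
protein module *p* (Myc and the E2Fs, treated as one transcriptional
unit) and the miR-17-92 cluster *m*.  The dimensional dynamics are

    dP/dt = a + k₁ P² / (K + P² + c·M) − δ P
    dM/dt = b₀ + k₂ P − γ M

protein synthesis has a constitutive, growth-factor-driven part *a* and a
saturating autocatalytic part whose effective saturation is raised by the
miRNA (the c·M term in the denominator: miRNA inhibition acts on the
positive loop, not as an extra degradation channel); the miRNA is
transcribed constitutively (b₀) and proportionally to the protein (k₂P).

Scaling protein by √K, miRNA by b₀/γ and time by the miRNA lifetime 1/γ
gives

    ε dp/dτ = α + κ p²/(Γ₁ + p² + Γ m) − p ,   dm/dτ = β + k₃ p − m

with ε = γ/δ.  This scaling pins Γ₁ = β = 1 and leaves exactly five free
constants (α, κ, Γ, ε, k₃); both pinned constants are nevertheless kept
as explicit `ModelParams` fields so other scalings remain representable.
ε multiplies the *protein* time derivative: protein is less stable than
miRNA (δ > γ), so ε < 1 and the protein module is the fast subsystem.
Where ε sits matters for nothing stationary (steady states, folds,
sensitivities are ε-free) but for everything spectral: the protein
corner frequency is ∝ 1/ε, so ε controls how much of the input-noise band
the module integrates away.

## Default scenario

All shipped scans read one versioned defaults file
(`src/mirnoise/defaults.toml`):

| constant | default | meaning / rationale |
|---|---|---|
| α  | 0.05 | input strength; inside the 0–0.4 operating range, low enough that no point of the scanned plane is left without a stable state |
| κ  | 7.0  | positive feedback; the default transect crosses mono→bistable→excitable→mono in Γ |
| Γ  | 0.5  | negative feedback; bistable at (κ=7, Γ=0.5) |
| Γ₁, β | 1.0 | pinned by the canonical scaling |
| ε  | 0.2  | protein ~5× less stable than miRNA |
| k₃ | 4.0  | miRNA induction, inside the stated 2–5 range |
| τ₀ | 1.0  | noise correlation comparable to the miRNA lifetime (cell-cycle-scale extrinsic noise) |
| D  | 1e-4 | σ_ξ = 0.01: 20% relative input fluctuation, small enough for the linearization to hold |

Grids default to 61×51 over κ ∈ [0,10], Γ ∈ [0,2.5] — fine enough to
resolve the excitable band, coarse enough for desk-scale runtimes.

## Equilibria and bifurcations

Substituting the linear miRNA nullcline m*(p) = β + k₃p into the protein
equation and clearing the (positive) denominator leaves a cubic in p; its
real non-negative roots, Newton-polished and residual-verified
(|rhs| < 1e-10), are the equilibria.  Root pairs closer than 1e-8 (an
exact fold tangency) are merged.  This is exhaustive and
initial-guess-free, and it is cross-checked in the tests against a dense
bracket-scan of the reduced scalar equation.

The system is planar, so bifurcations reduce to scalar sign tests on the
2×2 Jacobian: a fold is a change of equilibrium multiplicity (det J → 0)
and a Hopf point is tr J = 0 with det J > 0 on a continued branch.  Both
are located by bisection — folds on the integer root count, Hopf on the
trace along the branch — refined well past the nominal bracket so event
positions are grid-independent (the Hopf until |tr J| < 1e-9).  Branch
continuation is nearest-neighbor matching of states between grid points
under a continuity bound (10× the local secant); no pseudo-arclength is
needed because every branch here terminates in a simple fold.

Regimes follow from multiplicity and stability: one stable state →
monostable; three states with two stable → bistable; three with one
stable → excitable.  The excitable rest state is always the low-protein
state in this model (the high branch is the one that loses stability
through the Hopf, which therefore sits on the upper branch of every
default scan).  Monostable cells are labelled on/off by continuity: the
state is compared with the midpoint of the (off, on) range at the nearest
coexistence point along Γ (then κ), with a configurable absolute
threshold as the last resort.  Along Γ the default transect runs
monostable(on) → bistable → excitable → monostable(off); along κ it runs
monostable(off) → excitable → bistable → monostable(on) — the two
orderings are the same wedge crossed from different sides.

## Noise metrics

The input noise is Ornstein–Uhlenbeck with ⟨ξ(t)ξ(t′)⟩ =
(D/τ₀)e^(−|t−t′|/τ₀) (variance D/τ₀, Lorentzian spectrum
2D/(1+ω²τ₀²)); a `convention` switch selects the variance-D alternative
(⟨ξξ′⟩ = D·e^(−|Δ|/τ₀)) should a different normalization be wanted — the
amplification ratio A is unaffected, only generated paths change.

Sensitivity: J·dx*/dα = −∂rhs/∂α solved at the stable state;
S = (α/x*)·dx*/dα.  S contains no τ₀, D or ε (ε cancels between the
Jacobian row and the input vector) — the tests assert this invariance
exactly.

Amplification: two independent backends, equal to ≲1e-12 in practice.
(1) Covariance route: append ξ to the linearized system,
A = [[J, b], [0, −1/τ₀]] with b = ∂rhs/∂α = (1/ε, 0), forcing
Q = diag(0, 0, 2/τ₀) for unit input variance, solve AC + CAᵀ + Q = 0
(`scipy.linalg.solve_continuous_lyapunov`).  (2) Spectral route:
σ² = (1/2π)∫|H(ω)|²S_ξ(ω)dω with H = (iωI − J)⁻¹b, folded to (0, ∞) and
integrated adaptively (abs/rel 1e-10/1e-8; the integrand decays as ω⁻⁴).
Both are computed at unit input variance because D cancels in A exactly.
At unstable states the metrics are reported invalid rather than
extrapolated — the linearization diverges there.

Limits used as oracles: for the decoupled linear protein (κ=Γ=0, ε=1)
the closed form is A_p = √(τ₀/(1+τ₀)); for τ₀ → ∞ the input is
quasi-static and A → |S|.  The approach to |S| is monotone when the
equilibrium responds like an overdamped filter (slow protein module,
larger ε) but passes through a resonant maximum at finite τ₀ when the
state is an underdamped spiral (small ε, or near the Hopf): the noise
band then overlaps the rotation frequency.  Both shapes are asserted in
the tests at the default on-state point (ε = 0.5 monotone, ε = 0.05
resonant); at fixed τ₀, A_p decreases monotonically in ε while S is
unchanged — slowing the protein module buffers noise for free.

## Synthetic data

The generators emulate exactly the stochastic structure the analytic
theory assumes — extrinsic OU fluctuations of the input only.

* OU: exact discretization (ρ = e^(−dt/τ₀) update from a stationary
  start), so variance and autocorrelation are exact at any dt.  This is
  the module's contract and is verified at n = 10⁶ against the analytic
  stationary law.
* Langevin: classical RK4 on the deterministic field with ξ held
  piecewise-constant per step (dt = 0.01 ≤ ε/10 resolves the fast
  module; the zero-order hold bias is O((dt/τ₀)²)).  States are clipped
  at zero and clips counted — heavy-clip regimes are flagged, not
  silently biased.
* SSA: exact Gillespie on the four dimensional reactions (protein
  birth/death, miRNA birth/death) with counts N = Ω·concentration; the
  extrinsic input is a piecewise-constant OU path updated every
  Δt_ext = τ₀/50 (quasi-static hybrid; its error is controlled by
  Δt_ext/τ₀), with negative effective inputs floored at zero.  The inner
  loop is numba-compiled.

What the generators deliberately do *not* model: transcription/translation
delays, bursting, cell division, or any intrinsic-noise contribution in
the *analytic* formulas (the SSA carries intrinsic noise, which is the
point of the comparison below).  Passing tests therefore show that the
implementation is internally consistent and that the analytic metrics
describe the model under its stated assumptions — not that real
Myc/E2F circuits behave quantitatively this way.

## Empirical estimation and validation

`estimate_metrics` pools all post-burn-in samples of all ensemble members
into grand moments: per-trajectory variances would be biased low by
2τ_corr/T, which at the achievable standard errors would be a visible
systematic.  Batch-means standard errors use one batch per trajectory.

The validation pipeline (`run_validation`) uses 200 Langevin trajectories of length 500 (burn-in 100,
dt 0.01, D = 1e-4) at the two stable states of the default transect:
the bistable on-state (κ=7, Γ=0.5) and the rest state (κ=7, Γ=1.1).
Both must match the analytic A_p within 3 batch-means SEs.  The hybrid
SSA runs at Ω = 10⁴ (8 trajectories × 250 time units) at the rest state
and must agree within 10%.  The SSA check lives at the rest state by
design: its protein count carries an intrinsic noise floor
~1/√(Ω·p*) that the analytic (extrinsic-only) formula excludes; at the
rest state the extrinsic component (A ≈ 1.1, CV ≈ 22%·σ_ξ/α) dominates
that floor, while at the deeply buffered on-state (A ≈ 0.018) the floor
dominates and the comparison would measure molecule-number noise, not
noise propagation.  Validation points far from the Hopf are used because
weakly damped near-Hopf states amplify fluctuations nonlinearly and the
linear theory is then only asymptotically correct.

## Numerical choices and degenerate inputs

* Root dedup 1e-8 (absolute in p), residual acceptance 1e-10: far below
  any biological precision, far above double-precision noise.
* D = 0: OU paths are identically zero; empirical A is reported NaN;
  analytic A is the D-independent ratio (computed at unit variance).
* Exactly at a fold the colliding pair is merged and reported once;
  sensitivity raises at a singular Jacobian instead of returning a
  pseudo-value.
* Points with no stable state (unstable-focus-only, reachable at larger
  α) raise in `classify_regime`/`select_branch`: the stationary metrics
  are undefined there and the default scenario avoids them.
* Reproducibility: every stochastic routine takes an integer seed;
  ensembles are bit-reproducible from (seed, n_traj); scan outputs are
  pure functions of (config, defaults, seed) and each run writes a
  manifest (version, config hash, seed, wall time).

## Known limitations

* Nearest-neighbor continuation assumes branches separate faster than
  the sweep step; pathological grids (step ≫ branch separation) could
  mislink — the continuity bound turns this into branch termination, not
  silent misassignment.
* The analytic metrics are linear-noise results; for σ_ξ/α approaching 1
  or near bifurcations they acquire O(σ²) corrections (visible as a few
  per-mille bias in the Langevin checks near the Hopf).
* The Hopf test function (trace) is planar-specific by design; the code
  does not generalize to higher-dimensional variants of the network.
* No time-delay terms, no limit-cycle continuation, no switching-rate
  (first-passage) statistics.
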