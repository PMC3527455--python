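# mirnoise

Noise propagation through interlinked positive and negative feedback loops,
for the abstracted **Myc/E2F/miR-17-92** cancer network.

Growth-factor input drives a lumped transcription-factor module *p*
(Myc/E2F), which activates its own synthesis through a saturating
autocatalytic term (positive feedback) and induces the miR-17-92 cluster
*m*, which in turn weakens the autocatalysis (negative feedback).  In
dimensionless form, with time in miRNA lifetimes:

    ε dp/dτ = α + κ p² / (Γ₁ + p² + Γ m) − p
      dm/dτ = β + k₃ p − m

Here α is the input strength, κ the positive-feedback strength, Γ the
miRNA-inhibition strength, and ε < 1 the timescale of the (less stable,
hence faster) protein module.  Depending on (κ, Γ) the network is
monostable, bistable (coexisting low/"off" and high/"on" protein states)
or excitable (a stable rest state plus two unstable states, so a
super-threshold kick fires a protein pulse).

The input fluctuates, α → α + ξ(t), with ξ an Ornstein–Uhlenbeck process
(autocorrelation time τ₀, intensity D, ⟨ξξ'⟩ = (D/τ₀)·e^(−|Δt|/τ₀)).  The
package quantifies what arrives at each module:

* **signal sensitivity** S = (α/x*) ∂x*/∂α — the logarithmic steady-state
  gain, by implicit differentiation of the equilibrium condition;
* **noise amplification** A = (σₓ/x*) / (σ_ξ/α) — the ratio of output to
  input relative standard deviations under the linear noise approximation,
  computed by two independent backends (a 3×3 stationary-covariance
  Lyapunov solve with the OU variable appended, and a quadrature of the
  squared transfer function against the OU Lorentzian).  A > 1 means the
  fluctuations are amplified, A < 1 that they are buffered; A → |S| as
  τ₀ → ∞.

Everything analytic is cross-checked by simulation: exact OU sampling,
RK4 Langevin integration of the dimensionless model, and an exact
Gillespie simulation of the dimensional reaction scheme at system size Ω
with the extrinsic input hybridized on a fine time grid.

Who is this for: modelers studying how coupled feedback loops shape
extrinsic-noise transmission in gene regulatory networks, and anyone who
needs a tested reference implementation of LNA-with-colored-noise metrics
on a planar ODE model.

## Worked example

```python
import mirnoise as mn

params = mn.default_params()          # alpha=0.05, kappa=7, Gamma=0.5, ...
noise = mn.default_noise()            # tau0=1, D=1e-4

print("regime:", mn.classify_regime(params).value)
for eq in mn.steady_states(params):
    print(f"  {eq.branch_tag:>6}: p*={eq.p:.4f}  m*={eq.m:.4f}  stable={eq.stable}")

on = mn.select_branch(mn.steady_states(params), "on")
S_p, S_m = mn.sensitivity(params, on)
A_p, A_m = mn.noise_amplification_cov(params, noise, on)
print(f"on-state sensitivity   S_p={S_p:.4f}  S_m={S_m:.4f}")
print(f"on-state amplification A_p={A_p:.4f}  A_m={A_m:.4f}")

hopf = mn.find_event(params, "Gamma", (0.8, 1.0), kind="hopf")
print(f"Hopf on the upper branch at Gamma={hopf.param_value:.4f}")
```

prints

```
regime: bistable
     off: p*=0.0720  m*=1.2880  stable=True
  middle: p*=0.2189  m*=1.8754  stable=False
      on: p*=4.7591  m*=20.0366  stable=True
on-state sensitivity   S_p=0.0166  S_m=0.0158
on-state amplification A_p=0.0178  A_m=0.0125
Hopf on the upper branch at Gamma=0.9162
```

Read: at the default constants the network is bistable; sitting on the
high-protein ("on") state, input fluctuations are strongly buffered
(A_p ≈ 0.018 ≪ 1), the miRNA module is quieter still (A_m < A_p), and the
on state loses stability through a Hopf point at Γ ≈ 0.916 — approaching
it, A_p rises and peaks exactly there.  On the low-protein rest state of
the excitable region (e.g. Γ = 1.1) the same machinery gives A_p ≈ 1.10:
noise is amplified.

The same analyses run from the shell:

```bash
mirnoise sweep --which Gamma --lo 0 --hi 2.5 -n 101     # regime sequence + events
mirnoise regime-map --out out/                          # (kappa, Gamma) diagram
mirnoise metrics-grid --branch on --out out/            # S and A over the plane
mirnoise tau-eps-grid --out out/                        # A vs tau0 and epsilon
mirnoise validate --seed 1 --out out/                   # Langevin + SSA recovery
```

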