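# Versioned default scenario for the Myc/E2F/miR-17-92 noise-propagation analysis.
# Single source of truth for the parameter values used by the shipped scans,
# the validation pipeline and the test suite.
version = 1

[model]
alpha = 0.05    # input strength (range 0-0.4)
kappa = 7.0     # positive-feedback strength; default 1-D transect of the plane
Gamma = 0.5     # miRNA-inhibition strength (range 0-2.5); bistable at defaults
Gamma1 = 1.0    # saturation constant (canonical scaling)
epsilon = 0.2   # protein-module timescale (protein ~5x less stable than miRNA)
k3 = 4.0        # miRNA-induction constant (range 2-5)
extra = 1.0     # basal miRNA transcription (canonical scaling)

[noise]
tau0 = 1.0      # autocorrelation time of the extrinsic input noise
D = 1e-4        # noise intensity (spectral height); sigma_xi = sqrt(D/tau0)

[scan]
kappa_min = 0.0
kappa_max = 10.0
n_kappa = 61
Gamma_min = 0.0
Gamma_max = 2.5
n_Gamma = 51

[validation]
# stable states of the default kappa = 7 transect used for stochastic checks
Gamma_on = 0.5     # bistable on-state
Gamma_rest = 1.1   # monostable low-protein (rest/off) state
n_traj = 200
tmax = 500.0
burn_in = 100.0
dt = 0.01
ssa_omega = 10000.0
ssa_n_traj = 8
ssa_tmax = 250.0
ssa_burn_in = 50.0

[tau_eps]
# Fixed on-state point for the tau0 x epsilon scans
Gamma = 0.5
eps_slow = 0.5   # slow-protein setting: A(tau0) saturates monotonically
eps_fast = 0.05  # fast-protein setting: A(tau0) shows an interior maximum
tau0_max = 1e4
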