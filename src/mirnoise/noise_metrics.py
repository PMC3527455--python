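"""Analytic signal sensitivity and noise amplification under colored noise.

The growth-factor input fluctuates around its mean, alpha -> alpha + xi(t),
with xi an Ornstein-Uhlenbeck process of autocorrelation time tau0 and
intensity D.  Two stationary measures quantify propagation through the
network at a stable state (p*, m*):

* signal sensitivity S = (alpha/x*) dx*/dalpha, the logarithmic gain of the
  steady state with respect to the input strength, obtained by implicit
  differentiation of the equilibrium condition;
* noise amplification A = (sigma_x/x*) / (sigma_xi/alpha), the ratio of
  output to input relative standard deviations under the linear noise
  approximation.  A > 1 means the input noise is propagated and amplified,
  A < 1 that it is buffered.

A is computed by two independent numerical routes that must agree: the
stationary covariance of the OU-augmented linear system (a 3x3 Lyapunov
equation) and the frequency-domain integral of the squared transfer
function against the OU Lorentzian spectrum.  Both are exact within the
linearization; A is independent of D (D scales input and output alike) and
tends to |S| in the quasi-static limit tau0 -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.linalg import solve_continuous_lyapunov

from .model_core import Equilibrium, ModelParams, jacobian, steady_states

__all__ = [
    "NoiseSpec",
    "NoiseMetrics",
    "sensitivity",
    "noise_amplification_cov",
    "noise_amplification_spectral",
    "metrics_grid",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Ornstein-Uhlenbeck extrinsic input noise.

    Convention 'spectral' (default): <xi(t) xi(t')> = (D/tau0) exp(-|t-t'|/tau0),
    stationary variance D/tau0, spectrum S(omega) = 2 D / (1 + omega^2 tau0^2),
    so D is the zero-frequency spectral height and 1/tau0 the bandwidth.
    Convention 'amplitude': <xi xi'> = D exp(-|dt|/tau0), variance D.
    The amplification ratio A is insensitive to the choice; the generated
    noise paths are not.
    """

    tau0: float = 1.0
    D: float = 1e-4
    convention: str = "spectral"

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.convention not in ("spectral", "amplitude"):
            raise ValueError("convention must be 'spectral' or 'amplitude'")

    @property
    def variance(self) -> float:
        """Stationary variance of xi."""
        return self.D / self.tau0 if self.convention == "spectral" else self.D

    @property
    def sigma(self) -> float:
        """Stationary standard deviation of xi."""
        return float(np.sqrt(self.variance))

    def spectrum(self, omega) -> np.ndarray:
        """Two-sided power spectral density of xi."""
        return 2.0 * self.variance * self.tau0 / (1.0 + (omega * self.tau0) ** 2)


@dataclass(frozen=True)
class NoiseMetrics:
    """Sensitivity and amplification of both modules at one stable state."""

    S_p: float
    S_m: float
    A_p: float
    A_m: float
    branch_tag: str = ""
    valid: bool = True


def _require_stable(branch: Equilibrium) -> None:
    if not branch.stable:
        raise ValueError(
            "metrics are defined only at stable equilibria (branch is unstable)"
        )


def _input_vector(params: ModelParams) -> np.ndarray:
    """d(rhs)/d(alpha): the input enters the protein equation scaled by
    1/epsilon."""
    return np.array([1.0 / params.epsilon, 0.0])


def sensitivity(params: ModelParams, branch: Equilibrium) -> tuple[float, float]:
    """Logarithmic steady-state sensitivities (S_p, S_m) to the input alpha.

    Implicit differentiation of rhs(x*, alpha) = 0 gives
    J dx*/dalpha = -d(rhs)/dalpha; S then rescales to relative changes.
    Independent of epsilon, tau0 and D by construction.
    """
    _require_stable(branch)
    J = jacobian(branch.state, params)
    if abs(np.linalg.det(J)) < 1e-12:
        raise ValueError("sensitivity undefined at bifurcation (singular Jacobian)")
    dx = np.linalg.solve(J, -_input_vector(params))
    p, m = branch.state
    if p == 0 or m == 0:
        raise ValueError("logarithmic sensitivity undefined at a zero state")
    return params.alpha * dx[0] / p, params.alpha * dx[1] / m


def noise_amplification_cov(
    params: ModelParams, noise: NoiseSpec, branch: Equilibrium
) -> tuple[float, float]:
    """(A_p, A_m) via the stationary covariance of the OU-augmented system.

    The linearized dynamics with the OU variable appended,
    x = (dp, dm, xi), obey dx = A x dt + sqrt(q) e3 dW with forcing only in
    the OU block; the stationary covariance solves A C + C A^T + Q = 0.
    Computed at unit input variance (A does not depend on D).
    """
    _require_stable(branch)
    J = jacobian(branch.state, params)
    b = _input_vector(params)
    A = np.zeros((3, 3))
    A[:2, :2] = J
    A[:2, 2] = b
    A[2, 2] = -1.0 / noise.tau0
    Q = np.zeros((3, 3))
    Q[2, 2] = 2.0 / noise.tau0  # unit stationary variance of xi
    C = solve_continuous_lyapunov(A, -Q)
    p, m = branch.state
    sig_p = np.sqrt(max(C[0, 0], 0.0))
    sig_m = np.sqrt(max(C[1, 1], 0.0))
    # sigma_xi = 1 here; the ratio of relative SDs is (sig/x*) / (1/alpha)
    return float(sig_p / p * params.alpha), float(sig_m / m * params.alpha)


def noise_amplification_spectral(
    params: ModelParams,
    noise: NoiseSpec,
    branch: Equilibrium,
    abs_tol: float = 1e-10,
    rel_tol: float = 1e-8,
) -> tuple[float, float]:
    """(A_p, A_m) via the frequency-domain route.

    sigma_out^2 = (1/2pi) Int |H(omega)|^2 S_xi(omega) domega with
    H(omega) = (i omega I - J)^(-1) b; the integrand is even, so the
    integral is folded onto (0, inf).  Computed at unit input variance.
    """
    _require_stable(branch)
    J = jacobian(branch.state, params)
    b = _input_vector(params)
    tau0 = noise.tau0

    def integrand(w, idx):
        H = np.linalg.solve(1j * w * np.eye(2) - J, b)
        S = 2.0 * tau0 / (1.0 + (w * tau0) ** 2)  # unit-variance OU spectrum
        return (H[idx].real ** 2 + H[idx].imag ** 2) * S

    out = []
    for idx in (0, 1):
        val, err = quad(
            integrand, 0.0, np.inf, args=(idx,),
            epsabs=abs_tol, epsrel=rel_tol, limit=400,
        )
        if not np.isfinite(val):
            raise RuntimeError(f"spectral quadrature failed (value={val}, err={err})")
        out.append(2.0 * val / (2.0 * np.pi))  # fold factor 2, then 1/2pi
    p, m = branch.state
    return float(np.sqrt(out[0]) / p * params.alpha), float(
        np.sqrt(out[1]) / m * params.alpha
    )


def metrics_at(
    params: ModelParams,
    noise: NoiseSpec,
    branch: Equilibrium,
    backend: str = "cov",
) -> NoiseMetrics:
    """Full metric set at one equilibrium; invalid if the branch is unstable."""
    if not branch.stable:
        return NoiseMetrics(np.nan, np.nan, np.nan, np.nan, branch.branch_tag, False)
    S_p, S_m = sensitivity(params, branch)
    amp = noise_amplification_cov if backend == "cov" else noise_amplification_spectral
    A_p, A_m = amp(params, noise, branch)
    return NoiseMetrics(S_p, S_m, A_p, A_m, branch.branch_tag, True)


def metrics_grid(
    params: ModelParams,
    kappa_values,
    Gamma_values,
    noise: NoiseSpec,
    branch_mode: str = "on",
    backend: str = "cov",
) -> pd.DataFrame:
    """Sensitivity and amplification over a (kappa, Gamma) grid.

    Per grid point the stable branch requested by ``branch_mode`` is
    selected (highest-p stable state for 'on', lowest for 'off'; the unique
    stable state wherever only one exists); points without any stable
    branch are carried through with valid=False.
    """
    from .pipeline import select_branch  # local import to avoid a cycle

    if branch_mode not in ("on", "off"):
        raise ValueError("branch_mode must be 'on' or 'off'")
    rows = []
    for ka in np.asarray(kappa_values, dtype=float):
        for G in np.asarray(Gamma_values, dtype=float):
            pt = params.with_(kappa=ka, Gamma=G)
            eqs = steady_states(pt)
            row = {
                "alpha": pt.alpha, "kappa": ka, "Gamma": G, "Gamma1": pt.Gamma1,
                "epsilon": pt.epsilon, "k3": pt.k3, "tau0": noise.tau0, "D": noise.D,
                "branch": branch_mode, "p_star": np.nan, "m_star": np.nan,
                "S_p": np.nan, "S_m": np.nan, "A_p": np.nan, "A_m": np.nan,
                "valid": False,
            }
            try:
                eq = select_branch(eqs, branch_mode)
            except ValueError:
                rows.append(row)
                continue
            mt = metrics_at(pt, noise, eq, backend=backend)
            row.update(
                p_star=eq.p, m_star=eq.m, S_p=mt.S_p, S_m=mt.S_m,
                A_p=mt.A_p, A_m=mt.A_m, valid=mt.valid,
            )
            rows.append(row)
    return pd.DataFrame(rows)
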