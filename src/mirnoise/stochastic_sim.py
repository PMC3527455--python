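"""Stochastic trajectory generation and empirical noise estimation.

Three generators emulate the stochastic structure the analytic theory
assumes:

* :func:`generate_ou` -- exact-discretization sampling of the
  Ornstein-Uhlenbeck input noise (the synthetic-data core: its stationary
  variance and exponential autocorrelation are the module's contract);
* :func:`integrate_langevin` / :func:`langevin_ensemble` -- fourth-order
  Runge-Kutta integration of the dimensionless ODEs with the fluctuating
  input held piecewise-constant on the integration grid;
* :func:`gillespie_ssa` -- exact stochastic simulation of the dimensional
  reaction scheme (protein birth/death, miRNA birth/death) at system size
  Omega, hybridized with the extrinsic OU input held piecewise-constant on
  a grid much finer than tau0.

:func:`estimate_metrics` turns an ensemble of stationary trajectories into
empirical noise-amplification estimates with batch-means standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .model_core import DimensionalParams, ModelParams, State
from .noise_metrics import NoiseSpec

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "generate_ou",
    "integrate_langevin",
    "langevin_ensemble",
    "gillespie_ssa",
    "estimate_metrics",
]


@dataclass
class Trajectory:
    """A sampled trajectory of the network driven by OU input noise."""

    times: np.ndarray
    p: np.ndarray
    m: np.ndarray
    xi: np.ndarray
    seed: int
    alpha: float          # mean input around which xi fluctuates
    kind: str = "langevin"  # 'langevin' | 'ssa'
    n_clipped: int = 0      # Langevin steps clipped at zero

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.p) == len(self.m) == len(self.xi) == n):
            raise ValueError("times, p, m, xi must have equal length")

    def to_csv(self, path) -> None:
        """Write t, p, m, xi columns plus a JSON sidecar with metadata."""
        path = Path(path)
        arr = np.column_stack([self.times, self.p, self.m, self.xi])
        header = "t,p,m,xi"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        side = {"seed": self.seed, "alpha": self.alpha, "kind": self.kind,
                "n_clipped": self.n_clipped}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


@dataclass
class EnsembleSummary:
    """Pooled stationary moments and empirical amplification of an ensemble."""

    n_traj: int
    burn_in: float
    mean_p: float
    sd_p: float
    mean_m: float
    sd_m: float
    sd_xi: float
    A_hat_p: float
    A_hat_m: float
    se_p: float
    se_m: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# OU input noise

def generate_ou(noise: NoiseSpec, dt: float, n: int, seed) -> np.ndarray:
    """Sample n values of the OU input noise on a dt grid.

    Uses the exact update xi_{k+1} = rho xi_k + sigma sqrt(1-rho^2) z_k
    with rho = exp(-dt/tau0), started from the stationary law, so the
    sampled sequence has the exact stationary variance and autocorrelation
    at any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma = noise.sigma
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma == 0.0:
        return np.zeros(n)
    rho = np.exp(-dt / noise.tau0)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), size=n - 1)
    for k in range(1, n):
        out[k] = out[k - 1] * rho + innov[k - 1]
    return out


# ---------------------------------------------------------------------------
# Langevin (RK4 with piecewise-constant input noise)

def _rhs_arrays(p, m, a_eff, params: ModelParams):
    denom = params.Gamma1 + p * p + params.Gamma * m
    dp = (a_eff + params.kappa * p * p / denom - p) / params.epsilon
    dm = params.extra + params.k3 * p - m
    return dp, dm


def _rk4_ensemble(params, noise, p0, m0, tmax, dt, rng, record_every):
    n_steps = int(round(tmax / dt))
    n_traj = len(p0)
    sigma = noise.sigma
    rho = np.exp(-dt / noise.tau0)
    innov_scale = sigma * np.sqrt(1.0 - rho * rho)
    p = p0.copy()
    m = m0.copy()
    xi = rng.normal(0.0, sigma, n_traj) if sigma > 0 else np.zeros(n_traj)
    n_rec = n_steps // record_every
    P = np.empty((n_rec, n_traj))
    M = np.empty((n_rec, n_traj))
    X = np.empty((n_rec, n_traj))
    T = np.empty(n_rec)
    n_clipped = 0
    irec = 0
    for k in range(n_steps):
        a = params.alpha + xi
        k1p, k1m = _rhs_arrays(p, m, a, params)
        k2p, k2m = _rhs_arrays(p + 0.5 * dt * k1p, m + 0.5 * dt * k1m, a, params)
        k3p, k3m = _rhs_arrays(p + 0.5 * dt * k2p, m + 0.5 * dt * k2m, a, params)
        k4p, k4m = _rhs_arrays(p + dt * k3p, m + dt * k3m, a, params)
        p = p + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        m = m + dt / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(m))):
            raise FloatingPointError(f"non-finite state at step {k} (t={k * dt:.4f})")
        neg = (p < 0) | (m < 0)
        if np.any(neg):
            n_clipped += int(np.count_nonzero(neg))
            np.clip(p, 0.0, None, out=p)
            np.clip(m, 0.0, None, out=m)
        if sigma > 0:
            xi = xi * rho + innov_scale * rng.normal(size=n_traj)
        if (k + 1) % record_every == 0:
            P[irec] = p
            M[irec] = m
            X[irec] = xi
            T[irec] = (k + 1) * dt
            irec += 1
    return T, P, M, X, n_clipped


def integrate_langevin(
    params: ModelParams,
    noise: NoiseSpec,
    x0,
    tmax: float,
    dt: float,
    seed: int,
    record_every: int = 1,
) -> Trajectory:
    """RK4 trajectory of the dimensionless model with OU-fluctuating input.

    The input alpha + xi(t) is held piecewise-constant over each dt step
    (xi sampled exactly on the grid).  dt should resolve the fast protein
    module (dt <= epsilon/10).  Negative excursions are clipped at zero and
    counted in ``n_clipped``.
    """
    if dt > params.epsilon / 10 + 1e-15:
        raise ValueError("dt must resolve the protein module: dt <= epsilon/10")
    x0 = State(*x0)
    if x0.p < 0 or x0.m < 0:
        raise ValueError("initial state must be non-negative")
    rng = np.random.default_rng(seed)
    T, P, M, X, nclip = _rk4_ensemble(
        params, noise, np.array([x0.p]), np.array([x0.m]), tmax, dt, rng, record_every
    )
    return Trajectory(T, P[:, 0], M[:, 0], X[:, 0], seed, params.alpha,
                      "langevin", nclip)


def langevin_ensemble(
    params: ModelParams,
    noise: NoiseSpec,
    x0,
    tmax: float,
    dt: float,
    n_traj: int,
    seed: int,
    record_every: int = 10,
) -> list[Trajectory]:
    """Ensemble of RK4 Langevin trajectories, vectorized across members.

    All members start at ``x0`` and share the base seed (member i is column
    i of the vectorized integration); the ensemble is bit-reproducible from
    (seed, n_traj, record_every).
    """
    if dt > params.epsilon / 10 + 1e-15:
        raise ValueError("dt must resolve the protein module: dt <= epsilon/10")
    x0 = State(*x0)
    rng = np.random.default_rng(seed)
    p0 = np.full(n_traj, x0.p)
    m0 = np.full(n_traj, x0.m)
    T, P, M, X, nclip = _rk4_ensemble(params, noise, p0, m0, tmax, dt, rng, record_every)
    return [
        Trajectory(T, P[:, i], M[:, i], X[:, i], seed, params.alpha, "langevin", nclip)
        for i in range(n_traj)
    ]


# ---------------------------------------------------------------------------
# hybrid Gillespie SSA

@njit(cache=True)
def _ssa_kernel(seed, tmax, dt_ext, dt_sample, Omega,
                a0, k1, K, c, b0, k2, delta, gamma,
                alpha_scale, sigma, rho, NP0, NM0):
    """Exact SSA with the extrinsic OU input frozen on a dt_ext grid.

    Reactions: protein birth Omega*(a_eff + k1 P^2/(K + P^2 + c M)),
    protein death delta*NP, miRNA birth Omega*(b0 + k2 P), miRNA death
    gamma*NM.  a_eff = a0 + alpha_scale*xi, floored at zero (flooring
    events are counted).
    """
    np.random.seed(seed)
    ns = int(tmax / dt_sample)
    out_p = np.empty(ns)
    out_m = np.empty(ns)
    out_xi = np.empty(ns)
    times = np.empty(ns)
    NP = NP0
    NM = NM0
    xi = np.random.normal() * sigma
    s1 = sigma * np.sqrt(max(1.0 - rho * rho, 0.0))
    t = 0.0
    t_next_ext = dt_ext
    t_next_s = dt_sample
    isamp = 0
    n_floored = 0
    while isamp < ns:
        P = NP / Omega
        M = NM / Omega
        a_eff = a0 + alpha_scale * xi
        if a_eff < 0.0:
            a_eff = 0.0
            n_floored += 1
        r1 = Omega * (a_eff + k1 * P * P / (K + P * P + c * M))
        r2 = delta * NP
        r3 = Omega * (b0 + k2 * P)
        r4 = gamma * NM
        rtot = r1 + r2 + r3 + r4
        if rtot <= 0.0:
            t = t_next_ext
        else:
            t_jump = t - np.log(np.random.random()) / rtot
            if t_jump > t_next_ext:
                t = t_next_ext
            else:
                t = t_jump
                u = np.random.random() * rtot
                if u < r1:
                    NP += 1
                elif u < r1 + r2:
                    NP -= 1
                elif u < r1 + r2 + r3:
                    NM += 1
                else:
                    NM -= 1
        while isamp < ns and t >= t_next_s:
            out_p[isamp] = NP
            out_m[isamp] = NM
            out_xi[isamp] = xi
            times[isamp] = t_next_s
            isamp += 1
            t_next_s += dt_sample
        if t >= t_next_ext:
            if sigma > 0.0:
                xi = xi * rho + s1 * np.random.normal()
            t_next_ext += dt_ext
    return times, out_p, out_m, out_xi, n_floored


def gillespie_ssa(
    dp: DimensionalParams,
    Omega: float,
    noise: NoiseSpec,
    tmax: float,
    seed: int,
    x0=None,
    dt_ext: float | None = None,
    dt_sample: float = 0.05,
) -> Trajectory:
    """Hybrid Gillespie simulation of the dimensional network at system
    size Omega (counts N = Omega * concentration).

    The dimensionless OU fluctuation xi perturbs the input as
    a -> a + protein_deg*sqrt(hill_const)*xi (the dimensional image of
    alpha -> alpha + xi) and is updated on a grid dt_ext (default tau0/50,
    in the same time units as ``dp``); between updates the SSA is exact
    with xi frozen.  Negative effective inputs are floored at zero.
    Returned p, m are molecule counts.
    """
    if Omega < 1:
        raise ValueError("Omega must be >= 1")
    if seed < 0 or seed >= 2**32:
        raise ValueError("seed must fit in uint32")
    tau0_dim = noise.tau0 / dp.mirna_deg  # NoiseSpec tau0 is in miRNA lifetimes
    if dt_ext is None:
        dt_ext = tau0_dim / 50.0
    P0 = float(np.sqrt(dp.hill_const))
    alpha = dp.input_rate / (dp.protein_deg * P0)
    if x0 is None:
        from .model_core import nondimensionalize, steady_states

        mp = nondimensionalize(dp)
        stable = [e for e in steady_states(mp) if e.stable]
        eq = min(stable, key=lambda e: e.p)
        M0 = dp.mirna_basal / dp.mirna_deg
        x0 = (eq.p * P0, eq.m * M0)
    NP0 = int(round(Omega * x0[0]))
    NM0 = int(round(Omega * x0[1]))
    rho = float(np.exp(-dt_ext / tau0_dim))
    times, p, m, xi, n_floored = _ssa_kernel(
        seed, tmax, dt_ext, dt_sample, float(Omega),
        dp.input_rate, dp.autocat_rate, dp.hill_const, dp.inhib_const,
        dp.mirna_basal, dp.mirna_induction, dp.protein_deg, dp.mirna_deg,
        dp.protein_deg * P0, noise.sigma, rho, NP0, NM0,
    )
    return Trajectory(times, p, m, xi, seed, alpha, "ssa", n_floored)


# ---------------------------------------------------------------------------
# empirical metrics

def estimate_metrics(trajectories: list[Trajectory], burn_in: float) -> EnsembleSummary:
    """Pooled stationary moments and empirical amplification of an ensemble.

    Moments are pooled across all post-burn-in samples of all members
    (grand mean), which avoids the 2*tau_corr/T short-window bias of
    per-trajectory variances; standard errors come from batch means with
    one batch per trajectory.  A_hat = (sd_out/mean_out)/(sd_xi/alpha); it
    is reported as NaN when the input noise is identically zero.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    if burn_in >= trajectories[0].times[-1]:
        raise ValueError("burn_in must be smaller than the trajectory length")
    alpha = trajectories[0].alpha
    Ps, Ms, Xs = [], [], []
    for tr in trajectories:
        keep = tr.times > burn_in
        Ps.append(np.asarray(tr.p, dtype=float)[keep])
        Ms.append(np.asarray(tr.m, dtype=float)[keep])
        Xs.append(np.asarray(tr.xi, dtype=float)[keep])
    P = np.concatenate(Ps)
    M = np.concatenate(Ms)
    X = np.concatenate(Xs)
    mean_p, sd_p = float(P.mean()), float(P.std())
    mean_m, sd_m = float(M.mean()), float(M.std())
    sd_xi = float(X.std())

    def _amp(sd, mean, sx):
        if sx == 0.0:
            return np.nan
        return (sd / mean) / (sx / alpha)

    A_p = _amp(sd_p, mean_p, sd_xi)
    A_m = _amp(sd_m, mean_m, sd_xi)
    # batch means: one batch per trajectory
    Ap_i, Am_i = [], []
    for Pi, Mi, Xi in zip(Ps, Ms, Xs):
        sxi = Xi.std()
        if sxi == 0.0:
            continue
        Ap_i.append((Pi.std() / Pi.mean()) / (sxi / alpha))
        Am_i.append((Mi.std() / Mi.mean()) / (sxi / alpha))
    nb = len(Ap_i)
    se_p = float(np.std(Ap_i, ddof=1) / np.sqrt(nb)) if nb > 1 else np.nan
    se_m = float(np.std(Am_i, ddof=1) / np.sqrt(nb)) if nb > 1 else np.nan
    return EnsembleSummary(
        n_traj=len(trajectories), burn_in=burn_in,
        mean_p=mean_p, sd_p=sd_p, mean_m=mean_m, sd_m=sd_m, sd_xi=sd_xi,
        A_hat_p=A_p, A_hat_m=A_m, se_p=se_p, se_m=se_m,
    )
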