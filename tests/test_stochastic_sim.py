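"""Tests for the OU generator, Langevin integrator and hybrid SSA."""

import numpy as np
import pytest

from mirnoise import (
    ModelParams,
    NoiseSpec,
    dimensionalize,
    select_branch,
    steady_states,
)
from mirnoise.model_core import Scales
from mirnoise.noise_metrics import noise_amplification_cov
from mirnoise.stochastic_sim import (
    Trajectory,
    estimate_metrics,
    generate_ou,
    gillespie_ssa,
    integrate_langevin,
    langevin_ensemble,
)


def _block_se(x, n_blocks=50):
    """Standard error of a statistic from block means."""
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestOUGenerator:
    def test_zero_intensity_gives_zero_path(self):
        xi = generate_ou(NoiseSpec(tau0=1.0, D=0.0), dt=0.01, n=1000, seed=1)
        assert np.all(xi == 0.0)

    def test_reproducible_from_seed(self):
        ns = NoiseSpec(tau0=0.5, D=0.01)
        a = generate_ou(ns, 0.01, 5000, seed=42)
        b = generate_ou(ns, 0.01, 5000, seed=42)
        c = generate_ou(ns, 0.01, 5000, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_stationary_variance(self):
        ns = NoiseSpec(tau0=1.0, D=1.0)
        xi = generate_ou(ns, dt=0.01, n=1_000_000, seed=7)
        # variance of the sample variance estimated from 50 blocks
        se = _block_se(xi * xi)
        assert abs(xi.var() - ns.variance) < 3 * se

    def test_autocorrelation_decay(self):
        tau0, dt = 1.0, 0.01
        ns = NoiseSpec(tau0=tau0, D=1.0)
        xi = generate_ou(ns, dt=dt, n=1_000_000, seed=11)
        xi0 = xi - xi.mean()
        var = xi0.var()
        for lag_t in (0.5, 1.0, 2.0, 3.0):
            k = int(lag_t / dt)
            prod = xi0[:-k] * xi0[k:]
            rho_hat = prod.mean() / var
            se = _block_se(prod) / var
            assert abs(rho_hat - np.exp(-lag_t / tau0)) < 3 * max(se, 1e-4)

    def test_bad_arguments(self):
        ns = NoiseSpec()
        with pytest.raises(ValueError):
            generate_ou(ns, dt=0.0, n=10, seed=0)
        with pytest.raises(ValueError):
            generate_ou(ns, dt=0.1, n=0, seed=0)


class TestLangevin:
    def test_deterministic_relaxation_to_stable_state(self, params):
        quiet = NoiseSpec(tau0=1.0, D=0.0)
        on = select_branch(steady_states(params), "on")
        traj = integrate_langevin(
            params, quiet, (on.p * 1.05, on.m * 0.95), tmax=80.0, dt=0.01, seed=0
        )
        assert traj.p[-1] == pytest.approx(on.p, abs=1e-8)
        assert traj.m[-1] == pytest.approx(on.m, abs=1e-8)

    def test_rk4_convergence_order(self, params):
        # halving dt shrinks the endpoint error ~16x for a smooth flow
        quiet = NoiseSpec(tau0=1.0, D=0.0)
        x0 = (1.0, 2.0)
        ref = integrate_langevin(params, quiet, x0, tmax=1.0, dt=0.00125, seed=0)
        errs = []
        for dt in (0.02, 0.01):
            tr = integrate_langevin(params, quiet, x0, tmax=1.0, dt=dt, seed=0)
            errs.append(abs(tr.p[-1] - ref.p[-1]) + abs(tr.m[-1] - ref.m[-1]))
        ratio = errs[0] / errs[1]
        assert 8 < ratio < 40

    def test_reproducible_from_seed(self, params, noise):
        a = integrate_langevin(params, noise, (1.0, 1.0), 5.0, 0.01, seed=5)
        b = integrate_langevin(params, noise, (1.0, 1.0), 5.0, 0.01, seed=5)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.xi, b.xi)

    def test_timestep_must_resolve_protein_module(self, params, noise):
        with pytest.raises(ValueError, match="epsilon/10"):
            integrate_langevin(params, noise, (1.0, 1.0), 1.0, dt=0.1, seed=0)

    def test_negative_initial_state_rejected(self, params, noise):
        with pytest.raises(ValueError):
            integrate_langevin(params, noise, (-1.0, 1.0), 1.0, 0.01, seed=0)

    def test_small_noise_ensemble_recovers_analytic_amplification(self, params, noise):
        on = select_branch(steady_states(params), "on")
        A_p, A_m = noise_amplification_cov(params, noise, on)
        trajs = langevin_ensemble(
            params, noise, (on.p, on.m), tmax=220.0, dt=0.01, n_traj=60, seed=902,
        )
        summ = estimate_metrics(trajs, burn_in=60.0)
        assert abs(summ.A_hat_p - A_p) < 3 * summ.se_p
        assert abs(summ.A_hat_m - A_m) < 3 * summ.se_m


def _kappa0_dimensional():
    # no feedback at all: protein is a linear birth-death process
    mp = ModelParams(alpha=0.1, kappa=0.0, Gamma=0.0, epsilon=0.5)
    return mp, dimensionalize(mp, Scales(1.0, 1.0, 1.0))


class TestSSA:
    def test_counts_are_nonnegative_integers(self, params, noise):
        dp = dimensionalize(params, Scales(1.0, 1.0, 1.0))
        tr = gillespie_ssa(dp, Omega=200, noise=noise, tmax=20.0, seed=3)
        assert tr.kind == "ssa"
        assert np.all(tr.p >= 0) and np.all(tr.m >= 0)
        assert np.all(tr.p == np.round(tr.p))
        assert np.all(tr.m == np.round(tr.m))

    def test_reproducible_from_seed(self, params, noise):
        dp = dimensionalize(params, Scales(1.0, 1.0, 1.0))
        a = gillespie_ssa(dp, 100, noise, 10.0, seed=9)
        b = gillespie_ssa(dp, 100, noise, 10.0, seed=9)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.m, b.m)

    def test_linear_birth_death_is_poissonian(self):
        # kappa = 0, no extrinsic noise: stationary law of the protein
        # count is Poisson with mean Omega*p* (Fano factor 1)
        mp, dp = _kappa0_dimensional()
        quiet = NoiseSpec(tau0=1.0, D=0.0)
        Omega = 500.0
        p_star = mp.alpha  # linear protein equation
        tr = gillespie_ssa(dp, Omega, quiet, tmax=2000.0, seed=21, dt_sample=0.5)
        counts = tr.p[tr.times > 50.0]
        mean, var = counts.mean(), counts.var()
        se_mean = _block_se(counts)
        assert abs(mean - Omega * p_star) < 3 * se_mean
        fano = var / mean
        se_fano = _block_se((counts - mean) ** 2 / mean)
        assert abs(fano - 1.0) < 3 * max(se_fano, 0.02)

    def test_large_system_size_approaches_ode(self, params):
        quiet = NoiseSpec(tau0=1.0, D=0.0)
        dp = dimensionalize(params, Scales(1.0, 1.0, 1.0))
        on = select_branch(steady_states(params), "on")
        tr = gillespie_ssa(
            dp, Omega=10_000, noise=quiet, tmax=60.0, seed=5, x0=(on.p, on.m),
            dt_sample=0.1,
        )
        keep = tr.times > 10.0
        assert tr.p[keep].mean() / 10_000 == pytest.approx(on.p, rel=0.01)
        assert tr.m[keep].mean() / 10_000 == pytest.approx(on.m, rel=0.01)

    def test_omega_validation(self, params, noise):
        dp = dimensionalize(params, Scales(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            gillespie_ssa(dp, Omega=0, noise=noise, tmax=1.0, seed=1)


class TestEstimateMetrics:
    def _identity_trajectories(self, rng, n_traj=4):
        # output equals the input fluctuation: amplification is exactly 1
        alpha = 0.3
        ns = NoiseSpec(tau0=1.0, D=0.01)
        out = []
        for i in range(n_traj):
            xi = generate_ou(ns, 0.01, 20_000, seed=100 + i)
            t = np.arange(20_000) * 0.01
            out.append(Trajectory(t, alpha + xi, np.ones_like(xi), xi, 100 + i, alpha))
        return out

    def test_identity_system_has_unit_amplification(self, rng):
        trajs = self._identity_trajectories(rng)
        summ = estimate_metrics(trajs, burn_in=1.0)
        # mean_p approx alpha, sd_p = sd_xi exactly
        assert summ.A_hat_p == pytest.approx(
            summ.mean_p and (summ.sd_p / summ.mean_p) / (summ.sd_xi / 0.3), rel=1e-12
        )
        assert summ.A_hat_p == pytest.approx(1.0, rel=0.05)

    def test_zero_input_noise_reports_nan(self, params):
        quiet = NoiseSpec(tau0=1.0, D=0.0)
        trajs = langevin_ensemble(params, quiet, (1.0, 1.0), 10.0, 0.01, 3, seed=1)
        summ = estimate_metrics(trajs, burn_in=2.0)
        assert np.isnan(summ.A_hat_p) and np.isnan(summ.A_hat_m)

    def test_standard_error_shrinks_with_ensemble_size(self, params, noise):
        on = select_branch(steady_states(params), "on")
        ses = {}
        for n in (25, 100):
            trajs = langevin_ensemble(
                params, noise, (on.p, on.m), tmax=60.0, dt=0.01, n_traj=n, seed=77,
            )
            ses[n] = estimate_metrics(trajs, burn_in=20.0).se_p
        ratio = ses[25] / ses[100]
        assert 1.3 < ratio < 3.1  # ideal sqrt(4) = 2

    def test_input_validation(self, params, noise):
        trajs = langevin_ensemble(params, noise, (1.0, 1.0), 5.0, 0.01, 2, seed=1)
        with pytest.raises(ValueError):
            estimate_metrics(trajs[:1], burn_in=1.0)
        with pytest.raises(ValueError):
            estimate_metrics(trajs, burn_in=10.0)


class TestTrajectoryIO:
    def test_csv_roundtrip_with_sidecar(self, tmp_path, params, noise):
        tr = integrate_langevin(params, noise, (1.0, 1.0), 2.0, 0.01, seed=8)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        import json

        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (len(tr.times), 4)
        side = json.loads((tmp_path / "traj.csv.json").read_text())
        assert side["seed"] == 8 and side["kind"] == "langevin"
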