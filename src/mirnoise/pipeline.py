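"""Configuration-driven scan and validation pipelines.

Every pipeline is a pure function of (config, defaults file, seed): it
produces a CSV table of records, a JSON summary and a manifest recording
the package version, configuration hash and seed, so any stochastic result
can be rerun exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import RegimeLabel, classify_regime, two_parameter_diagram
from .model_core import Equilibrium, ModelParams, Scales, dimensionalize, steady_states
from .noise_metrics import NoiseSpec, metrics_grid, noise_amplification_cov, sensitivity
from .stochastic_sim import estimate_metrics, gillespie_ssa, langevin_ensemble

__all__ = [
    "load_defaults",
    "default_params",
    "default_noise",
    "select_branch",
    "ScanConfig",
    "run_scan",
    "run_validation",
]

SCAN_KINDS = ("regime_map", "metrics_grid", "tau_eps_grid", "validate")


def load_defaults() -> dict:
    """The versioned default scenario shipped with the package."""
    text = resources.files("mirnoise").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)


def default_params() -> ModelParams:
    return ModelParams(**load_defaults()["model"])


def default_noise() -> NoiseSpec:
    d = load_defaults()["noise"]
    return NoiseSpec(tau0=d["tau0"], D=d["D"])


def select_branch(equilibria: list[Equilibrium], mode: str) -> Equilibrium:
    """Stable branch selected by initial condition.

    'on' picks the highest-p stable state, 'off' the lowest; wherever only
    one stable state exists (monostable or the excitable rest state) both
    modes return it.
    """
    if mode not in ("on", "off"):
        raise ValueError("mode must be 'on' or 'off'")
    stable = [e for e in equilibria if e.stable]
    if not stable:
        raise ValueError("no stable equilibrium to select")
    key = (lambda e: e.p)
    return max(stable, key=key) if mode == "on" else min(stable, key=key)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ScanConfig:
    """One scan or validation run.

    axes maps parameter names to (lo, hi, n); unspecified model/noise
    fields fall back to the shipped defaults.
    """

    kind: str
    params: ModelParams = field(default_factory=default_params)
    noise: NoiseSpec = field(default_factory=default_noise)
    axes: dict = field(default_factory=dict)
    branch_mode: str = "on"
    out_dir: str | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCAN_KINDS:
            raise ValueError(f"kind must be one of {SCAN_KINDS}, got {self.kind!r}")
        for name, spec in self.axes.items():
            lo, hi, n = spec
            if not (lo < hi and n >= 2):
                raise ValueError(f"axis {name}: need lo < hi and n >= 2")

    @classmethod
    def from_file(cls, path) -> "ScanConfig":
        path = Path(path)
        raw = (
            tomllib.loads(path.read_text())
            if path.suffix == ".toml"
            else json.loads(path.read_text())
        )
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScanConfig":
        known = {"kind", "model", "noise", "axes", "branch_mode", "out_dir", "seed",
                 "extra"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"invalid config keys: {sorted(bad)}")
        model = default_params().to_dict()
        model.update(raw.get("model", {}))
        noise_d = load_defaults()["noise"] | raw.get("noise", {})
        axes = {k: tuple(v) for k, v in raw.get("axes", {}).items()}
        return cls(
            kind=raw["kind"],
            params=ModelParams(**model),
            noise=NoiseSpec(**noise_d),
            axes=axes,
            branch_mode=raw.get("branch_mode", "on"),
            out_dir=raw.get("out_dir"),
            seed=int(raw.get("seed", 0)),
            extra=raw.get("extra", {}),
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "model": self.params.to_dict(),
            "noise": {"tau0": self.noise.tau0, "D": self.noise.D,
                      "convention": self.noise.convention},
            "axes": {k: list(v) for k, v in self.axes.items()},
            "branch_mode": self.branch_mode,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "extra": self.extra,
        }


def _axis(config: ScanConfig, name: str, fallback_key: str | None = None):
    if name in config.axes:
        lo, hi, n = config.axes[name]
        return np.linspace(lo, hi, int(n))
    d = load_defaults()["scan"]
    if fallback_key == "kappa":
        return np.linspace(d["kappa_min"], d["kappa_max"], d["n_kappa"])
    if fallback_key == "Gamma":
        return np.linspace(d["Gamma_min"], d["Gamma_max"], d["n_Gamma"])
    raise ValueError(f"axis {name} missing from config")


def _write_outputs(config: ScanConfig, df: pd.DataFrame, summary: dict, stem: str):
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{stem}.csv", index=False, float_format="%.10g")
    (out / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "wall_time_s": summary.get("wall_time_s"),
    }
    (out / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# scans

def run_scan(config: ScanConfig):
    """Execute a scan config; returns (records DataFrame, summary dict) and
    writes CSV/JSON/manifest when out_dir is set."""
    t0 = time.time()
    if config.kind == "regime_map":
        df, summary = _run_regime_map(config)
        stem = "regime_map"
    elif config.kind == "metrics_grid":
        df, summary = _run_metrics_grid(config)
        stem = f"metrics_{config.branch_mode}"
    elif config.kind == "tau_eps_grid":
        df, summary = _run_tau_eps(config)
        stem = "tau_eps"
    else:
        raise ValueError(f"run_scan cannot execute kind {config.kind!r}")
    summary["wall_time_s"] = round(time.time() - t0, 3)
    _write_outputs(config, df, summary, stem)
    return df, summary


def _run_regime_map(config: ScanConfig):
    kv = _axis(config, "kappa", "kappa")
    Gv = _axis(config, "Gamma", "Gamma")
    rm = two_parameter_diagram(config.params, kv, Gv)
    df = rm.to_dataframe()
    summary = {"counts": rm.counts(), "n_boundary_points": len(rm.boundaries),
               "boundaries": rm.boundaries}
    return df, summary


def _run_metrics_grid(config: ScanConfig):
    kv = _axis(config, "kappa", "kappa")
    Gv = _axis(config, "Gamma", "Gamma")
    df = metrics_grid(config.params, kv, Gv, config.noise, config.branch_mode)
    # regime label per record (independent diagram on the same grid)
    rm = two_parameter_diagram(config.params, kv, Gv, refine_boundaries=False)
    lab = {(round(ka, 12), round(G, 12)): rm.labels[i, j].value
           for i, ka in enumerate(rm.kappa) for j, G in enumerate(rm.Gamma)}
    df["regime"] = [
        lab[(round(ka, 12), round(G, 12))] for ka, G in zip(df["kappa"], df["Gamma"])
    ]
    valid = df[df["valid"]]
    summary = {
        "argmax_A_p": valid.loc[valid["A_p"].idxmax(), ["kappa", "Gamma", "A_p"]].to_dict()
        if len(valid)
        else None,
        "regime_counts": df["regime"].value_counts().to_dict(),
    }
    return df, summary


def _run_tau_eps(config: ScanConfig):
    d = load_defaults()["tau_eps"]
    params = config.params
    tau_grid = (
        np.linspace(*config.axes["tau0"][:2], int(config.axes["tau0"][2]))
        if "tau0" in config.axes
        else np.logspace(-2, np.log10(d["tau0_max"]), 25)
    )
    eps_grid = (
        np.linspace(*config.axes["epsilon"][:2], int(config.axes["epsilon"][2]))
        if "epsilon" in config.axes
        else np.array([0.05, 0.1, 0.2, 0.5, 0.9])
    )
    rows = []
    for eps in eps_grid:
        pt = params.with_(epsilon=float(eps))
        eqs = steady_states(pt)
        eq = select_branch(eqs, config.branch_mode)
        S_p, S_m = sensitivity(pt, eq)
        for tau0 in tau_grid:
            ns = NoiseSpec(tau0=float(tau0), D=config.noise.D)
            A_p, A_m = noise_amplification_cov(pt, ns, eq)
            rows.append(
                {"epsilon": eps, "tau0": tau0, "p_star": eq.p, "m_star": eq.m,
                 "S_p": S_p, "S_m": S_m, "A_p": A_p, "A_m": A_m}
            )
    df = pd.DataFrame(rows)
    summary = {"saturation_check": {
        str(eps): float(df[df["epsilon"] == eps].iloc[-1]["A_p"])
        for eps in eps_grid
    }}
    return df, summary


# ---------------------------------------------------------------------------
# stochastic validation

def run_validation(config: ScanConfig):
    """Langevin and hybrid-SSA recovery of the analytic amplification.

    Runs Langevin ensembles at the default on-state and rest-state points
    of the kappa transect (3-SE agreement expected) and the SSA at the rest
    state, where the extrinsic noise component dominates the molecule-number
    floor (10% agreement expected).  Returns a JSON-serializable report
    listing every point with its seed.
    """
    t0 = time.time()
    d = load_defaults()["validation"]
    v = {**d, **config.extra}
    params = config.params
    noise = config.noise
    seed = config.seed
    report = {"seed": seed, "points": []}

    jobs = [
        ("on_state", params.with_(Gamma=v["Gamma_on"]), "on", True, False),
        ("rest_state", params.with_(Gamma=v["Gamma_rest"]), "off", True, True),
    ]
    for i, (name, pt, mode, do_langevin, do_ssa) in enumerate(jobs):
        eqs = steady_states(pt)
        eq = select_branch(eqs, mode)
        A_p, A_m = noise_amplification_cov(pt, noise, eq)
        entry = {"point": name, "Gamma": pt.Gamma, "branch": mode,
                 "p_star": eq.p, "m_star": eq.m,
                 "A_p_analytic": A_p, "A_m_analytic": A_m}
        if do_langevin:
            lseed = (seed * 1000003 + 17 * i) % (2**31)
            trajs = langevin_ensemble(
                pt, noise, (eq.p, eq.m), v["tmax"], v["dt"],
                int(v["n_traj"]), lseed,
            )
            summ = estimate_metrics(trajs, v["burn_in"])
            z = (summ.A_hat_p - A_p) / summ.se_p
            entry["langevin"] = {
                "seed": lseed, "n_traj": int(v["n_traj"]), "tmax": v["tmax"],
                "A_hat_p": summ.A_hat_p, "se_p": summ.se_p, "z_p": z,
                "A_hat_m": summ.A_hat_m, "se_m": summ.se_m,
                "pass_3se": bool(abs(z) <= 3.0),
            }
        if do_ssa:
            dp = dimensionalize(pt, Scales(1.0, 1.0, 1.0))
            strajs = []
            for j in range(int(v["ssa_n_traj"])):
                sseed = (seed * 7919 + 104729 * j + 1) % (2**32)
                strajs.append(
                    gillespie_ssa(dp, v["ssa_omega"], noise, v["ssa_tmax"], sseed,
                                  x0=(eq.p, eq.m))
                )
            ssumm = estimate_metrics(strajs, v["ssa_burn_in"])
            rel = ssumm.A_hat_p / A_p - 1.0
            entry["ssa"] = {
                "seeds": [t.seed for t in strajs], "Omega": v["ssa_omega"],
                "tmax": v["ssa_tmax"], "A_hat_p": ssumm.A_hat_p,
                "A_hat_m": ssumm.A_hat_m, "rel_diff_p": rel,
                "pass_10pct": bool(abs(rel) <= 0.10),
            }
        report["points"].append(entry)
    report["all_passed"] = all(
        e.get("langevin", {}).get("pass_3se", True)
        and e.get("ssa", {}).get("pass_10pct", True)
        for e in report["points"]
    )
    report["wall_time_s"] = round(time.time() - t0, 3)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )
    return report
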