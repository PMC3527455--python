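"""Core model of the Myc/E2F/miR-17-92 interlinked feedback network.

The network couples a lumped transcription-factor ("protein") module p,
which activates its own synthesis through a saturating autocatalytic term
(positive feedback), with the miR-17-92 cluster m, which is induced by the
protein and in turn weakens the autocatalysis (negative feedback).

Dimensional form (concentrations P, M)::

    dP/dt = a + k1 * P^2 / (K + P^2 + c*M) - delta * P
    dM/dt = b0 + k2 * P - gamma * M

With protein measured in units of sqrt(K), miRNA in units of b0/gamma and
time in units of the miRNA lifetime 1/gamma, this becomes the dimensionless
system used throughout the package::

    eps * dp/dtau = alpha + kappa * p^2 / (Gamma1 + p^2 + Gamma*m) - p
          dm/dtau = extra + k3 * p - m

where eps = gamma/delta < 1 expresses that the protein module is less
stable (faster) than the miRNA module.  Under the canonical scaling both
``Gamma1`` and ``extra`` equal 1; they are kept as explicit fields so that
alternative scalings remain representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "State",
    "Equilibrium",
    "evaluate_rhs",
    "jacobian",
    "steady_states",
    "nondimensionalize",
    "dimensionalize",
    "load_params",
    "save_params",
]

#: absolute tolerance used to merge nearly coincident roots (in p)
ROOT_DEDUP_TOL = 1e-8
#: residual acceptance for a candidate equilibrium, |f(p*)| < RESIDUAL_TOL
RESIDUAL_TOL = 1e-10


class State(NamedTuple):
    """Dimensionless concentrations of the two modules."""

    p: float  #: protein module (Myc/E2F)
    m: float  #: miR-17-92 cluster


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional two-variable network.

    Units: concentrations are arbitrary but fixed; time in e.g. hours.
    """

    input_rate: float       # growth-factor driven protein synthesis, conc/time
    autocat_rate: float     # maximal autocatalytic synthesis rate, conc/time
    hill_const: float       # saturation constant of the autocatalysis, conc^2
    inhib_const: float      # weight of miRNA inhibition in the denominator, conc
    protein_deg: float      # protein elimination rate constant, 1/time
    mirna_basal: float      # constitutive miRNA transcription, conc/time
    mirna_induction: float  # protein-induced miRNA transcription, 1/time
    mirna_deg: float        # miRNA degradation rate, 1/time

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if self.protein_deg <= 0 or self.mirna_deg <= 0:
            raise ValueError("degradation rates must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters of the network.

    alpha   -- input (growth-factor) strength, typically 0-0.4
    kappa   -- positive-feedback (autocatalysis) strength
    Gamma   -- miRNA-inhibition (negative-feedback) strength, typically 0-2.5
    Gamma1  -- saturation constant of the autocatalytic term
    epsilon -- protein-module timescale relative to the miRNA module (< 1:
               protein is less stable, hence faster)
    k3      -- miRNA-induction constant, typically 2-5
    extra   -- basal (constitutive) miRNA transcription
    """

    alpha: float = 0.05
    kappa: float = 7.0
    Gamma: float = 0.5
    Gamma1: float = 1.0
    epsilon: float = 0.2
    k3: float = 4.0
    extra: float = 1.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if not 0 < self.epsilon <= 1:
            raise ValueError(f"epsilon must lie in (0, 1], got {self.epsilon}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the dimensionless system with its classification."""

    state: State
    eigenvalues: tuple  # two (possibly complex) Jacobian eigenvalues
    stable: bool        # both real parts < 0
    branch_tag: str     # 'off' | 'middle' | 'on' by ascending p

    @property
    def p(self) -> float:
        return self.state.p

    @property
    def m(self) -> float:
        return self.state.m


# ---------------------------------------------------------------------------
# dynamics


def _check_state(state) -> State:
    p, m = state
    if p < 0 or m < 0:
        raise ValueError(f"state must be non-negative, got {(p, m)}")
    return State(float(p), float(m))


def mirna_nullcline(p: float, params: ModelParams) -> float:
    """Steady miRNA level m*(p) = extra + k3 * p (the miRNA equation is
    linear in m)."""
    return params.extra + params.k3 * p


def evaluate_rhs(state, params: ModelParams) -> State:
    """Time derivatives (dp/dtau, dm/dtau) of the dimensionless model.

    The protein equation carries the 1/epsilon factor: the protein module
    relaxes on a timescale epsilon shorter than the miRNA module.
    """
    p, m = _check_state(state)
    denom = params.Gamma1 + p * p + params.Gamma * m
    if denom > 0:
        hill = params.kappa * p * p / denom
    elif params.kappa == 0.0:
        hill = 0.0
    else:
        raise ZeroDivisionError("saturation denominator vanished with kappa > 0")
    dp = (params.alpha + hill - p) / params.epsilon
    dm = params.extra + params.k3 * p - m
    return State(dp, dm)


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`evaluate_rhs` at ``state``."""
    p, m = _check_state(state)
    denom = params.Gamma1 + p * p + params.Gamma * m
    if denom > 0:
        d2 = denom * denom
        dhill_dp = params.kappa * 2 * p * (params.Gamma1 + params.Gamma * m) / d2
        dhill_dm = -params.kappa * p * p * params.Gamma / d2
    else:
        dhill_dp = dhill_dm = 0.0
    eps = params.epsilon
    return np.array(
        [
            [(dhill_dp - 1.0) / eps, dhill_dm / eps],
            [params.k3, -1.0],
        ]
    )


# ---------------------------------------------------------------------------
# equilibria

def _steady_state_polynomial(params: ModelParams) -> np.ndarray:
    """Coefficients (highest first) of the cubic whose non-negative real
    roots are the steady protein levels.

    Substituting the linear miRNA nullcline into the protein equation and
    clearing the (positive) denominator gives

        (alpha - p) * (p^2 + C1*p + C0) + kappa * p^2 = 0

    with C0 = Gamma1 + Gamma*extra and C1 = Gamma*k3.
    """
    a, k, G, k3 = params.alpha, params.kappa, params.Gamma, params.k3
    C0 = params.Gamma1 + G * params.extra
    C1 = G * k3
    return np.array([-1.0, a + k - C1, a * C1 - C0, a * C0])


def steady_states(params: ModelParams) -> list[Equilibrium]:
    """All non-negative equilibria, ascending in p, with stability labels.

    Roots of the reduced cubic are filtered to real, non-negative values,
    merged within ``ROOT_DEDUP_TOL`` and verified against the full
    right-hand side (residual below ``RESIDUAL_TOL``).
    """
    coeffs = _steady_state_polynomial(params)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-7].real
    real = np.sort(real[real > -ROOT_DEDUP_TOL])

    ps: list[float] = []
    for r in real:
        r = max(float(r), 0.0)
        if ps and abs(r - ps[-1]) <= ROOT_DEDUP_TOL:
            continue
        ps.append(r)

    out: list[Equilibrium] = []
    for p in ps:
        # polish with one or two Newton steps on the scalar reduced equation
        p = _polish_root(p, params)
        m = mirna_nullcline(p, params)
        rhs = evaluate_rhs((p, m), params)
        if abs(rhs.p * params.epsilon) > RESIDUAL_TOL or abs(rhs.m) > RESIDUAL_TOL:
            continue
        J = jacobian((p, m), params)
        eig = np.linalg.eigvals(J)
        out.append(
            Equilibrium(
                state=State(p, m),
                eigenvalues=tuple(eig),
                stable=bool(np.all(eig.real < 0)),
                branch_tag="",
            )
        )
    # merge once more after polishing (tangent roots can collapse)
    merged: list[Equilibrium] = []
    for eq in out:
        if merged and abs(eq.p - merged[-1].p) <= ROOT_DEDUP_TOL:
            continue
        merged.append(eq)
    return _tag_branches(merged)


def _polish_root(p: float, params: ModelParams, iters: int = 3) -> float:
    """Newton-polish a root of g(p) = alpha + hill(p, m*(p)) - p."""
    for _ in range(iters):
        m = mirna_nullcline(p, params)
        denom = params.Gamma1 + p * p + params.Gamma * m
        if denom <= 0:
            return p
        g = params.alpha + params.kappa * p * p / denom - p
        d2 = denom * denom
        dg = (
            params.kappa * 2 * p * (params.Gamma1 + params.Gamma * m) / d2
            - params.kappa * p * p * params.Gamma * params.k3 / d2
            - 1.0
        )
        if dg == 0.0:
            return p
        step = g / dg
        p_new = p - step
        if p_new < 0:
            return max(p, 0.0)
        p = p_new
        if abs(step) < 1e-14:
            break
    return p


def _tag_branches(eqs: list[Equilibrium]) -> list[Equilibrium]:
    if len(eqs) == 1:
        tags = [""]  # on/off for a lone state needs sweep context
    elif len(eqs) == 2:
        tags = ["off", "on"]
    elif len(eqs) == 3:
        tags = ["off", "middle", "on"]
    else:
        tags = [""] * len(eqs)
    return [replace(eq, branch_tag=t) for eq, t in zip(eqs, tags)]


# ---------------------------------------------------------------------------
# scaling

class Scales(NamedTuple):
    """Scales used by :func:`nondimensionalize` (protein, miRNA, time)."""

    protein: float
    mirna: float
    time: float


def nondimensionalize(dp: DimensionalParams, return_scales: bool = False):
    """Map dimensional rate constants to :class:`ModelParams`.

    Protein is scaled by sqrt(hill_const), miRNA by mirna_basal/mirna_deg
    and time by the miRNA lifetime 1/mirna_deg, so Gamma1 = extra = 1 and
    epsilon = mirna_deg/protein_deg.
    """
    if dp.hill_const <= 0 or dp.mirna_basal <= 0:
        raise ValueError("hill_const and mirna_basal must be positive for this scaling")
    P0 = float(np.sqrt(dp.hill_const))
    M0 = dp.mirna_basal / dp.mirna_deg
    delta = dp.protein_deg
    gamma = dp.mirna_deg
    mp = ModelParams(
        alpha=dp.input_rate / (delta * P0),
        kappa=dp.autocat_rate / (delta * P0),
        Gamma=dp.inhib_const * M0 / (P0 * P0),
        Gamma1=1.0,
        epsilon=gamma / delta,
        k3=dp.mirna_induction * P0 / (gamma * M0),
        extra=1.0,
    )
    if return_scales:
        return mp, Scales(P0, M0, 1.0 / gamma)
    return mp


def dimensionalize(mp: ModelParams, scales: Scales) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` for given scales."""
    P0, M0, T = scales.protein, scales.mirna, scales.time
    gamma = 1.0 / T
    delta = gamma / mp.epsilon
    return DimensionalParams(
        input_rate=mp.alpha * delta * P0,
        autocat_rate=mp.kappa * delta * P0,
        hill_const=mp.Gamma1 * P0 * P0,
        inhib_const=mp.Gamma * P0 * P0 / M0,
        protein_deg=delta,
        mirna_basal=mp.extra * gamma * M0,
        mirna_induction=mp.k3 * gamma * M0 / P0,
        mirna_deg=gamma,
    )


# ---------------------------------------------------------------------------
# config I/O

def save_params(params: ModelParams, path) -> None:
    """Write parameters as a flat JSON/TOML-compatible key-value file."""
    path = Path(path)
    if path.suffix == ".toml":
        lines = [f"{k} = {v!r}" for k, v in params.to_dict().items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_params(path) -> ModelParams:
    """Read parameters from a JSON or TOML key-value file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        d = tomllib.loads(path.read_text())
    else:
        d = json.loads(path.read_text())
    return ModelParams.from_dict(d)
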