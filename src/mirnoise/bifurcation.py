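"""Bifurcation structure and dynamical-regime classification.

The network admits three regimes: monostability (a single stable state,
low- or high-protein), bistability (two stable states separated by a
saddle) and excitability (a single stable rest state at low protein
coexisting with two unstable states, so that super-threshold perturbations
trigger a large protein excursion before returning).

Because the system is planar, both bifurcation types reduce to scalar sign
tests on the Jacobian at an equilibrium: a saddle-node is a root collision
(det J = 0, detected as a change in equilibrium multiplicity) and a Hopf
point is tr J = 0 with det J > 0.  Events are located by bisection along
the swept parameter; equilibrium branches are continued by nearest-neighbor
matching, which is adequate here because all branches terminate in simple
folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Equilibrium, ModelParams, jacobian, steady_states

__all__ = [
    "RegimeLabel",
    "BifurcationEvent",
    "Branch",
    "sweep_1d",
    "classify_regime",
    "find_event",
    "two_parameter_diagram",
    "RegimeMap",
]


class RegimeLabel(str, Enum):
    MONOSTABLE_OFF = "monostable_off"
    MONOSTABLE_ON = "monostable_on"
    EXCITABLE = "excitable"
    BISTABLE = "bistable"

    @property
    def is_monostable(self) -> bool:
        return self in (RegimeLabel.MONOSTABLE_OFF, RegimeLabel.MONOSTABLE_ON)


@dataclass(frozen=True)
class BifurcationEvent:
    kind: str            # 'saddle_node' | 'hopf'
    param_value: float   # location along the swept parameter
    state: tuple         # (p, m) at the event
    bracket_width: float # final bisection interval


@dataclass
class Branch:
    """One continued equilibrium branch of a 1-D sweep."""

    which: str
    param_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: np.ndarray = field(default_factory=lambda: np.empty(0))
    m: np.ndarray = field(default_factory=lambda: np.empty(0))
    stable: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    events: list = field(default_factory=list)


def _equilibria_at(params: ModelParams, which: str, value: float) -> list[Equilibrium]:
    return steady_states(params.with_(**{which: value}))


def _count_at(params: ModelParams, which: str, value: float) -> int:
    return len(_equilibria_at(params, which, value))


# ---------------------------------------------------------------------------
# classification

def classify_regime(
    params: ModelParams,
    equilibria: list[Equilibrium] | None = None,
    p_threshold: float | None = None,
) -> RegimeLabel:
    """Classify the dynamical regime at a parameter point.

    One stable equilibrium (and no others) is monostable; three equilibria
    with two stable are bistable; three with exactly one stable are
    excitable.  A monostable state is labelled on/off by continuing in
    Gamma (then kappa) to the nearest coexistence window and comparing the
    state with the midpoint of the window, falling back to ``p_threshold``
    when no window exists along either axis.

    Raises ``ValueError`` when no equilibrium is stable (outside the
    regime map, e.g. a noise-sustained oscillation around an unstable
    focus).
    """
    eqs = equilibria if equilibria is not None else steady_states(params)
    n_stable = sum(e.stable for e in eqs)
    if n_stable == 0:
        raise ValueError(
            f"no stable equilibrium at {params}; point is outside the regime map"
        )
    if len(eqs) >= 3:
        return RegimeLabel.BISTABLE if n_stable >= 2 else RegimeLabel.EXCITABLE
    # monostable: decide on/off
    p_star = eqs[0].p
    mid = _nearest_coexistence_midpoint(params)
    if mid is None:
        mid = p_threshold if p_threshold is not None else 1.0
    return RegimeLabel.MONOSTABLE_ON if p_star > mid else RegimeLabel.MONOSTABLE_OFF


def _coexistence_midpoint(eqs: list[Equilibrium]) -> float:
    return 0.5 * (eqs[0].p + eqs[-1].p)


def _nearest_coexistence_midpoint(
    params: ModelParams,
    Gamma_range: tuple[float, float] = (0.0, 2.5),
    kappa_range: tuple[float, float] = (0.0, 12.0),
    n_scan: int = 101,
) -> float | None:
    """Midpoint of the (off, on) p-range at the nearest parameter point
    with coexisting equilibria, scanning Gamma first, then kappa."""
    for which, (lo, hi), center in (
        ("Gamma", Gamma_range, params.Gamma),
        ("kappa", kappa_range, params.kappa),
    ):
        grid = np.linspace(lo, hi, n_scan)
        order = np.argsort(np.abs(grid - center))
        for idx in order:
            eqs = _equilibria_at(params, which, grid[idx])
            if len(eqs) >= 3:
                return _coexistence_midpoint(eqs)
    return None


# ---------------------------------------------------------------------------
# event location

def find_event(
    params: ModelParams,
    which: str,
    bracket: tuple[float, float],
    kind: str | None = None,
    rel_width: float = 1e-4,
) -> BifurcationEvent:
    """Locate a bifurcation inside ``bracket`` along parameter ``which``.

    Saddle-nodes are found by bisecting the change in equilibrium
    multiplicity; Hopf points by bisecting the sign of the Jacobian trace
    along a continued branch (checking det > 0 at the event).  With
    ``kind=None`` a multiplicity change takes precedence.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    tol = (hi - lo) * rel_width

    if kind in (None, "saddle_node"):
        n_lo, n_hi = _count_at(params, which, lo), _count_at(params, which, hi)
        if n_lo != n_hi:
            return _bisect_fold(params, which, lo, hi, n_lo, tol)
        if kind == "saddle_node":
            raise ValueError("no event in bracket: equilibrium count does not change")
    return _bisect_hopf(params, which, lo, hi, tol)


def _bisect_fold(params, which, lo, hi, n_lo, tol) -> BifurcationEvent:
    # refine well past the requested width: each iteration is one cubic
    # root count, so machine-level location is cheap and makes event
    # positions independent of the sweep grid
    tol = min(tol, 1e-10 * max(1.0, abs(hi)))
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _count_at(params, which, mid) == n_lo:
            lo = mid
        else:
            hi = mid
    # state: mean of the two colliding roots on the many-root side
    side = lo if _count_at(params, which, lo) >= 3 else hi
    eqs = _equilibria_at(params, which, side)
    if len(eqs) >= 3:
        other = _equilibria_at(params, which, lo if side == hi else hi)
        other_ps = [e.p for e in other]
        # colliding pair = the two roots of the triple farthest from the survivors
        dists = [min(abs(e.p - q) for q in other_ps) for e in eqs]
        i, j = sorted(np.argsort(dists)[-2:])
        state = (0.5 * (eqs[i].p + eqs[j].p), 0.5 * (eqs[i].m + eqs[j].m))
    else:
        state = (eqs[0].p, eqs[0].m)
    return BifurcationEvent("saddle_node", 0.5 * (lo + hi), state, hi - lo)


def _trace_on_branch(params, which, value, p_seed):
    eqs = _equilibria_at(params, which, value)
    if not eqs:
        return None, None
    eq = min(eqs, key=lambda e: abs(e.p - p_seed))
    J = jacobian(eq.state, params.with_(**{which: value}))
    return float(np.trace(J)), eq


def _bisect_hopf(params, which, lo, hi, tol) -> BifurcationEvent:
    eqs_lo = _equilibria_at(params, which, lo)
    for seed in eqs_lo:
        p_seed = seed.p
        t_lo, _ = _trace_on_branch(params, which, lo, p_seed)
        t_hi, _ = _trace_on_branch(params, which, hi, p_seed)
        if t_lo is None or t_hi is None or np.sign(t_lo) == np.sign(t_hi):
            continue
        a, b, ta = lo, hi, t_lo
        p_track = p_seed
        t_mid = ta
        # refine past the bracket-width target until the trace itself is
        # resolved to ~1e-9 (definitional Hopf test function)
        for _ in range(120):
            if b - a <= tol and abs(t_mid) < 1e-9:
                break
            if b - a < 1e-15 * max(1.0, abs(a)):
                break
            mid = 0.5 * (a + b)
            t_mid, eq_mid = _trace_on_branch(params, which, mid, p_track)
            if eq_mid is not None:
                p_track = eq_mid.p
            if np.sign(t_mid) == np.sign(ta):
                a, ta = mid, t_mid
            else:
                b = mid
        v = 0.5 * (a + b)
        _, eq = _trace_on_branch(params, which, v, p_track)
        J = jacobian(eq.state, params.with_(**{which: v}))
        if np.linalg.det(J) <= 0:
            continue  # trace zero on a saddle is not a Hopf point
        return BifurcationEvent("hopf", v, (eq.p, eq.m), b - a)
    raise ValueError("no event in bracket: no sign change of any test function")


# ---------------------------------------------------------------------------
# 1-D sweep

def sweep_1d(
    params: ModelParams,
    which: str,
    lo: float,
    hi: float,
    n: int,
) -> list[Branch]:
    """Sweep parameter ``which`` over [lo, hi] on an ``n``-point grid and
    return the continued equilibrium branches with refined events.

    Branches are matched between neighboring grid points by nearest state;
    fold events are refined to a bracket below (hi-lo)/1e4 and attached to
    the branches that appear/terminate there; Hopf events are attached to
    the branch whose trace changes sign.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if n < 10:
        raise ValueError("need n >= 10")
    grid = np.linspace(lo, hi, n)
    eq_sets = [_equilibria_at(params, which, v) for v in grid]

    # --- link branches by globally-closest pairs under a continuity bound
    active: list[dict] = []
    done: list[dict] = []
    for v, eqs in zip(grid, eq_sets):
        cands = []
        for bi, br in enumerate(active):
            for j, e in enumerate(eqs):
                d = abs(e.p - br["p"][-1]) + 0.1 * abs(e.m - br["m"][-1])
                if d <= br["bound"]:
                    cands.append((d, bi, j))
        cands.sort()
        used_b, used_e = set(), set()
        matched = {}
        for d, bi, j in cands:
            if bi in used_b or j in used_e:
                continue
            used_b.add(bi)
            used_e.add(j)
            matched[bi] = j
        still = []
        for bi, br in enumerate(active):
            j = matched.get(bi)
            if j is None:
                done.append(br)
                continue
            e = eqs[j]
            secant = abs(e.p - br["p"][-1])
            # continuity bound: 10x the local secant, floored at a fraction
            # of the branch scale so smooth starts are not rejected
            br["bound"] = max(10 * secant, 0.15 * (1.0 + abs(e.p)))
            br["v"].append(v)
            br["p"].append(e.p)
            br["m"].append(e.m)
            br["s"].append(e.stable)
            still.append(br)
        for j, e in enumerate(eqs):
            if j not in used_e:
                still.append(
                    {"v": [v], "p": [e.p], "m": [e.m], "s": [e.stable],
                     "bound": 0.15 * (1.0 + abs(e.p)), "events": []}
                )
        active = still
    done.extend(active)

    branches = []
    for br in done:
        branches.append(
            Branch(
                which=which,
                param_grid=np.asarray(br["v"]),
                p=np.asarray(br["p"]),
                m=np.asarray(br["m"]),
                stable=np.asarray(br["s"], dtype=bool),
                events=br["events"],
            )
        )

    # --- fold events where multiplicity changes between neighbors
    counts = [len(e) for e in eq_sets]
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            ev = find_event(params, which, (grid[i], grid[i + 1]), kind="saddle_node")
            for b in branches:
                t0, t1 = b.param_grid[0], b.param_grid[-1]
                starts = abs(t0 - grid[i + 1]) < 1e-12 or abs(t0 - grid[i]) < 1e-12
                ends = abs(t1 - grid[i]) < 1e-12 or abs(t1 - grid[i + 1]) < 1e-12
                endpoint_p = b.p[0] if starts else b.p[-1]
                if (starts or ends) and abs(endpoint_p - ev.state[0]) < 0.5 * max(
                    1.0, ev.state[0]
                ):
                    b.events.append(ev)

    # --- Hopf events along each branch
    for b in branches:
        s = b.stable
        for i in range(len(s) - 1):
            if s[i] != s[i + 1]:
                # stability flip without a fold: trace crossing on this branch
                try:
                    ev = _bisect_hopf(
                        params, which, b.param_grid[i], b.param_grid[i + 1],
                        (b.param_grid[i + 1] - b.param_grid[i]) * 1e-4,
                    )
                except ValueError:
                    continue
                b.events.append(ev)
    return branches


def regime_sequence(params: ModelParams, which: str, lo: float, hi: float, n: int):
    """Condensed sequence of regime labels along a 1-D sweep (adjacent
    duplicates removed), using branch continuity for monostable on/off."""
    grid = np.linspace(lo, hi, n)
    labels = []
    for v in grid:
        pt = params.with_(**{which: v})
        eqs = steady_states(pt)
        labels.append(classify_regime(pt, eqs))
    seq = [labels[0]]
    for l in labels[1:]:
        if l != seq[-1]:
            seq.append(l)
    return seq, labels, grid


# ---------------------------------------------------------------------------
# 2-D diagram

@dataclass
class RegimeMap:
    kappa: np.ndarray
    Gamma: np.ndarray
    labels: np.ndarray      # (n_kappa, n_Gamma) object array of RegimeLabel
    boundaries: list        # (kind, kappa, Gamma) triples

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"kappa": ka, "Gamma": G, "label": self.labels[i, j].value}
            for i, ka in enumerate(self.kappa)
            for j, G in enumerate(self.Gamma)
        ]
        return pd.DataFrame(rows)

    def boundaries_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.boundaries, columns=["kind", "kappa", "Gamma"])

    def counts(self) -> dict:
        flat = [l.value for l in self.labels.ravel()]
        return {lab: flat.count(lab) for lab in sorted(set(flat))}

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kappa": self.kappa.tolist(),
                    "Gamma": self.Gamma.tolist(),
                    "counts": self.counts(),
                    "boundaries": self.boundaries,
                },
                indent=2,
            )
        )


def two_parameter_diagram(
    params: ModelParams,
    kappa_values,
    Gamma_values,
    refine_boundaries: bool = True,
) -> RegimeMap:
    """Regime label per (kappa, Gamma) cell plus refined boundary points.

    Monostable cells are labelled on/off by continuity with the nearest
    coexistence cell of the map (midpoint rule); boundary points between
    cells of different multiplicity/stability are refined with
    :func:`find_event` along the local Gamma transect.
    """
    kv = np.asarray(kappa_values, dtype=float)
    Gv = np.asarray(Gamma_values, dtype=float)
    nk, nG = len(kv), len(Gv)
    eq_grid = [[steady_states(params.with_(kappa=ka, Gamma=G)) for G in Gv] for ka in kv]

    # structural label first
    labels = np.empty((nk, nG), dtype=object)
    mono_cells = []
    mids = []
    for i in range(nk):
        for j in range(nG):
            eqs = eq_grid[i][j]
            n_stab = sum(e.stable for e in eqs)
            if n_stab == 0:
                raise ValueError(
                    f"no stable equilibrium at kappa={kv[i]}, Gamma={Gv[j]}"
                )
            if len(eqs) >= 3:
                labels[i, j] = (
                    RegimeLabel.BISTABLE if n_stab >= 2 else RegimeLabel.EXCITABLE
                )
                mids.append((i, j, _coexistence_midpoint(eqs)))
            else:
                mono_cells.append((i, j))
    # on/off by nearest coexistence cell in grid metric
    for i, j in mono_cells:
        p_star = eq_grid[i][j][0].p
        if mids:
            _, _, mid = min(mids, key=lambda t: (t[0] - i) ** 2 + (t[1] - j) ** 2)
        else:
            mid = 1.0
        labels[i, j] = (
            RegimeLabel.MONOSTABLE_ON if p_star > mid else RegimeLabel.MONOSTABLE_OFF
        )

    boundaries = []
    if refine_boundaries:
        for i in range(nk):
            base = params.with_(kappa=kv[i])
            for j in range(nG - 1):
                l0, l1 = labels[i, j], labels[i, j + 1]
                if l0 == l1 or (l0.is_monostable and l1.is_monostable):
                    continue
                n0 = len(eq_grid[i][j])
                n1 = len(eq_grid[i][j + 1])
                kind = "saddle_node" if n0 != n1 else "hopf"
                try:
                    ev = find_event(base, "Gamma", (Gv[j], Gv[j + 1]), kind=kind)
                except ValueError:
                    continue
                boundaries.append((ev.kind, float(kv[i]), float(ev.param_value)))
    return RegimeMap(kv, Gv, labels, boundaries)
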