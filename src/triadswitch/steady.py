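"""Steady-state location, branch tracing and switchability classification.

Steady states are found by multi-start Newton refinement (in log
concentration space, so states spanning decades are equally well
conditioned) from a log-spaced grid of initial guesses plus the endpoints of
forward integrations, then deduplicated.  Stability comes from the real
parts of the Jacobian eigenvalues, with ambiguous (near-zero) cases resolved
by simulation.  Signal-response branches are traced on a dense grid with
warm-started refinement at every point, and saddle-node thresholds are
bracketed by the grid and refined by bisection.  No external continuation
package is used: the system is three-dimensional and cheap, so dense-grid
robustness beats pseudo-arclength elegance.

Response curves are classified as irreversible_bistable (two stable states
coexist somewhere on the axis *and* at zero signal), reversible_bistable
(coexistence only away from zero signal) or monostable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .enhancers import SignalInput, ZERO_SIGNAL
from .fitting import (
    ReporterTable,
    feasibility_bound,
    fit_enhancer,
    InfeasibleFitError,
)
from .triad import TriadParameters, build_triad, rhs

__all__ = [
    "SteadyStatePoint",
    "SteadyStateSet",
    "ResponseCurve",
    "find_steady_states",
    "trace_response",
    "signal_of",
    "default_axis_grid",
    "can_switch",
    "switchability_scan",
]

ROOT_TOL = 1e-10  # max |rhs| for an accepted steady state
MERGE_RTOL = 1e-4  # relative (log-space) dedup radius
STABILITY_MARGIN = 1e-8  # |Re lambda| below this is ambiguous

AXES = ("notch", "bmp4", "gata1")

#: Physiological signal ceiling (in units of the promoter dissociation
#: constant) used when asking whether a signal "can switch" the module.  At
#: fully saturating concentrations the promoter-bound signal itself opens
#: chromatin strongly enough that any feasible parameter set switches; the
#: Fig-2-style band structure (both / Bmp4-only / neither) appears for
#: signals up to a few tens of dissociation constants.
PHYSIOLOGICAL_AMPLITUDE = 30.0


def signal_of(axis: str, value: float) -> SignalInput:
    """Map an axis value to a SignalInput; the gata1 axis carries eta."""
    if axis == "notch":
        return SignalInput(n=value)
    if axis == "bmp4":
        return SignalInput(b=value)
    if axis == "gata1":
        return SignalInput(eta=value)
    raise ValueError(f"unknown signal axis {axis!r}; expected one of {AXES}")


def zero_signal_value(axis: str) -> float:
    return 1.0 if axis == "gata1" else 0.0


def default_axis_grid(axis: str, n: int = 25) -> np.ndarray:
    """Signal grid from the neutral value outward (eta descends from 1)."""
    if axis == "gata1":
        return np.geomspace(1.0, 1e-3, n)
    return np.concatenate([[0.0], np.geomspace(1e-2, 1e3, n - 1)])


@dataclass(frozen=True)
class SteadyStatePoint:
    state: tuple
    stable: bool
    max_real_eig: float
    residual: float


@dataclass(frozen=True)
class SteadyStateSet:
    points: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "points", tuple(sorted(self.points, key=lambda p: p.state[1]))
        )

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def stable_points(self) -> tuple:
        return tuple(p for p in self.points if p.stable)

    @property
    def unstable_points(self) -> tuple:
        return tuple(p for p in self.points if not p.stable)

    def lowest_stable(self) -> SteadyStatePoint:
        return min(self.stable_points, key=lambda p: p.state[1])

    def highest_stable(self) -> SteadyStatePoint:
        return max(self.stable_points, key=lambda p: p.state[1])


def _dims(params: TriadParameters):
    clamped = [0] if params.clamped else []
    zero = [
        i
        for i in range(3)
        if params.production_scale[i] == 0.0 and i not in clamped
    ]
    solve_dims = [i for i in range(3) if i not in clamped and i not in zero]
    dynamic = [i for i in range(3) if i not in clamped]
    return clamped, zero, solve_dims, dynamic


def _full_state(params, u, solve_dims, zero):
    x = [0.0, 0.0, 0.0]
    if params.clamped:
        x[0] = params.clamp_xs
    for k, i in enumerate(solve_dims):
        # Clamp the log-coordinate so stray solver excursions cannot overflow.
        x[i] = math.exp(min(max(u[k], -60.0), 60.0))
    return tuple(x)


def _rhs_vec(params, signal):
    def f(x):
        return rhs(x, signal, params)

    return f


def _integrate_to(params, signal, x0, horizon=300.0, rtol=1e-7, atol=1e-10):
    fun = lambda t, y: rhs(np.clip(y, 0.0, None), signal, params)
    sol = solve_ivp(
        fun, (0.0, horizon), np.asarray(x0, float), method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return tuple(np.clip(sol.y[:, -1], 0.0, None))


def _jacobian(params, signal, x, dims):
    """Finite-difference Jacobian of rhs over the dynamic dims, one-sided at
    the nonnegativity boundary."""
    f0 = np.asarray(rhs(x, signal, params))
    J = np.zeros((len(dims), len(dims)))
    for col, j in enumerate(dims):
        h = 1e-7 * max(abs(x[j]), 1e-4)
        xp = list(x)
        xm = list(x)
        xp[j] += h
        if x[j] - h >= 0.0:
            xm[j] -= h
            fp = np.asarray(rhs(tuple(xp), signal, params))
            fm = np.asarray(rhs(tuple(xm), signal, params))
            deriv = (fp - fm) / (2 * h)
        else:
            fp = np.asarray(rhs(tuple(xp), signal, params))
            deriv = (fp - f0) / h
        J[:, col] = deriv[dims]
    return J


def _stability(params, signal, x, dynamic):
    J = _jacobian(params, signal, x, dynamic)
    eigs = np.linalg.eigvals(J)
    max_re = float(np.max(eigs.real))
    if abs(max_re) < STABILITY_MARGIN:
        # Ambiguous: perturb and simulate back.
        pert = tuple(
            xi * (1 + 1e-3) + 1e-6 if i in dynamic else xi for i, xi in enumerate(x)
        )
        end = _integrate_to(params, signal, pert, horizon=100.0)
        back = all(
            abs(end[i] - x[i]) <= 1e-3 * max(abs(x[i]), 1e-6) for i in dynamic
        )
        return back, max_re
    return max_re < 0.0, max_re


def _default_starts(params, solve_dims):
    axis_vals = (1e-3, 5e-2, 1.0, 4.0)
    return [
        dict(zip(solve_dims, combo))
        for combo in itertools.product(axis_vals, repeat=len(solve_dims))
    ]


def find_steady_states(
    params: TriadParameters,
    signal: SignalInput = ZERO_SIGNAL,
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
    tol: float = ROOT_TOL,
    with_integration: bool = True,
) -> SteadyStateSet:
    """All steady states reachable from a log-spaced grid of starts plus
    forward-integration endpoints, with Jacobian-based stability flags."""
    clamped, zero, solve_dims, dynamic = _dims(params)
    if not solve_dims:
        raise ValueError("no free dimensions to solve")
    fvec = _rhs_vec(params, signal)

    starts = []
    for s in _default_starts(params, solve_dims):
        starts.append([s[i] for i in solve_dims])
    if extra_starts is not None:
        for s in extra_starts:
            s = list(s)
            if len(s) == 3:
                s = [s[i] for i in solve_dims]
            starts.append([max(float(v), 1e-12) for v in s])
    if with_integration:
        for v in (1e-3, 1.0, 5.0):
            x0 = [0.0, 0.0, 0.0]
            if params.clamped:
                x0[0] = params.clamp_xs
            for i in solve_dims:
                x0[i] = v
            end = _integrate_to(params, signal, x0)
            starts.append([max(end[i], 1e-12) for i in solve_dims])

    found = []
    for s in starts:
        u0 = np.log(np.asarray(s, float))

        def fun(u):
            x = _full_state(params, u, solve_dims, zero)
            r = fvec(x)
            return [r[i] for i in solve_dims]

        sol = _scipy_root(fun, u0, method="hybr", options={"xtol": 1e-13})
        if not sol.success:
            continue
        x = _full_state(params, sol.x, solve_dims, zero)
        resid = max(abs(v) for v in fvec(x))
        if resid > tol:
            continue
        found.append((x, resid))

    if not found:
        raise RuntimeError("no steady state converged from any start")

    # Deduplicate in log space over the solved dims.
    merged: list = []
    for x, resid in found:
        matched = False
        for k, (y, yres) in enumerate(merged):
            close = all(
                abs(math.log(x[i]) - math.log(y[i])) < MERGE_RTOL
                for i in solve_dims
            )
            if close:
                if resid < yres:
                    merged[k] = (x, resid)
                matched = True
                break
        if not matched:
            merged.append((x, resid))

    points = []
    for x, resid in merged:
        stable, max_re = _stability(params, signal, x, dynamic)
        points.append(
            SteadyStatePoint(
                state=tuple(x), stable=stable, max_real_eig=max_re, residual=resid
            )
        )
    return SteadyStateSet(points=tuple(points))


@dataclass(frozen=True)
class ResponseCurve:
    """Steady-state branches along one signal axis.

    classification: irreversible_bistable / reversible_bistable / monostable.
    thresholds: saddle-node signal values (stable-count changes), refined by
    bisection between grid points.
    """

    axis: str
    grid: tuple
    sets: tuple
    classification: str
    thresholds: tuple

    def stable_counts(self) -> list:
        return [len(s.stable_points) for s in self.sets]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for v, sset in zip(self.grid, self.sets):
            for k, p in enumerate(sset):
                recs.append(
                    {
                        "signal": v,
                        "branch": k,
                        "x_s": p.state[0],
                        "x_g": p.state[1],
                        "x_f": p.state[2],
                        "stable": p.stable,
                    }
                )
        return pd.DataFrame(recs)

    def summary(self) -> dict:
        return {
            "axis": self.axis,
            "classification": self.classification,
            "thresholds": list(self.thresholds),
            "n_stable_at_zero_signal": len(self.sets[0].stable_points),
        }


def _classify(sets: Sequence[SteadyStateSet]) -> str:
    counts = [len(s.stable_points) for s in sets]
    if max(counts) >= 2:
        return "irreversible_bistable" if counts[0] >= 2 else "reversible_bistable"
    return "monostable"


def _refine_threshold(params, axis, lo, hi, n_lo, count_fn, tol_rel=1e-3, max_iter=40):
    """Bisection on the signal value where the stable-state count changes."""
    for _ in range(max_iter):
        if lo > 0 and hi > 0:
            mid = math.sqrt(lo * hi)
            done = hi / lo - 1.0 < tol_rel
        else:
            mid = 0.5 * (lo + hi)
            done = hi - lo < tol_rel * max(hi, 1e-6)
        if done:
            break
        if count_fn(mid) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def trace_response(
    params: TriadParameters,
    axis: str,
    grid: Optional[Sequence[float]] = None,
    refine_thresholds: bool = True,
) -> ResponseCurve:
    """Trace steady-state branches along one signal axis (others neutral).

    Every grid point is solved independently from the full multistart grid
    plus warm starts carried from the previous point, so branch sets do not
    depend on continuation bookkeeping.
    """
    if grid is None:
        grid = default_axis_grid(axis)
    grid = np.asarray(grid, float)
    sets = []
    warm: list = []
    for v in grid:
        sset = find_steady_states(
            params, signal_of(axis, v), extra_starts=warm, with_integration=not warm
        )
        warm = [p.state for p in sset]
        sets.append(sset)

    counts = [len(s.stable_points) for s in sets]
    thresholds = []
    if refine_thresholds:
        def count_at(value):
            near = min(
                range(len(grid)), key=lambda i: abs(grid[i] - value)
            )
            sset = find_steady_states(
                params,
                signal_of(axis, value),
                extra_starts=[p.state for p in sets[near]],
                with_integration=False,
            )
            return len(sset.stable_points)

        for i in range(len(grid) - 1):
            if counts[i] != counts[i + 1]:
                thresholds.append(
                    _refine_threshold(
                        params, axis, grid[i], grid[i + 1], counts[i], count_at
                    )
                )
    return ResponseCurve(
        axis=axis,
        grid=tuple(grid),
        sets=tuple(sets),
        classification=_classify(sets),
        thresholds=tuple(thresholds),
    )


def _log_dist(x, y, dims=(0, 1, 2)):
    return max(
        abs(math.log(max(x[i], 1e-12)) - math.log(max(y[i], 1e-12))) for i in dims
    )


def nearest_stable(sset: SteadyStateSet, state, dims=(0, 1, 2)) -> SteadyStatePoint:
    """Nearest stable steady state in log-concentration space."""
    return min(sset.stable_points, key=lambda p: _log_dist(p.state, state, dims))


def can_switch(
    params: TriadParameters,
    axis: str,
    amplitude: float,
    sustain: float = 200.0,
    settle: float = 200.0,
    zero_sets: Optional[SteadyStateSet] = None,
) -> bool:
    """Whether a sustained signal of the given amplitude flips the system to
    the other stable branch *and it stays there after the signal is removed*.

    Activation axes start from the OFF (lowest-x_g) state; the gata1 axis
    starts from ON, with amplitude a mapped to eta = 1/(1+a).
    """
    zs = zero_sets or find_steady_states(params)
    if len(zs.stable_points) < 2:
        return False  # no second attractor to switch into (irreversibly)
    _clamped, _zero, solve_dims, _dyn = _dims(params)
    if axis == "gata1":
        start = zs.highest_stable()
        signal = SignalInput(eta=1.0 / (1.0 + amplitude))
    else:
        start = zs.lowest_stable()
        signal = signal_of(axis, amplitude)
    mid = _integrate_to(params, signal, start.state, horizon=sustain)
    end = _integrate_to(params, ZERO_SIGNAL, mid, horizon=settle)
    final = nearest_stable(zs, end, dims=tuple(solve_dims))
    return _log_dist(final.state, start.state, tuple(solve_dims)) > MERGE_RTOL


def switchability_scan(
    tables: Sequence[ReporterTable],
    K_s: float,
    Kg_values: Sequence[float],
    Kf_values: Sequence[float],
    amplitude: float = PHYSIOLOGICAL_AMPLITUDE,
    fold_notch: float = 3.5,
    fold_bmp4: float = 4.0,
    half_lives=None,
) -> pd.DataFrame:
    """Refit all free energies at each (K_g, K_f) grid point, recalibrate the
    promoter cooperativities, and classify whether physiological Notch and/or
    Bmp4 can irreversibly switch OFF -> ON.

    Returns a tidy frame with outcome in {both_switch, notch_only, bmp4_only,
    neither, infeasible}.
    """
    from .enhancers import calibrate_omegas
    from .triad import DEFAULT_HALF_LIVES

    half_lives = half_lives or DEFAULT_HALF_LIVES
    by_name = {t.enhancer: t for t in tables}
    scl = fit_enhancer(by_name["Scl+19"], K_s)
    bound_g = feasibility_bound(by_name["Gata2-3"])
    bound_f = feasibility_bound(by_name["Fli1+12"])

    recs = []
    for K_g in Kg_values:
        for K_f in Kf_values:
            if K_g <= bound_g or K_f <= bound_f:
                recs.append({"K_g": K_g, "K_f": K_f, "outcome": "infeasible"})
                continue
            try:
                gata = calibrate_omegas(
                    fit_enhancer(by_name["Gata2-3"], K_g),
                    fold_notch=fold_notch,
                    fold_bmp4=fold_bmp4,
                )
                fli = calibrate_omegas(
                    fit_enhancer(by_name["Fli1+12"], K_f), fold_bmp4=fold_bmp4
                )
            except InfeasibleFitError:
                recs.append({"K_g": K_g, "K_f": K_f, "outcome": "infeasible"})
                continue
            params = build_triad(scl, gata, fli, half_lives=half_lives)
            zs = find_steady_states(params)
            notch_ok = can_switch(params, "notch", amplitude, zero_sets=zs)
            bmp_ok = can_switch(params, "bmp4", amplitude, zero_sets=zs)
            outcome = {
                (True, True): "both_switch",
                (True, False): "notch_only",
                (False, True): "bmp4_only",
                (False, False): "neither",
            }[(notch_ok, bmp_ok)]
            recs.append({"K_g": K_g, "K_f": K_f, "outcome": outcome})
    return pd.DataFrame(recs)
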