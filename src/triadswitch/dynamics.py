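"""Time-domain response: pulses, minimum switching durations, low-pass curves.

A bistable switch ignores signal pulses shorter than a minimum duration --
low-pass filtering.  For the triad the OFF -> ON transition is rate-limited
by the slow accumulation of Scl (half-life 8 h, gamma_s = 1): Gata2 responds
to Notch within minutes, but the Scl-dependent enhancer configurations of
*Gata2-3* and *Fli1+12* only gain weight once Scl has built up, so the
system must hold the signal for a few Scl lifetimes before release leaves it
in the ON basin.  Deactivation by Gata1 bypasses Scl dynamics and is much
faster.

Durations are in dimensionless tau units (Scl mean lifetimes); multiply by
``params.hours_per_tau`` (~11.54 h) for hours.  Everything here is
deterministic: a pulse either switches or it does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .enhancers import SignalInput, ZERO_SIGNAL
from .steady import (
    MERGE_RTOL,
    SteadyStateSet,
    _dims,
    _log_dist,
    find_steady_states,
    nearest_stable,
    signal_of,
)
from .triad import TriadParameters, rhs

__all__ = [
    "Trajectory",
    "PulseSpec",
    "PulseResult",
    "integrate",
    "simulate_pulse",
    "min_pulse_duration",
    "filter_curve",
    "static_threshold",
    "match_reduced_module",
]

SETTLE_TAU = 200.0  # post-pulse integration horizon for basin classification
DURATION_TOL = 0.01  # tau; bisection tolerance on minimal pulse duration


def _pulse_signal(axis: str, amplitude: float) -> SignalInput:
    """Pulse amplitude -> signal.  The gata1 (deactivation) axis measures
    Gata1 strength a >= 0 phenomenologically as eta = 1/(1+a)."""
    if axis == "gata1":
        return SignalInput(eta=1.0 / (1.0 + amplitude))
    return signal_of(axis, amplitude)


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # shape (3, len(t)); rows x_s, x_g, x_f

    @property
    def final(self) -> tuple:
        return tuple(self.y[:, -1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x_s": self.y[0], "x_g": self.y[1], "x_f": self.y[2]}
        )

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            t=np.concatenate([self.t, other.t]),
            y=np.concatenate([self.y, other.y], axis=1),
        )


@dataclass(frozen=True)
class PulseSpec:
    """A rectangular signal pulse: amplitude for the given duration (tau),
    zero signal afterwards."""

    axis: str
    amplitude: float
    duration: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("pulse amplitude must be nonnegative")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass(frozen=True)
class PulseResult:
    switched: bool
    final_state: tuple
    trajectory: Trajectory
    t_acc: Optional[float]  # time for x_s to reach a fraction of its ON value


def integrate(
    params: TriadParameters,
    initial: Sequence[float],
    signal: SignalInput | Callable[[float], SignalInput] = ZERO_SIGNAL,
    horizon: float = 100.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Adaptive integration of the triad ODEs (LSODA, stiff-capable).

    ``signal`` is either a constant SignalInput or a callable t -> SignalInput
    (piecewise schedules are better integrated segment-by-segment)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if callable(signal):
        fun = lambda t, y: rhs(np.clip(y, 0.0, None), signal(t), params)
    else:
        fun = lambda t, y: rhs(np.clip(y, 0.0, None), signal, params)
    sol = solve_ivp(
        fun,
        (0.0, horizon),
        np.asarray(initial, float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    return Trajectory(t=sol.t, y=np.clip(sol.y, 0.0, None))


def simulate_pulse(
    params: TriadParameters,
    start: Sequence[float],
    pulse: PulseSpec,
    zero_sets: Optional[SteadyStateSet] = None,
    settle: float = SETTLE_TAU,
    acc_fraction: float = 0.5,
    rtol: float = 1e-8,
) -> PulseResult:
    """Apply a rectangular pulse from ``start`` and classify the outcome.

    After the pulse the system relaxes for ``settle`` tau at zero signal and
    is assigned to the nearest stable zero-signal steady state (log space).
    ``switched`` means that attractor differs from the start attractor.
    """
    zs = zero_sets or find_steady_states(params)
    _c, _z, solve_dims, _d = _dims(params)
    during = integrate(
        params, start, _pulse_signal(pulse.axis, pulse.amplitude),
        horizon=pulse.duration, rtol=rtol,
    )
    after = integrate(params, during.final, ZERO_SIGNAL, horizon=settle, rtol=rtol)
    traj = during.concat(
        Trajectory(t=after.t + pulse.duration, y=after.y)
    )
    dims = tuple(solve_dims)
    attractor = nearest_stable(zs, after.final, dims=dims)
    origin = nearest_stable(zs, start, dims=dims)
    if _log_dist(attractor.state, after.final, dims) > 0.5:
        raise RuntimeError(
            "unresolved basin membership: trajectory endpoint is far from "
            "every stable steady state"
        )
    switched = _log_dist(attractor.state, origin.state, dims) > MERGE_RTOL

    t_acc = None
    if switched and not params.clamped:
        target = acc_fraction * attractor.state[0]
        above = np.nonzero(traj.y[0] >= target)[0]
        if above.size:
            t_acc = float(traj.t[above[0]])
    return PulseResult(
        switched=switched, final_state=after.final, trajectory=traj, t_acc=t_acc
    )


def _switches(params, axis, amplitude, duration, start, zs, rtol=1e-8):
    res = simulate_pulse(
        params,
        start,
        PulseSpec(axis=axis, amplitude=amplitude, duration=duration),
        zero_sets=zs,
        rtol=rtol,
    )
    return res.switched


def min_pulse_duration(
    params: TriadParameters,
    axis: str,
    amplitude: float,
    direction: str = "on",
    tol: float = DURATION_TOL,
    zero_sets: Optional[SteadyStateSet] = None,
    max_duration: float = 500.0,
    rtol: float = 1e-8,
) -> float:
    """Minimal pulse duration (tau) for irreversible switching; ``math.inf``
    when no pulse of any length can switch at this amplitude.

    direction "on" pulses an activation signal from the OFF state;
    direction "off" pulses Gata1 (the eta axis) from the ON state.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if direction not in ("on", "off"):
        raise ValueError("direction must be 'on' or 'off'")
    if direction == "off" and axis != "gata1":
        raise ValueError("ON->OFF switching uses the gata1 (eta) axis")
    zs = zero_sets or find_steady_states(params)
    if len(zs.stable_points) < 2:
        return math.inf
    start = (zs.lowest_stable() if direction == "on" else zs.highest_stable()).state

    # Below the static threshold even a sustained signal cannot switch.
    if not _switches(params, axis, amplitude, max_duration, start, zs, rtol):
        return math.inf
    lo, hi = 0.0, 1.0
    while not _switches(params, axis, amplitude, hi, start, zs, rtol):
        lo, hi = hi, 2.0 * hi
        if hi > max_duration:
            return math.inf
    # Refine to the absolute tolerance and to 0.5% relative, so the reported
    # duration is sharp (a 1% shorter pulse fails, a 1% longer one switches).
    while hi - lo > min(tol, 5e-3 * hi):
        mid = 0.5 * (lo + hi)
        if _switches(params, axis, amplitude, mid, start, zs, rtol):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def filter_curve(
    params: TriadParameters,
    axis: str,
    amplitudes: Sequence[float],
    direction: str = "on",
    tol: float = DURATION_TOL,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Minimum-pulse-duration curve over a grid of amplitudes.

    Monotone nonincreasing in amplitude; diverges as the amplitude approaches
    the static switching threshold from above."""
    zs = find_steady_states(params)
    recs = []
    for a in amplitudes:
        d = min_pulse_duration(
            params, axis, a, direction=direction, tol=tol, zero_sets=zs, rtol=rtol
        )
        recs.append(
            {
                "amplitude": a,
                "min_duration_tau": d,
                "min_duration_hours": d * params.hours_per_tau,
            }
        )
    return pd.DataFrame(recs)


def static_threshold(
    params: TriadParameters,
    axis: str,
    direction: str = "on",
    hi: float = 1e6,
    rel_tol: float = 1e-3,
) -> float:
    """Saddle-node signal amplitude beyond which the starting branch no
    longer exists (the sustained-signal switching threshold): the system is
    bistable at zero signal and the starting branch folds where the stable
    count drops to one -- for activation the OFF branch vanishes, for
    deactivation (gata1 axis, amplitude a with eta = 1/(1+a)) the ON branch
    does.  Located by geometric bisection on the stable-state count."""
    zs = find_steady_states(params)
    if len(zs.stable_points) < 2:
        raise RuntimeError("system is not bistable at zero signal")
    warm = [p.state for p in zs.points]

    def bistable(value):
        sset = find_steady_states(
            params, _pulse_signal(axis, value), extra_starts=warm
        )
        return len(sset.stable_points) >= 2

    if bistable(hi):
        raise RuntimeError(f"both branches persist up to amplitude {hi}")
    lo = 1e-6
    if not bistable(lo):
        return lo / 2.0
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if bistable(mid):
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def match_reduced_module(
    params: TriadParameters,
    axis: str,
    clamp_lo: float = 1e-3,
    clamp_hi: float = 10.0,
    rel_tol: float = 1e-3,
) -> float:
    """Clamped Scl concentration at which the reduced module's saddle-node
    threshold on the given axis equals the full triad's.

    More Scl lowers the activation threshold (and raises the deactivation
    threshold), so the matching condition is monotone in the clamp and is
    solved by bisection.  Raises if no clamp in (clamp_lo, clamp_hi] matches.
    """
    from .triad import make_design, ModuleDesign

    direction = "off" if axis == "gata1" else "on"
    target = static_threshold(params, axis, direction=direction)

    def threshold_gap(clamp):
        reduced = make_design(params, ModuleDesign(kind="reduced", clamp=clamp))
        try:
            thr = static_threshold(reduced, axis, direction=direction)
        except RuntimeError:
            return None
        return math.log(thr / target)

    lo, hi = clamp_lo, clamp_hi
    g_lo, g_hi = threshold_gap(lo), threshold_gap(hi)
    # Walk the bracket inward past clamps where the reduced module is not
    # bistable at zero signal.
    while g_lo is None and lo * 1.5 < hi:
        lo *= 1.5
        g_lo = threshold_gap(lo)
    while g_hi is None and hi / 1.5 > lo:
        hi /= 1.5
        g_hi = threshold_gap(hi)
    if g_lo is None or g_hi is None or g_lo * g_hi > 0:
        raise RuntimeError(
            f"no clamp in ({clamp_lo}, {clamp_hi}] matches the full-triad "
            f"threshold on the {axis} axis"
        )
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        g_mid = threshold_gap(mid)
        if g_mid is None:
            raise RuntimeError("reduced module lost bistability inside the bracket")
        if (g_mid > 0) == (g_lo > 0):
            lo, g_lo = mid, g_mid
        else:
            hi, g_hi = mid, g_mid
    return math.sqrt(lo * hi)
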