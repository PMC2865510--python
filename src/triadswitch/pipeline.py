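"""End-to-end assembly: tables -> fitted enhancers -> calibrated triad.

The chromatin constants are the only free parameters after the exact fit.
``choose_K`` implements the "auto" rule: start each K at its feasibility
bound (the largest measured fold for that enhancer) times a small margin,
verify that both Notch and Bmp4 can irreversibly switch the module, and if
not, scan the margin upward until the first switchable value -- the
switchable region sits in a narrow band just above the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .enhancers import calibrate_omegas
from .fitting import ReporterTable, feasibility_bound, fit_enhancer
from .steady import PHYSIOLOGICAL_AMPLITUDE, can_switch, find_steady_states
from .triad import DEFAULT_HALF_LIVES, TriadParameters, build_triad

__all__ = ["FitResult", "fit_triad", "choose_K", "fit_reference_triad"]

AUTO_MARGIN = 1.05
SCAN_MARGINS = tuple(np.geomspace(1.01, 2.0, 25))
FOLD_NOTCH = 3.5
FOLD_BMP4 = 4.0


@dataclass(frozen=True)
class FitResult:
    params: TriadParameters
    K: dict  # enhancer name -> chromatin constant used
    margins: dict  # enhancer name -> K / feasibility bound
    switchable: bool


def _assemble(tables_by_name, K, half_lives, time_convention) -> TriadParameters:
    scl = fit_enhancer(tables_by_name["Scl+19"], K["Scl+19"])
    gata = calibrate_omegas(
        fit_enhancer(tables_by_name["Gata2-3"], K["Gata2-3"]),
        fold_notch=FOLD_NOTCH,
        fold_bmp4=FOLD_BMP4,
    )
    fli = calibrate_omegas(
        fit_enhancer(tables_by_name["Fli1+12"], K["Fli1+12"]), fold_bmp4=FOLD_BMP4
    )
    return build_triad(
        scl, gata, fli, half_lives=half_lives, time_convention=time_convention
    )


def _is_switchable(
    params: TriadParameters, amplitude: float = PHYSIOLOGICAL_AMPLITUDE
) -> bool:
    zs = find_steady_states(params)
    return can_switch(params, "notch", amplitude, zero_sets=zs) and can_switch(
        params, "bmp4", amplitude, zero_sets=zs
    )


def choose_K(
    tables: Sequence[ReporterTable],
    half_lives=DEFAULT_HALF_LIVES,
    time_convention: str = "mean_lifetime",
) -> FitResult:
    """Auto-select chromatin constants: bound x 1.05, scanned up to x 2 for
    the first margin at which both Notch and Bmp4 switch the triad."""
    by_name = {t.enhancer: t for t in tables}
    bounds = {name: feasibility_bound(t) for name, t in by_name.items()}
    for margin in (AUTO_MARGIN,) + SCAN_MARGINS:
        K = {name: b * margin for name, b in bounds.items()}
        params = _assemble(by_name, K, half_lives, time_convention)
        if _is_switchable(params):
            return FitResult(
                params=params,
                K=K,
                margins={name: margin for name in K},
                switchable=True,
            )
    # Fall back to the default margin, flagged unswitchable.
    K = {name: b * AUTO_MARGIN for name, b in bounds.items()}
    params = _assemble(by_name, K, half_lives, time_convention)
    return FitResult(
        params=params, K=K, margins={n: AUTO_MARGIN for n in K}, switchable=False
    )


def fit_triad(
    tables: Sequence[ReporterTable],
    K: Optional[dict] = None,
    half_lives=DEFAULT_HALF_LIVES,
    time_convention: str = "mean_lifetime",
) -> FitResult:
    """Fit the triad with explicit chromatin constants, or auto-select them
    (K=None or any value set to the string "auto")."""
    by_name = {t.enhancer: t for t in tables}
    missing = {"Scl+19", "Gata2-3", "Fli1+12"} - set(by_name)
    if missing:
        raise ValueError(f"missing reporter tables for {sorted(missing)}")
    if K is None or any(v == "auto" for v in (K or {}).values()):
        if K is None or all(v == "auto" for v in K.values()):
            return choose_K(tables, half_lives, time_convention)
        raise ValueError('mixed "auto"/numeric K values are not supported')
    params = _assemble(by_name, K, half_lives, time_convention)
    bounds = {name: feasibility_bound(t) for name, t in by_name.items()}
    return FitResult(
        params=params,
        K=dict(K),
        margins={n: K[n] / bounds[n] for n in K},
        switchable=_is_switchable(params),
    )


def fit_reference_triad(**kwargs) -> FitResult:
    """Fit the packaged reference library with auto-selected K."""
    from .synth import reference_library

    return fit_triad(reference_library(), **kwargs)
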