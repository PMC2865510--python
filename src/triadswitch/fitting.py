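"""Recursive closed-form estimation of configuration weights from reporter data.

A reporter library measures the fold enhancement ``F`` of expression for the
wild-type enhancer and for site-deletion constructs, each relative to an
enhancerless control.  Because ``F = K (1 + Z_b)/(K + Z_b)`` is invertible,

    Z_b = K (F - 1) / (K - F),

each construct pins down the weight sum of the configurations it retains.
Constructs ordered from single sites to full occupancy each introduce exactly
one new configuration, so the system is triangular and solves in closed form:
singles first, then composites by subtraction.  The fit is exact -- refitting
and re-simulating the constructs reproduces every measured fold value.

Feasibility requires ``K`` strictly above every measured fold (K is the
maximum possible enhancement) and every composite weight to be nonnegative
(a measured synergy below the additive expectation has no thermodynamic
solution and aborts with a structured error rather than being clamped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .enhancers import (
    CONFIG_TEMPLATES,
    REF_STATE,
    EnhancerModel,
    fold_enhancement,
    fli1p12_model,
    gata2m3_model,
    restrict_model,
    scl19_model,
)

__all__ = [
    "ReporterRow",
    "ReporterTable",
    "InfeasibleFitError",
    "invert_single",
    "feasibility_bound",
    "fit_scl19",
    "fit_gata2m3",
    "fit_fli1p12",
    "fit_enhancer",
    "fit_relaxed",
    "read_reporter_csv",
    "write_reporter_csv",
]

# Numerical slack when a composite weight comes out a hair below zero purely
# from floating-point subtraction (true weight zero); anything beyond this is
# a genuine infeasibility and raises.
_NEG_WEIGHT_RTOL = 1e-9

_BUILDERS = {
    "Scl+19": scl19_model,
    "Gata2-3": gata2m3_model,
    "Fli1+12": fli1p12_model,
}


class InfeasibleFitError(ValueError):
    """The reporter data admit no thermodynamic solution at the given K."""


@dataclass(frozen=True)
class ReporterRow:
    construct: str
    intact_sites: frozenset
    fold: float
    source: str = "measured"

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError(
                f"construct {self.construct!r}: fold enhancement must be > 0"
            )
        object.__setattr__(self, "intact_sites", frozenset(self.intact_sites))


@dataclass(frozen=True)
class ReporterTable:
    """Measured fold enhancements for one enhancer's construct library.

    The enhancerless reference (all sites deleted, fold 1) is implicit.
    """

    enhancer: str
    rows: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.enhancer not in CONFIG_TEMPLATES:
            raise ValueError(f"unknown enhancer {self.enhancer!r}")

    def fold_for(self, intact_sites) -> float:
        intact = frozenset(intact_sites)
        for row in self.rows:
            if row.intact_sites == intact:
                return row.fold
        raise KeyError(
            f"{self.enhancer}: no construct with intact sites {sorted(intact)}"
        )

    def wild_type(self) -> ReporterRow:
        return max(self.rows, key=lambda r: len(r.intact_sites))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enhancer": self.enhancer,
                "construct": [r.construct for r in self.rows],
                "intact_sites": [";".join(sorted(r.intact_sites)) for r in self.rows],
                "fold_enhancement": [r.fold for r in self.rows],
                "source": [r.source for r in self.rows],
            }
        )


def invert_single(F: float, K: float) -> float:
    """Unique bound-weight sum Z_b solving F = K(1+Z_b)/(K+Z_b).

    Round-trips with the fold-enhancement formula to machine precision.
    """
    if K <= 1:
        raise InfeasibleFitError(f"chromatin constant K must exceed 1, got {K}")
    if F < 1:
        raise InfeasibleFitError(
            f"fold enhancement {F} < 1: below the enhancerless baseline"
        )
    if F >= K:
        raise InfeasibleFitError(
            f"fold enhancement {F} is not achievable: the maximal possible "
            f"enhancement is K = {K}"
        )
    return K * (F - 1.0) / (K - F)


def feasibility_bound(table: ReporterTable) -> float:
    """Strict lower bound on K for this enhancer: the largest measured fold."""
    if not table.rows:
        raise ValueError("empty reporter table")
    return max(r.fold for r in table.rows)


def _fit_recursive(table: ReporterTable, K: float) -> dict:
    """Solve the triangular system construct-by-construct.

    Template order guarantees each construct introduces exactly one new
    configuration; its weight is the inverted weight sum minus the weights of
    the configurations already determined that survive in that construct.
    """
    template = CONFIG_TEMPLATES[table.enhancer]
    weights: dict = {}
    known = []  # (id, sites) already solved
    for cid, _stoich, sites in template:
        sites = frozenset(sites)
        F = table.fold_for(sites)
        z_total = invert_single(F, K)
        z_prev = sum(w for other_sites, w in known if other_sites <= sites)
        w = z_total - z_prev
        if w < 0:
            if z_total > 0 and -w <= _NEG_WEIGHT_RTOL * z_total:
                w = 0.0
            else:
                raise InfeasibleFitError(
                    f"{table.enhancer}: configuration {cid!r} requires negative "
                    f"weight {w:.6g} (measured synergy below the additive "
                    "expectation of its sub-configurations)"
                )
        weights[cid] = w
        known.append((sites, w))
    return weights


def _fit(table: ReporterTable, K: float, expected: str) -> EnhancerModel:
    if table.enhancer != expected:
        raise ValueError(f"expected a {expected} table, got {table.enhancer}")
    w = _fit_recursive(table, K)
    builder = _BUILDERS[expected]
    return builder(*(w[cid] for cid, _s, _t in CONFIG_TEMPLATES[expected]), K)


def fit_scl19(table: ReporterTable, K_s: float) -> EnhancerModel:
    """Fit *Scl+19* weights (w_G, w_FF, w_G.FF) from {G-only, FF-only, wt}."""
    return _fit(table, K_s, "Scl+19")


def fit_gata2m3(table: ReporterTable, K_g: float) -> EnhancerModel:
    """Fit *Gata2-3* weights from {G-only, FF-only, dScl (G+FF sites), wt}."""
    return _fit(table, K_g, "Gata2-3")


def fit_fli1p12(table: ReporterTable, K_f: float) -> EnhancerModel:
    """Fit *Fli1+12* weights from {primary-G-only, FF-only, both, wt}."""
    return _fit(table, K_f, "Fli1+12")


def fit_enhancer(table: ReporterTable, K: float) -> EnhancerModel:
    """Dispatch to the enhancer-specific exact fit."""
    return _fit(table, K, table.enhancer)


def fit_relaxed(table: ReporterTable, K: float, rtol: float = 1e-10) -> EnhancerModel:
    """Least-squares fit in log-fold space with nonnegative weights.

    For feasible tables this reproduces the exact recursion; for noisy or
    infeasible tables it returns the weights minimizing the summed squared
    log-ratio between modeled and measured fold values (folds are ratio-scale,
    so residuals live on the log scale).
    """
    from scipy.optimize import least_squares

    template = CONFIG_TEMPLATES[table.enhancer]
    builder = _BUILDERS[table.enhancer]
    rows = [(frozenset(s), table.fold_for(s)) for _cid, _st, s in template]

    def residuals(log_w):
        model = builder(*np.exp(log_w), K)
        out = []
        for sites, fold in rows:
            sub = restrict_model(model, sites)
            out.append(np.log(fold_enhancement(sub, REF_STATE)) - np.log(fold))
        return out

    try:
        exact = _fit_recursive(table, K)
        x0 = np.log([max(exact[cid], 1e-8) for cid, _s, _t in template])
    except InfeasibleFitError:
        x0 = np.zeros(len(template))
    sol = least_squares(residuals, x0, xtol=rtol, ftol=rtol, gtol=rtol)
    return builder(*np.exp(sol.x), K)


def fit_report(table: ReporterTable, model: EnhancerModel) -> pd.DataFrame:
    """Round-trip residual report: measured vs re-simulated fold values."""
    recs = []
    for row in table.rows:
        sub = restrict_model(model, row.intact_sites)
        pred = fold_enhancement(sub, REF_STATE)
        recs.append(
            {
                "enhancer": table.enhancer,
                "construct": row.construct,
                "measured": row.fold,
                "modeled": pred,
                "abs_residual": abs(pred - row.fold),
            }
        )
    return pd.DataFrame(recs)


def read_reporter_csv(path) -> list[ReporterTable]:
    """Read reporter tables from CSV with columns enhancer, construct,
    intact_sites (semicolon-joined), fold_enhancement[, source]."""
    df = pd.read_csv(path)
    required = {"enhancer", "construct", "intact_sites", "fold_enhancement"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reporter CSV is missing columns {sorted(missing)}")
    tables = []
    for name, group in df.groupby("enhancer", sort=False):
        rows = []
        for _, r in group.iterrows():
            raw = r["intact_sites"]
            if pd.isna(raw):
                sites = frozenset()
            else:
                sites = frozenset(s for s in str(raw).split(";") if s)
            rows.append(
                ReporterRow(
                    construct=str(r["construct"]),
                    intact_sites=sites,
                    fold=float(r["fold_enhancement"]),
                    source=str(r.get("source", "measured")),
                )
            )
        tables.append(ReporterTable(enhancer=str(name), rows=tuple(rows)))
    return tables


def write_reporter_csv(tables: Iterable[ReporterTable], path) -> None:
    pd.concat([t.to_dataframe() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )
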