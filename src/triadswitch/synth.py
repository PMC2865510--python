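"""Synthetic enhancer-reporter libraries and the packaged reference fixture.

``generate_truth`` draws a ground-truth parameter set (configuration weights
log-uniform in [1e-1, 1e4]; chromatin constants log-uniform in [10, 1e4],
the range reported for nucleosome-unwrapping equilibria) and
``generate_library`` turns it into the reporter tables the fitting recursion
needs, optionally with multiplicative lognormal measurement noise (reporter
intensities are ratio-scale, so noise acts on the log of the fold value).
At sigma = 0 the fit recovers the truth exactly, which makes the whole
pipeline testable end to end without any external data.

Feasibility of a truth is enforced as ``K > 1 + Z_wt`` (the enhancer operates
below chromatin saturation).  The naive reading "K exceeds the wild-type fold
enhancement" is vacuous -- the model guarantees F < K -- whereas keeping the
enhancer unsaturated both matches the regime the real enhancers were fitted
in and keeps the closed-form inversion well conditioned.

``reference_library`` packages the published anchor measurements (wild-type
*Scl+19* at 820.51-fold; *Fli1+12* at ~60-fold full and ~20-fold for the
primary-GATA + ETS construct) together with clearly flagged synthetic
placeholder values for the single-site constructs whose exact measurements
are not reprinted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhancers import (
    CONFIG_TEMPLATES,
    REF_STATE,
    EnhancerModel,
    bound_weight_sum,
    fold_enhancement,
    fli1p12_model,
    gata2m3_model,
    restrict_model,
    scl19_model,
)
from .fitting import ReporterRow, ReporterTable

__all__ = [
    "GroundTruth",
    "generate_truth",
    "generate_library",
    "reference_library",
]

_BUILDERS = {
    "Scl+19": scl19_model,
    "Gata2-3": gata2m3_model,
    "Fli1+12": fli1p12_model,
}

WEIGHT_RANGE = (1e-1, 1e4)
K_RANGE = (10.0, 1e4)


@dataclass(frozen=True)
class GroundTruth:
    """Known enhancer models plus the noise level and seed that generated
    them; every downstream random draw is a pure function of the seed."""

    models: dict  # enhancer name -> EnhancerModel
    sigma: float
    seed: int

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def _sample_enhancer(name: str, rng: np.random.Generator) -> EnhancerModel:
    n_cfg = len(CONFIG_TEMPLATES[name])
    lo_w, hi_w = np.log(WEIGHT_RANGE)
    lo_k, hi_k = np.log(K_RANGE)
    for _ in range(10_000):
        weights = np.exp(rng.uniform(lo_w, hi_w, size=n_cfg))
        K = float(np.exp(rng.uniform(lo_k, hi_k)))
        model = _BUILDERS[name](*weights, K)
        # Feasible: enhancer below chromatin saturation at the reference state.
        if K > 1.0 + bound_weight_sum(model, REF_STATE):
            return model
    raise RuntimeError("failed to sample a feasible enhancer model")


def generate_truth(seed: int, sigma: float = 0.0) -> GroundTruth:
    """Deterministically sample a feasible ground-truth parameter set."""
    rng = np.random.default_rng(seed)
    models = {name: _sample_enhancer(name, rng) for name in _BUILDERS}
    return GroundTruth(models=models, sigma=float(sigma), seed=int(seed))


def _construct_rows(model: EnhancerModel, noise):
    """The construct set the fit recursion requires: one per configuration,
    each with exactly that configuration's sites intact (recursion order),
    the last being the wild type."""
    rows = []
    template = CONFIG_TEMPLATES[model.name]
    for i, (cid, _stoich, sites) in enumerate(template):
        sites = frozenset(sites)
        sub = restrict_model(model, sites)
        fold = fold_enhancement(sub, REF_STATE) * noise(i)
        label = "wt" if len(sites) == len(model.sites) else f"only:{'+'.join(sorted(sites))}"
        rows.append(
            ReporterRow(
                construct=label, intact_sites=sites, fold=fold, source="synthetic"
            )
        )
    return rows


def generate_library(truth: GroundTruth) -> list[ReporterTable]:
    """Emit the three reporter tables implied by a ground truth.

    Fold values are computed at the wild-type reference state and multiplied
    by exp(sigma * z), z standard normal; sigma = 0 gives exact values.
    Reproducible: the noise stream is derived from the truth's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    tables = []
    for name, model in truth.models.items():
        if truth.sigma > 0:
            draws = rng.standard_normal(len(model.configurations))
            noise = lambda i, d=draws: float(np.exp(truth.sigma * d[i]))
        else:
            noise = lambda i: 1.0
        tables.append(
            ReporterTable(enhancer=name, rows=tuple(_construct_rows(model, noise)))
        )
    return tables


# --- packaged reference fixture ------------------------------------------

# Published anchors: Scl+19 wild type 820.51-fold; Fli1+12 wild type ~60-fold
# and ~20-fold once the E-BOX and secondary GATA sites are deleted.  The
# single-site constructs below are synthetic placeholders standing in for the
# unpublished library cells and are flagged as such.
_REFERENCE_ROWS = {
    "Scl+19": (
        ("only:GATA", {"GATA"}, 40.0, "placeholder"),
        ("only:ETS", {"ETS"}, 60.0, "placeholder"),
        ("wt", {"GATA", "ETS"}, 820.51, "reported"),
    ),
    "Gata2-3": (
        ("only:GATA", {"GATA"}, 15.0, "placeholder"),
        ("only:ETS", {"ETS"}, 25.0, "placeholder"),
        ("dEbox", {"GATA", "ETS"}, 150.0, "placeholder"),
        ("wt", {"GATA", "ETS", "E-BOX"}, 500.0, "placeholder"),
    ),
    "Fli1+12": (
        ("only:GATAp", {"GATA-primary"}, 5.0, "placeholder"),
        ("only:ETS", {"ETS"}, 8.0, "placeholder"),
        ("dEbox+dGATAs", {"GATA-primary", "ETS"}, 20.0, "reported"),
        ("wt", {"GATA-primary", "ETS", "E-BOX", "GATA-secondary"}, 60.0, "reported"),
    ),
}


def reference_library() -> list[ReporterTable]:
    """The packaged enhancer-reporter fixture (anchors + placeholders)."""
    tables = []
    for name, rows in _REFERENCE_ROWS.items():
        tables.append(
            ReporterTable(
                enhancer=name,
                rows=tuple(
                    ReporterRow(
                        construct=c, intact_sites=frozenset(s), fold=f, source=src
                    )
                    for c, s, f, src in rows
                ),
            )
        )
    return tables
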