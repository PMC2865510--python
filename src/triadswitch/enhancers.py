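"""Statistical-thermodynamic models of the triad enhancers.

Each enhancer (*Scl+19*, *Gata2-3*, *Fli1+12*) is described by the set of
transcriptional-regulator (TR) binding configurations that measurably affect
reporter expression, a Boltzmann weight per configuration, and a chromatin
equilibrium constant ``K`` governing the closed/open competition.  Chromatin
can spontaneously unwrap from a closed (inaccessible) to an open state; bound
TRs trap the open state (ratchet mechanism), so the probability of the open
state -- and hence of transcription -- increases with TR occupancy.

With the open, empty-enhancer state taken as the zero of free energy and the
closed state carrying statistical weight ``K - 1``, the probability of open
chromatin is ``(1 + Z_b) / (K + Z_b)`` where ``Z_b`` is the bound-state weight
sum.  Relative to an enhancerless construct (``Z_b = 0``) the fold enhancement
of expression is ``F = K (1 + Z_b) / (K + Z_b)``, bounded by ``K``: the
chromatin constant *is* the maximum possible fold enhancement.

Signals act at the promoters: Notch and Bmp4 bind cooperatively with RNA
polymerase (interaction factors ``omega_N``, ``omega_B``), and the Gata1
repressor is represented phenomenologically by a factor ``eta`` in (0, 1]
multiplying Gata2 transcription.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "TR_NAMES",
    "NOTCH",
    "BMP4",
    "REF_STATE",
    "BindingConfiguration",
    "EnhancerModel",
    "SignalInput",
    "ZERO_SIGNAL",
    "CONFIG_TEMPLATES",
    "ENHANCER_SITES",
    "scl19_model",
    "gata2m3_model",
    "fli1p12_model",
    "restrict_model",
    "bound_weight_sum",
    "fold_enhancement",
    "transcription_factor",
    "calibrate_omegas",
]

TR_NAMES = ("Scl", "Gata2", "Fli1")
NOTCH = "Notch"
BMP4 = "Bmp4"

#: Wild-type HSC reference state: concentrations are normalized so that the
#: actively expressing stem-cell steady state sits at (x_s, x_g, x_f) = (1,1,1).
REF_STATE = (1.0, 1.0, 1.0)


class InfeasibleModelError(ValueError):
    """A parameter combination violates the thermodynamic model's constraints."""


@dataclass(frozen=True)
class BindingConfiguration:
    """One TR-binding configuration of an enhancer.

    The weight is the dimensionless Boltzmann factor of the configuration at
    the wild-type reference concentrations, i.e. ``exp(-dG)`` with the free
    energy adjusted for concentration entropy and including any TR-TR
    interaction energy (e.g. the Gata2/Fli1-dimer contact).  ``sites`` lists
    the enhancer binding sites the configuration requires; deleting any of
    them eliminates the configuration.
    """

    id: str
    stoichiometry: Mapping[str, int]
    weight: float
    sites: frozenset = frozenset()

    def __post_init__(self):
        if self.weight < 0:
            raise InfeasibleModelError(
                f"configuration {self.id!r}: weight must be >= 0, got {self.weight}"
            )
        stoich = dict(self.stoichiometry)
        if not stoich or all(v == 0 for v in stoich.values()):
            raise InfeasibleModelError(
                f"configuration {self.id!r}: at least one TR copy required"
            )
        for name, copies in stoich.items():
            if name not in TR_NAMES:
                raise InfeasibleModelError(f"unknown TR {name!r}")
            if not isinstance(copies, int) or copies < 0:
                raise InfeasibleModelError(
                    f"configuration {self.id!r}: copy number for {name} must be a "
                    f"nonnegative integer, got {copies!r}"
                )
        # Fli1 binds its ETS sites as a dimer, so it always enters in pairs.
        if stoich.get("Fli1", 0) % 2 != 0:
            raise InfeasibleModelError(
                f"configuration {self.id!r}: Fli1 binds as a dimer (even copy number)"
            )
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "sites", frozenset(self.sites))

    def monomial(self, state: Sequence[float]) -> float:
        """Concentration factor prod_T x_T^stoich at the given state."""
        x = dict(zip(TR_NAMES, state))
        out = 1.0
        for name, copies in self.stoichiometry.items():
            if copies:
                out *= x[name] ** copies
        return out


@dataclass(frozen=True)
class EnhancerModel:
    """An enhancer's configurations, chromatin constant and promoter cofactors.

    ``K`` is dimensionless and equals the maximum possible fold enhancement.
    ``cofactors`` are the promoter-acting signals (Notch and/or Bmp4) relevant
    to the regulated gene; ``omega`` holds their polymerase-interaction
    factors.  ``gata1_sensitive`` marks the *Gata2-3* enhancer, whose output
    is scaled by the Gata1 factor eta.
    """

    name: str
    configurations: tuple
    K: float
    cofactors: tuple = ()
    omega: Mapping[str, float] = field(default_factory=dict)
    gata1_sensitive: bool = False
    sites: tuple = ()

    def __post_init__(self):
        if self.K <= 1:
            raise InfeasibleModelError(
                f"enhancer {self.name!r}: chromatin constant K must exceed 1, got {self.K}"
            )
        object.__setattr__(self, "configurations", tuple(self.configurations))
        object.__setattr__(self, "cofactors", tuple(self.cofactors))
        object.__setattr__(self, "omega", dict(self.omega))
        object.__setattr__(self, "sites", tuple(self.sites))
        for c in self.cofactors:
            if c not in (NOTCH, BMP4):
                raise InfeasibleModelError(f"unknown promoter cofactor {c!r}")

    def weights(self) -> dict:
        return {c.id: c.weight for c in self.configurations}

    def energies(self) -> dict:
        """Concentration-adjusted free energies, -ln(weight), for display."""
        return {
            c.id: (math.inf if c.weight == 0 else -math.log(c.weight))
            for c in self.configurations
        }

    def with_weights(self, weights: Mapping[str, float]) -> "EnhancerModel":
        new = tuple(
            replace(c, weight=float(weights.get(c.id, c.weight)))
            for c in self.configurations
        )
        return replace(self, configurations=new)


@dataclass(frozen=True)
class SignalInput:
    """Promoter signals: Notch ``n`` and Bmp4 ``b`` concentrations (normalized
    by their promoter dissociation constants) and the Gata1 repression factor
    ``eta`` in (0, 1]; ``eta = 1`` means no Gata1."""

    n: float = 0.0
    b: float = 0.0
    eta: float = 1.0

    def __post_init__(self):
        if self.n < 0 or self.b < 0:
            raise ValueError("signal concentrations must be nonnegative")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must lie in (0, 1], got {self.eta}")


ZERO_SIGNAL = SignalInput()

# Binding-site inventories (Fig 1B-style): which sites each enhancer carries.
ENHANCER_SITES = {
    "Scl+19": ("GATA", "ETS"),
    "Gata2-3": ("GATA", "ETS", "E-BOX"),
    "Fli1+12": ("GATA-primary", "ETS", "E-BOX", "GATA-secondary"),
}

# Configuration templates: (id, stoichiometry, required sites), ordered by the
# recursion used for fitting (single sites first, full occupancy last).
CONFIG_TEMPLATES = {
    "Scl+19": (
        ("G", {"Gata2": 1}, {"GATA"}),
        ("FF", {"Fli1": 2}, {"ETS"}),
        ("G.FF", {"Gata2": 1, "Fli1": 2}, {"GATA", "ETS"}),
    ),
    "Gata2-3": (
        ("G", {"Gata2": 1}, {"GATA"}),
        ("FF", {"Fli1": 2}, {"ETS"}),
        ("G.FF", {"Gata2": 1, "Fli1": 2}, {"GATA", "ETS"}),
        ("S.G.FF", {"Scl": 1, "Gata2": 1, "Fli1": 2}, {"GATA", "ETS", "E-BOX"}),
    ),
    "Fli1+12": (
        ("G", {"Gata2": 1}, {"GATA-primary"}),
        ("FF", {"Fli1": 2}, {"ETS"}),
        ("G.FF", {"Gata2": 1, "Fli1": 2}, {"GATA-primary", "ETS"}),
        (
            "G.S.FF.G",
            {"Scl": 1, "Gata2": 2, "Fli1": 2},
            {"GATA-primary", "ETS", "E-BOX", "GATA-secondary"},
        ),
    ),
}


def _build(name, weights, K, cofactors, gata1_sensitive, omega=None):
    template = CONFIG_TEMPLATES[name]
    ids = [t[0] for t in template]
    if set(weights) != set(ids):
        raise InfeasibleModelError(
            f"enhancer {name!r} expects weights for {ids}, got {sorted(weights)}"
        )
    configs = tuple(
        BindingConfiguration(cid, stoich, float(weights[cid]), frozenset(sites))
        for cid, stoich, sites in template
    )
    return EnhancerModel(
        name=name,
        configurations=configs,
        K=float(K),
        cofactors=cofactors,
        omega=omega or {c: 1.0 for c in cofactors},
        gata1_sensitive=gata1_sensitive,
        sites=ENHANCER_SITES[name],
    )


def scl19_model(w_g: float, w_ff: float, w_gff: float, K: float) -> EnhancerModel:
    """*Scl+19*: Gata2 site + Fli1-dimer (ETS) site; no promoter cofactors."""
    return _build("Scl+19", {"G": w_g, "FF": w_ff, "G.FF": w_gff}, K, (), False)


def gata2m3_model(
    w_g: float, w_ff: float, w_gff: float, w_sgff: float, K: float, omega=None
) -> EnhancerModel:
    """*Gata2-3*: Gata2, Fli1-dimer and Scl (E-BOX) sites; Notch and Bmp4 act
    at the Gata2 promoter, and the enhancer is Gata1-sensitive."""
    return _build(
        "Gata2-3",
        {"G": w_g, "FF": w_ff, "G.FF": w_gff, "S.G.FF": w_sgff},
        K,
        (NOTCH, BMP4),
        True,
        omega,
    )


def fli1p12_model(
    w_g: float, w_ff: float, w_gff: float, w_gsffg: float, K: float, omega=None
) -> EnhancerModel:
    """*Fli1+12*: primary/secondary Gata2 sites, Fli1-dimer site, Scl site;
    Bmp4 acts at the Fli1 promoter."""
    return _build(
        "Fli1+12",
        {"G": w_g, "FF": w_ff, "G.FF": w_gff, "G.S.FF.G": w_gsffg},
        K,
        (BMP4,),
        False,
        omega,
    )


def restrict_model(model: EnhancerModel, intact_sites) -> EnhancerModel:
    """Model of a site-deletion construct: keep only configurations whose
    required sites are all intact (cascade removal)."""
    intact = frozenset(intact_sites)
    unknown = intact - set(model.sites)
    if unknown:
        raise ValueError(f"unknown sites for {model.name}: {sorted(unknown)}")
    kept = tuple(c for c in model.configurations if c.sites <= intact)
    return replace(model, configurations=kept)


def _check_state(state):
    if len(state) != 3:
        raise ValueError("state must be (x_s, x_g, x_f)")
    if any(x < 0 for x in state):
        raise ValueError(f"state components must be nonnegative, got {tuple(state)}")


def bound_weight_sum(model: EnhancerModel, state: Sequence[float]) -> float:
    """Bound-configuration weight sum Z_b = sum_c w_c prod_T x_T^stoich."""
    _check_state(state)
    return sum(c.weight * c.monomial(state) for c in model.configurations)


def fold_enhancement(model: EnhancerModel, state: Sequence[float]) -> float:
    """Reporter fold enhancement relative to the enhancerless construct,
    F = K (1 + Z_b) / (K + Z_b), bounded in [1, K)."""
    zb = bound_weight_sum(model, state)
    return model.K * (1.0 + zb) / (model.K + zb)


def _signal_terms(model: EnhancerModel, signal: SignalInput):
    n = signal.n if NOTCH in model.cofactors else 0.0
    b = signal.b if BMP4 in model.cofactors else 0.0
    wn = model.omega.get(NOTCH, 1.0)
    wb = model.omega.get(BMP4, 1.0)
    return n, b, wn, wb


def transcription_factor(
    model: EnhancerModel, state: Sequence[float], signal: SignalInput = ZERO_SIGNAL
) -> float:
    """Dimensionless transcription rate f (promoter occupancy by polymerase,
    up to the constant maximal open-state rate).

    ``f = eta_eff (1+Z_b)(1 + omega_N n + omega_B b) /
    (K - 1 + (1+Z_b)(1 + n + b))`` with the n/b terms present only for the
    model's promoter cofactors and eta applied only at *Gata2-3*.  At zero
    signal this reduces to ``fold_enhancement / K``.
    """
    zb = bound_weight_sum(model, state)
    n, b, wn, wb = _signal_terms(model, signal)
    eta_eff = signal.eta if model.gata1_sensitive else 1.0
    num = (1.0 + zb) * (1.0 + wn * n + wb * b)
    den = model.K - 1.0 + (1.0 + zb) * (1.0 + n + b)
    return eta_eff * num / den


def saturating_fold(model: EnhancerModel, state, cofactor: str) -> float:
    """Ratio f(signal -> infinity)/f(0) for one promoter cofactor; the
    saturating limit is omega (K + Z_b)/(1 + Z_b)."""
    zb = bound_weight_sum(model, state)
    return model.omega[cofactor] * (model.K + zb) / (1.0 + zb)


def calibrate_omegas(
    model: EnhancerModel,
    wt_state: Sequence[float] = REF_STATE,
    fold_notch: float | None = None,
    fold_bmp4: float | None = None,
) -> EnhancerModel:
    """Set omega so that the saturating-signal fold increase of transcription
    at the wild-type state equals the given values (3.5x for Notch and 4x for
    Bmp4 on Gata2 in wild-type HSCs).

    The saturating ratio is ``omega (K + Z_b)/(1 + Z_b)``, so
    ``omega = fold (1 + Z_b)/(K + Z_b)``.
    """
    zb = bound_weight_sum(model, wt_state)
    omega = dict(model.omega)
    for cofactor, fold in ((NOTCH, fold_notch), (BMP4, fold_bmp4)):
        if fold is None:
            continue
        if cofactor not in model.cofactors:
            raise InfeasibleModelError(
                f"{model.name} has no {cofactor} promoter cofactor to calibrate"
            )
        if fold <= 0:
            raise InfeasibleModelError(f"{cofactor} fold must be positive, got {fold}")
        w = fold * (1.0 + zb) / (model.K + zb)
        if w <= 0:
            raise InfeasibleModelError(
                f"calibrated omega for {cofactor} is nonpositive ({w})"
            )
        if w <= 1:
            warnings.warn(
                f"calibrated omega_{cofactor} = {w:.4g} <= 1: repression-like "
                "polymerase interaction (the model assumes activation)",
                stacklevel=2,
            )
        omega[cofactor] = w
    return replace(model, omega=omega)
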