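"""Dimensionless ODE model of the Scl-Gata2-Fli1 triad and its mutant designs.

The state ``x = (x_s, x_g, x_f)`` holds TR concentrations in units of their
wild-type HSC steady-state values, so the actively expressing stem cell sits
at (1, 1, 1).  With first-order degradation and time measured in units of the
Scl protein lifetime, the dynamics are

    dx_i/dtau = gamma_i (s_i f_i(x, signal) / f_i^wt - x_i),

where ``f_i`` is the enhancer transcription factor of gene i, ``f_i^wt`` its
zero-signal value at (1,1,1) (so the wild-type state is always a zero-signal
equilibrium), ``gamma_i`` the degradation-rate ratio relative to Scl
(gamma_s = 1) and ``s_i`` a production scale (1 wild-type, 0.5 heterozygote,
0 knockout).  Reported half-lives of 8 h (Scl), ~10 min (Gata2) and 2 h
(Fli1) give gamma = (1, 48, 4): Gata2 tracks its transcription rate almost
instantaneously while Scl integrates slowly -- the origin of the triad's
low-pass filtering.

Mutant designs modify the wild-type parameter set without refitting: enhancer
site deletions cascade-remove every configuration that requires a deleted
site; knockouts/heterozygotes scale production; the reduced module clamps
x_s to a constant (Scl under external control, its enhancer feedback cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .enhancers import (
    REF_STATE,
    ZERO_SIGNAL,
    EnhancerModel,
    SignalInput,
    restrict_model,
    transcription_factor,
)

__all__ = [
    "GENES",
    "DEFAULT_HALF_LIVES",
    "TriadParameters",
    "ModuleDesign",
    "build_triad",
    "derive_gammas",
    "hours_per_tau",
    "rhs",
    "make_design",
    "parse_design",
    "enumerate_mutant_designs",
]

GENES = ("Scl", "Gata2", "Fli1")

#: Protein half-lives in hours (Scl, Gata2, Fli1): 8 h, ~10 min, 2 h.
DEFAULT_HALF_LIVES = (8.0, 1.0 / 6.0, 2.0)

_ENHANCER_KEYS = {"scl19": "Scl+19", "gata2m3": "Gata2-3", "fli1p12": "Fli1+12"}
_SITE_KEYS = {
    "dGATA": "GATA",
    "dETS": "ETS",
    "dEbox": "E-BOX",
    "dGATAp": "GATA-primary",
    "dGATAs": "GATA-secondary",
}


def derive_gammas(half_lives: Sequence[float]) -> tuple:
    """Degradation-rate ratios gamma_i = t_half(Scl) / t_half(i); gamma_s = 1."""
    if len(half_lives) != 3:
        raise ValueError("expected (Scl, Gata2, Fli1) half-lives")
    if any(h <= 0 for h in half_lives):
        raise ValueError(f"half-lives must be positive, got {tuple(half_lives)}")
    h_s = half_lives[0]
    return tuple(h_s / h for h in half_lives)


def hours_per_tau(
    scl_half_life: float = DEFAULT_HALF_LIVES[0], convention: str = "mean_lifetime"
) -> float:
    """Hours per dimensionless time unit tau.

    With ``convention="mean_lifetime"`` (default) tau is the Scl mean protein
    lifetime t_half/ln 2 (~11.54 h), which makes Scl's dimensionless decay
    rate exactly 1; ``"half_life"`` uses the half-life itself.
    """
    if convention == "mean_lifetime":
        return scl_half_life / math.log(2.0)
    if convention == "half_life":
        return scl_half_life
    raise ValueError(f"unknown time convention {convention!r}")


@dataclass(frozen=True)
class TriadParameters:
    """Complete parameter set of the triad ODE system.

    ``models`` maps each gene to the enhancer model driving it.  ``wt_rates``
    are the wild-type zero-signal transcription factors used for
    normalization; mutant designs deliberately retain the wild-type values so
    that their steady states are directly comparable.
    """

    models: dict
    gamma: tuple = (1.0, 48.0, 4.0)
    wt_rates: tuple = ()
    production_scale: tuple = (1.0, 1.0, 1.0)
    clamp_xs: Optional[float] = None
    hours_per_tau: float = hours_per_tau()

    def __post_init__(self):
        if set(self.models) != set(GENES):
            raise ValueError(f"models must be keyed by {GENES}")
        if self.gamma[0] != 1.0:
            raise ValueError("gamma_s must be 1 (time is normalized to Scl)")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("gamma values must be positive")
        if not self.wt_rates:
            wt = tuple(
                transcription_factor(self.models[g], REF_STATE, ZERO_SIGNAL)
                for g in GENES
            )
            object.__setattr__(self, "wt_rates", wt)
        if any(f <= 0 for f in self.wt_rates):
            raise ValueError("wild-type transcription factors must be positive")

    @property
    def clamped(self) -> bool:
        return self.clamp_xs is not None

    def effective_state(self, state: Sequence[float]) -> tuple:
        if self.clamped:
            return (self.clamp_xs, state[1], state[2])
        return tuple(state)


def build_triad(
    scl19: EnhancerModel,
    gata2m3: EnhancerModel,
    fli1p12: EnhancerModel,
    half_lives: Sequence[float] = DEFAULT_HALF_LIVES,
    time_convention: str = "mean_lifetime",
) -> TriadParameters:
    """Assemble triad parameters from the three fitted enhancer models."""
    return TriadParameters(
        models={"Scl": scl19, "Gata2": gata2m3, "Fli1": fli1p12},
        gamma=derive_gammas(half_lives),
        hours_per_tau=hours_per_tau(half_lives[0], time_convention),
    )


def rhs(
    state: Sequence[float],
    signal: SignalInput,
    params: TriadParameters,
) -> tuple:
    """Time derivatives (dx_s, dx_g, dx_f)/dtau.

    For the reduced module (clamped x_s) the Scl derivative is zero and all
    transcription factors see the clamped Scl concentration.
    """
    x = params.effective_state(state)
    rates = []
    for i, gene in enumerate(GENES):
        f = transcription_factor(params.models[gene], x, signal)
        prod = params.production_scale[i] * f / params.wt_rates[i]
        rates.append(params.gamma[i] * (prod - x[i]))
    if params.clamped:
        rates[0] = 0.0
    return tuple(rates)


@dataclass(frozen=True)
class ModuleDesign:
    """A modification of the wild-type triad.

    kind: one of wildtype, site_deletion, knockout, heterozygote, reduced.
    site_deletions: (enhancer name, site) pairs for site_deletion designs.
    gene: target gene for knockout/heterozygote.
    clamp: fixed x_s for the reduced module.
    """

    kind: str
    site_deletions: tuple = ()
    gene: Optional[str] = None
    clamp: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in (
            "wildtype",
            "site_deletion",
            "knockout",
            "heterozygote",
            "reduced",
        ):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "site_deletion":
            inv = {v: k for k, v in _ENHANCER_KEYS.items()}
            sk = {v: k for k, v in _SITE_KEYS.items()}
            return "+".join(f"{inv[e]}:{sk[s]}" for e, s in self.site_deletions)
        if self.kind in ("knockout", "heterozygote"):
            return f"{'ko' if self.kind == 'knockout' else 'het'}:{self.gene}"
        if self.kind == "reduced":
            return f"reduced:xs={self.clamp}"
        return "wildtype"

    def mutated_enhancers(self) -> set:
        return {e for e, _ in self.site_deletions}


def parse_design(key: str) -> ModuleDesign:
    """Parse string keys like ``fli1p12:dEbox``, ``scl19:dGATA+gata2m3:dEbox``,
    ``ko:Scl``, ``het:Gata2`` or ``reduced:xs=0.8``."""
    key = key.strip()
    if key == "wildtype":
        return ModuleDesign(kind="wildtype")
    if key.startswith("ko:") or key.startswith("het:"):
        prefix, gene = key.split(":", 1)
        if gene not in GENES:
            raise ValueError(f"unknown gene {gene!r}")
        kind = "knockout" if prefix == "ko" else "heterozygote"
        return ModuleDesign(kind=kind, gene=gene)
    if key.startswith("reduced:"):
        spec = key.split(":", 1)[1]
        if not spec.startswith("xs="):
            raise ValueError(f"reduced design must give xs=<value>, got {key!r}")
        return ModuleDesign(kind="reduced", clamp=float(spec[3:]))
    from .enhancers import ENHANCER_SITES

    deletions = []
    for part in key.split("+"):
        try:
            enh_key, site_key = part.split(":")
            enh, site = _ENHANCER_KEYS[enh_key], _SITE_KEYS[site_key]
        except (ValueError, KeyError):
            raise ValueError(f"unknown design key {part!r}") from None
        if site not in ENHANCER_SITES[enh]:
            raise ValueError(f"{enh} has no {site} site ({part!r})")
        deletions.append((enh, site))
    return ModuleDesign(kind="site_deletion", site_deletions=tuple(deletions))


def make_design(params: TriadParameters, design: ModuleDesign) -> TriadParameters:
    """Apply a design to wild-type parameters.

    Normalization constants (wt_rates) are retained from the wild type, so a
    mutant generally does not have (1,1,1) as a steady state.
    """
    if design.kind == "wildtype":
        return params
    if design.kind == "site_deletion":
        models = dict(params.models)
        gene_of = {m.name: g for g, m in params.models.items()}
        for enh_name, site in design.site_deletions:
            if enh_name not in gene_of:
                raise ValueError(f"unknown enhancer {enh_name!r}")
            gene = gene_of[enh_name]
            model = models[gene]
            if site not in model.sites:
                raise ValueError(f"{enh_name} has no site {site!r}")
            intact = set(model.sites) - {site}
            models[gene] = restrict_model(model, intact)
        return replace(params, models=models)
    if design.kind in ("knockout", "heterozygote"):
        scale = list(params.production_scale)
        factor = 0.0 if design.kind == "knockout" else 0.5
        scale[GENES.index(design.gene)] = factor
        return replace(params, production_scale=tuple(scale))
    if design.kind == "reduced":
        return replace(params, clamp_xs=float(design.clamp))
    raise ValueError(f"unknown design kind {design.kind!r}")


#: The 10 single/double enhancer-site-deletion designs analyzed for their
#: steady-state phenotype: 6 mutate Scl+19 or Gata2-3 (all lose the high
#: expression state) and 4 mutate only Fli1+12 (a high state survives).
_MUTANT_DESIGN_KEYS = (
    "scl19:dGATA",
    "scl19:dETS",
    "gata2m3:dGATA",
    "gata2m3:dETS",
    "gata2m3:dEbox",
    "scl19:dGATA+gata2m3:dEbox",
    "fli1p12:dEbox",
    "fli1p12:dGATAs",
    "fli1p12:dETS",
    "fli1p12:dGATAp",
)


def enumerate_mutant_designs() -> list:
    """The stable enumeration of the 10 site-deletion module designs."""
    return [parse_design(k) for k in _MUTANT_DESIGN_KEYS]
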