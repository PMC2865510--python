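# Methods

## Enhancer thermodynamics

Each enhancer is modelled as a two-level equilibrium.  Chromatin is either
closed (nucleosome-wrapped, no binding of any factor) or open; transcriptional
regulators bound at the open enhancer trap the unwrapped state.  Free energies
are measured in units of kT with the open, empty enhancer as the reference
state, so the closed state carries statistical weight `K − 1` and each bound
configuration `c` a weight `w_c · Π_T x_T^n(c,T)`, where `w_c = exp(−ΔG_c)`
absorbs TR–DNA and TR–TR interaction energies adjusted to the wild-type
reference concentrations, and `n(c,T)` is the copy number of regulator `T`
in the configuration (Fli1 always enters as a dimer, hence `x_f²`).

Only configurations with a measurable effect on reporter expression are kept:

| enhancer  | configurations                    | promoter signals |
|-----------|-----------------------------------|------------------|
| *Scl+19*  | G, FF, G·FF                       | —                |
| *Gata2-3* | G, FF, G·FF, S·G·FF               | Notch, Bmp4, η   |
| *Fli1+12* | G, FF, G·FF, G·S·FF·G             | Bmp4             |

Because promoters bind RNA polymerase weakly, the transcription rate is
proportional to the probability of the open-chromatin, polymerase-accessible
state, and the dimensionless transcription factor is

```
f = η_eff (1 + Z_b)(1 + ω_N n + ω_B b) / (K − 1 + (1 + Z_b)(1 + n + b))
```

with signal terms present only for the gene's promoter cofactors.  Notch and
Bmp4 binding is treated as mutually exclusive at the promoter (additive
`n + b`); the saturating-fold calibration below is insensitive to this
choice.  Note the partition function does not factor into enhancer and
promoter parts: promoter-bound signals add statistical weight to open
chromatin, an emergent cooperativity of the competition with nucleosomes.
Gata1 acts only on *Gata2-3* and only as the multiplicative factor
`η ∈ (0, 1]` (no binding model): its mechanism is chromatin remodelling whose
net effect is reduced polymerase recruitment.

`ω_N` and `ω_B` are calibrated at the wild-type state so that saturating
signal raises Gata2 output by exactly 3.5× (Notch) and 4× (Bmp4); the
saturating ratio is `ω (K + Z_b)/(1 + Z_b)`, giving
`ω = fold (1 + Z_b)/(K + Z_b)` in closed form.  Bmp4 at the Fli1 promoter is
calibrated to the same 4× — its own measured value is not printed, and the
Gata2 measurement is the closest available anchor.

## Free-energy estimation

Measured fold enhancements invert exactly: `Z_b = K (F − 1)/(K − F)`, defined
for `1 ≤ F < K`.  Constructs ordered singles → pairs → full enhancer each add
one configuration, so the system is triangular: composite weights are the
inverted total minus the already-known weights of surviving
sub-configurations.  A composite weight below zero (beyond a 1e-9 relative
rounding slack) means the measured synergy contradicts the configuration
model; the fit aborts with a structured infeasibility error rather than
clamping, because a negative Boltzmann weight is unphysical.  A relaxed
least-squares mode (`fit_relaxed`, residuals on log-fold since reporter
intensities are ratio-scale) is provided for noisy or infeasible tables.

Weights are stored directly; energies (−ln w) are derived display quantities.

Chromatin constants are the only free parameters.  The "auto" rule starts each
`K` at its feasibility bound (the largest measured fold for that enhancer)
× 1.05 and scans the margin up to ×2 for the first value at which both Notch
and Bmp4 can irreversibly switch the module; for the packaged library the
initial margin already switches, giving K = (861.5, 525, 63).

## The ODE system

States are normalized to the wild-type HSC steady state and time to the Scl
mean lifetime (half-life/ln 2 ≈ 11.54 h; a `half_life` convention is also
available behind the `time_convention` flag).  With first-order degradation,

```
dx_i/dτ = γ_i (s_i f_i / f_i^wt − x_i),   γ = (1, 48, 4)
```

from half-lives 8 h / 10 min / 2 h.  `f_i^wt` is the zero-signal transcription
factor at (1,1,1), which makes the wild-type state an exact equilibrium.
mRNA is at quasi-steady state (proteins are long-lived relative to
transcripts), so production is proportional to the transcription factor.

Mutant designs modify this system without refitting: site deletions
cascade-remove every configuration requiring a deleted site; knockouts and
heterozygotes set the production scale `s_i` to 0 or 0.5; the reduced module
clamps `x_s` (Scl under external control, its feedback cut).  Normalization
constants are deliberately retained from the wild type so mutants are
directly comparable.  The ten single/double site-deletion designs analysed
are Scl+19 ΔGATA, ΔETS; Gata2-3 ΔGATA, ΔETS, ΔE-BOX; the Scl+19 ΔGATA +
Gata2-3 ΔE-BOX double (six touching the Scl/Gata2 enhancers), and Fli1+12
ΔE-BOX, Δsecondary-GATA, ΔETS, Δprimary-GATA (four touching only Fli1+12).

## Numerics

Steady states: multi-start Newton (scipy `hybr`) in log-concentration space
(states span 1e-3…1, log coordinates keep conditioning uniform and
positivity automatic) from a 4-per-axis log grid plus forward-integration
endpoints; accepted at residual < 1e-10, merged at 1e-4 relative (log)
radius.  Stability from finite-difference Jacobian eigenvalues with margin
1e-8; ambiguous cases are resolved by perturbed simulation.  Knocked-out
genes are pinned at zero and kept in the Jacobian; the clamped Scl dimension
is excluded.  Branch tracing re-solves every grid point independently with
warm starts carried along; saddle-node thresholds are grid-bracketed and
bisection-refined on the stable-state count.  No continuation package is
used — the system is three-dimensional and cheap, so dense-grid robustness
beats pseudo-arclength elegance.

Dynamics: LSODA with rtol 1e-8, atol 1e-10.  Pulses integrate signal-on and
signal-off segments separately; basin membership is assigned after 200 τ of
relaxation to the nearest stable state in log space (200 τ ≫ the slowest
relaxation time).  Minimum pulse durations are bisected to
min(0.01 τ, 0.5% relative), so reported durations are sharp to the 1% level
even for sub-τ Bmp4 pulses.  `t_acc` is the time for `x_s` to reach 50% of
its ON value (configurable fraction; no canonical definition exists).
Deactivation pulses parameterize Gata1 strength as `a ≥ 0` with
`η = 1/(1 + a)` so all filter curves share an amplitude axis; plateau
durations are evaluated at 1000× the static threshold.

"Can signal X switch the module?" is answered by simulation: start at OFF
(ON for Gata1), sustain the signal 200 τ, release, and test whether the
system settles on a different attractor.  The default physiological signal
ceiling is 30 promoter-dissociation-constant units: up to a few tens, the
(K_g, K_f) plane splits into the expected bands (both signals switch just
above the feasibility bounds; only Bmp4 at larger K_g; neither at large
K_g and K_f), whereas fully saturating signals (~1e3) open chromatin
strongly enough through promoter binding that every feasible refit point
switches and the band structure disappears.  With energies fixed (no refit),
severalfold changes of K preserve irreversible bistability with finite
thresholds — the narrow-band constraint comes from exact refitting, not from
fragility of the switch.

## Synthetic data

`generate_truth` samples configuration weights log-uniform on [0.1, 1e4] and
chromatin constants log-uniform on [10, 1e4] (the reported range for
nucleosome-unwrapping equilibria), jointly rejected until `K > 1 + Z_wt` so
the enhancer operates below chromatin saturation.  This feasibility rule is
the package's reading of "K must exceed the wild-type enhancement": the model
guarantees `F < K` identically, so the non-vacuous content is unsaturated
operation — which is also the regime of the real enhancers and what keeps the
closed-form inversion well conditioned (noise-free round trips recover every
weight to better than 1e-9 across 100 seeds).  Measurement noise is
multiplicative lognormal on fold values (`F · exp(σz)`), reflecting the
ratio-scale of reporter intensities; no error model is published.

What the generator does *not* emulate: replicate structure, flow-cytometry
population heterogeneity, construct-specific integration effects.  Passing
recovery tests therefore shows the estimator is exact and well conditioned
on the model's own measurement geometry, not that real libraries are free of
systematic error.

## Placeholder data and known limitations

The packaged reference library pins the published anchors — 820.51× for
wild-type *Scl+19*, ~20× and ~60× for the *Fli1+12* constructs — and fills
the remaining construct cells with clearly flagged placeholder values
(*Scl+19*: G = 40, FF = 60; *Gata2-3*: G = 15, FF = 25, ΔScl = 150,
wt = 500; *Fli1+12*: G = 5, FF = 8).  Results that survive any choice of
placeholders: exact fit round trips, feasibility bounds, the 3.5×/4×
calibration, wild-type irreversible bistability with (1,1,1) as the ON
state, knockout monostability, the Fli1+12 mutant phenotypes, all ordering
results (Notch pulses longer than Bmp4; the full triad a stricter low-pass
filter than the reduced module for activation; both modules equivalent for
Gata1 deactivation; switching rate-limited by Scl accumulation).

Placeholder-sensitive results: the absolute hour-scale of minimum pulse
durations (here ~4.6 h Notch / ~0.7 h Bmp4 / ~3 h Gata1 at plateau — the
placeholder values make the Scl-independent feedbacks strong and switching
correspondingly fast); whether the six Scl+19/Gata2-3 deletion designs are
strictly monostable along the whole Notch axis (here a signal-sustained
high state exists in a window n ≈ 2.5–20); and the existence of an exact
activation-threshold match for the reduced module (here the reduced module's
OFF-branch fold sits below the full triad's for every clamp that keeps it
irreversibly bistable, so controlled activation comparisons use the
closest-threshold clamp instead).  Transcribing the full supplementary
library into the CSV schema replaces all placeholders and re-runs the whole
pipeline unchanged.

Further non-goals: stochastic switching statistics, explicit mRNA dynamics,
Scl positive autoregulation, sequence-based affinity prediction.
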