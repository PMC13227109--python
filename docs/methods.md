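# Methods

## Kinetic model

`polbkin` models single-nucleotide gap filling as a network of elementary
mass-action reactions. Two variants are built by `build_scheme`:

**Crosslinked mechanism (ten numbered steps).** The polymerase (E) binds
gapped DNA noncovalently (Step 1, bimolecular, reversible), forms the Schiff
base crosslink (Step 2, irreversible on the assay timescale), and the
crosslinked binary complex equilibrates between two conformers A and B
(Step 3). Nucleotide binds the B conformer (Step 4, bimolecular, K_d =
k₋₄/k₄), the ternary complex closes and aligns its active site (Step 5,
rate-limiting, k₅ = k_p; optionally split into two sequential sub-steps 5
and 5i whose harmonic mean equals the composite k₅), chemistry forms the
phosphodiester bond reversibly (Step 6, k₆/k₋₆), the domain reopens
(Step 7), pyrophosphate dissociates (Step 8), β-elimination releases the
dRP-derived aldehyde HPP and breaks the crosslink (Step 9), and the nicked
product DNA dissociates (Step 10). Because the enzyme is covalently tethered
between Steps 2 and 9, every step in that span is unimolecular — DNA cannot
dissociate.

**Uncrosslinked mechanism (seven steps).** DNA binding, nucleotide binding,
conformational closing, reversible chemistry, reopening, PPi release, DNA
dissociation — the classical polymerase scheme.

Each species carries a conserved-moiety composition (enzyme, DNA strand,
incoming-nucleotide α-phosphate, β,γ-diphosphate, dRP moiety); every
reaction is balance-checked at construction, and integration verifies that
enzyme and DNA totals stay constant to 10⁻⁶ relative.

Units: concentrations in nM, time in s, temperature in K. Bimolecular rate
constants are configured in µM⁻¹s⁻¹ and converted to the nM scale when
reaction rates are evaluated.

## Default rate constants

The packaged defaults (`data/default_rates.json`, each value annotated with
its provenance) combine measured constants with model-completion choices:

| label | value | status |
|---|---|---|
| k₂ | 4.5 s⁻¹ | measured (Schiff-base formation) |
| K_d = k₋₄/k₄ | 0.38 µM | measured; k₄ = 10 µM⁻¹s⁻¹ assumed diffusion-limited, k₋₄ = 3.8 s⁻¹ |
| k₅ = k_p | 0.72 s⁻¹ | measured (rate-limiting closing/alignment) |
| k₆/k₋₆ | 2 | inferred from pulse amplitudes; absolute k₆ = 50·k₅ = 36 s⁻¹ (see below) |
| k₇ | 0.02 s⁻¹ | chosen: slow reopening (see below) |
| k₈ | 10 s⁻¹ | chosen: fast PPi release, non-rate-limiting |
| k₉ | 0.14 s⁻¹ | estimated (β-elimination/HPP release) |
| k₋₁, k₁₀ | 0.93 s⁻¹ | measured for the uncrosslinked enzyme, assumed transferable |
| k₃ = k₋₃ | 100 s⁻¹ | chosen: conformers near-isoenergetic, fast-equilibrating |

Three completion choices deserve explanation because the data constrain only
ratios or inequalities:

* **k₆ = 50·k₅.** Only the ratio k₆/k₋₆ ≈ 2 is constrained. The absolute
  scale must be fast enough that the chemical step does not imprint a
  sigmoidal lag on the product transient — the measured time courses are
  clean single exponentials with k_obs ≈ k_p. At 10·k₅ the simulated
  transient, sampled on a log-spaced rapid-quench grid, fits ~30% below k₅;
  at 50·k₅ the fitted k_obs is within ~12% of k₅. The small observed
  elemental effect is equally consistent with either scale.
* **k₃ = k₋₃ = 100 s⁻¹.** The binary-conformer equilibration is invisible in
  the observed transients, so it must be fast relative to every observed
  rate; 100 s⁻¹ makes it kinetically transparent while keeping the two
  conformers resolvable as distinct species.
* **k₇ = 0.02 s⁻¹.** The amplitude difference between pulse-quench and
  pulse-chase requires the post-chemistry complex to drain slowly (Steps 5
  and 7 slower than Step 6): a slow k₇ preserves the quench plateau at the
  partition amplitude A·k₆/(k₆+k₋₆) over the fitting window. With the
  literal 20-s chase, a single k₇ cannot simultaneously keep the pulse
  window drain-free and fully commit the intermediate pool during the
  chase; the closed-form amplitude ratio 1 + k₋₆/k₆ is therefore verified
  in the constructed committed-chase limit (k₇ ≪ k₅ with a long chase),
  where the simulated plateau ratio reaches 1.49 against the closed-form
  1.5.

All defaults are config-overridable; `k₋₅ = k₋₇ = 0` treat Steps 5 and 7 as
irreversible on the experimental timescale (flagged in the config file).

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 10⁻⁸, atol
10⁻⁶ nM. Small negative excursions within 10³·atol are clamped to zero on
output; anything larger raises an integration error carrying the last good
time. Solutions are grid-refinement invariant to well below 10⁻⁶ relative
(the solver steps adaptively; output times only interpolate).

## Protocol emulation

All protocols start from the preformed complex at 30 nM (crosslinked binary
conformers at their Step 3 equilibrium ratio) and free nucleotide at the
configured concentration; the quench readout sums every species at or after
phosphodiester bond formation (EDTA and HCl quenches are modeled
identically as instantaneous readouts).

Pulse-quench/pulse-chase duplicates every α-phosphate-carrying species into
labeled and unlabeled copies — the [α-³²P] label travels from free dNTP
through the ternary complexes into the extended DNA, while the leaving PPi
is unlabeled. The pulse starts with labeled nucleotide only (1.5 µM); at
each quench time the chase adds a 1000-fold unlabeled pool, integration
continues for the chase duration (default 20 s), and labeled product is
read out. No quasi-steady-state shortcut is used; the chase is integrated
literally.

Rate-set transforms:

* `apply_elemental_substitution(rates, f)` divides the chemical-step rates
  (k₆, k₋₆) by f ≥ 1, modeling the transition-state destabilization by the
  α-thio substitution;
* `apply_temperature` recomputes designated rates from transition-state
  theory (κ = 1 by default); only the rate-limiting step is mapped by
  default because the saturating k_obs reports on that step alone;
* `apply_viscosity` divides the diffusion-sensitive steps (the bimolecular
  binding steps and their reverses by default; tag additional steps to
  model large-scale-motion hypotheses) by the relative viscosity.

## Fitting

The burst fit uses derivative-based least squares (lmfit/`leastsq`) on
A·(1 − e^(−k·t)), both parameters bounded below at zero, initialized at
A₀ = max(signal) and k₀ = ln 2 / t½ from the first half-max crossing; a
signal with no curvature is returned non-converged rather than fitted.
Linear and Eyring fits are closed-form OLS (normal equations); the Eyring
regression of ln(k/T) on 1/T yields ΔH‡ = −slope·R and
ΔS‡ = (intercept − ln(k_B/h))·R with standard errors and the slope–intercept
covariance mapped through.

ΔG‡(T) = ΔH‡ − T·ΔS‡ with σ_G = √(σ_H² + T²σ_S²) by default — the
ΔH‡–ΔS‡ covariance is neglected, matching the conventional simple
propagation. Because the linearized fit makes the two parameters strongly
anticorrelated, the simple propagation overstates σ_G; an optional
covariance-aware mode (`use_covariance=True`) includes the cross term.

Replicates are fit individually and aggregated as mean ± sample (n−1) SD;
SD is reported as undefined for n = 1.

## Diagnostics

* Elemental effect: per-replicate ratios averaged when paired replicates are
  supplied, else the ratio of means (both conventions are available because
  published practice varies). Classification against the revised 10–160
  benchmark, endpoints inclusive: below → not chemistry-limited, inside →
  chemistry-limited, above → indeterminate.
* Slope-derived k_obs = slope/amplitude for transients sampled at t ≪ 1/k,
  with the amplitude taken from a faster companion reaction.
* Partition analysis: f = A_quench/A_chase, K_int = A_quench/(A_chase −
  A_quench), release rate = k_chase·(1−f)/f. The forward fraction is
  rounded to two decimals before the release-rate arithmetic by default,
  matching the convention of reporting partitions as two-digit percentages
  (67%/33% → 0.27 s⁻¹); full precision (which yields 0.2767 s⁻¹ for the
  same inputs) is available with `fraction_decimals=None`.
* The rate-limiting-step classifier implements a decision table over three
  evidence channels (elemental ratio vs benchmark, viscosity slope vs a 10%
  flatness threshold or inverse proportionality, amplitude excess) and
  reports which channels fired.

## Synthetic data

The generator emulates gel-quantified ³²P product-formation time courses:
rapid-quench grids (t = 0 plus 12 log-spaced points from 0.2 to 5 half-lives
of the expected rate), 2–3 replicates per experiment, additive Gaussian
quantification noise (default SD 0.5 nM, chosen to reproduce the order of
the published replicate scatter; an optional proportional CV term), negative
draws clamped at zero, and per-(experiment, replicate) seeded streams so
suites serialize byte-identically.

Closed-form mode draws signals directly from the published transient
parameters (so the full pipeline can be validated against the printed
numbers and by exact parameter recovery); mechanism mode simulates the
mass-action network through the protocol emulators (so mechanism-level
hypotheses can be probed). The generator does not emulate gel images,
band-quantification bias, radiolabel decay, instrument dead time, or
enzyme inactivation — so passing recovery tests demonstrate correctness of
the estimation machinery under the stated noise model, not robustness to
every artifact of real gel data. In mechanism mode the amplitudes reflect
the kinetic partitioning of a fully active 30 nM complex, whereas measured
amplitudes also fold in the active fraction; simulated and printed
amplitudes therefore agree in structure, not value.

## Problem sizes

The test suite and acceptance script run deterministic ODE integrations of
11–27 species over ≤ 10⁴ s spans, fits of 13-point transients, a
20 000-realization event-driven stochastic cross-check of a two-reaction
chain, a 1000-repetition Eyring Monte-Carlo, and a 200-seed noise
calibration — a few seconds in total on one core.

## Known limitations

* Absolute k₆ and k₋₆ are not identifiable from the emulated experiments
  (only their ratio); the defaults fix the scale by the transparency
  argument above.
* The viscosity map from %(v/v) glycerol to relative viscosity is a fixed
  lookup (1.0/1.31/1.76/2.50 at 0/10/20/30%), adequate for flat-vs-inverse
  discrimination but not for quantitative viscogen physics.
* Quench chemistry is idealized as an instantaneous readout; EDTA and HCl
  are not distinguished.
* The uncrosslinked default rate set beyond the measured k₋₁/k₇ is a
  plausibility completion (K_d ≈ 26.6 µM, k_p ≈ 2.9 s⁻¹, internal
  equilibrium 0.89) intended for qualitative comparison only.
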