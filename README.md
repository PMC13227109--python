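# polbkin

Pre-steady-state kinetic analysis of single-nucleotide gap-filling DNA
synthesis by DNA-crosslinked human DNA polymerase β (hPolβ).

During base excision repair, hPolβ fills the single-nucleotide gap while its
dRP lyase domain is covalently tethered to the DNA through a Schiff base, so
the catalytically relevant species is an enzyme–DNA crosslink rather than the
freely dissociating binary complex. `polbkin` packages the quantitative
machinery used to dissect the kinetic mechanism of that crosslinked complex:

* a **mass-action simulator** of the minimal kinetic mechanisms of nucleotide
  incorporation (a ten-step crosslinked scheme with reversible chemistry, and
  the classical seven-step uncrosslinked scheme), integrated with a
  stiff-capable ODE solver under strict conservation checks;
* **protocol emulators** for the standard transient-kinetics experiments:
  single-turnover rapid chemical quench, pulse-quench / pulse-chase with
  explicit [α-³²P] radiolabel bookkeeping, phosphorothioate (sulfur)
  elemental substitution, temperature series via transition-state theory,
  and solvent-viscosity series;
* the **estimation layer**: single-exponential burst fits
  `[product](t) = A·(1 − e^(−k_obs·t))`, linear fits for very slow
  misincorporation, the linearized Eyring fit
  `ln(k/T) = ln(κ·k_B/h) + ΔS‡/R − ΔH‡/(R·T)`, ΔG‡(T) error propagation,
  and mean ± SD replicate aggregation;
* **mechanistic diagnostics**: sulfur elemental effects with the revised
  10–160 benchmark for a rate-limiting S_N2 chemical step, slope-derived
  rate constants, pulse-chase/pulse-quench amplitude partitioning (internal
  equilibrium constant `K_int = A_quench/(A_chase − A_quench)` and nucleotide
  release rate `k_chase·(1−f)/f` with `f = A_quench/A_chase`), and a
  rate-limiting-step classifier combining the evidence channels;
* a **synthetic-data generator** that reproduces the reference experiment
  set (correct/incorrect incorporation and their α-thio analogs, the pulse
  pair, 0–30% glycerol, 20–37 °C) either from the published transient
  parameters (closed form) or by simulating the full mechanism, with seeded
  Gaussian quantification noise and ground truth attached for recovery
  testing.

## Worked example

```python
from polbkin.io import run_pipeline

report = run_pipeline({"suite": {"mode": "closed_form", "seed": 1,
                                 "noise_sd_nM": 0.0}})
print(report.summary)
```

prints (noise-free reference design):

```
{'elemental_effect_correct': 3.7, 'elemental_effect_incorrect': 24.0,
 'k_obs_thio_incorrect_per_s': 2.2e-05, 'amplitude_ratio': 1.5,
 'amplitude_difference_nM': 8.2, 'K_int': 2.0, 'release_rate_per_s': 0.27,
 'dH_kcal_per_mol': 21.5, 'dS_cal_per_mol_K': 11.5,
 'dG_37C_kcal_per_mol': 17.9, 'viscosity_slope': 2.6e-16}
```

Reading the numbers: the sulfur elemental effect for correct dCTP
incorporation (3.7) falls far below the 10–160 benchmark, so phosphodiester
bond formation is not rate-limiting for the correct nucleotide, while the
misincorporation effect (24) falls inside it. The pulse-chase amplitude
exceeds the pulse-quench amplitude 1.5-fold (difference 8.2 nM), revealing a
pre-chemistry ternary intermediate whose chemical-step internal equilibrium
constant is ≈ 2 and whose nucleotide release rate is 0.27 s⁻¹. The Eyring
analysis gives ΔH‡ = 21.5 kcal/mol, ΔS‡ = 11.5 cal/(mol·K), hence
ΔG‡(37 °C) ≈ 17.9 kcal/mol, and the flat viscosity series rules out
large-scale domain motions — together the classifier returns
`pre_chemical_local_step`: a local active-site rearrangement preceding
chemistry limits correct incorporation.

The same pipeline runs from the command line:

```sh
polbkin generate --out suite/ --noise-sd 0.5 --seed 7
polbkin run --config config.json --out report/
polbkin simulate --protocol pulse_chase --dntp-um 1.5 --out chase.csv
```

## Layout

```
src/polbkin/mechanism.py    reaction networks, rate sets, ODE integration
src/polbkin/protocols.py    experiment emulators and rate-set transforms
src/polbkin/fitting.py      exponential / linear / Eyring fits, aggregation
src/polbkin/diagnostics.py  elemental effect, partitioning, classification
src/polbkin/synth.py        synthetic experiment suites
src/polbkin/io.py           CSV I/O, pipeline, reports
src/polbkin/cli.py          command-line driver
src/polbkin/data/           packaged default rate constants with provenance
docs/methods.md             model, parameter defaults, numerical choices
```
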