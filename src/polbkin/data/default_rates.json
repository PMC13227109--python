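{
  "crosslinked": {
    "mechanism_variant": "crosslinked",
    "rates": {
      "k1": {
        "value": 10.0,
        "units": "uM^-1 s^-1",
        "provenance": "default: diffusion-limited noncovalent DNA binding (not measured)"
      },
      "k-1": {
        "value": 0.93,
        "units": "s^-1",
        "provenance": "measured: DNA dissociation from the noncovalent binary complex, assumed equal to the uncrosslinked value"
      },
      "k2": {
        "value": 4.5,
        "units": "s^-1",
        "provenance": "measured: Schiff-base formation rate at 25C"
      },
      "k3": {
        "value": 100.0,
        "units": "s^-1",
        "provenance": "default: binary conformers near-isoenergetic and fast-equilibrating; fast enough to leave no lag in the observed transient"
      },
      "k-3": {
        "value": 100.0,
        "units": "s^-1",
        "provenance": "default: k3/k-3 = 1"
      },
      "k4": {
        "value": 10.0,
        "units": "uM^-1 s^-1",
        "provenance": "default: typical diffusion-limited nucleotide association"
      },
      "k-4": {
        "value": 3.8,
        "units": "s^-1",
        "provenance": "derived: K_d(dCTP) = k-4/k4 = 0.38 uM (measured) with default k4"
      },
      "k5": {
        "value": 0.72,
        "units": "s^-1",
        "provenance": "measured: rate-limiting closing/active-site alignment, k5 = k_p = 0.72 s^-1"
      },
      "k-5": {
        "value": 0.0,
        "units": "s^-1",
        "provenance": "default: Step 5 treated as irreversible on the experimental timescale"
      },
      "k6": {
        "value": 36.0,
        "units": "s^-1",
        "provenance": "default: chemistry fast relative to Step 5 (50 x k5) so the observed transient stays single-exponential with k_obs ~ k_p, consistent with the small sulfur elemental effect"
      },
      "k-6": {
        "value": 18.0,
        "units": "s^-1",
        "provenance": "derived: internal equilibrium k6/k-6 ~ 2 inferred from pulse-quench/pulse-chase amplitudes"
      },
      "k7": {
        "value": 0.02,
        "units": "s^-1",
        "provenance": "default: slow reopening (well below k5); the pulse-quench/pulse-chase roadblock requires Steps 5 and 7 slower than Step 6"
      },
      "k-7": {
        "value": 0.0,
        "units": "s^-1",
        "provenance": "default: reopening treated as irreversible"
      },
      "k8": {
        "value": 10.0,
        "units": "s^-1",
        "provenance": "default: fast pyrophosphate release after reopening (not measured)"
      },
      "k9": {
        "value": 0.14,
        "units": "s^-1",
        "provenance": "estimated: beta-elimination/HPP release from disappearance of the crosslinked product complex"
      },
      "k10": {
        "value": 0.93,
        "units": "s^-1",
        "provenance": "assumed: nicked-product DNA dissociation, close to the uncrosslinked DNA off-rate"
      }
    }
  },
  "uncrosslinked": {
    "mechanism_variant": "uncrosslinked",
    "rates": {
      "k1": {
        "value": 10.0,
        "units": "uM^-1 s^-1",
        "provenance": "default: diffusion-limited DNA binding"
      },
      "k-1": {
        "value": 0.93,
        "units": "s^-1",
        "provenance": "measured: DNA dissociation at 37C, ~0.93 s^-1"
      },
      "k2": {
        "value": 10.0,
        "units": "uM^-1 s^-1",
        "provenance": "default: diffusion-limited nucleotide association"
      },
      "k-2": {
        "value": 266.0,
        "units": "s^-1",
        "provenance": "derived: dCTP K_d ~70-fold weaker than the crosslinked 0.38 uM (K_d ~ 26.6 uM) with default k2"
      },
      "k3": {
        "value": 2.9,
        "units": "s^-1",
        "provenance": "derived: rate-limiting conformational closing, k_p ~4-fold above the crosslinked 0.72 s^-1"
      },
      "k-3": {
        "value": 0.0,
        "units": "s^-1",
        "provenance": "default: closing treated as irreversible on the experimental timescale"
      },
      "k4": {
        "value": 29.0,
        "units": "s^-1",
        "provenance": "default: chemistry fast relative to closing (10 x k3)"
      },
      "k-4": {
        "value": 32.6,
        "units": "s^-1",
        "provenance": "derived: internal equilibrium k4/k-4 = 0.89 for the uncrosslinked enzyme"
      },
      "k5": {
        "value": 10.0,
        "units": "s^-1",
        "provenance": "default: fast reopening"
      },
      "k-5": {
        "value": 0.0,
        "units": "s^-1",
        "provenance": "default: irreversible"
      },
      "k6": {
        "value": 10.0,
        "units": "s^-1",
        "provenance": "default: fast pyrophosphate release"
      },
      "k7": {
        "value": 0.93,
        "units": "s^-1",
        "provenance": "measured: nicked-product DNA dissociation at 37C"
      }
    }
  }
}
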