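"""Emulators of the pre-steady-state experimental designs layered on the
mass-action simulator: single-turnover rapid quench, pulse-quench and
pulse-chase with explicit radiolabel bookkeeping, sulfur (alpha-thio)
elemental substitution, temperature series via transition-state theory, and
solvent-viscosity series.

All protocols start from a preformed enzyme--DNA complex (covalently
crosslinked for the crosslinked mechanism variant) at 30 nM by default and
read out the acid/EDTA-quench product signal: the summed concentration of
every species at or after phosphodiester bond formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import NM_PER_UM
from .fitting import eyring_rate
from .mechanism import (
    CROSSLINKED,
    DIFFUSION_LABELS,
    KineticScheme,
    RateConstantSet,
    Reaction,
    TimeCourse,
    integrate,
    observe,
)

__all__ = [
    "ProtocolConfig",
    "default_quench_times",
    "initial_state",
    "simulate_single_turnover",
    "simulate_pulse_quench",
    "simulate_pulse_chase",
    "apply_elemental_substitution",
    "apply_temperature",
    "apply_viscosity",
    "with_isotope_label",
    "LABELED_SUFFIX",
]

LABELED_SUFFIX = "*"   # radiolabeled ([alpha-32P]) species name suffix


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of one pre-steady-state experiment."""

    protocol: str = "single_turnover"
    enzyme_complex_nM: float = 30.0
    dNTP_uM: float = 25.0
    chase_dNTP_uM: float = 1500.0
    chase_duration_s: float = 20.0
    quench_times_s: tuple[float, ...] | None = None
    temperature_K: float = 310.15
    relative_viscosity: float = 1.0
    elemental_factor: float = 1.0

    _PROTOCOLS = (
        "single_turnover",
        "pulse_quench",
        "pulse_chase",
        "temperature_series",
        "viscosity_series",
    )

    def __post_init__(self):
        if self.protocol not in self._PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.enzyme_complex_nM <= 0:
            raise ValueError("enzyme_complex_nM must be > 0")
        if self.dNTP_uM < 0 or self.chase_dNTP_uM < 0:
            raise ValueError("nucleotide concentrations must be >= 0")
        if self.chase_duration_s < 0:
            raise ValueError("chase_duration_s must be >= 0")
        if self.quench_times_s is not None:
            times = tuple(float(t) for t in self.quench_times_s)
            if any(t < 0 for t in times):
                raise ValueError("quench times must be >= 0")
            object.__setattr__(self, "quench_times_s", times)
        if self.protocol == "pulse_chase" and self.dNTP_uM > 0:
            if self.chase_dNTP_uM / self.dNTP_uM < 1:
                raise ValueError("chase pool must be at least as large as the pulse pool")


def default_quench_times(k_expected: float, n_points: int = 12, span_halflives: float = 5.0):
    """Rapid-quench sampling grid: t = 0 plus log-spaced times from
    0.2 to ``span_halflives`` half-lives of the expected rate."""
    if k_expected <= 0:
        raise ValueError("k_expected must be positive")
    if n_points < 5:
        raise ValueError("need at least 5 points")
    t_half = math.log(2.0) / k_expected
    grid = np.geomspace(0.2 * t_half, span_halflives * t_half, n_points)
    return np.concatenate([[0.0], grid])


def initial_state(
    scheme: KineticScheme, rates: RateConstantSet, cfg: ProtocolConfig
) -> dict[str, float]:
    """Pre-mix state: all enzyme as the preformed (crosslinked or
    noncovalent) binary complex, free nucleotide at the configured
    concentration.  Crosslinked binary conformers A/B start at their
    Step 3 equilibrium ratio."""
    state: dict[str, float] = {}
    e0 = cfg.enzyme_complex_nM
    if scheme.variant == CROSSLINKED:
        if "E-DNA_n" in scheme.species:
            state["E-DNA_n"] = e0
        else:
            k3, km3 = rates["k3"], rates["k-3"]
            fb = k3 / (k3 + km3) if (k3 + km3) > 0 else 0.5
            state["E-DNA_n_A"] = e0 * (1.0 - fb)
            state["E-DNA_n_B"] = e0 * fb
    else:
        state["E.DNA_n"] = e0
    state["dNTP"] = cfg.dNTP_uM * NM_PER_UM
    return state


def _quench_grid(rates: RateConstantSet, cfg: ProtocolConfig) -> np.ndarray:
    if cfg.quench_times_s is not None:
        return np.asarray(cfg.quench_times_s, dtype=float)
    return default_quench_times(rates.kp)


def simulate_single_turnover(
    scheme: KineticScheme, rates: RateConstantSet, cfg: ProtocolConfig
) -> TimeCourse:
    """Single-turnover rapid-quench run: product signal at each quench time."""
    times = _quench_grid(rates, cfg)
    tc = integrate(scheme, initial_state(scheme, rates, cfg), rates, times)
    out = observe(scheme, tc, "acid_quench_product")
    out.metadata.update(protocol="single_turnover", temperature_K=cfg.temperature_K)
    return out


# --------------------------------------------------------------------------
# radiolabel bookkeeping for pulse-quench / pulse-chase


def with_isotope_label(scheme: KineticScheme) -> KineticScheme:
    """Duplicate every species carrying the incoming-nucleotide
    alpha-phosphate into labeled (suffix ``*``) and unlabeled copies.

    The alpha-phosphate is what [alpha-32P] labeling marks: it travels from
    free dNTP through the ternary complexes into the extended DNA, while
    the leaving pyrophosphate is unlabeled.  Reactions touching a labeled
    carrier are duplicated for both isotopic pools; all rate constants are
    shared (no isotope effect on rates).
    """

    def carries(name: str) -> bool:
        return scheme.compositions.get(name, {}).get("aP", 0) > 0

    species: list[str] = []
    comps: dict[str, dict] = {}
    for name in scheme.species:
        if carries(name):
            for suffix in ("", LABELED_SUFFIX):
                species.append(name + suffix)
                comps[name + suffix] = dict(scheme.compositions[name])
        else:
            species.append(name)
            if name in scheme.compositions:
                comps[name] = dict(scheme.compositions[name])

    reactions: list[Reaction] = []
    for rxn in scheme.reactions:
        touched = any(carries(n) for n, _ in rxn.reactants + rxn.products)
        if not touched:
            reactions.append(rxn)
            continue
        for suffix in ("", LABELED_SUFFIX):
            reactions.append(
                replace(
                    rxn,
                    reactants=tuple(
                        (n + suffix if carries(n) else n, nu) for n, nu in rxn.reactants
                    ),
                    products=tuple(
                        (n + suffix if carries(n) else n, nu) for n, nu in rxn.products
                    ),
                )
            )

    observables = {}
    for obs, members in scheme.observables.items():
        expanded: list[str] = []
        labeled: list[str] = []
        for name in members:
            if carries(name):
                expanded += [name, name + LABELED_SUFFIX]
                labeled.append(name + LABELED_SUFFIX)
            else:
                expanded.append(name)
        observables[obs] = tuple(expanded)
        if labeled:
            observables[obs + "_labeled"] = tuple(labeled)

    return KineticScheme(
        variant=scheme.variant,
        species=tuple(species),
        reactions=tuple(reactions),
        observables=observables,
        compositions=comps,
    )


def _labeled_initial(scheme_l, rates, cfg) -> dict[str, float]:
    state = initial_state(scheme_l, rates, cfg)
    state[f"dNTP{LABELED_SUFFIX}"] = state.pop("dNTP")
    return state


def simulate_pulse_quench(
    scheme: KineticScheme, rates: RateConstantSet, cfg: ProtocolConfig
) -> TimeCourse:
    """Pulse with radiolabeled nucleotide, quench with acid at each time:
    counts labeled species at/after phosphodiester bond formation."""
    scheme_l = with_isotope_label(scheme)
    times = _quench_grid(rates, cfg)
    tc = integrate(scheme_l, _labeled_initial(scheme_l, rates, cfg), rates, times)
    out = observe(scheme_l, tc, "acid_quench_product_labeled")
    out.metadata.update(protocol="pulse_quench", temperature_K=cfg.temperature_K)
    return out


def simulate_pulse_chase(
    scheme: KineticScheme, rates: RateConstantSet, cfg: ProtocolConfig
) -> TimeCourse:
    """Pulse with labeled nucleotide; at each quench time dilute the free
    label into a large unlabeled pool, integrate the chase, then read the
    labeled product.  Committed enzyme-bound label proceeds forward during
    the chase, so the signal is >= the pulse-quench signal at every time."""
    scheme_l = with_isotope_label(scheme)
    times = _quench_grid(rates, cfg)
    y0 = scheme_l.state_vector(_labeled_initial(scheme_l, rates, cfg))
    product = scheme_l.observables["acid_quench_product_labeled"]
    chase_nM = cfg.chase_dNTP_uM * NM_PER_UM
    i_cold = scheme_l.index("dNTP")

    signal = np.empty(len(times))
    for i, t in enumerate(times):
        if t > 0:
            pulse = integrate(scheme_l, y0, rates, np.array([0.0, t]))
            state = pulse.values[-1].copy()
        else:
            state = y0.copy()
        if cfg.chase_duration_s > 0:
            state[i_cold] += chase_nM
            chased = integrate(
                scheme_l, state, rates, np.array([0.0, cfg.chase_duration_s])
            )
            state = chased.values[-1]
        signal[i] = sum(state[scheme_l.index(name)] for name in product)

    return TimeCourse(
        times=times,
        values=signal,
        metadata={
            "protocol": "pulse_chase",
            "temperature_K": cfg.temperature_K,
            "chase_duration_s": cfg.chase_duration_s,
            "variant": scheme.variant,
        },
    )


# --------------------------------------------------------------------------
# rate-set transformations


def apply_elemental_substitution(rates: RateConstantSet, factor: float) -> RateConstantSet:
    """Alpha-thio (Sp-dNTPalphaS) substitution: the sulfur destabilizes the
    phosphoryl-transfer transition state, slowing the chemical step in both
    directions by ``factor`` (>= 1).  All other rates are untouched."""
    if factor < 1:
        raise ValueError("elemental factor must be >= 1")
    return rates.scaled(rates.chemistry_labels, 1.0 / factor)


def apply_temperature(
    rates: RateConstantSet,
    T_K: float,
    activation: Mapping[str, tuple[float, float]] | None = None,
    kappa: float = 1.0,
) -> RateConstantSet:
    """Recompute designated rate constants from transition-state theory.

    ``activation`` maps rate labels to (dH' kcal/mol, dS' cal/(mol*K)); by
    default only the rate-limiting step (k_p, i.e. k5 for the crosslinked
    variant) is temperature-mapped, since the saturating k_obs reports on
    that step alone.  Undesignated rates are unchanged.
    """
    if T_K <= 0:
        raise ValueError("temperature must be positive")
    if activation is None:
        raise ValueError("supply activation parameters for at least one step")
    changes = {
        label: eyring_rate(dH, dS, T_K, kappa=kappa)
        for label, (dH, dS) in activation.items()
    }
    return rates.with_entries(changes)


def apply_viscosity(
    rates: RateConstantSet,
    relative_viscosity: float,
    affected_steps: Sequence[str] | None = None,
) -> RateConstantSet:
    """Scale diffusion-sensitive steps by 1/relative_viscosity.

    Defaults to the bimolecular binding steps and their reverses; local
    active-site rearrangements and chemistry are insensitive to bulk solvent
    viscosity and are untouched.  Steps limited by large-scale domain motion
    can be added via ``affected_steps``.
    """
    if relative_viscosity < 1:
        raise ValueError("relative viscosity must be >= 1")
    labels = (
        tuple(affected_steps)
        if affected_steps is not None
        else DIFFUSION_LABELS[rates.mechanism_variant]
    )
    return rates.scaled(labels, 1.0 / relative_viscosity)
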