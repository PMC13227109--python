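"""Mass-action representation and deterministic integration of the minimal
kinetic mechanisms of single-nucleotide gap-filling DNA synthesis.

Two mechanism variants are modeled:

* ``crosslinked`` -- the polymerase is covalently tethered to its gapped DNA
  substrate through a Schiff base between the dRP lyase lysine and the
  ring-opened 5'-deoxyribose-phosphate (dRP).  Ten numbered steps: noncovalent
  DNA binding (1), Schiff-base formation (2), equilibration of two binary
  conformers A/B (3), nucleotide binding (4), closing/active-site alignment
  (5, optionally split into 5 and 5i), reversible phosphodiester bond
  formation (6), reopening (7), pyrophosphate release (8), beta-elimination
  releasing HPP (9), and DNA dissociation (10).  Because the enzyme is
  crosslinked, no step between 2 and 9 can dissociate the DNA.

* ``uncrosslinked`` -- the classical seven-step polymerase scheme: DNA
  binding (1), nucleotide binding (2), conformational closing (3), chemistry
  (4), reopening (5), PPi release (6), and DNA dissociation (7).

Rate constants are first-order (s^-1) except the bimolecular binding steps,
which are given in uM^-1 s^-1 and converted to the internal nM scale when
reaction rates are evaluated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import NM_PER_UM

__all__ = [
    "CROSSLINKED",
    "UNCROSSLINKED",
    "RateConstantSet",
    "Reaction",
    "KineticScheme",
    "TimeCourse",
    "IntegrationError",
    "default_rates",
    "build_scheme",
    "mass_action_derivative",
    "integrate",
    "observe",
]

CROSSLINKED = "crosslinked"
UNCROSSLINKED = "uncrosslinked"

#: rate labels that are bimolecular (uM^-1 s^-1) per mechanism variant
_BIMOLECULAR_LABELS = {
    CROSSLINKED: frozenset({"k1", "k4"}),
    UNCROSSLINKED: frozenset({"k1", "k2"}),
}

#: (nucleotide-binding reverse, forward) labels defining K_d per variant
_KD_LABELS = {CROSSLINKED: ("k-4", "k4"), UNCROSSLINKED: ("k-2", "k2")}

#: the maximal-incorporation-rate label (k_p) per variant
_KP_LABEL = {CROSSLINKED: "k5", UNCROSSLINKED: "k3"}

#: labels of the chemical (phosphodiester bond formation) step per variant
CHEMISTRY_LABELS = {
    CROSSLINKED: ("k6", "k-6"),
    UNCROSSLINKED: ("k4", "k-4"),
}

#: diffusion-sensitive (binding) steps, slowed by solvent viscogens
DIFFUSION_LABELS = {
    CROSSLINKED: ("k1", "k-1", "k4", "k-4"),
    UNCROSSLINKED: ("k1", "k-1", "k2", "k-2"),
}


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


# --------------------------------------------------------------------------
# rate constants


@dataclass(frozen=True)
class RateConstantSet:
    """Named microscopic rate constants for one mechanism variant.

    ``entries`` maps rate labels (``"k1"``, ``"k-1"``, ...) to values;
    first-order steps in s^-1, bimolecular steps in uM^-1 s^-1.
    """

    mechanism_variant: str
    entries: Mapping[str, float]

    def __post_init__(self):
        if self.mechanism_variant not in (CROSSLINKED, UNCROSSLINKED):
            raise ValueError(f"unknown mechanism variant {self.mechanism_variant!r}")
        object.__setattr__(self, "entries", dict(self.entries))
        for label, value in self.entries.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {label} must be finite and >= 0, got {value}")

    def __getitem__(self, label: str) -> float:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(f"missing rate label {label}") from None

    def is_bimolecular(self, label: str) -> bool:
        return label in _BIMOLECULAR_LABELS[self.mechanism_variant]

    @property
    def kd_uM(self) -> float:
        """Nucleotide dissociation constant K_d (uM) from the binding step."""
        rev, fwd = _KD_LABELS[self.mechanism_variant]
        return self[rev] / self[fwd]

    @property
    def kp(self) -> float:
        """Maximal incorporation rate constant k_p (s^-1)."""
        return self[_KP_LABEL[self.mechanism_variant]]

    @property
    def chemistry_labels(self) -> tuple[str, str]:
        return CHEMISTRY_LABELS[self.mechanism_variant]

    def updated(self, **changes: float) -> "RateConstantSet":
        """Copy with some labels replaced (``k minus`` written ``k_m``
        is not supported; pass a dict for labels containing '-')."""
        entries = dict(self.entries)
        entries.update(changes)
        return replace(self, entries=entries)

    def with_entries(self, changes: Mapping[str, float]) -> "RateConstantSet":
        entries = dict(self.entries)
        entries.update(changes)
        return replace(self, entries=entries)

    def scaled(self, labels: Iterable[str], factor: float) -> "RateConstantSet":
        """Copy with each of ``labels`` multiplied by ``factor``."""
        entries = dict(self.entries)
        for label in labels:
            entries[label] = self[label] * factor
        return replace(self, entries=entries)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        units = {
            label: ("uM^-1 s^-1" if self.is_bimolecular(label) else "s^-1")
            for label in self.entries
        }
        return {
            "mechanism_variant": self.mechanism_variant,
            "rates": {
                label: {"value": value, "units": units[label]}
                for label, value in self.entries.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RateConstantSet":
        rates = payload["rates"]
        entries = {
            label: (spec["value"] if isinstance(spec, Mapping) else float(spec))
            for label, spec in rates.items()
        }
        return cls(mechanism_variant=payload["mechanism_variant"], entries=entries)

    @classmethod
    def from_json(cls, path) -> "RateConstantSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_rates(variant: str = CROSSLINKED) -> RateConstantSet:
    """Packaged default rate constants for a mechanism variant.

    Loaded from ``data/default_rates.json``, which carries the measured
    constants together with provenance notes for each value.
    """
    text = resources.files("polbkin.data").joinpath("default_rates.json").read_text()
    payload = json.loads(text)
    try:
        return RateConstantSet.from_dict(payload[variant])
    except KeyError:
        raise ValueError(f"unknown mechanism variant {variant!r}") from None


# --------------------------------------------------------------------------
# reaction network


@dataclass(frozen=True)
class Reaction:
    """One elementary, unidirectional mass-action reaction.

    ``multiplier`` scales the looked-up rate constant (used when a composite
    step is split into sequential sub-steps that share one label).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_label: str
    step: str
    multiplier: float = 1.0

    @property
    def order(self) -> int:
        return sum(stoich for _, stoich in self.reactants)


@dataclass(frozen=True)
class KineticScheme:
    """Species list plus elementary reactions for a mechanism variant.

    ``compositions`` maps each species to its conserved-moiety content
    (enzyme ``E``, DNA strand ``DNA``, incoming-nucleotide alpha-phosphate
    ``aP``, beta/gamma diphosphate ``PPi``, dRP moiety ``dRP``); it is used
    for reaction balance checks and conservation diagnostics.  Observables
    are named species subsets summed by a readout.
    """

    variant: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    observables: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    compositions: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        index = {name: i for i, name in enumerate(self.species)}
        object.__setattr__(self, "_index", index)
        for rxn in self.reactions:
            for name, _ in rxn.reactants + rxn.products:
                if name not in index:
                    raise ValueError(f"reaction references unknown species {name!r}")
        object.__setattr__(self, "observables", dict(self.observables))
        object.__setattr__(self, "compositions", dict(self.compositions))
        for obs, members in self.observables.items():
            for name in members:
                if name not in index:
                    raise ValueError(f"observable {obs!r} references unknown species {name!r}")
        self._check_balance()
        # stoichiometry matrix (n_species x n_reactions)
        stoich = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name, nu in rxn.reactants:
                stoich[index[name], j] -= nu
            for name, nu in rxn.products:
                stoich[index[name], j] += nu
        stoich.setflags(write=False)
        object.__setattr__(self, "stoichiometry", stoich)

    def _check_balance(self):
        if not self.compositions:
            return
        moieties = set()
        for comp in self.compositions.values():
            moieties.update(comp)
        for rxn in self.reactions:
            for m in moieties:
                lhs = sum(self.compositions.get(n, {}).get(m, 0) * nu for n, nu in rxn.reactants)
                rhs = sum(self.compositions.get(n, {}).get(m, 0) * nu for n, nu in rxn.products)
                if lhs != rhs:
                    raise ValueError(
                        f"reaction (step {rxn.step}, {rxn.rate_label}) does not "
                        f"conserve moiety {m!r}"
                    )

    # -- convenience -------------------------------------------------------

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_steps(self) -> int:
        """Number of numbered mechanism steps (sub-steps such as 5i share
        their parent step's number)."""
        numbers = set()
        for r in self.reactions:
            digits = "".join(ch for ch in r.step if ch.isdigit())
            numbers.add(int(digits))
        return len(numbers)

    @property
    def step_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.step.rstrip("r"), None)
        return tuple(seen)

    def state_vector(self, concentrations: Mapping[str, float]) -> np.ndarray:
        """Dense concentration vector (nM) from a species->value mapping."""
        y = np.zeros(len(self.species))
        for name, value in concentrations.items():
            y[self.index(name)] = value
        return y

    def moiety_total(self, y: np.ndarray, moiety: str) -> float:
        """Total concentration of a conserved moiety (e.g. ``"E"``, ``"DNA"``)."""
        return float(
            sum(
                self.compositions.get(name, {}).get(moiety, 0) * y[i]
                for i, name in enumerate(self.species)
            )
        )

    def moiety_totals(self, values: np.ndarray, moiety: str) -> np.ndarray:
        """Per-time conserved-moiety totals for a (n_times, n_species) array."""
        weights = np.array(
            [self.compositions.get(name, {}).get(moiety, 0) for name in self.species],
            dtype=float,
        )
        return values @ weights

    def validate_rates(self, rates: RateConstantSet):
        if rates.mechanism_variant != self.variant:
            raise ValueError(
                f"rate set variant {rates.mechanism_variant!r} does not match "
                f"scheme variant {self.variant!r}"
            )
        for rxn in self.reactions:
            if rxn.rate_label not in rates.entries:
                raise KeyError(f"missing rate label {rxn.rate_label}")


@dataclass
class TimeCourse:
    """Concentrations versus time.

    ``values`` is either (n_times, n_species) for a full trajectory (with
    ``species`` naming the columns) or (n_times,) for an observed scalar
    signal.  Times are seconds, concentrations nM.
    """

    times: np.ndarray
    values: np.ndarray
    species: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values and times length mismatch")
        if self.values.ndim == 2 and self.species is not None:
            if self.values.shape[1] != len(self.species):
                raise ValueError("species names do not match value columns")

    @property
    def is_signal(self) -> bool:
        return self.values.ndim == 1

    @property
    def signal(self) -> np.ndarray:
        if not self.is_signal:
            raise ValueError("time course holds a full trajectory, not a signal")
        return self.values

    def column(self, name: str) -> np.ndarray:
        if self.species is None:
            raise ValueError("no species columns")
        return self.values[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        if self.is_signal:
            return pd.DataFrame({"time_s": self.times, "signal_nM": self.values})
        data = {"time_s": self.times}
        for i, name in enumerate(self.species):
            data[name] = self.values[:, i]
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# scheme construction

# species name shorthands (ASCII renderings of the mechanism nomenclature;
# "E'" is the closed conformation, "E-" a covalent crosslink, "E." a
# noncovalent complex)
_XL = {
    "E": {"E": 1},
    "DNA_n": {"DNA": 1, "dRP": 1},
    "E.DNA_n": {"E": 1, "DNA": 1, "dRP": 1},
    "E-DNA_n_A": {"E": 1, "DNA": 1, "dRP": 1},
    "E-DNA_n_B": {"E": 1, "DNA": 1, "dRP": 1},
    "dNTP": {"aP": 1, "PPi": 1},
    "E-DNA_n.dNTP": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1, "PPi": 1},
    "E'-DNA_n.dNTP_1": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1, "PPi": 1},
    "E'-DNA_n.dNTP_2": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1, "PPi": 1},
    "E'-DNA_n+1.PPi": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1, "PPi": 1},
    "E-DNA_n+1.PPi": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1, "PPi": 1},
    "E-DNA_n+1": {"E": 1, "DNA": 1, "dRP": 1, "aP": 1},
    "PPi": {"PPi": 1},
    "HPP": {"dRP": 1},
    "E.DNA_n+1": {"E": 1, "DNA": 1, "aP": 1},
    "DNA_n+1": {"DNA": 1, "aP": 1},
}

_UX = {
    "E": {"E": 1},
    "DNA_n": {"DNA": 1},
    "E.DNA_n": {"E": 1, "DNA": 1},
    "dNTP": {"aP": 1, "PPi": 1},
    "E.DNA_n.dNTP": {"E": 1, "DNA": 1, "aP": 1, "PPi": 1},
    "E'.DNA_n.dNTP": {"E": 1, "DNA": 1, "aP": 1, "PPi": 1},
    "E'.DNA_n+1.PPi": {"E": 1, "DNA": 1, "aP": 1, "PPi": 1},
    "E.DNA_n+1.PPi": {"E": 1, "DNA": 1, "aP": 1, "PPi": 1},
    "E.DNA_n+1": {"E": 1, "DNA": 1, "aP": 1},
    "PPi": {"PPi": 1},
    "DNA_n+1": {"DNA": 1, "aP": 1},
}


def _rxn(reactants, products, label, step, multiplier=1.0):
    return Reaction(
        reactants=tuple((n, 1) for n in reactants),
        products=tuple((n, 1) for n in products),
        rate_label=label,
        step=step,
        multiplier=multiplier,
    )


def build_scheme(
    variant: str,
    rates: RateConstantSet,
    *,
    explicit_binary_isomers: bool = True,
    explicit_step5i: bool = False,
) -> KineticScheme:
    """Enumerate the elementary reactions of the chosen mechanism variant.

    Parameters
    ----------
    variant
        ``"crosslinked"`` or ``"uncrosslinked"``.
    rates
        Rate-constant set; every label the scheme references must exist.
    explicit_binary_isomers
        Crosslinked only: model the two binary conformers A and B and their
        Step 3 equilibrium explicitly (default) or lump them into one species.
    explicit_step5i
        Crosslinked only: split the closing/alignment Step 5 into two
        sequential first-order sub-steps (5 and 5i) through two distinct
        closed ternary states.  Each sub-step runs at 2*k5 so their harmonic
        sum equals the configured composite k5.
    """
    if variant not in (CROSSLINKED, UNCROSSLINKED):
        raise ValueError(f"unknown mechanism variant {variant!r}")
    if rates.mechanism_variant != variant:
        raise ValueError(
            f"rate set variant {rates.mechanism_variant!r} does not match {variant!r}"
        )

    if variant == CROSSLINKED:
        scheme = _build_crosslinked(explicit_binary_isomers, explicit_step5i)
    else:
        scheme = _build_uncrosslinked()
    scheme.validate_rates(rates)
    return scheme


def _build_crosslinked(explicit_isomers: bool, explicit_5i: bool) -> KineticScheme:
    comps = dict(_XL)
    reactions = [
        _rxn(["E", "DNA_n"], ["E.DNA_n"], "k1", "1"),
        _rxn(["E.DNA_n"], ["E", "DNA_n"], "k-1", "1r"),
    ]
    if explicit_isomers:
        reactions += [
            _rxn(["E.DNA_n"], ["E-DNA_n_A"], "k2", "2"),
            _rxn(["E-DNA_n_A"], ["E-DNA_n_B"], "k3", "3"),
            _rxn(["E-DNA_n_B"], ["E-DNA_n_A"], "k-3", "3r"),
            _rxn(["E-DNA_n_B", "dNTP"], ["E-DNA_n.dNTP"], "k4", "4"),
        ]
        binary = ["E-DNA_n_A", "E-DNA_n_B"]
    else:
        comps["E-DNA_n"] = comps.pop("E-DNA_n_A")
        del comps["E-DNA_n_B"]
        reactions += [
            _rxn(["E.DNA_n"], ["E-DNA_n"], "k2", "2"),
            _rxn(["E-DNA_n", "dNTP"], ["E-DNA_n.dNTP"], "k4", "4"),
        ]
        binary = ["E-DNA_n"]
    reactions.append(_rxn(["E-DNA_n.dNTP"], binary[-1:] + ["dNTP"], "k-4", "4r"))

    if explicit_5i:
        closed = ["E'-DNA_n.dNTP_1", "E'-DNA_n.dNTP_2"]
        reactions += [
            _rxn(["E-DNA_n.dNTP"], [closed[0]], "k5", "5", multiplier=2.0),
            _rxn([closed[0]], ["E-DNA_n.dNTP"], "k-5", "5r", multiplier=2.0),
            _rxn([closed[0]], [closed[1]], "k5", "5i", multiplier=2.0),
            _rxn([closed[1]], [closed[0]], "k-5", "5ir", multiplier=2.0),
        ]
    else:
        comps["E'-DNA_n.dNTP"] = comps.pop("E'-DNA_n.dNTP_1")
        del comps["E'-DNA_n.dNTP_2"]
        closed = ["E'-DNA_n.dNTP"]
        reactions += [
            _rxn(["E-DNA_n.dNTP"], [closed[0]], "k5", "5"),
            _rxn([closed[0]], ["E-DNA_n.dNTP"], "k-5", "5r"),
        ]

    reactions += [
        _rxn([closed[-1]], ["E'-DNA_n+1.PPi"], "k6", "6"),
        _rxn(["E'-DNA_n+1.PPi"], [closed[-1]], "k-6", "6r"),
        _rxn(["E'-DNA_n+1.PPi"], ["E-DNA_n+1.PPi"], "k7", "7"),
        _rxn(["E-DNA_n+1.PPi"], ["E'-DNA_n+1.PPi"], "k-7", "7r"),
        _rxn(["E-DNA_n+1.PPi"], ["E-DNA_n+1", "PPi"], "k8", "8"),
        _rxn(["E-DNA_n+1"], ["E.DNA_n+1", "HPP"], "k9", "9"),
        _rxn(["E.DNA_n+1"], ["E", "DNA_n+1"], "k10", "10"),
    ]

    product = ("E'-DNA_n+1.PPi", "E-DNA_n+1.PPi", "E-DNA_n+1", "E.DNA_n+1", "DNA_n+1")
    observables = {
        "acid_quench_product": product,
        "edta_quench_product": product,
        "closed_ternary": tuple(closed),
        "all": tuple(comps),
    }
    return KineticScheme(
        variant=CROSSLINKED,
        species=tuple(comps),
        reactions=tuple(reactions),
        observables=observables,
        compositions=comps,
    )


def _build_uncrosslinked() -> KineticScheme:
    comps = dict(_UX)
    reactions = [
        _rxn(["E", "DNA_n"], ["E.DNA_n"], "k1", "1"),
        _rxn(["E.DNA_n"], ["E", "DNA_n"], "k-1", "1r"),
        _rxn(["E.DNA_n", "dNTP"], ["E.DNA_n.dNTP"], "k2", "2"),
        _rxn(["E.DNA_n.dNTP"], ["E.DNA_n", "dNTP"], "k-2", "2r"),
        _rxn(["E.DNA_n.dNTP"], ["E'.DNA_n.dNTP"], "k3", "3"),
        _rxn(["E'.DNA_n.dNTP"], ["E.DNA_n.dNTP"], "k-3", "3r"),
        _rxn(["E'.DNA_n.dNTP"], ["E'.DNA_n+1.PPi"], "k4", "4"),
        _rxn(["E'.DNA_n+1.PPi"], ["E'.DNA_n.dNTP"], "k-4", "4r"),
        _rxn(["E'.DNA_n+1.PPi"], ["E.DNA_n+1.PPi"], "k5", "5"),
        _rxn(["E.DNA_n+1.PPi"], ["E'.DNA_n+1.PPi"], "k-5", "5r"),
        _rxn(["E.DNA_n+1.PPi"], ["E.DNA_n+1", "PPi"], "k6", "6"),
        _rxn(["E.DNA_n+1"], ["E", "DNA_n+1"], "k7", "7"),
    ]
    product = ("E'.DNA_n+1.PPi", "E.DNA_n+1.PPi", "E.DNA_n+1", "DNA_n+1")
    observables = {
        "acid_quench_product": product,
        "edta_quench_product": product,
        "closed_ternary": ("E'.DNA_n.dNTP",),
        "all": tuple(comps),
    }
    return KineticScheme(
        variant=UNCROSSLINKED,
        species=tuple(comps),
        reactions=tuple(reactions),
        observables=observables,
        compositions=comps,
    )


# --------------------------------------------------------------------------
# mass-action evaluation and integration


def _rate_vector(scheme: KineticScheme, rates: RateConstantSet) -> np.ndarray:
    """Per-reaction rate constants on the nM scale."""
    k = np.empty(len(scheme.reactions))
    for j, rxn in enumerate(scheme.reactions):
        value = rates[rxn.rate_label] * rxn.multiplier
        if rxn.order >= 2:
            # bimolecular constants are configured in uM^-1 s^-1
            value /= NM_PER_UM ** (rxn.order - 1)
        k[j] = value
    return k


def mass_action_derivative(
    scheme: KineticScheme,
    state: Mapping[str, float] | np.ndarray,
    rates: RateConstantSet,
    *,
    negative_tolerance: float = 1e-6,
) -> np.ndarray:
    """Rate of change (nM/s) of every species under mass-action kinetics."""
    scheme.validate_rates(rates)
    y = state if isinstance(state, np.ndarray) else scheme.state_vector(state)
    if np.any(y < -negative_tolerance):
        worst = scheme.species[int(np.argmin(y))]
        raise ValueError(f"negative concentration for {worst} beyond tolerance")
    k = _rate_vector(scheme, rates)
    return scheme.stoichiometry @ _fluxes(scheme, y, k)


def _fluxes(scheme: KineticScheme, y: np.ndarray, k: np.ndarray) -> np.ndarray:
    v = k.copy()
    for j, rxn in enumerate(scheme.reactions):
        for name, nu in rxn.reactants:
            v[j] *= y[scheme.index(name)] ** nu
    return v


def integrate(
    scheme: KineticScheme,
    initial: Mapping[str, float] | np.ndarray,
    rates: RateConstantSet,
    times: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    metadata: dict | None = None,
) -> TimeCourse:
    """Integrate the mechanism with a stiff-capable solver (LSODA).

    Returns the full-species trajectory sampled at ``times`` (strictly
    increasing, first >= 0).  Small negative excursions within the solver
    tolerance are clamped to zero on output.
    """
    scheme.validate_rates(rates)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be >= 0")

    y0 = initial if isinstance(initial, np.ndarray) else scheme.state_vector(initial)
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be non-negative")

    k = _rate_vector(scheme, rates)
    stoich = scheme.stoichiometry
    # index lists for fast flux evaluation
    reactant_idx = [
        [scheme.index(name) for name, nu in rxn.reactants for _ in range(nu)]
        for rxn in scheme.reactions
    ]

    def rhs(_t, y):
        v = k.copy()
        for j, idx in enumerate(reactant_idx):
            for i in idx:
                v[j] *= y[i]
        return stoich @ v

    t0 = 0.0
    tf = float(times[-1])
    if tf == t0:
        values = np.tile(y0, (len(times), 1))
    else:
        sol = solve_ivp(
            rhs,
            (t0, tf),
            y0,
            method="LSODA",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last = float(sol.t[-1]) if len(sol.t) else t0
            raise IntegrationError(f"integration failed: {sol.message}", last_time=last)
        values = sol.y.T
    clip_floor = -1e3 * atol
    if np.any(values < clip_floor):
        raise IntegrationError("negative concentrations beyond tolerance", last_time=tf)
    values = np.clip(values, 0.0, None)
    meta = dict(metadata or {})
    meta.setdefault("variant", scheme.variant)
    return TimeCourse(times=times, values=values, species=scheme.species, metadata=meta)


def observe(scheme: KineticScheme, tc: TimeCourse, observable: str) -> TimeCourse:
    """Collapse a full trajectory to a scalar signal: the summed concentration
    of the species in the named observable set (the quantified gel band)."""
    if observable not in scheme.observables:
        raise KeyError(f"unknown observable {observable!r}")
    if tc.is_signal:
        raise ValueError("time course is already an observed signal")
    members = scheme.observables[observable]
    if members:
        signal = np.sum([tc.column(name) for name in members], axis=0)
    else:
        signal = np.zeros_like(tc.times)
    meta = dict(tc.metadata)
    meta["observable"] = observable
    return TimeCourse(times=tc.times, values=signal, metadata=meta)
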