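"""Synthetic pre-steady-state experiments with the statistical structure the
analysis layer assumes: gel-quantified product signals on rapid-quench time
grids, replicated, with additive Gaussian quantification noise.

Two generation modes:

* ``closed_form`` -- signals drawn from the single-exponential transient
  A*(1 - exp(-k_obs t)) (or a line, for very slow misincorporation) with the
  published amplitudes and rate constants as ground truth;
* ``mechanism`` -- signals produced by simulating the full mass-action
  mechanism through the protocol emulators, with the rate-constant set as
  ground truth.

Every generated time course carries its generating truth so that parameter
recovery can be tested end to end.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import celsius_to_kelvin
from .fitting import eyring_rate
from .mechanism import CROSSLINKED, RateConstantSet, TimeCourse, build_scheme, default_rates
from . import protocols as proto

__all__ = [
    "NoiseModel",
    "ExperimentSuite",
    "rfq_time_grid",
    "generate_exponential_timecourse",
    "generate_linear_timecourse",
    "generate_suite",
    "REFERENCE_DESIGN_TRUTH",
]

#: printed single-exponential parameters of the reference experiment set
#: (amplitude nM, k_obs s^-1, replicates)
REFERENCE_DESIGN_TRUTH: dict[str, dict] = {
    "dCTP": {"A": 18.8, "k_obs": 0.77, "replicates": 3},
    "dCTPaS": {"A": 19.8, "k_obs": 0.21, "replicates": 3},
    "dGTP": {"A": 23.8, "k_obs": 5.2e-4, "replicates": 3},
    "dGTPaS": {"slope": 5.2e-4, "replicates": 3},
    "pulse_quench": {"A": 16.3, "k_obs": 0.74, "replicates": 2},
    "pulse_chase": {"A": 24.5, "k_obs": 0.55, "replicates": 2},
}

#: activation parameters generating the temperature series (kcal/mol,
#: cal/(mol*K))
ACTIVATION_TRUTH = {"dH_kcal": 21.5, "dS_cal": 11.5}

#: glycerol %(v/v) -> approximate relative solvent viscosity at 37C
GLYCEROL_VISCOSITY = {0: 1.0, 10: 1.31, 20: 1.76, 30: 2.50}

TEMPERATURES_C = (20.0, 25.0, 30.0, 37.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian quantification scatter on the product signal (nM),
    with an optional proportional (multiplicative CV) term.  Negative noisy
    draws are clamped to zero (signals are concentrations)."""

    sd_nM: float = 0.5
    proportional_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_nM < 0 or self.proportional_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = clean + rng.normal(0.0, self.sd_nM, size=clean.shape)
        if self.proportional_cv > 0:
            noisy += clean * rng.normal(0.0, self.proportional_cv, size=clean.shape)
        return np.clip(noisy, 0.0, None)


def rfq_time_grid(
    k_expected: float, n_points: int = 12, span_halflives: float = 5.0
) -> np.ndarray:
    """Rapid-quench sampling grid: t = 0 followed by a log-spaced grid from
    0.2 to ``span_halflives`` half-lives of the expected rate."""
    return proto.default_quench_times(k_expected, n_points, span_halflives)


def _replicate_rng(seed: int, experiment: str, replicate: int) -> np.random.Generator:
    # stable per-(experiment, replicate) stream so suites are reproducible
    tag = zlib.crc32(experiment.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([seed, tag, replicate])
    return np.random.default_rng(ss)


def generate_exponential_timecourse(
    A: float,
    k_obs: float,
    grid: Sequence[float],
    noise: NoiseModel,
    replicates: int = 3,
    experiment_id: str = "exp",
) -> list[TimeCourse]:
    """Replicated noisy realizations of A*(1 - exp(-k_obs t)) on a grid."""
    if A < 0 or k_obs < 0:
        raise ValueError("A and k_obs must be >= 0")
    grid = np.asarray(grid, dtype=float)
    clean = A * (1.0 - np.exp(-k_obs * grid))
    out = []
    for r in range(replicates):
        rng = _replicate_rng(noise.seed, experiment_id, r)
        out.append(
            TimeCourse(
                times=grid,
                values=noise.apply(clean, rng),
                metadata={
                    "experiment_id": experiment_id,
                    "replicate": r + 1,
                    "truth": {"A": A, "k_obs": k_obs},
                },
            )
        )
    return out


def generate_linear_timecourse(
    slope: float,
    grid: Sequence[float],
    noise: NoiseModel,
    replicates: int = 3,
    experiment_id: str = "lin",
) -> list[TimeCourse]:
    """Replicated noisy realizations of slope*t (early-time linear regime)."""
    grid = np.asarray(grid, dtype=float)
    clean = slope * grid
    out = []
    for r in range(replicates):
        rng = _replicate_rng(noise.seed, experiment_id, r)
        out.append(
            TimeCourse(
                times=grid,
                values=noise.apply(clean, rng),
                metadata={
                    "experiment_id": experiment_id,
                    "replicate": r + 1,
                    "truth": {"slope": slope},
                },
            )
        )
    return out


@dataclass
class ExperimentSuite:
    """Collection of observed time courses keyed by experiment id, each
    carrying the ground truth used to generate it."""

    experiments: dict[str, list[TimeCourse]]
    truth: dict[str, dict]
    design: str = "reference"
    mode: str = "closed_form"
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __iter__(self):
        return iter(self.experiments.items())

    # -- serialization: directory of CSVs plus a JSON manifest -------------

    def to_dir(self, path) -> None:
        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for exp_id, tcs in sorted(self.experiments.items()):
            for tc in tcs:
                rep = tc.metadata.get("replicate", 1)
                for t, s in zip(tc.times, tc.signal):
                    rows.append((exp_id, rep, t, s))
        frame = pd.DataFrame(
            rows, columns=["experiment_id", "replicate", "time_s", "signal_nM"]
        )
        frame.to_csv(path / "timecourses.csv", index=False)
        manifest = {
            "design": self.design,
            "mode": self.mode,
            "noise": {
                "sd_nM": self.noise.sd_nM,
                "proportional_cv": self.noise.proportional_cv,
                "seed": self.noise.seed,
            },
            "truth": self.truth,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def from_dir(cls, path) -> "ExperimentSuite":
        from .io import read_timecourses

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        tcs = read_timecourses(path / "timecourses.csv")
        experiments: dict[str, list[TimeCourse]] = {}
        for tc in tcs:
            experiments.setdefault(tc.metadata["experiment_id"], []).append(tc)
        noise = NoiseModel(**manifest["noise"])
        return cls(
            experiments=experiments,
            truth=manifest["truth"],
            design=manifest["design"],
            mode=manifest["mode"],
            noise=noise,
        )


def generate_suite(
    rates: RateConstantSet | None = None,
    design: str | Sequence[str] = "reference",
    noise: NoiseModel | None = None,
    mode: str = "closed_form",
    elemental_factor: float = 50.0,
    n_points: int = 12,
) -> ExperimentSuite:
    """Generate the full reference experiment set.

    ``design="reference"`` produces the correct/incorrect elemental-effect pairs,
    the pulse-quench/pulse-chase pair, the glycerol viscosity series, and the
    20--37C temperature series.  A custom design is a list of experiment ids
    (subset of the reference design); an empty list yields an empty suite.

    ``mode="closed_form"`` draws signals from the printed transient
    parameters; ``mode="mechanism"`` simulates the mass-action mechanism with
    ``rates`` (defaults to the packaged crosslinked set).  In mechanism mode
    the misincorporation experiments (dGTP/dGTPaS) are omitted: the default
    rate set characterizes correct incorporation only.
    """
    noise = noise or NoiseModel()
    if mode not in ("closed_form", "mechanism"):
        raise ValueError(f"unknown suite mode {mode!r}")

    if design == "reference":
        wanted = None
    else:
        wanted = set(design)

    def included(name: str) -> bool:
        return wanted is None or name in wanted

    experiments: dict[str, list[TimeCourse]] = {}
    truth: dict[str, dict] = {}

    if mode == "closed_form":
        _closed_form_suite(experiments, truth, noise, included, n_points)
    else:
        rates = rates or default_rates(CROSSLINKED)
        _mechanism_suite(
            experiments, truth, rates, noise, included, elemental_factor, n_points
        )

    return ExperimentSuite(
        experiments=experiments,
        truth=truth,
        design="reference" if wanted is None else "custom",
        mode=mode,
        noise=noise,
    )


def _closed_form_suite(experiments, truth, noise, included, n_points):
    for exp_id, spec in REFERENCE_DESIGN_TRUTH.items():
        if not included(exp_id):
            continue
        if "slope" in spec:
            # slow misincorporation probed on the companion experiment's grid
            grid = rfq_time_grid(REFERENCE_DESIGN_TRUTH["dGTP"]["k_obs"], n_points)
            experiments[exp_id] = generate_linear_timecourse(
                spec["slope"], grid, noise, spec["replicates"], exp_id
            )
        else:
            grid = rfq_time_grid(spec["k_obs"], n_points)
            experiments[exp_id] = generate_exponential_timecourse(
                spec["A"], spec["k_obs"], grid, noise, spec["replicates"], exp_id
            )
        truth[exp_id] = dict(spec)

    base = REFERENCE_DESIGN_TRUTH["dCTP"]
    for pct in GLYCEROL_VISCOSITY:
        exp_id = f"viscosity_{pct:02d}"
        if not included(exp_id):
            continue
        grid = rfq_time_grid(base["k_obs"], n_points)
        experiments[exp_id] = generate_exponential_timecourse(
            base["A"], base["k_obs"], grid, noise, 3, exp_id
        )
        truth[exp_id] = {"A": base["A"], "k_obs": base["k_obs"], "glycerol_pct": pct}

    for t_c in TEMPERATURES_C:
        exp_id = f"temperature_{t_c:g}C"
        if not included(exp_id):
            continue
        t_k = celsius_to_kelvin(t_c)
        k = eyring_rate(ACTIVATION_TRUTH["dH_kcal"], ACTIVATION_TRUTH["dS_cal"], t_k)
        grid = rfq_time_grid(k, n_points)
        experiments[exp_id] = generate_exponential_timecourse(
            base["A"], k, grid, noise, 2, exp_id
        )
        truth[exp_id] = {
            "A": base["A"],
            "k_obs": k,
            "temperature_K": t_k,
            **ACTIVATION_TRUTH,
        }


def _mechanism_suite(experiments, truth, rates, noise, included, elemental_factor, n_points):
    scheme = build_scheme(rates.mechanism_variant, rates)

    def noisy(exp_id, tc, replicates):
        out = []
        for r in range(replicates):
            rng = _replicate_rng(noise.seed, exp_id, r)
            out.append(
                TimeCourse(
                    times=tc.times,
                    values=noise.apply(tc.signal, rng),
                    metadata={
                        **tc.metadata,
                        "experiment_id": exp_id,
                        "replicate": r + 1,
                    },
                )
            )
        return out

    def add(exp_id, tc, replicates, extra_truth):
        experiments[exp_id] = noisy(exp_id, tc, replicates)
        truth[exp_id] = {"rates": dict(rates.entries), **extra_truth}

    st_cfg = proto.ProtocolConfig(
        protocol="single_turnover",
        quench_times_s=tuple(rfq_time_grid(rates.kp, n_points)),
    )
    if included("dCTP"):
        add("dCTP", proto.simulate_single_turnover(scheme, rates, st_cfg), 3, {"kp": rates.kp})
    if included("dCTPaS"):
        thio = proto.apply_elemental_substitution(rates, elemental_factor)
        add(
            "dCTPaS",
            proto.simulate_single_turnover(scheme, thio, st_cfg),
            3,
            {"elemental_factor": elemental_factor},
        )

    pulse_cfg = proto.ProtocolConfig(
        protocol="pulse_quench",
        dNTP_uM=1.5,
        quench_times_s=tuple(rfq_time_grid(rates.kp, n_points)),
    )
    if included("pulse_quench"):
        add("pulse_quench", proto.simulate_pulse_quench(scheme, rates, pulse_cfg), 2, {})
    if included("pulse_chase"):
        chase_cfg = proto.ProtocolConfig(
            protocol="pulse_chase",
            dNTP_uM=1.5,
            quench_times_s=pulse_cfg.quench_times_s,
        )
        add("pulse_chase", proto.simulate_pulse_chase(scheme, rates, chase_cfg), 2, {})

    for pct, eta in GLYCEROL_VISCOSITY.items():
        exp_id = f"viscosity_{pct:02d}"
        if not included(exp_id):
            continue
        visc = proto.apply_viscosity(rates, eta)
        add(
            exp_id,
            proto.simulate_single_turnover(scheme, visc, st_cfg),
            3,
            {"glycerol_pct": pct, "relative_viscosity": eta},
        )

    for t_c in TEMPERATURES_C:
        exp_id = f"temperature_{t_c:g}C"
        if not included(exp_id):
            continue
        t_k = celsius_to_kelvin(t_c)
        warm = proto.apply_temperature(
            rates,
            t_k,
            activation={"k5": (ACTIVATION_TRUTH["dH_kcal"], ACTIVATION_TRUTH["dS_cal"])},
        )
        cfg = proto.ProtocolConfig(
            protocol="single_turnover",
            quench_times_s=tuple(rfq_time_grid(warm.kp, n_points)),
            temperature_K=t_k,
        )
        add(
            exp_id,
            proto.simulate_single_turnover(scheme, warm, cfg),
            2,
            {"temperature_K": t_k, **ACTIVATION_TRUTH},
        )
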