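"""Time-course file I/O, pipeline orchestration, and report generation.

Time-course tables are comma-separated UTF-8 text with a mandatory header
``experiment_id,replicate,time_s,signal_nM``; one row per quenched point.
The pipeline runs ingest/simulate -> fit -> aggregate -> diagnose and emits a
JSON report whose every number is traceable to the input files or to the
recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import diagnostics as diag
from . import synth
from .constants import celsius_to_kelvin
from .fitting import (
    aggregate_replicates,
    delta_g,
    fit_eyring,
    fit_linear,
    fit_single_exponential,
)
from .mechanism import TimeCourse

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_timecourses",
    "write_timecourses",
    "RunReport",
    "run_pipeline",
    "round_sig",
]

log = logging.getLogger("polbkin")

REQUIRED_COLUMNS = ("experiment_id", "replicate", "time_s", "signal_nM")


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (summary reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def read_timecourses(path) -> list[TimeCourse]:
    """Read observed time courses, grouped by (experiment_id, replicate).

    Times are sorted within each group; duplicate (experiment, replicate,
    time) rows and non-numeric fields are rejected with the offending line
    numbers.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    for col in ("time_s", "signal_nM"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() & frame[col].notna()] + 2  # header is line 1
        if len(bad):
            raise SchemaError(
                f"non-numeric {col} at line(s) {', '.join(map(str, bad.tolist()))}"
            )
        if frame[col].isna().any():
            bad = (frame.index[frame[col].isna()] + 2).tolist()
            raise SchemaError(f"empty {col} at line(s) {', '.join(map(str, bad))}")
        frame[col] = values

    dup = frame.duplicated(subset=["experiment_id", "replicate", "time_s"], keep=False)
    if dup.any():
        lines = (frame.index[dup] + 2).tolist()
        raise SchemaError(
            f"duplicate (experiment, replicate, time) rows at line(s) "
            f"{', '.join(map(str, lines))}"
        )

    out: list[TimeCourse] = []
    for (exp_id, rep), group in frame.groupby(["experiment_id", "replicate"], sort=True):
        group = group.sort_values("time_s")
        out.append(
            TimeCourse(
                times=group["time_s"].to_numpy(float),
                values=group["signal_nM"].to_numpy(float),
                metadata={"experiment_id": exp_id, "replicate": rep},
            )
        )
    return out


def write_timecourses(tcs, path) -> None:
    """Write observed time courses to the canonical CSV schema."""
    rows = []
    for tc in tcs:
        exp_id = tc.metadata.get("experiment_id", "exp")
        rep = tc.metadata.get("replicate", 1)
        for t, s in zip(tc.times, tc.signal):
            rows.append((exp_id, rep, t, s))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


# --------------------------------------------------------------------------
# pipeline


DEFAULT_ANALYSES = (
    "elemental_correct",
    "elemental_incorrect",
    "partition",
    "eyring",
    "viscosity",
    "verdict",
)


@dataclass
class RunReport:
    fits: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    verdict: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fits": self.fits,
            "diagnostics": self.diagnostics,
            "summary": self.summary,
            "verdict": self.verdict,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = ["polbkin run report", "=" * 18]
        for key, value in sorted(self.summary.items()):
            lines.append(f"{key}: {value}")
        if self.verdict:
            lines.append(f"verdict: {self.verdict['verdict']}")
        lines.append(f"config sha256: {self.provenance.get('config_sha256', '-')}")
        return "\n".join(lines)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _obtain_suite(config: dict) -> synth.ExperimentSuite:
    spec = config.get("suite", {})
    if "path" in spec:
        return synth.ExperimentSuite.from_dir(spec["path"])
    noise = synth.NoiseModel(
        sd_nM=spec.get("noise_sd_nM", 0.0),
        proportional_cv=spec.get("proportional_cv", 0.0),
        seed=spec.get("seed", 0),
    )
    return synth.generate_suite(
        design=spec.get("design", "reference"),
        noise=noise,
        mode=spec.get("mode", "closed_form"),
    )


def _fit_experiment(exp_id: str, tcs) -> dict:
    """Per-replicate fits plus mean +/- SD aggregation for one experiment."""
    if exp_id == "dGTPaS":
        fits = [fit_linear(tc) for tc in tcs]
        slopes = aggregate_replicates([f.slope for f in fits])
        return {
            "kind": "linear",
            "replicates": [f.to_dict() for f in fits],
            "slope_nM_per_s": slopes.to_dict(),
        }
    fits = [fit_single_exponential(tc) for tc in tcs]
    amps = aggregate_replicates([f.amplitude for f in fits])
    ks = aggregate_replicates([f.k_obs for f in fits])
    return {
        "kind": "exponential",
        "replicates": [f.to_dict() for f in fits],
        "amplitude_nM": amps.to_dict(),
        "k_obs_per_s": ks.to_dict(),
    }


def run_pipeline(config: dict) -> RunReport:
    """Execute ingest/simulate -> fit -> aggregate -> diagnose.

    ``config`` sections: ``suite`` (a synthetic-suite spec or a ``path`` to
    serialized time courses), ``analyses`` (list; default all), ``output``
    (optional directory for the JSON + text reports).
    """
    t_start = time.perf_counter()
    analyses = tuple(config.get("analyses", DEFAULT_ANALYSES))
    report = RunReport(
        provenance={
            "config_sha256": _config_hash(config),
            "seed": config.get("suite", {}).get("seed", 0),
            "software_version": _version,
            "analyses": list(analyses),
        }
    )

    suite = _obtain_suite(config)
    log.info("suite ready: %d experiments", len(suite.experiments))

    for exp_id, tcs in sorted(suite.experiments.items()):
        t0 = time.perf_counter()
        report.fits[exp_id] = _fit_experiment(exp_id, tcs)
        log.info("fit %s (%d replicates) in %.3f s", exp_id, len(tcs), time.perf_counter() - t0)

    fits = report.fits
    summary = report.summary

    def mean_of(exp_id, key):
        return fits[exp_id][key]["mean"]

    if "elemental_correct" in analyses and {"dCTP", "dCTPaS"} <= fits.keys():
        k_o = [r["k_obs_per_s"] for r in fits["dCTP"]["replicates"]]
        k_s = [r["k_obs_per_s"] for r in fits["dCTPaS"]["replicates"]]
        effect = diag.elemental_effect(k_o, k_s)
        report.diagnostics["elemental_correct"] = effect.to_dict()
        summary["elemental_effect_correct"] = round_sig(effect.ratio)

    if "elemental_incorrect" in analyses and {"dGTP", "dGTPaS"} <= fits.keys():
        amplitude = mean_of("dGTP", "amplitude_nM")
        slope = mean_of("dGTPaS", "slope_nM_per_s")
        k_thio = diag.kobs_from_slope(slope, amplitude)
        effect = diag.elemental_effect(mean_of("dGTP", "k_obs_per_s"), k_thio)
        payload = effect.to_dict()
        payload["k_thio_from_slope"] = True
        report.diagnostics["elemental_incorrect"] = payload
        summary["elemental_effect_incorrect"] = round_sig(effect.ratio)
        summary["k_obs_thio_incorrect_per_s"] = round_sig(k_thio)

    if "partition" in analyses and {"pulse_quench", "pulse_chase"} <= fits.keys():
        part = diag.partition_analysis(
            A_quench=mean_of("pulse_quench", "amplitude_nM"),
            A_chase=mean_of("pulse_chase", "amplitude_nM"),
            k_obs_chase=mean_of("pulse_chase", "k_obs_per_s"),
        )
        report.diagnostics["partition"] = part.to_dict()
        summary["amplitude_ratio"] = round_sig(part.amplitude_ratio)
        summary["amplitude_difference_nM"] = round_sig(part.amplitude_difference)
        summary["K_int"] = round_sig(part.K_int)
        summary["release_rate_per_s"] = round_sig(part.release_rate)

    if "eyring" in analyses:
        k_by_T = []
        for exp_id, payload in fits.items():
            truth = suite.truth.get(exp_id, {})
            if exp_id.startswith("temperature_") and "k_obs_per_s" in payload:
                t_k = truth.get("temperature_K")
                if t_k is None:
                    t_k = celsius_to_kelvin(float(exp_id.removeprefix("temperature_")[:-1]))
                k_by_T.append((t_k, payload["k_obs_per_s"]["mean"]))
        if len(k_by_T) >= 2:
            efit = fit_eyring(sorted(k_by_T))
            g, g_err = delta_g(efit, celsius_to_kelvin(37.0))
            payload = efit.to_dict()
            payload["dG_37C_kcal_per_mol"] = g
            payload["dG_37C_stderr"] = g_err
            report.diagnostics["eyring"] = payload
            summary["dH_kcal_per_mol"] = round_sig(efit.dH_kcal, 3)
            summary["dS_cal_per_mol_K"] = round_sig(efit.dS_cal, 3)
            summary["dG_37C_kcal_per_mol"] = round_sig(g, 3)

    if "viscosity" in analyses:
        points = []
        for exp_id, payload in fits.items():
            if exp_id.startswith("viscosity_") and "k_obs_per_s" in payload:
                truth = suite.truth.get(exp_id, {})
                eta = truth.get("relative_viscosity")
                if eta is None:
                    pct = truth.get("glycerol_pct", int(exp_id.removeprefix("viscosity_")))
                    eta = synth.GLYCEROL_VISCOSITY[int(pct)]
                points.append((eta, payload["k_obs_per_s"]["mean"]))
        if len(points) >= 2:
            points.sort()
            etas = np.array([p[0] for p in points])
            ks = np.array([p[1] for p in points])
            rel = ks / ks[0]
            lin = fit_linear((etas, rel))
            report.diagnostics["viscosity"] = {
                "relative_viscosities": etas.tolist(),
                "k_obs_per_s": ks.tolist(),
                "fractional_slope_per_unit_viscosity": lin.slope,
            }
            summary["viscosity_slope"] = round_sig(lin.slope)

    if "verdict" in analyses:
        elemental = report.diagnostics.get("elemental_correct", {}).get("ratio")
        visc_slope = report.diagnostics.get("viscosity", {}).get(
            "fractional_slope_per_unit_viscosity"
        )
        amp_ratio = report.diagnostics.get("partition", {}).get("amplitude_ratio")
        if any(v is not None for v in (elemental, visc_slope, amp_ratio)):
            report.verdict = diag.classify_rate_limiting(
                elemental=elemental,
                viscosity_slope=visc_slope,
                amplitude_ratio=amp_ratio,
            )

    report.provenance["runtime_s"] = round(time.perf_counter() - t_start, 3)

    out_dir = config.get("output")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.txt").write_text(report.to_text() + "\n")
        log.info("report written to %s", out_dir)
    return report
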