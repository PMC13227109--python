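"""Derived mechanistic statistics: sulfur elemental effects with benchmark
classification, slope-derived rate constants for near-linear transients,
pulse-quench/pulse-chase amplitude partitioning (internal equilibrium
constant and nucleotide release rate), and the rate-limiting-step verdict.

The sulfur elemental effect is k_obs(dNTP)/k_obs(Sp-dNTPalphaS).  For an
S_N2 phosphoryl transfer the benchmark for a rate-limiting chemical step is
10--160; a ratio below 10 indicates the chemistry is masked by a slower
non-chemical step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import ExponentialFit

__all__ = [
    "BENCHMARK_RANGE",
    "ElementalEffect",
    "PartitionAnalysis",
    "elemental_effect",
    "kobs_from_slope",
    "partition_analysis",
    "classify_rate_limiting",
]

#: revised sulfur-elemental-effect benchmark for a rate-limiting S_N2
#: chemical step (inclusive endpoints)
BENCHMARK_RANGE: tuple[float, float] = (10.0, 160.0)

NOT_CHEMISTRY_LIMITED = "not_chemistry_limited"
CHEMISTRY_LIMITED = "chemistry_limited"
INDETERMINATE = "indeterminate"


@dataclass
class ElementalEffect:
    k_oxygen: float
    k_thio: float
    ratio: float
    ratio_sd: float | None
    per_replicate: tuple[float, ...] | None
    classification: str
    benchmark_range: tuple[float, float] = BENCHMARK_RANGE

    def to_dict(self) -> dict:
        return {
            "k_oxygen_per_s": self.k_oxygen,
            "k_thio_per_s": self.k_thio,
            "ratio": self.ratio,
            "ratio_sd": self.ratio_sd,
            "per_replicate": list(self.per_replicate) if self.per_replicate else None,
            "classification": self.classification,
            "benchmark_range": list(self.benchmark_range),
        }


@dataclass
class PartitionAnalysis:
    """Amplitude partitioning between immediate quench and chase.

    forward_fraction f = A_quench/A_chase is the commitment of the
    pre-chemistry ternary intermediate to product formation; the internal
    equilibrium constant of the chemical step is K_int =
    A_quench/(A_chase - A_quench); the nucleotide release rate is
    k_obs(chase) * (1 - f)/f.
    """

    A_quench: float
    A_chase: float
    amplitude_ratio: float
    amplitude_difference: float
    forward_fraction: float
    K_int: float
    release_rate: float

    def to_dict(self) -> dict:
        return {
            "A_quench_nM": self.A_quench,
            "A_chase_nM": self.A_chase,
            "amplitude_ratio": self.amplitude_ratio,
            "amplitude_difference_nM": self.amplitude_difference,
            "forward_fraction": self.forward_fraction,
            "K_int": self.K_int,
            "release_rate_per_s": self.release_rate,
        }


def _rates_of(arg) -> list[float]:
    if isinstance(arg, ExponentialFit):
        return [arg.k_obs]
    if isinstance(arg, (int, float)):
        return [float(arg)]
    return [f.k_obs if isinstance(f, ExponentialFit) else float(f) for f in arg]


def _classify(ratio: float, benchmark: tuple[float, float]) -> str:
    low, high = benchmark
    if ratio < low:
        return NOT_CHEMISTRY_LIMITED
    if ratio <= high:
        return CHEMISTRY_LIMITED
    return INDETERMINATE


def elemental_effect(
    fit_oxygen,
    fit_thio,
    benchmark_range: tuple[float, float] = BENCHMARK_RANGE,
) -> ElementalEffect:
    """Sulfur elemental effect from natural-dNTP and alpha-thio rates.

    Each argument is a rate (s^-1), an :class:`ExponentialFit`, or a list of
    either (paired replicates).  With paired replicates the per-replicate
    ratios are averaged (mean +/- sample SD); otherwise the ratio of means
    is reported.
    """
    k_o = _rates_of(fit_oxygen)
    k_s = _rates_of(fit_thio)
    if any(k <= 0 for k in k_o + k_s):
        raise ValueError("rate constants must be positive")
    per_replicate = None
    ratio_sd = None
    if len(k_o) > 1 or len(k_s) > 1:
        if len(k_o) != len(k_s):
            raise ValueError("replicate lists must have equal length when paired")
        per_replicate = tuple(o / s for o, s in zip(k_o, k_s))
        ratio = float(np.mean(per_replicate))
        ratio_sd = float(np.std(per_replicate, ddof=1)) if len(per_replicate) > 1 else None
    else:
        ratio = k_o[0] / k_s[0]
    return ElementalEffect(
        k_oxygen=float(np.mean(k_o)),
        k_thio=float(np.mean(k_s)),
        ratio=ratio,
        ratio_sd=ratio_sd,
        per_replicate=per_replicate,
        classification=_classify(ratio, benchmark_range),
        benchmark_range=benchmark_range,
    )


def kobs_from_slope(slope: float, amplitude: float) -> float:
    """Observed rate constant for a near-linear (t << 1/k) transient:
    k = slope/amplitude, with the amplitude taken as the active complex
    concentration established by a faster companion reaction."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    return slope / amplitude


def partition_analysis(
    A_quench: float,
    A_chase: float,
    k_obs_chase: float,
    fraction_decimals: int | None = 2,
) -> PartitionAnalysis:
    """Partitioning of the pre-chemistry intermediate from paired quench and
    chase amplitudes.

    ``fraction_decimals`` rounds the forward fraction before the release-rate
    arithmetic (default 2, matching the convention of reporting the
    partition as two-digit percentages, e.g. 67%/33%); pass ``None`` for
    full precision.
    """
    if A_quench <= 0:
        raise ValueError("A_quench must be positive")
    if A_chase < A_quench:
        raise ValueError("A_chase < A_quench violates the chase >= quench invariant")
    if k_obs_chase <= 0:
        raise ValueError("k_obs_chase must be positive")

    diff = A_chase - A_quench
    ratio = A_chase / A_quench
    f = A_quench / A_chase
    if diff == 0:
        k_int = math.inf
        release = 0.0
    else:
        k_int = A_quench / diff
        f_used = round(f, fraction_decimals) if fraction_decimals is not None else f
        release = k_obs_chase * (1.0 - f_used) / f_used
    return PartitionAnalysis(
        A_quench=A_quench,
        A_chase=A_chase,
        amplitude_ratio=ratio,
        amplitude_difference=diff,
        forward_fraction=f,
        K_int=k_int,
        release_rate=release,
    )


PRE_CHEMICAL = "pre_chemical_local_step"
CHEMISTRY = "chemistry"
LARGE_SCALE_MOTION = "large_scale_motion"


def classify_rate_limiting(
    elemental: ElementalEffect | float | None = None,
    viscosity_slope: float | None = None,
    amplitude_ratio: float | None = None,
    viscosity_threshold: float = 0.10,
) -> dict:
    """Combine evidence channels into a rate-limiting-step verdict.

    Decision table:

    * elemental ratio below benchmark AND amplitude ratio > 1 AND
      |viscosity slope| below threshold (fraction change per unit relative
      viscosity, default 10%) -> ``pre_chemical_local_step``
    * elemental ratio within benchmark -> ``chemistry``
    * viscosity slope ~ -1 (inverse proportionality) -> ``large_scale_motion``
    * otherwise -> ``indeterminate``

    Returns a dict with the verdict and which channels fired.
    """
    if elemental is None and viscosity_slope is None and amplitude_ratio is None:
        raise ValueError("at least one evidence channel is required")

    ratio = elemental.ratio if isinstance(elemental, ElementalEffect) else elemental
    low, high = (
        elemental.benchmark_range
        if isinstance(elemental, ElementalEffect)
        else BENCHMARK_RANGE
    )

    channels = {
        "elemental_below_benchmark": ratio is not None and ratio < low,
        "elemental_within_benchmark": ratio is not None and low <= ratio <= high,
        "viscosity_flat": viscosity_slope is not None
        and abs(viscosity_slope) < viscosity_threshold,
        "viscosity_inverse": viscosity_slope is not None
        and abs(viscosity_slope + 1.0) < viscosity_threshold,
        "amplitude_excess": amplitude_ratio is not None and amplitude_ratio > 1.0,
    }

    if (
        channels["elemental_below_benchmark"]
        and channels["amplitude_excess"]
        and channels["viscosity_flat"]
    ):
        verdict = PRE_CHEMICAL
    elif channels["elemental_within_benchmark"]:
        verdict = CHEMISTRY
    elif channels["viscosity_inverse"]:
        verdict = LARGE_SCALE_MOTION
    else:
        verdict = INDETERMINATE
    return {"verdict": verdict, "channels": channels}
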