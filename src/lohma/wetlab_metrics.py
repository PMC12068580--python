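"""Closed-form wet-lab quantification: growth, comet assay, qPCR.

Growth arithmetic assumes exponential growth N = N0 * exp(r t), so
r = ln(N/N0)/t, the generation (doubling) time is g = ln2/r hours, and a
window of T hours holds T/g generations.  MA-line totals use the
trapezoid rule: bottlenecks x (initial + final generations per
bottleneck)/2.

Comet-assay damage metrics are unit-agnostic products of tail geometry
and the percentage of DNA signal in the tail; qPCR fold changes follow
the 2^-ddCt method against a reference (housekeeping) gene and a control
condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GrowthObservation:
    n0: float  # initial cell count
    n: float  # final cell count
    t: float  # hours

    def __post_init__(self) -> None:
        if self.n0 <= 0 or self.n <= 0 or self.t <= 0:
            raise ValueError("cell counts and time must be positive")


def growth_rate(obs: GrowthObservation) -> float:
    """r per hour from N = N0 * exp(r t)."""
    return math.log(obs.n / obs.n0) / obs.t


def generation_time(r: float) -> float:
    """Doubling time g = ln2 / r hours; requires r > 0."""
    if r <= 0:
        raise ValueError("growth rate must be positive for a generation time")
    return math.log(2) / r


def generations_in(t_hours: float, g_hours: float) -> float:
    """Number of generations in a window of t hours."""
    if g_hours <= 0:
        raise ValueError("generation time must be positive")
    return t_hours / g_hours


def total_generations(
    n_bottlenecks: int, initial_per_bottleneck: float, final_per_bottleneck: float
) -> float:
    """Bottlenecks x (initial + final generations per bottleneck) / 2."""
    if n_bottlenecks < 0 or initial_per_bottleneck < 0 or final_per_bottleneck < 0:
        raise ValueError("inputs must be >= 0")
    return n_bottlenecks * (initial_per_bottleneck + final_per_bottleneck) / 2.0


# ---------------------------------------------------------------------------
# Comet assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CometMeasurement:
    pct_tail_dna: float  # percent of total signal in the tail
    tail_length: float
    head_tail_centre_distance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_tail_dna <= 100.0:
            raise ValueError("%Tail DNA must be in [0, 100]")
        if self.tail_length < 0 or self.head_tail_centre_distance < 0:
            raise ValueError("lengths must be >= 0")


def comet_metrics(m: CometMeasurement) -> tuple[float, float, float]:
    """(%Tail DNA, Tail Moment, Olive Tail Moment).

    Tail Moment = tail length x %Tail DNA; Olive Tail Moment =
    head-to-tail-centre distance x %Tail DNA.  Length units pass through
    unchanged.
    """
    tm = m.tail_length * m.pct_tail_dna
    otm = m.head_tail_centre_distance * m.pct_tail_dna
    return m.pct_tail_dna, tm, otm


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrObservation:
    """Ct values of target and reference gene in treated and control, one replicate."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_treated, self.ct_reference_treated,
            self.ct_target_control, self.ct_reference_control,
        ):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")

    @property
    def ddct(self) -> float:
        d_treated = self.ct_target_treated - self.ct_reference_treated
        d_control = self.ct_target_control - self.ct_reference_control
        return d_treated - d_control

    @property
    def fold(self) -> float:
        return 2.0 ** (-self.ddct)


def fold_change(
    replicates: list[QpcrObservation], log_scale: bool = False
) -> tuple[float, float]:
    """Mean fold change and standard error over biological replicates.

    The SE is computed on the fold-change scale by default;
    ``log_scale=True`` averages -ddCt (log2 folds) and reports the
    geometric mean with its SE back-transformed factorwise.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    folds = np.array([r.fold for r in replicates], dtype=float)
    if log_scale:
        logs = np.log2(folds)
        mean = float(2.0 ** logs.mean())
        se = float(
            2.0 ** (logs.std(ddof=1) / math.sqrt(len(logs))) if len(logs) > 1 else 1.0
        )
        return mean, se
    mean = float(folds.mean())
    se = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else 0.0
    return mean, se
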