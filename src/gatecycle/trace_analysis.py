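"""Steady-state current extraction and stationary noise analysis.

The voltage-step protocol holds the membrane at a fixed potential for
350 ms; the analysis averages the final 40 ms of each sweep, where the
current is stationary.  From the windowed mean ``I`` (magnitude after
baseline subtraction) and unbiased sample variance ``sigma^2``, together
with the externally measured single-channel current ``i``, the number of
channels in the patch follows from the binomial moment identities:

    N  = I^2 / (i I - sigma^2)
    Po = I / (i N)

``i I - sigma^2 <= 0`` means the observed variance exceeds what N two-state
channels can produce (excess recording noise, or channels dwelling near
Po = 1/2); it is reported as an estimation error, never as a silent negative
or infinite N.  An optional noise-floor correction subtracts a known
additive-noise variance (e.g. measured from a ligand-free sweep of the same
cell) from ``sigma^2`` before inverting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, EstimationError, InputError
from .simulate import RecordingTrace

__all__ = [
    "SteadyStateMeasurement",
    "NoiseAnalysisResult",
    "steady_state",
    "channel_count",
    "open_probability_from_noise",
    "noise_analysis",
    "steady_state_table",
]

DEFAULT_WINDOW_MS = 40.0

STEADY_STATE_COLUMNS = [
    "construct",
    "ligand",
    "voltage_mV",
    "concentration_uM",
    "replicate",
    "I_mean_pA",
    "I_signed_pA",
    "I_var_pA2",
    "baseline_pA",
    "window_start_ms",
    "window_end_ms",
    "n_window_samples",
]


@dataclass
class SteadyStateMeasurement:
    """Windowed mean/variance of one sweep, with its metadata.

    ``I_mean`` is the baseline-subtracted current magnitude; ``I_signed``
    keeps the raw (signed, baseline-included) windowed mean for baseline
    bookkeeping.
    """

    construct: str
    ligand: str
    voltage_mV: float
    concentration_uM: float
    replicate: str
    I_mean: float
    I_signed: float
    I_var: float
    baseline: float
    window: Tuple[float, float]
    n_window_samples: int

    def to_row(self) -> dict:
        return {
            "construct": self.construct,
            "ligand": self.ligand,
            "voltage_mV": self.voltage_mV,
            "concentration_uM": self.concentration_uM,
            "replicate": self.replicate,
            "I_mean_pA": self.I_mean,
            "I_signed_pA": self.I_signed,
            "I_var_pA2": self.I_var,
            "baseline_pA": self.baseline,
            "window_start_ms": self.window[0],
            "window_end_ms": self.window[1],
            "n_window_samples": self.n_window_samples,
        }


@dataclass
class NoiseAnalysisResult:
    """Channel count and open probability from stationary noise analysis."""

    N_channels: float
    Po: float
    i_single: float
    I_max: float


def steady_state(
    trace: RecordingTrace,
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline: float = 0.0,
) -> SteadyStateMeasurement:
    """Mean and variance over the window flush with the end of the step.

    The mean is baseline-subtracted and collapsed to a magnitude (inward
    sweeps at negative voltages analyse identically to outward ones); the
    variance is the unbiased (n-1) sample variance over the same window.
    """
    duration = trace.duration_ms
    if window_ms <= 0 or window_ms > duration + trace.sample_interval_ms:
        raise InputError(
            f"window of {window_ms} ms does not fit a {duration:.6g} ms trace"
        )
    start = duration - window_ms
    idx = trace.time_ms >= start - 1e-9
    win = trace.samples[idx]
    if win.size < 2:
        raise InputError(f"analysis window holds {win.size} sample(s); need >= 2")
    signed = float(np.mean(win))
    return SteadyStateMeasurement(
        construct=trace.construct,
        ligand=trace.ligand,
        voltage_mV=trace.voltage_mV,
        concentration_uM=trace.concentration_uM,
        replicate=trace.replicate,
        I_mean=abs(signed - baseline),
        I_signed=signed,
        I_var=float(np.var(win, ddof=1)),
        baseline=float(baseline),
        window=(start, duration),
        n_window_samples=int(win.size),
    )


def channel_count(
    I_mean: float,
    I_var: float,
    i_single: float,
    noise_var: float = 0.0,
) -> float:
    """Channel count ``N = I^2 / (|i| I - sigma^2)`` from stationary moments.

    ``noise_var`` (pA^2) is subtracted from ``I_var`` first when a measured
    additive-noise floor is available; it defaults to no correction.
    """
    if i_single == 0 or not np.isfinite(i_single):
        raise DomainError(f"i_single must be finite and nonzero, got {i_single!r}")
    if I_mean <= 0 or not np.isfinite(I_mean):
        raise DomainError(f"I_mean must be finite and > 0, got {I_mean!r}")
    if noise_var < 0:
        raise DomainError(f"noise_var must be >= 0, got {noise_var!r}")
    var = I_var - noise_var
    if var < 0:
        var = 0.0  # corrected variance cannot be negative; clamp to the Po->1 limit
    denom = abs(i_single) * I_mean - var
    if denom <= 0:
        raise EstimationError(
            "variance exceeds the binomial bound (|i|*I <= sigma^2): "
            f"|i|*I = {abs(i_single) * I_mean:.6g} pA^2, sigma^2 = {var:.6g} pA^2; "
            "channel count undefined (excess noise or Po near 1/2 with too few channels)"
        )
    return I_mean**2 / denom


def open_probability_from_noise(
    I_mean: float,
    i_single: float,
    N_channels: float,
    tol: float = 0.05,
) -> float:
    """Open probability as the macroscopic/maximum current ratio.

    ``Po = I / (|i| N)``.  Values above ``1 + tol`` or at/below zero are
    inconsistent inputs and raise; values in ``(1, 1+tol]`` — possible from
    sampling error on a saturated patch — are returned as computed, never
    clamped.
    """
    if N_channels <= 0 or not np.isfinite(N_channels):
        raise DomainError(f"N_channels must be finite and > 0, got {N_channels!r}")
    if i_single == 0 or not np.isfinite(i_single):
        raise DomainError(f"i_single must be finite and nonzero, got {i_single!r}")
    po = I_mean / (abs(i_single) * N_channels)
    if po <= 0 or po > 1.0 + tol:
        raise EstimationError(
            f"open probability estimate {po:.6g} outside (0, 1 + {tol}]: inconsistent inputs"
        )
    return po


def noise_analysis(
    measurement: SteadyStateMeasurement,
    i_single: float,
    noise_var: float = 0.0,
) -> NoiseAnalysisResult:
    """Full stationary noise analysis of one steady-state measurement."""
    n = channel_count(measurement.I_mean, measurement.I_var, i_single, noise_var=noise_var)
    po = open_probability_from_noise(measurement.I_mean, i_single, n)
    return NoiseAnalysisResult(
        N_channels=n, Po=po, i_single=i_single, I_max=abs(i_single) * n
    )


def steady_state_table(
    traces: Iterable[RecordingTrace],
    window_ms: float = DEFAULT_WINDOW_MS,
    subtract_zero_sweep: bool = True,
) -> pd.DataFrame:
    """Steady-state measurements for a set of sweeps, one row per sweep.

    When ``subtract_zero_sweep`` is set, each cell's zero-concentration
    sweep (matched on construct, voltage and replicate) provides the
    baseline that is subtracted from every other sweep of that cell; cells
    without a zero sweep use baseline 0.
    """
    traces = list(traces)
    baselines: dict = {}
    if subtract_zero_sweep:
        for tr in traces:
            if tr.concentration_uM == 0.0:
                m = steady_state(tr, window_ms=window_ms, baseline=0.0)
                baselines[(tr.construct, tr.voltage_mV, tr.replicate)] = m.I_signed
    rows = []
    for tr in traces:
        base = baselines.get((tr.construct, tr.voltage_mV, tr.replicate), 0.0)
        rows.append(steady_state(tr, window_ms=window_ms, baseline=base).to_row())
    return pd.DataFrame(rows, columns=STEADY_STATE_COLUMNS)
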