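"""Synthetic patch-clamp recordings with the statistical structure the
analysis assumes.

Each sweep models ``N`` identical, independent two-state channels held at a
fixed voltage: every sample is

    I_t = baseline + i_single * Binomial(N, Po(c; Kd, L)) + Normal(0, noise_sd)

so in the stationary regime the macroscopic mean is ``baseline + N i Po`` and
the variance is ``N i^2 Po (1 - Po) + noise_sd^2`` — exactly the moments the
stationary noise analysis inverts.  Samples are independent across time
(a Markov kinetic scheme is deliberately not modelled: the downstream
analysis is a stationary moment method and never looks at correlations).

Sign convention: ``i_single`` is negative at negative voltages, so inward
currents are generated negative; the analysis side collapses to magnitudes
after baseline subtraction.

A complete four-corner mutant-cycle study (wild-type/mutant x two ligands)
is generated cell by cell: each simulated cell has its own channel count
(drawn with +-20% jitter around the nominal N to emulate expression
variability), a zero-concentration sweep (baseline/noise floor), a ladder of
test-ligand sweeps, and — for cells probed with the non-reference ligand — a
saturating sweep of the reference ligand on the same cell, mirroring the
per-cell normalization protocol.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, InputError
from .gating import open_probability, pomax_from_l

__all__ = [
    "SimulationCondition",
    "RecordingTrace",
    "Study",
    "child_seed",
    "simulate_trace",
    "simulate_dose_response",
    "generate_tmca_study",
    "read_study",
    "default_ladder",
    "default_noise_sd",
    "default_study_conditions",
    "expected_mean",
    "expected_variance",
]

#: Default perfusion ladder in µM; the 2000 µM top point doubles as the
#: reference concentration (2 mM reference ligand).
DEFAULT_LADDER = (10.0, 30.0, 100.0, 300.0, 1000.0, 2000.0)
DEFAULT_DURATION_MS = 350.0

TRACE_COLUMNS = [
    "construct",
    "ligand",
    "voltage_mV",
    "concentration_uM",
    "replicate",
    "time_ms",
    "current_pA",
]


def default_ladder() -> tuple:
    return DEFAULT_LADDER


def child_seed(master: int, *keys) -> int:
    """Deterministic, platform-stable child seed.

    SHA-256 of the master seed and the string forms of the keys, reduced to
    a non-negative int below 2**31.
    """
    digest = hashlib.sha256("|".join([str(int(master))] + [str(k) for k in keys]).encode())
    return int.from_bytes(digest.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimulationCondition:
    """Generating parameters for one (construct, ligand, voltage) condition.

    ``activates=False`` marks a ligand that cannot open this construct
    (the non-activating corner case); ``kd``/``L`` are then ignored and the
    open probability is identically zero.
    """

    construct: str
    ligand: str
    voltage_mV: float
    n_channels: int
    i_single: float
    kd: Optional[float] = None
    L: Optional[float] = None
    baseline_pA: float = 0.0
    noise_sd_pA: float = 0.0
    activates: bool = True

    def __post_init__(self):
        if self.n_channels < 1 or int(self.n_channels) != self.n_channels:
            raise DomainError(f"n_channels must be a positive integer, got {self.n_channels!r}")
        if self.i_single == 0 or not np.isfinite(self.i_single):
            raise DomainError(f"i_single must be finite and nonzero, got {self.i_single!r}")
        if self.noise_sd_pA < 0 or not np.isfinite(self.noise_sd_pA):
            raise DomainError(f"noise_sd_pA must be finite and >= 0, got {self.noise_sd_pA!r}")
        if self.activates:
            if self.kd is None or self.L is None:
                raise DomainError("kd and L are required for an activating condition")
            if self.kd <= 0 or self.L <= 0:
                raise DomainError(f"Kd and L must be > 0, got Kd={self.kd!r}, L={self.L!r}")

    def open_prob(self, concentration: float) -> float:
        if not self.activates or concentration == 0.0:
            return 0.0
        return open_probability(concentration, self.kd, self.L)

    @property
    def po_max(self) -> float:
        return pomax_from_l(self.L) if self.activates else 0.0


def expected_mean(cond: SimulationCondition, concentration: float) -> float:
    """Analytic stationary mean current (pA), baseline included."""
    return cond.baseline_pA + cond.n_channels * cond.i_single * cond.open_prob(concentration)


def expected_variance(cond: SimulationCondition, concentration: float) -> float:
    """Analytic stationary current variance (pA^2)."""
    po = cond.open_prob(concentration)
    return cond.n_channels * cond.i_single**2 * po * (1.0 - po) + cond.noise_sd_pA**2


def default_noise_sd(n_channels: int, i_single: float, po_max: float) -> float:
    """Default additive recording noise: 10% of the saturating current."""
    return 0.1 * abs(i_single) * n_channels * po_max


@dataclass
class RecordingTrace:
    """One voltage-step sweep: metadata plus the sampled current."""

    construct: str
    ligand: str
    voltage_mV: float
    concentration_uM: float
    replicate: str
    sample_interval_ms: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        for name in ("construct", "ligand", "replicate"):
            if not getattr(self, name):
                raise InputError(f"trace metadata field {name!r} must be non-empty")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * self.sample_interval_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sample_interval_ms


def simulate_trace(
    cond: SimulationCondition,
    concentration: float,
    n_samples: int,
    seed: int,
    replicate: str = "r0",
    duration_ms: float = DEFAULT_DURATION_MS,
) -> RecordingTrace:
    """Simulate one stationary voltage-step sweep.

    Every sample is an independent draw of
    ``baseline + i_single * Binomial(N, Po(c)) + Normal(0, noise_sd)``.
    Identical arguments (including the seed) give identical sample
    sequences.
    """
    if n_samples < 1:
        raise InputError(f"n_samples must be >= 1, got {n_samples}")
    if concentration < 0 or not np.isfinite(concentration):
        raise DomainError(f"concentration must be finite and >= 0, got {concentration!r}")
    po = cond.open_prob(concentration)
    rng = np.random.default_rng(seed)
    open_counts = rng.binomial(cond.n_channels, po, size=n_samples) if po > 0 else np.zeros(n_samples)
    samples = cond.baseline_pA + cond.i_single * open_counts
    if cond.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, cond.noise_sd_pA, size=n_samples)
    return RecordingTrace(
        construct=cond.construct,
        ligand=cond.ligand,
        voltage_mV=cond.voltage_mV,
        concentration_uM=float(concentration),
        replicate=replicate,
        sample_interval_ms=duration_ms / n_samples,
        samples=np.asarray(samples, dtype=float),
    )


def simulate_dose_response(
    cond: SimulationCondition,
    concentrations: Sequence[float],
    n_sweeps: int,
    n_samples: int,
    seed: int,
    replicate: str = "r0",
) -> list[RecordingTrace]:
    """One or more sweeps per concentration of an ascending perfusion ladder.

    Child seeds derive deterministically from the master seed, the
    concentration index and the sweep index.
    """
    concs = [float(c) for c in concentrations]
    if len(set(concs)) != len(concs):
        raise InputError(f"duplicate concentrations in ladder: {concs}")
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise InputError(f"concentrations must be strictly ascending: {concs}")
    traces = []
    for ci, c in enumerate(concs):
        for s in range(n_sweeps):
            sd = child_seed(seed, cond.construct, cond.ligand, cond.voltage_mV, ci, s, replicate)
            traces.append(simulate_trace(cond, c, n_samples, sd, replicate=replicate))
    return traces


@dataclass
class Study:
    """A complete simulated study: sweeps plus the generating manifest."""

    traces: list[RecordingTrace]
    manifest: dict

    def traces_frame(self) -> pd.DataFrame:
        frames = []
        for tr in self.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "construct": tr.construct,
                        "ligand": tr.ligand,
                        "voltage_mV": tr.voltage_mV,
                        "concentration_uM": tr.concentration_uM,
                        "replicate": tr.replicate,
                        "time_ms": tr.time_ms,
                        "current_pA": tr.samples,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=TRACE_COLUMNS)
        return pd.concat(frames, ignore_index=True)

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        df = self.traces_frame()
        df.to_csv(directory / "traces.csv", index=False, float_format="%.6g")
        with open(directory / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        return directory


def read_study(directory) -> Study:
    """Read a study written by :meth:`Study.write`.

    The manifest round-trips every generating parameter; traces are
    reassembled sweep by sweep in file order.
    """
    directory = Path(directory)
    df = pd.read_csv(directory / "traces.csv", comment="#")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trace table missing columns: {sorted(missing)}")
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    traces = []
    keys = ["construct", "ligand", "voltage_mV", "concentration_uM", "replicate"]
    for key, grp in df.groupby(keys, sort=False):
        t = grp["time_ms"].to_numpy()
        dt = t[1] - t[0] if len(t) > 1 else 1.0
        traces.append(
            RecordingTrace(
                construct=str(key[0]),
                ligand=str(key[1]),
                voltage_mV=float(key[2]),
                concentration_uM=float(key[3]),
                replicate=str(key[4]),
                sample_interval_ms=float(dt),
                samples=grp["current_pA"].to_numpy(),
            )
        )
    return Study(traces=traces, manifest=manifest)


def _condition_to_dict(cond: SimulationCondition) -> dict:
    return {
        "construct": cond.construct,
        "ligand": cond.ligand,
        "voltage_mV": float(cond.voltage_mV),
        "n_channels": int(cond.n_channels),
        "i_single_pA": float(cond.i_single),
        "kd_uM": None if cond.kd is None else float(cond.kd),
        "L": None if cond.L is None else float(cond.L),
        "baseline_pA": float(cond.baseline_pA),
        "noise_sd_pA": float(cond.noise_sd_pA),
        "activates": bool(cond.activates),
    }


def condition_from_dict(d: dict) -> SimulationCondition:
    return SimulationCondition(
        construct=d["construct"],
        ligand=d["ligand"],
        voltage_mV=d["voltage_mV"],
        n_channels=d["n_channels"],
        i_single=d["i_single_pA"],
        kd=d["kd_uM"],
        L=d["L"],
        baseline_pA=d["baseline_pA"],
        noise_sd_pA=d["noise_sd_pA"],
        activates=d["activates"],
    )


def generate_tmca_study(
    corners: Sequence[SimulationCondition],
    ladder: Sequence[float] = DEFAULT_LADDER,
    replicates: int = 6,
    seed: int = 0,
    n_samples: int = 20000,
    n_jitter: float = 0.2,
    reference_ligand: Optional[str] = None,
    reference_concentration: float = 2000.0,
) -> Study:
    """Generate a four-corner mutant-cycle study.

    ``corners`` must cover the 2x2 design {wild type, mutant} x {reference
    ligand, alternative ligand} at a single voltage.  For every corner,
    ``replicates`` independent cells are simulated; each cell carries its own
    channel count N drawn uniformly within ``+-n_jitter`` of the corner's
    nominal value, a zero-concentration sweep, the full ladder of its test
    ligand, and (for alternative-ligand cells) a saturating reference-ligand
    sweep using the same cell's N and the construct's reference-corner
    (Kd, L).

    The manifest records every generating parameter and seed, so downstream
    parameter-recovery scoring is exact; identical master seeds give
    byte-identical studies.
    """
    if len(corners) != 4:
        raise InputError(f"a mutant cycle needs exactly 4 corners, got {len(corners)}")
    voltages = {c.voltage_mV for c in corners}
    if len(voltages) != 1:
        raise InputError(f"all four corners must share a voltage, got {sorted(voltages)}")
    constructs = sorted({c.construct for c in corners})
    ligands = sorted({c.ligand for c in corners})
    if len(constructs) != 2 or len(ligands) != 2:
        raise InputError(
            "corners must cover two constructs x two ligands, got "
            f"constructs={constructs}, ligands={ligands}"
        )
    combos = {(c.construct, c.ligand) for c in corners}
    if len(combos) != 4:
        raise InputError("duplicated corner: each (construct, ligand) pair must appear once")
    if replicates < 3:
        raise InputError(f"replicates must be >= 3, got {replicates}")
    if reference_ligand is None:
        reference_ligand = ligands[0]
    if reference_ligand not in ligands:
        raise InputError(f"reference ligand {reference_ligand!r} not among corner ligands {ligands}")

    by_combo = {(c.construct, c.ligand): c for c in corners}
    ladder = [float(c) for c in ladder]
    traces: list[RecordingTrace] = []
    cell_manifest = []
    for corner in sorted(corners, key=lambda c: (c.construct, c.ligand)):
        ref_cond = by_combo[(corner.construct, reference_ligand)]
        for rep in range(replicates):
            rep_id = f"{corner.construct}:{corner.ligand}:r{rep}"
            jseed = child_seed(seed, "jitter", corner.construct, corner.ligand, rep)
            jit = np.random.default_rng(jseed).uniform(-n_jitter, n_jitter)
            n_cell = max(1, int(round(corner.n_channels * (1.0 + jit))))
            cell_cond = replace(corner, n_channels=n_cell)
            cell_manifest.append(
                {
                    "replicate": rep_id,
                    "construct": corner.construct,
                    "ligand": corner.ligand,
                    "n_channels": n_cell,
                    "jitter_seed": jseed,
                }
            )
            # zero-concentration sweep: baseline + noise floor for this cell
            traces.append(
                simulate_trace(
                    cell_cond,
                    0.0,
                    n_samples,
                    child_seed(seed, "zero", rep_id, corner.voltage_mV),
                    replicate=rep_id,
                )
            )
            for ci, conc in enumerate(ladder):
                traces.append(
                    simulate_trace(
                        cell_cond,
                        conc,
                        n_samples,
                        child_seed(seed, "ladder", rep_id, corner.voltage_mV, ci),
                        replicate=rep_id,
                    )
                )
            if corner.ligand != reference_ligand:
                # same cell, perfused with the saturating reference ligand
                ref_cell = replace(ref_cond, n_channels=n_cell)
                traces.append(
                    simulate_trace(
                        ref_cell,
                        float(reference_concentration),
                        n_samples,
                        child_seed(seed, "refsweep", rep_id, corner.voltage_mV),
                        replicate=rep_id,
                    )
                )

    manifest = {
        "seed": int(seed),
        "replicates": int(replicates),
        "n_samples": int(n_samples),
        "n_jitter": float(n_jitter),
        "ladder_uM": ladder,
        "reference_ligand": reference_ligand,
        "reference_concentration_uM": float(reference_concentration),
        "voltage_mV": float(corners[0].voltage_mV),
        "corners": [_condition_to_dict(by_combo[k]) for k in sorted(by_combo)],
        "cells": cell_manifest,
    }
    return Study(traces=traces, manifest=manifest)


def default_study_conditions(kind: str = "coupled", voltage_mV: float = 80.0) -> list[SimulationCondition]:
    """Generating corner parameters for the three canonical study designs.

    ``coupled``    — the mutation perturbs the two ligands differently,
                     by construction |LnOmega| = 3.0 (1.5 per axis);
    ``null``       — the mutation rescales both ligands' Kd identically,
                     LnOmega = 0;
    ``incomplete`` — as ``coupled`` but the alternative ligand cannot
                     activate the mutant (non-activating corner).

    The wild-type/reference corner sits at EC50 = 62.64 µM with
    Po_max = 0.8 (L = 4, Kd = 313.2 µM); mutants gate with Po_max = 0.6 so
    their open probability stays in the noise-analysis-friendly range.  The
    single-channel current is +1 pA at +80 mV and −0.8 pA at −80 mV, the
    nominal patch holds 200 channels, the standing leak is +20 pA at +80 mV
    and 0 at −80 mV, and the recording noise is 10% of each corner's
    saturating current.
    """
    if kind not in {"coupled", "null", "incomplete"}:
        raise InputError(f"unknown study kind {kind!r}")
    if voltage_mV >= 0:
        i_single, baseline = 1.0, 20.0
    else:
        i_single, baseline = -0.8, 0.0
    n = 200
    wt, mut = "WT", "MUT"
    lig_ref, lig_alt = "ligA", "ligB"

    kd_wt_ref, L_wt_ref = 62.64 * 5.0, 4.0          # EC50 62.64 µM, Po_max 0.8
    kd_wt_alt, L_wt_alt = kd_wt_ref * 1.5, 7.0 / 3.0  # Po_max 0.7
    shift = float(np.exp(1.5))
    kd_mut_ref, L_mut = kd_wt_ref * shift, 1.5       # mutant Po_max 0.6
    if kind == "null":
        kd_mut_alt = kd_wt_alt * shift               # same fold-change: LnOmega = 0
    else:
        kd_mut_alt = kd_wt_alt / shift               # opposite sign: |LnOmega| = 3

    def make(construct, ligand, kd, L, activates=True):
        po_max = pomax_from_l(L) if activates else 0.0
        return SimulationCondition(
            construct=construct,
            ligand=ligand,
            voltage_mV=voltage_mV,
            n_channels=n,
            i_single=i_single,
            kd=kd if activates else None,
            L=L if activates else None,
            baseline_pA=baseline,
            noise_sd_pA=default_noise_sd(n, i_single, po_max) if activates else 5.0,
            activates=activates,
        )

    corners = [
        make(wt, lig_ref, kd_wt_ref, L_wt_ref),
        make(wt, lig_alt, kd_wt_alt, L_wt_alt),
        make(mut, lig_ref, kd_mut_ref, L_mut),
        make(mut, lig_alt, kd_mut_alt, L_mut, activates=(kind != "incomplete")),
    ]
    return corners
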