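"""End-to-end orchestration: traces -> steady state -> fits -> gating -> cycles.

The estimation chain per voltage mirrors the experimental protocol:

1. every sweep is reduced to a windowed steady-state mean/variance, with the
   cell's own zero-concentration sweep as baseline;
2. each corner's concentration-response curve is fitted with a Hill curve
   (h = 1 by default);
3. the maximal open probability is anchored per construct — the wild type
   at the externally measured single-channel value ``po_max_ref``, mutants
   by stationary noise analysis of their saturating reference-ligand sweeps
   (with a c/(c+EC50) saturation correction) — and carried to the
   alternative ligand by per-cell normalization to the same cell's
   saturating reference-ligand sweep;
4. EC50 and Po_max are converted to (Kd, L) through the two-state
   identities, and the four corner Kds are combined into LnOmega, a
   coupling energy in kT, and an interaction classification.

Corners whose ligand fails to activate the channel are detected before
fitting (top response below an absolute floor) and yield an incomplete
cycle, never a spurious Kd.

All randomness is confined to the simulator; given identical inputs and
config the pipeline output is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_response import DoseResponseCurve, HillFit, fit_hill, gating_from_fit
from .errors import DomainError, EstimationError, FitError, InputError
from .gating import GatingParams, gating_table
from .mutant_cycle import (
    DEFAULT_THRESHOLD_KT,
    MutantCycleResult,
    build_cycle,
    cycle_report_table,
)
from .simulate import Study, child_seed, read_study
from .trace_analysis import (
    DEFAULT_WINDOW_MS,
    channel_count,
    open_probability_from_noise,
    steady_state_table,
)

__all__ = [
    "StudyConfig",
    "PipelineResult",
    "run_pipeline",
    "analyze_study",
    "config_from_manifest",
    "bootstrap_coupling_sem",
]


@dataclass
class StudyConfig:
    """Analysis settings; defaults follow the recording protocol
    (±80 mV steps of 350 ms, last-40-ms window, 2 mM reference ligand,
    1.5 kT coupling threshold)."""

    wildtype: str = "WT"
    reference_ligand: str = "ligA"
    reference_concentration_uM: float = 2000.0
    po_max_ref: float = 0.8
    sem_po_max_ref: float = 0.0
    window_ms: float = DEFAULT_WINDOW_MS
    voltages: Optional[Sequence[float]] = None  # None -> every voltage present
    i_single: dict = field(default_factory=dict)  # (construct, voltage_mV) -> pA
    fix_h: bool = True
    threshold_kT: float = DEFAULT_THRESHOLD_KT
    noise_floor: str = "none"  # "none" | "zero_sweep"
    activation_floor_pA: float = 1.0
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if not (0.0 < self.po_max_ref < 1.0):
            raise DomainError(f"po_max_ref must lie in (0, 1), got {self.po_max_ref!r}")
        if self.noise_floor not in {"none", "zero_sweep"}:
            raise InputError(f"noise_floor must be 'none' or 'zero_sweep', got {self.noise_floor!r}")

    def i_single_for(self, construct: str, voltage_mV: float) -> Optional[float]:
        return self.i_single.get((construct, float(voltage_mV)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["i_single"] = [
            {"construct": k[0], "voltage_mV": k[1], "i_pA": v}
            for k, v in sorted(self.i_single.items())
        ]
        d["voltages"] = None if self.voltages is None else [float(v) for v in self.voltages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        entries = d.pop("i_single", []) or []
        if isinstance(entries, dict):
            entries = [
                {"construct": k[0], "voltage_mV": k[1], "i_pA": v} for k, v in entries.items()
            ]
        i_single = {(e["construct"], float(e["voltage_mV"])): float(e["i_pA"]) for e in entries}
        return cls(i_single=i_single, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sha256(self) -> str:
        """Hash of the analysis settings; I/O paths do not affect it."""
        d = self.to_dict()
        d.pop("input_dir", None)
        d.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def config_from_manifest(manifest: dict, **overrides) -> StudyConfig:
    """Build an analysis config from a simulated study's manifest.

    Only quantities the experimental protocol also treats as measured
    inputs are taken from the manifest: the single-channel currents, the
    reference ligand/concentration and the construct labels.  Generating
    Kd/L values are never read.
    """
    manifests = manifest.get("studies", [manifest])
    i_single = {}
    constructs = set()
    ligands = set()
    ref_ligand = None
    ref_conc = None
    for m in manifests:
        ref_ligand = m["reference_ligand"]
        ref_conc = m["reference_concentration_uM"]
        for c in m["corners"]:
            i_single[(c["construct"], float(c["voltage_mV"]))] = float(c["i_single_pA"])
            constructs.add(c["construct"])
            ligands.add(c["ligand"])
    wildtype = overrides.pop("wildtype", "WT" if "WT" in constructs else sorted(constructs)[0])
    defaults = dict(
        wildtype=wildtype,
        reference_ligand=ref_ligand,
        reference_concentration_uM=float(ref_conc),
        i_single=i_single,
        noise_floor="zero_sweep",
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


# ---------------------------------------------------------------------------
# corner-level data and estimation


@dataclass
class _CornerData:
    construct: str
    ligand: str
    voltage_mV: float
    cells: list
    concs: np.ndarray           # ascending ladder, > 0
    R: np.ndarray               # cells x concs raw response magnitudes (pA)
    ref_resp: np.ndarray        # per-cell saturating reference-ligand response (pA)
    noise_var: np.ndarray       # per-cell additive-noise floor variance (pA^2)
    top_var: np.ndarray         # per-cell variance at the top concentration
    n_window: float             # samples per analysis window

    def activation_threshold(self, floor_pA: float, z: float = 6.0) -> float:
        """Smallest credible response: an absolute floor, or ``z`` standard
        errors of the windowed mean given the cells' zero-sweep noise."""
        noise_se = float(np.sqrt(np.nanmean(self.noise_var) / max(self.n_window, 1.0)))
        return max(floor_pA, z * noise_se)


def _collect_corners(ss: pd.DataFrame, config: StudyConfig, voltage: float) -> dict:
    """Group the steady-state table into per-corner response matrices.

    A cell's *primary* ligand is the one it was ladder-perfused with (most
    distinct concentrations); any other sweep on that cell is its
    saturating reference sweep.
    """
    sv = ss[(ss["voltage_mV"] == voltage) & (ss["concentration_uM"] > 0)]
    corners: dict = {}
    for (construct,), cgrp in sv.groupby(["construct"], sort=True):
        for rep, rgrp in cgrp.groupby("replicate", sort=True):
            counts = rgrp.groupby("ligand")["concentration_uM"].nunique()
            primary = counts.sort_values(ascending=False).index[0]
            lad = rgrp[rgrp["ligand"] == primary]
            per_conc = lad.groupby("concentration_uM")["I_mean_pA"].mean().sort_index()
            refrow = rgrp[
                (rgrp["ligand"] == config.reference_ligand)
                & (rgrp["concentration_uM"] == config.reference_concentration_uM)
            ]
            if primary == config.reference_ligand:
                ref_resp = (
                    per_conc.get(config.reference_concentration_uM, np.nan)
                )
            else:
                ref_resp = refrow["I_mean_pA"].mean() if len(refrow) else np.nan
            zero = ss[
                (ss["construct"] == construct)
                & (ss["voltage_mV"] == voltage)
                & (ss["replicate"] == rep)
                & (ss["concentration_uM"] == 0.0)
            ]
            nv = float(zero["I_var_pA2"].mean()) if len(zero) else 0.0
            key = (construct, primary)
            entry = corners.setdefault(
                key,
                {"cells": [], "concs": per_conc.index.to_numpy(), "rows": [],
                 "ref": [], "nv": [], "topvar": [],
                 "nw": float(lad["n_window_samples"].mean())},
            )
            if not np.array_equal(entry["concs"], per_conc.index.to_numpy()):
                raise InputError(
                    f"cells of corner {key} were perfused with different ladders"
                )
            top = lad[lad["concentration_uM"] == entry["concs"].max()]
            entry["cells"].append(rep)
            entry["rows"].append(per_conc.to_numpy())
            entry["ref"].append(float(ref_resp))
            entry["nv"].append(nv)
            entry["topvar"].append(float(top["I_var_pA2"].mean()))
    out = {}
    for (construct, ligand), e in corners.items():
        order = np.argsort(e["cells"])
        out[(construct, ligand)] = _CornerData(
            construct=construct,
            ligand=ligand,
            voltage_mV=voltage,
            cells=[e["cells"][i] for i in order],
            concs=e["concs"],
            R=np.array(e["rows"])[order],
            ref_resp=np.array(e["ref"])[order],
            noise_var=np.array(e["nv"])[order],
            top_var=np.array(e["topvar"])[order],
            n_window=e["nw"],
        )
    return out


def _per_conc_curve(cd: _CornerData, values: np.ndarray, idx: np.ndarray) -> DoseResponseCurve:
    sub = values[idx]
    n = sub.shape[0]
    means = sub.mean(axis=0)
    sems = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(means)
    return DoseResponseCurve(
        construct=cd.construct,
        ligand=cd.ligand,
        voltage_mV=cd.voltage_mV,
        concentrations=cd.concs,
        responses=means,
        sems=sems,
        n_replicates=np.full(means.size, n),
        replicate_responses=sub,
    )


@dataclass
class _CornerEstimate:
    fit: Optional[HillFit]
    fit_units: str
    po_max: Optional[float]
    sem_po_max: Optional[float]
    po_max_source: str
    params: Optional[GatingParams]
    status: str
    n_cells: int


def _estimate_voltage(
    corners: dict,
    config: StudyConfig,
    voltage: float,
    cell_idx: Optional[dict] = None,
    log: Optional[list] = None,
    ec50_starts: Optional[dict] = None,
) -> dict:
    """Estimate gating parameters for every corner at one voltage.

    ``cell_idx`` optionally maps corner keys to index arrays into the
    corner's cell list (used by the replicate bootstrap).
    """
    log = log if log is not None else []
    results: dict = {}
    constructs = sorted({k[0] for k in corners})
    for construct in constructs:
        ref_key = (construct, config.reference_ligand)
        anchor = anchor_sem = None
        f_ref = None
        ref_fit = None
        # --- reference-ligand corner: raw fit + Po_max anchor -------------
        if ref_key in corners:
            cd = corners[ref_key]
            idx = np.asarray(
                cell_idx.get(ref_key, np.arange(len(cd.cells)))
                if cell_idx else np.arange(len(cd.cells))
            )
            raw = _per_conc_curve(cd, cd.R, idx)
            if float(np.max(raw.responses)) < cd.activation_threshold(config.activation_floor_pA):
                results[ref_key] = _CornerEstimate(
                    None, "pA", None, None, "none", None, "no_activation", len(idx)
                )
                log.append(f"{ref_key} at {voltage:+g} mV: no activation")
            else:
                try:
                    ref_fit = fit_hill(
                        raw, fix_h=config.fix_h,
                        ec50_starts=(ec50_starts or {}).get(ref_key),
                    )
                except FitError as exc:
                    results[ref_key] = _CornerEstimate(
                        None, "pA", None, None, "none", None, f"fit_failed: {exc}", len(idx)
                    )
                    log.append(f"{ref_key} at {voltage:+g} mV: fit failed ({exc})")
                if ref_fit is not None:
                    c_top = float(cd.concs.max())
                    f_ref = c_top / (c_top + ref_fit.ec50)
                    if construct == config.wildtype:
                        anchor, anchor_sem = config.po_max_ref, config.sem_po_max_ref
                        source = "reference_constant"
                    else:
                        anchor, anchor_sem, source = _noise_anchor(
                            cd, idx, config, f_ref, log
                        )
                    if anchor is None:
                        results[ref_key] = _CornerEstimate(
                            ref_fit, "pA", None, None, source, None,
                            "po_max_unavailable", len(idx),
                        )
                    else:
                        try:
                            params = gating_from_fit(
                                ref_fit, anchor,
                                construct=construct, ligand=config.reference_ligand,
                                voltage_mV=voltage, sem_po_max=anchor_sem,
                            )
                            results[ref_key] = _CornerEstimate(
                                ref_fit, "pA", anchor, anchor_sem, source,
                                params, "ok", len(idx),
                            )
                            log.append(
                                f"{ref_key} at {voltage:+g} mV: Po_max {anchor:.4g} "
                                f"({source}), EC50 {ref_fit.ec50:.4g} uM"
                            )
                        except DomainError as exc:
                            results[ref_key] = _CornerEstimate(
                                ref_fit, "pA", anchor, anchor_sem, source,
                                None, f"invalid_po_max: {exc}", len(idx),
                            )
                            log.append(f"{ref_key}: invalid Po_max ({exc})")
        # --- alternative-ligand corners: normalized fits ------------------
        for key in sorted(k for k in corners if k[0] == construct and k[1] != config.reference_ligand):
            cd = corners[key]
            idx = np.asarray(
                cell_idx.get(key, np.arange(len(cd.cells)))
                if cell_idx else np.arange(len(cd.cells))
            )
            raw = _per_conc_curve(cd, cd.R, idx)
            if float(np.max(raw.responses)) < cd.activation_threshold(config.activation_floor_pA):
                results[key] = _CornerEstimate(
                    None, "ref_fraction", None, None, "none", None, "no_activation", len(idx)
                )
                log.append(f"{key} at {voltage:+g} mV: no activation")
                continue
            if anchor is None or f_ref is None:
                results[key] = _CornerEstimate(
                    None, "ref_fraction", None, None, "none", None,
                    "no_reference_anchor", len(idx),
                )
                log.append(f"{key}: reference corner unavailable, Po_max chain broken")
                continue
            if np.any(~np.isfinite(cd.ref_resp[idx])) or np.any(cd.ref_resp[idx] <= 0):
                results[key] = _CornerEstimate(
                    None, "ref_fraction", None, None, "none", None,
                    "missing_reference_sweep", len(idx),
                )
                log.append(f"{key}: cells lack a saturating reference sweep")
                continue
            norm = cd.R / cd.ref_resp[:, None]
            curve = _per_conc_curve(cd, norm, idx)
            try:
                fit = fit_hill(
                    curve, fix_h=config.fix_h, ec50_starts=(ec50_starts or {}).get(key)
                )
            except FitError as exc:
                results[key] = _CornerEstimate(
                    None, "ref_fraction", None, None, "none", None,
                    f"fit_failed: {exc}", len(idx),
                )
                log.append(f"{key} at {voltage:+g} mV: fit failed ({exc})")
                continue
            po_max = fit.imax * anchor * f_ref
            rel = np.hypot(
                fit.sem_imax / fit.imax if fit.imax > 0 else 0.0,
                (anchor_sem or 0.0) / anchor,
            )
            sem_po = po_max * rel
            try:
                params = gating_from_fit(
                    fit, po_max, construct=construct, ligand=key[1],
                    voltage_mV=voltage, sem_po_max=sem_po,
                )
                results[key] = _CornerEstimate(
                    fit, "ref_fraction", po_max, sem_po, "reference_normalization",
                    params, "ok", len(idx),
                )
                log.append(
                    f"{key} at {voltage:+g} mV: Po_max {po_max:.4g} "
                    f"(reference_normalization), EC50 {fit.ec50:.4g} uM"
                )
            except DomainError as exc:
                results[key] = _CornerEstimate(
                    fit, "ref_fraction", po_max, sem_po, "reference_normalization",
                    None, f"invalid_po_max: {exc}", len(idx),
                )
                log.append(f"{key}: invalid Po_max ({exc})")
    return results


def _noise_anchor(cd: _CornerData, idx, config: StudyConfig, f_ref: float, log: list):
    """Po_max anchor from stationary noise analysis at the top concentration."""
    i_single = config.i_single_for(cd.construct, cd.voltage_mV)
    if i_single is None:
        log.append(
            f"({cd.construct}, {cd.ligand}): no i_single configured for "
            f"{cd.voltage_mV:+g} mV; noise anchor unavailable"
        )
        return None, None, "noise_analysis"
    top_col = int(np.argmax(cd.concs))
    po_cells = []
    for j in np.asarray(idx):
        nv = cd.noise_var[j] if config.noise_floor == "zero_sweep" else 0.0
        try:
            n_hat = channel_count(cd.R[j, top_col], cd.top_var[j], i_single, noise_var=nv)
            po_cells.append(open_probability_from_noise(cd.R[j, top_col], i_single, n_hat))
        except (EstimationError, DomainError) as exc:
            log.append(f"({cd.construct}, {cd.ligand}) cell {cd.cells[j]}: noise analysis failed ({exc})")
    if not po_cells:
        return None, None, "noise_analysis"
    po_cells = np.asarray(po_cells)
    po_top = float(po_cells.mean())
    sem_top = float(po_cells.std(ddof=1) / np.sqrt(po_cells.size)) if po_cells.size > 1 else 0.0
    anchor = po_top / f_ref  # correct for incomplete saturation at the top concentration
    if not (0.0 < anchor < 1.0):
        log.append(
            f"({cd.construct}, {cd.ligand}): noise-analysis Po_max {anchor:.4g} outside (0, 1)"
        )
        return None, None, "noise_analysis"
    return anchor, sem_top / f_ref, "noise_analysis"


# ---------------------------------------------------------------------------
# public pipeline surface


@dataclass
class PipelineResult:
    steady_state: pd.DataFrame
    fits: pd.DataFrame
    gating: pd.DataFrame
    cycles: pd.DataFrame
    log: list
    config: StudyConfig
    gating_params: list

    def n_incomplete(self) -> int:
        if self.cycles.empty:
            return 0
        return int((self.cycles["status"] != "complete").sum())

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# gatecycle {__version__}\n# config_sha256={self.config.sha256()}\n"
        for name, df in [
            ("steady_state.csv", self.steady_state),
            ("fits.csv", self.fits),
            ("gating.csv", self.gating),
            ("cycles.csv", self.cycles),
        ]:
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        with open(out / "run_log.txt", "w") as fh:
            fh.write(header)
            fh.write("\n".join(self.log) + "\n")
        self.config.to_yaml(out / "config_used.yaml")
        return out


def analyze_study(study: Study, config: StudyConfig) -> PipelineResult:
    """Run the full analysis on an in-memory study."""
    ss = steady_state_table(study.traces, window_ms=config.window_ms)
    return analyze_steady_state(ss, config)


def analyze_steady_state(ss: pd.DataFrame, config: StudyConfig) -> PipelineResult:
    """Run the fit/decomposition/cycle stages on a steady-state table."""
    log: list = [f"gatecycle {__version__}", f"config sha256 {config.sha256()}"]
    voltages = (
        sorted(v for v in ss["voltage_mV"].unique())
        if config.voltages is None
        else [float(v) for v in config.voltages]
    )
    fit_rows = []
    all_params: list[GatingParams] = []
    cycles: list[MutantCycleResult] = []
    for voltage in voltages:
        corners = _collect_corners(ss, config, voltage)
        if not corners:
            log.append(f"no ladder data at {voltage:+g} mV")
            continue
        estimates = _estimate_voltage(corners, config, voltage, log=log)
        for key in sorted(estimates):
            est = estimates[key]
            fit = est.fit
            fit_rows.append(
                {
                    "construct": key[0],
                    "ligand": key[1],
                    "voltage_mV": voltage,
                    "n_cells": est.n_cells,
                    "Imax": None if fit is None else fit.imax,
                    "sem_Imax": None if fit is None else fit.sem_imax,
                    "Imax_units": est.fit_units,
                    "EC50_uM": None if fit is None else fit.ec50,
                    "sem_EC50_uM": None if fit is None else fit.sem_ec50,
                    "hill_h": None if fit is None else fit.hill_h,
                    "fixed_h": None if fit is None else fit.fixed_h,
                    "rss": None if fit is None else fit.rss,
                    "extrapolated": None if fit is None else fit.extrapolated,
                    "Po_max": est.po_max,
                    "sem_Po_max": est.sem_po_max,
                    "Po_max_source": est.po_max_source,
                    "status": est.status,
                }
            )
            if est.params is not None:
                all_params.append(est.params)
        constructs = sorted({k[0] for k in corners})
        ligands = sorted({k[1] for k in corners})
        mutants = [c for c in constructs if c != config.wildtype]
        alts = [l for l in ligands if l != config.reference_ligand]
        for mutant in mutants:
            for alt in alts:
                wanted = [
                    (config.wildtype, config.reference_ligand),
                    (mutant, config.reference_ligand),
                    (config.wildtype, alt),
                    (mutant, alt),
                ]
                params = [
                    estimates[k].params if k in estimates else None for k in wanted
                ]
                cyc = build_cycle(
                    params,
                    wildtype=config.wildtype,
                    mutant=mutant,
                    ligand_ref=config.reference_ligand,
                    ligand_alt=alt,
                    threshold=config.threshold_kT,
                )
                if not cyc.complete:
                    # attach the voltage even when no corner carried one
                    cyc.voltage_mV = voltage
                cycles.append(cyc)
                log.append(
                    f"cycle {mutant} x {alt} at {voltage:+g} mV: "
                    + (
                        f"coupling {cyc.coupling_energy_kT:.4g} kT "
                        f"({'interacting' if cyc.interacting else 'not interacting'})"
                        if cyc.complete
                        else cyc.status
                    )
                )
    return PipelineResult(
        steady_state=ss,
        fits=pd.DataFrame(fit_rows),
        gating=gating_table(all_params),
        cycles=cycle_report_table(cycles) if cycles else pd.DataFrame(),
        log=log,
        config=config,
        gating_params=all_params,
    )


def run_pipeline(config: StudyConfig, study: Optional[Study] = None) -> PipelineResult:
    """Analyze a study from disk (``config.input_dir``) or from memory.

    Writes report tables and the run log to ``config.out_dir`` when set.
    Incomplete cycles are reported in the tables, never raised.
    """
    if study is None:
        if config.input_dir is None:
            raise InputError("run_pipeline needs either an in-memory study or config.input_dir")
        study = read_study(config.input_dir)
    result = analyze_study(study, config)
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result


def bootstrap_coupling_sem(
    study: Study,
    config: StudyConfig,
    mutant: str,
    ligand_alt: str,
    voltage: float,
    n_boot: int = 400,
    seed: int = 0,
) -> float:
    """Replicate-bootstrap s.e.m. of one cycle's coupling energy.

    Cells are resampled with replacement independently per corner; each
    draw re-runs the Po_max chain and the Hill fits (warm-started at the
    full-sample EC50s) and recomputes LnOmega.  Returns the standard
    deviation of |LnOmega| across draws.
    """
    ss = steady_state_table(study.traces, window_ms=config.window_ms)
    corners = _collect_corners(ss, config, voltage)
    wanted = [
        (config.wildtype, config.reference_ligand),
        (mutant, config.reference_ligand),
        (config.wildtype, ligand_alt),
        (mutant, ligand_alt),
    ]
    base = _estimate_voltage(corners, config, voltage)
    starts = {
        k: [base[k].fit.ec50] for k in wanted if k in base and base[k].fit is not None
    }
    rng = np.random.default_rng(child_seed(seed, "bootstrap", mutant, ligand_alt, voltage))
    draws = []
    for _ in range(n_boot):
        idx = {
            k: rng.integers(0, len(corners[k].cells), size=len(corners[k].cells))
            for k in wanted
            if k in corners
        }
        est = _estimate_voltage(corners, config, voltage, cell_idx=idx, ec50_starts=starts)
        params = [est[k].params if k in est else None for k in wanted]
        if any(p is None for p in params):
            continue
        cyc = build_cycle(
            params,
            wildtype=config.wildtype,
            mutant=mutant,
            ligand_ref=config.reference_ligand,
            ligand_alt=ligand_alt,
            threshold=config.threshold_kT,
        )
        draws.append(cyc.coupling_energy_kT)
    if len(draws) < 2:
        raise EstimationError("bootstrap produced fewer than 2 complete cycles")
    return float(np.std(draws, ddof=1))
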