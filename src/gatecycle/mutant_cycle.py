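"""Thermodynamic mutant-cycle analysis of ligand-binding constants.

A mutant cycle compares how a point mutation shifts the dissociation
constant of two chemically related ligands.  With the four corners

    Kd_1  wild type + reference ligand      Kd_3  wild type + alternative
    Kd_2  mutant    + reference ligand      Kd_4  mutant    + alternative

the non-additivity of the perturbations is

    LnOmega = ln( Kd_1 * Kd_4 / (Kd_2 * Kd_3) )

and the coupling energy is kT * LnOmega; on the kT scale the reported
number is the magnitude |LnOmega|.  LnOmega = 0 means the mutation shifts
both ligands identically (no interaction between the mutated residue and
the chemical group that distinguishes the ligands); a coupling energy
larger than 1.5 kT (strict inequality) is classified as an interaction.

Uncertainty is propagated from the corner s.e.m.s by the delta method on
log-Kds: sem(LnOmega) = sqrt( sum_k (sem_k / Kd_k)^2 ).  A replicate
bootstrap alternative lives in :mod:`gatecycle.pipeline`.

A cycle with a corner whose ligand cannot activate the channel has no Kd
there; the result is reported with status ``incomplete`` and is never
classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .gating import GatingParams

__all__ = [
    "MutantCycleResult",
    "ln_omega",
    "coupling_energy",
    "classify",
    "build_cycle",
    "cycle_report_table",
]

DEFAULT_THRESHOLD_KT = 1.5

#: kT -> kcal/mol at 298 K, offered for reports only; core results stay in kT.
KT_TO_KCAL_PER_MOL = 0.593

CORNER_NAMES = ("WT+ref", "Mut+ref", "WT+alt", "Mut+alt")


class IncompleteCycleError(InputError):
    """A corner Kd is missing or invalid; carries which corner failed."""

    def __init__(self, corner: str, reason: str):
        super().__init__(f"incomplete cycle at corner {corner}: {reason}")
        self.corner = corner
        self.reason = reason


def ln_omega(kd_1: float, kd_2: float, kd_3: float, kd_4: float) -> float:
    """``ln(Kd_1 Kd_4 / (Kd_2 Kd_3))`` — invariant to common Kd rescaling."""
    kds = (kd_1, kd_2, kd_3, kd_4)
    for name, kd in zip(CORNER_NAMES, kds):
        if kd is None or not np.isfinite(kd) or kd <= 0:
            raise IncompleteCycleError(name, f"Kd = {kd!r} is not a positive finite value")
    return math.log(kd_1) + math.log(kd_4) - math.log(kd_2) - math.log(kd_3)


def coupling_energy(
    ln_om: float, rel_sems: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
) -> tuple[float, float]:
    """Coupling energy ``|LnOmega|`` in kT with its delta-method s.e.m.

    ``rel_sems`` are the four relative corner errors ``sem_k / Kd_k``; the
    propagated s.e.m. is their quadrature sum (errors on a log scale are
    relative errors).
    """
    if len(rel_sems) != 4:
        raise InputError(f"need 4 relative s.e.m. values, got {len(rel_sems)}")
    for r in rel_sems:
        if r < 0 or not np.isfinite(r):
            raise DomainError(f"relative s.e.m. must be finite and >= 0, got {r!r}")
    sem = float(np.sqrt(np.sum(np.square(rel_sems))))
    return abs(float(ln_om)), sem


def classify(coupling_energy_kT: float, threshold: float = DEFAULT_THRESHOLD_KT) -> bool:
    """True iff the coupling energy strictly exceeds the threshold (default 1.5 kT)."""
    if coupling_energy_kT < 0 or not np.isfinite(coupling_energy_kT):
        raise DomainError(f"coupling energy must be finite and >= 0, got {coupling_energy_kT!r}")
    return coupling_energy_kT > threshold


@dataclass
class MutantCycleResult:
    """Four-corner cycle result: corners, LnOmega, energy, classification."""

    voltage_mV: float
    wildtype: str
    mutant: str
    ligand_ref: str
    ligand_alt: str
    kd: dict            # corner name -> Kd (µM) or None
    sem_kd: dict        # corner name -> s.e.m. or None
    ln_omega: Optional[float]
    coupling_energy_kT: Optional[float]
    sem_kT: Optional[float]
    interacting: Optional[bool]
    status: str         # "complete" | "incomplete(<reason>)"

    @property
    def complete(self) -> bool:
        return self.status == "complete"

    def to_row(self) -> dict:
        row = {
            "voltage_mV": self.voltage_mV,
            "wildtype": self.wildtype,
            "mutant": self.mutant,
            "ligand_ref": self.ligand_ref,
            "ligand_alt": self.ligand_alt,
        }
        for name in CORNER_NAMES:
            key = name.replace("+", "_")
            row[f"Kd_{key}_uM"] = self.kd.get(name)
            row[f"sem_Kd_{key}_uM"] = self.sem_kd.get(name)
        row["ln_omega"] = self.ln_omega
        row["coupling_energy_kT"] = self.coupling_energy_kT
        row["sem_kT"] = self.sem_kT
        row["coupling_energy_kcal_mol"] = (
            None if self.coupling_energy_kT is None
            else self.coupling_energy_kT * KT_TO_KCAL_PER_MOL
        )
        row["interacting"] = self.interacting
        row["status"] = self.status
        return row


def build_cycle(
    params: Iterable[Optional[GatingParams]],
    wildtype: str,
    mutant: str,
    ligand_ref: str,
    ligand_alt: str,
    threshold: float = DEFAULT_THRESHOLD_KT,
) -> MutantCycleResult:
    """Assemble a mutant-cycle result from per-corner gating parameters.

    ``params`` may omit corners (e.g. a ligand that fails to activate a
    mutant yields no fit); the result is then reported as incomplete with
    the missing corner named, and no classification is made.  Supplying
    mismatched voltages or a duplicated corner is an input error.
    """
    corner_map = {
        (wildtype, ligand_ref): "WT+ref",
        (mutant, ligand_ref): "Mut+ref",
        (wildtype, ligand_alt): "WT+alt",
        (mutant, ligand_alt): "Mut+alt",
    }
    kd = {name: None for name in CORNER_NAMES}
    sem = {name: None for name in CORNER_NAMES}
    voltages = set()
    for p in params:
        if p is None:
            continue
        key = (p.construct, p.ligand)
        if key not in corner_map:
            raise InputError(f"gating parameters for {key} do not fit the 2x2 design")
        name = corner_map[key]
        if kd[name] is not None:
            raise InputError(f"duplicated corner {name}")
        kd[name] = p.kd
        sem[name] = p.sem_kd
        voltages.add(p.voltage_mV)
    if len(voltages) > 1:
        raise InputError(f"corners mix voltages: {sorted(voltages)}")
    voltage = voltages.pop() if voltages else float("nan")

    missing = [name for name in CORNER_NAMES if kd[name] is None]
    if missing:
        reason = "no activation: " + ", ".join(missing)
        return MutantCycleResult(
            voltage_mV=voltage,
            wildtype=wildtype,
            mutant=mutant,
            ligand_ref=ligand_ref,
            ligand_alt=ligand_alt,
            kd=kd,
            sem_kd=sem,
            ln_omega=None,
            coupling_energy_kT=None,
            sem_kT=None,
            interacting=None,
            status=f"incomplete({reason})",
        )

    ln_om = ln_omega(kd["WT+ref"], kd["Mut+ref"], kd["WT+alt"], kd["Mut+alt"])
    rel = [(sem[name] or 0.0) / kd[name] for name in CORNER_NAMES]
    energy, sem_kt = coupling_energy(ln_om, rel)
    return MutantCycleResult(
        voltage_mV=voltage,
        wildtype=wildtype,
        mutant=mutant,
        ligand_ref=ligand_ref,
        ligand_alt=ligand_alt,
        kd=kd,
        sem_kd=sem,
        ln_omega=ln_om,
        coupling_energy_kT=energy,
        sem_kT=sem_kt,
        interacting=classify(energy, threshold),
        status="complete",
    )


def cycle_report_table(results: Iterable[MutantCycleResult]) -> pd.DataFrame:
    """One row per mutant x ligand-pair x voltage."""
    return pd.DataFrame([r.to_row() for r in results])
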