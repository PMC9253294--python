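"""Two-state ligand-gating model and its exact algebra.

The channel is assumed to equilibrate rapidly among three states: the
unliganded closed state C0, the ligand-bound closed state C1 and the open
state O.  Binding of a single ligand molecule is governed by the
dissociation constant ``Kd`` (µM) and the final closed-to-open transition by
the dimensionless equilibrium constant ``L``, giving relative occupancies

    C0 : C1 : O  =  1 : c/Kd : (c/Kd) L

at free ligand concentration ``c``.  The open probability is therefore

    Po(c) = L c / (Kd + c (1 + L)),

a rectangular hyperbola with ``Po(0) = 0`` and saturating value
``Po_max = L / (1 + L)``.  Two identities follow and are used throughout the
pipeline to decompose an apparent affinity into binding and gating terms:

    EC50   = Kd / (1 + L)          (half-maximal concentration)
    L      = Po_max / (1 - Po_max)

Equivalently, the model curve is exactly a Hill function with coefficient 1,
``I(c) = Imax c / (c + EC50)`` — which is why a fixed-slope Hill fit of a
concentration-response curve yields the EC50 that this module converts into
``Kd`` once ``Po_max`` (hence ``L``) is known.

Units are fixed package-wide: µM for concentrations and ``Kd``, pA for
currents, mV for voltages, kT for energies.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

__all__ = [
    "GatingParams",
    "open_probability",
    "pomax_from_l",
    "l_from_pomax",
    "ec50_from_kd",
    "kd_from_ec50",
    "model_response_curve",
    "write_gating_table",
    "read_gating_table",
]

#: Relative tolerance for the internal-consistency checks of GatingParams.
CONSISTENCY_RTOL = 1e-9

GATING_TABLE_COLUMNS = [
    "construct",
    "ligand",
    "voltage_mV",
    "Kd_uM",
    "sem_Kd_uM",
    "L",
    "sem_L",
    "Po_max",
    "EC50_uM",
    "sem_EC50_uM",
]


def _require_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
        raise DomainError(f"{name} must be finite and > 0, got {value!r}")


def open_probability(concentration, kd: float, L: float):
    """Open probability of the two-state scheme at ligand concentration c.

    Parameters
    ----------
    concentration : float or array-like
        Free ligand concentration in µM, >= 0.
    kd : float
        Dissociation constant of the binding step, µM, > 0.
    L : float
        Equilibrium constant of the ligand-bound closed-to-open step, > 0.

    Returns
    -------
    float or ndarray
        ``Po(c) = L c / (Kd + c (1 + L))``; strictly increasing in ``c``,
        zero at ``c = 0``, saturating at ``L / (1 + L)``.
    """
    _require_positive("Kd", kd)
    _require_positive("L", L)
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0.0) or not np.all(np.isfinite(c)):
        raise DomainError(f"concentration must be finite and >= 0, got {concentration!r}")
    po = L * c / (kd + c * (1.0 + L))
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(po)
    return po


def pomax_from_l(L: float) -> float:
    """Maximal open probability ``Po_max = L / (1 + L)``."""
    _require_positive("L", L)
    return L / (1.0 + L)


def l_from_pomax(po_max: float) -> float:
    """Gating equilibrium constant from the maximal open probability.

    ``L = Po_max / (1 - Po_max)`` — the exact inverse of
    :func:`pomax_from_l`.

    Raises
    ------
    DomainError
        If ``po_max`` is outside the open interval (0, 1).  ``po_max == 1``
        signals a saturated normalization (infinite L) and is reported as an
        error rather than silently clipped.
    """
    po_max = float(po_max)
    if not np.isfinite(po_max) or po_max <= 0.0 or po_max >= 1.0:
        raise DomainError(
            f"Po_max must lie strictly inside (0, 1); got {po_max!r}"
            + (" (saturated normalization implies a non-finite L)" if po_max >= 1.0 else "")
        )
    return po_max / (1.0 - po_max)


def ec50_from_kd(kd: float, L: float) -> float:
    """Apparent half-maximal concentration ``EC50 = Kd / (1 + L)`` (µM)."""
    _require_positive("Kd", kd)
    _require_positive("L", L)
    return kd / (1.0 + L)


def kd_from_ec50(ec50: float, L: float) -> float:
    """Dissociation constant from the apparent affinity: ``Kd = EC50 (1 + L)``.

    Since ``L > 0`` the binding constant always satisfies ``Kd >= EC50``:
    gating makes the channel look higher-affinity than the binding step is.
    """
    _require_positive("EC50", ec50)
    _require_positive("L", L)
    return ec50 * (1.0 + L)


def model_response_curve(concentrations, kd: float, L: float, imax_unit: float):
    """Macroscopic current predicted by the gating model.

    ``I(c) = imax_unit * Po(c)`` where ``imax_unit`` is the current at
    ``Po = 1`` (i.e. ``i_single * N_channels``).  Algebraically identical to
    a Hill curve with coefficient 1, ``Imax = imax_unit * L/(1+L)`` and
    ``EC50 = Kd/(1+L)``.
    """
    _require_positive("imax_unit", abs(imax_unit))
    po = open_probability(np.asarray(concentrations, dtype=float), kd, L)
    return imax_unit * po


@dataclass
class GatingParams:
    """Binding/gating decomposition for one (construct, ligand, voltage).

    ``kd`` (µM), ``L`` (dimensionless), ``po_max`` and ``ec50`` (µM) are
    linked by the model identities and checked for mutual consistency to
    ``1e-9`` relative tolerance on construction.  Standard errors are on the
    same scales and optional.
    """

    construct: str
    ligand: str
    voltage_mV: float
    kd: float
    L: float
    po_max: float
    ec50: float
    sem_kd: Optional[float] = None
    sem_L: Optional[float] = None
    sem_ec50: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("Kd", self.kd)
        _require_positive("L", self.L)
        _require_positive("EC50", self.ec50)
        if not (0.0 < self.po_max < 1.0):
            raise DomainError(f"Po_max must lie strictly inside (0, 1); got {self.po_max!r}")
        for name in ("sem_kd", "sem_L", "sem_ec50"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0.0):
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isclose(self.ec50, self.kd / (1.0 + self.L), rtol=CONSISTENCY_RTOL, atol=0.0):
            raise DomainError(
                f"inconsistent parameters: EC50 = {self.ec50} but Kd/(1+L) = "
                f"{self.kd / (1.0 + self.L)}"
            )
        if not np.isclose(self.po_max, self.L / (1.0 + self.L), rtol=CONSISTENCY_RTOL, atol=0.0):
            raise DomainError(
                f"inconsistent parameters: Po_max = {self.po_max} but L/(1+L) = "
                f"{self.L / (1.0 + self.L)}"
            )

    @classmethod
    def from_ec50_pomax(
        cls,
        construct: str,
        ligand: str,
        voltage_mV: float,
        ec50: float,
        po_max: float,
        sem_ec50: Optional[float] = None,
        sem_po_max: Optional[float] = None,
    ) -> "GatingParams":
        """Build a consistent parameter set from the two measured quantities.

        ``L`` and ``Kd`` follow from the identities; ``sem_kd`` and ``sem_L``
        are propagated by the delta method:

            L  = p/(1-p)        ->  dL/dp  = 1/(1-p)^2
            Kd = EC50/(1-p)     ->  dKd/dE = 1+L,   dKd/dp = EC50/(1-p)^2
        """
        L = l_from_pomax(po_max)
        kd = kd_from_ec50(ec50, L)
        sem_L = sem_kd = None
        if sem_po_max is not None or sem_ec50 is not None:
            sp = 0.0 if sem_po_max is None else float(sem_po_max)
            se = 0.0 if sem_ec50 is None else float(sem_ec50)
            one_minus = 1.0 - po_max
            sem_L = sp / one_minus**2
            sem_kd = float(np.hypot((1.0 + L) * se, ec50 / one_minus**2 * sp))
        return cls(
            construct=construct,
            ligand=ligand,
            voltage_mV=voltage_mV,
            kd=kd,
            L=L,
            po_max=po_max,
            ec50=ec50,
            sem_kd=sem_kd,
            sem_L=sem_L,
            sem_ec50=sem_ec50,
        )

    def to_row(self) -> dict:
        return {
            "construct": self.construct,
            "ligand": self.ligand,
            "voltage_mV": self.voltage_mV,
            "Kd_uM": self.kd,
            "sem_Kd_uM": self.sem_kd,
            "L": self.L,
            "sem_L": self.sem_L,
            "Po_max": self.po_max,
            "EC50_uM": self.ec50,
            "sem_EC50_uM": self.sem_ec50,
        }

    @classmethod
    def from_row(cls, row) -> "GatingParams":
        def _opt(key):
            v = row[key]
            return None if pd.isna(v) else float(v)

        return cls(
            construct=str(row["construct"]),
            ligand=str(row["ligand"]),
            voltage_mV=float(row["voltage_mV"]),
            kd=float(row["Kd_uM"]),
            L=float(row["L"]),
            po_max=float(row["Po_max"]),
            ec50=float(row["EC50_uM"]),
            sem_kd=_opt("sem_Kd_uM"),
            sem_L=_opt("sem_L"),
            sem_ec50=_opt("sem_EC50_uM"),
        )


def gating_table(params: Iterable[GatingParams]) -> pd.DataFrame:
    """Flat table with one row per construct x ligand x voltage."""
    rows = [p.to_row() for p in params]
    return pd.DataFrame(rows, columns=GATING_TABLE_COLUMNS)


def write_gating_table(params: Iterable[GatingParams], path) -> None:
    gating_table(params).to_csv(path, index=False)


def read_gating_table(path) -> list[GatingParams]:
    df = pd.read_csv(path, comment="#")
    missing = set(GATING_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"gating table {Path(path)} missing columns: {sorted(missing)}")
    return [GatingParams.from_row(row) for _, row in df.iterrows()]
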