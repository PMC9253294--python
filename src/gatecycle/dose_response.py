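"""Hill concentration-response fitting and conversion to gating parameters.

The fitted model is ``I(c) = Imax * c^h / (c^h + EC50^h)``.  By default the
Hill coefficient is pinned to ``h = 1``, because the two-state single-binding
gating scheme used downstream is exactly a Hill curve with unit slope; a
free-``h`` mode is available as a diagnostic.  Fits are deterministic: a
fixed multi-start grid (EC50 started at every observed concentration, Imax
at the maximal response), best residual sum of squares wins, ties broken
toward the smallest EC50.

The second half of the module converts a fit into gating parameters: the
maximal open probability comes either from reference normalization (the
test ligand's saturating current over the reference ligand's, scaled by the
reference Po_max) or from stationary noise analysis, and then

    L = Po_max / (1 - Po_max),     Kd = EC50 * (1 + L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, InputError
from .gating import GatingParams, kd_from_ec50, l_from_pomax

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "hill",
    "fit_hill",
    "pomax_by_reference",
    "gating_from_fit",
]


def hill(c, imax, ec50, h=1.0):
    """Hill curve ``Imax * c^h / (c^h + EC50^h)`` (vectorized in c)."""
    c = np.asarray(c, dtype=float)
    ch = np.power(c, h)
    return imax * ch / (ch + ec50**h)


@dataclass
class DoseResponseCurve:
    """Per-concentration mean responses for one (construct, ligand, voltage).

    Responses are current magnitudes (pA) or normalized response fractions;
    ``sems`` and ``n_replicates`` describe the per-concentration replicate
    scatter.  Zero-concentration rows belong to baseline handling, not here.
    """

    construct: str
    ligand: str
    voltage_mV: float
    concentrations: np.ndarray
    responses: np.ndarray
    sems: Optional[np.ndarray] = None
    n_replicates: Optional[np.ndarray] = None
    replicate_responses: Optional[np.ndarray] = None  # cells x concentrations

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.size != self.responses.size:
            raise InputError("concentrations and responses must have the same length")
        if np.any(self.concentrations <= 0):
            raise InputError("concentrations must all be > 0 (zero rows go to baseline handling)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise InputError("concentrations must be strictly ascending")
        if self.sems is not None:
            self.sems = np.asarray(self.sems, dtype=float)
        if self.n_replicates is not None:
            self.n_replicates = np.asarray(self.n_replicates, dtype=int)
            if np.any(self.n_replicates < 1):
                raise InputError("n_replicates must be >= 1 at every concentration")


@dataclass
class HillFit:
    """Result of a Hill fit, with curvature-based standard errors."""

    imax: float
    ec50: float
    hill_h: float
    fixed_h: bool
    sem_imax: float
    sem_ec50: float
    sem_h: float
    converged: bool
    rss: float
    extrapolated: bool = False


def _fit_once(x, y, p0, bounds, fix_h):
    if fix_h:
        f = lambda c, imax, ec50: hill(c, imax, ec50, 1.0)
    else:
        f = hill
    popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    resid = y - f(x, *popt)
    return popt, pcov, float(np.dot(resid, resid))


def fit_hill(
    curve: DoseResponseCurve,
    fix_h: bool = True,
    ec50_starts: Optional[Sequence[float]] = None,
) -> HillFit:
    """Deterministic multi-start least-squares Hill fit.

    Requires at least 3 distinct concentrations (4 when ``h`` is free).
    Degenerate data (all responses identical, or no positive response)
    raise :class:`FitError` rather than returning a spurious fit.
    ``ec50_starts`` overrides the default start grid (every observed
    concentration), e.g. for warm-started bootstrap refits.
    """
    x = curve.concentrations
    y = curve.responses
    min_pts = 3 if fix_h else 4
    if x.size < min_pts:
        raise FitError(
            f"need >= {min_pts} concentrations for a {'fixed' if fix_h else 'free'}-h fit, got {x.size}"
        )
    if np.ptp(y) == 0.0:
        raise FitError("degenerate data: all responses identical", {"responses": y.tolist()})
    if np.max(y) <= 0.0:
        raise FitError("degenerate data: no positive response", {"responses": y.tolist()})

    imax0 = float(np.max(y))
    results = []
    diagnostics = {"starts": [], "errors": []}
    for ec50_start in (x if ec50_starts is None else np.asarray(ec50_starts, dtype=float)):
        if fix_h:
            p0 = [imax0, float(ec50_start)]
            bounds = ([0.0, 0.0], [np.inf, np.inf])
        else:
            p0 = [imax0, float(ec50_start), 1.0]
            bounds = ([0.0, 0.0, 0.1], [np.inf, np.inf, 10.0])
        try:
            popt, pcov, rss = _fit_once(x, y, p0, bounds, fix_h)
        except (RuntimeError, ValueError) as exc:
            diagnostics["errors"].append(f"start ec50={ec50_start}: {exc}")
            continue
        diagnostics["starts"].append({"ec50_start": float(ec50_start), "rss": rss})
        results.append((rss, popt, pcov))
    if not results:
        raise FitError("Hill fit failed to converge from every start", diagnostics)

    # best RSS wins; exact ties resolved toward the smallest EC50
    rss, popt, pcov = min(results, key=lambda r: (r[0], r[1][1]))
    sems = np.sqrt(np.abs(np.diag(pcov)))
    imax, ec50 = float(popt[0]), float(popt[1])
    h = 1.0 if fix_h else float(popt[2])
    if imax <= 0 or ec50 <= 0:
        raise FitError(f"fit collapsed to a boundary: Imax={imax}, EC50={ec50}", diagnostics)
    return HillFit(
        imax=imax,
        ec50=ec50,
        hill_h=h,
        fixed_h=fix_h,
        sem_imax=float(sems[0]),
        sem_ec50=float(sems[1]),
        sem_h=0.0 if fix_h else float(sems[2]),
        converged=True,
        rss=rss,
        extrapolated=not (x.min() / 10.0 <= ec50 <= x.max() * 10.0),
    )


def pomax_by_reference(imax_test: float, imax_ref: float, po_max_ref: float) -> float:
    """Maximal open probability by normalization to the reference ligand.

    ``Po_max = Po_max_ref * Imax_test / Imax_ref``.  A result at or above 1
    means the normalization is saturated (the test ligand apparently opens
    the channel more often than always) and raises rather than clips.
    """
    if imax_ref <= 0 or not np.isfinite(imax_ref):
        raise DomainError(f"Imax_ref must be finite and > 0, got {imax_ref!r}")
    if imax_test < 0 or not np.isfinite(imax_test):
        raise DomainError(f"Imax_test must be finite and >= 0, got {imax_test!r}")
    if not (0.0 < po_max_ref < 1.0):
        raise DomainError(f"Po_max_ref must lie in (0, 1), got {po_max_ref!r}")
    po = po_max_ref * imax_test / imax_ref
    if po >= 1.0:
        raise DomainError(
            f"saturated normalization: Po_max = {po:.6g} >= 1 "
            f"(Imax_test/Imax_ref = {imax_test / imax_ref:.6g}, Po_max_ref = {po_max_ref})"
        )
    if po <= 0.0:
        raise DomainError(f"normalization gave non-positive Po_max = {po!r}")
    return po


def gating_from_fit(
    fit: HillFit,
    po_max: float,
    construct: str = "",
    ligand: str = "",
    voltage_mV: float = 0.0,
    sem_po_max: Optional[float] = None,
) -> GatingParams:
    """Convert an EC50 fit plus a Po_max estimate into gating parameters.

    Standard errors on Kd and L are propagated from ``sem_EC50`` and
    ``sem_po_max`` by the delta method (see
    :meth:`gatecycle.gating.GatingParams.from_ec50_pomax`).
    """
    if not (0.0 < po_max < 1.0):
        raise DomainError(f"Po_max must lie in (0, 1), got {po_max!r}")
    return GatingParams.from_ec50_pomax(
        construct=construct,
        ligand=ligand,
        voltage_mV=voltage_mV,
        ec50=fit.ec50,
        po_max=po_max,
        sem_ec50=fit.sem_ec50,
        sem_po_max=sem_po_max,
    )
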