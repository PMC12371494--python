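"""Competition-binding analytics.

Single-dose triage (residual signal vs a DMSO control at 1 mM, 60 % cutoff),
four-parameter-logistic IC50 fitting, Cheng–Prusoff conversion of FP IC50
values to K_d, ligand efficiency, per-protein selectivity ratios and
screening summaries.  Censored affinities (e.g. "K_d > 400 μM") are
first-class values and propagate through ratios as bounds.

Conventions follow fragment-screening practice against non-enzymatic
readers: "IC50" denotes the compound concentration halving the assay signal
window, and K_d = IC50 / (1 + [L]/K_d^probe) with [L] the labelled-probe
concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProbeSpec",
    "Censored",
    "DoseResponseFit",
    "normalize_residual",
    "triage",
    "fit_dose_response",
    "cheng_prusoff",
    "ligand_efficiency",
    "selectivity",
    "screen_summary",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant, kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass(frozen=True)
class ProbeSpec:
    """Fluorescent-probe parameters for Cheng–Prusoff conversion.

    Defaults: 3 nM fluorescein-labelled m6A-DNA probe with K_d of 5 nM for
    DF2, 7 nM for DC2 and 5 nM for DC1.
    """

    probe_concentration: float = 3e-9                       # M
    probe_kd: Mapping[str, float] = field(
        default_factory=lambda: {"DF2": 5e-9, "DC2": 7e-9, "DC1": 5e-9}
    )

    def __post_init__(self) -> None:
        if self.probe_concentration <= 0:
            raise ValueError("probe_concentration must be positive")
        if any(v <= 0 for v in self.probe_kd.values()):
            raise ValueError("probe K_d values must be positive")

    def divisor(self, protein: str) -> float:
        """1 + [L]/K_d^probe for the given protein."""
        if protein not in self.probe_kd:
            raise KeyError(f"no probe K_d for protein {protein!r}")
        return 1.0 + self.probe_concentration / self.probe_kd[protein]


@dataclass(frozen=True)
class Censored:
    """A censored measurement, e.g. K_d > 400 μM (lower bound)."""

    value: float
    lower_bound: bool = True

    def __str__(self) -> str:
        return f"{'>' if self.lower_bound else '<'}{self.value:g}"


def normalize_residual(raw_signal, dmso_control_signal: float) -> float:
    """Percent residual signal vs the DMSO (vehicle) control.

    Technical replicates passed as a sequence are averaged before
    normalization.
    """
    if dmso_control_signal <= 0:
        raise ValueError("DMSO control signal must be positive")
    raw = float(np.mean(np.asarray(raw_signal, dtype=float)))
    return 100.0 * raw / dmso_control_signal


def triage(residuals: Mapping[str, float], cutoff: float = 60.0) -> list[str]:
    """Compounds advancing to dose–response: residual strictly below the
    cutoff (a compound at exactly 60 % does not advance)."""
    return [c for c, r in residuals.items() if r < cutoff]


@dataclass
class DoseResponseFit:
    """4PL fit result.  ``ok`` is False when the IC50 could not be
    determined (non-convergence, IC50 outside the tested range, or a
    signal window indistinguishable from flat); ``flags`` say why."""

    ic50: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    ic50_ci: tuple[float, float] | None      # ~95 % CI from the covariance
    ok: bool
    flags: list[str] = field(default_factory=list)

    @property
    def determined(self) -> bool:
        return self.ok


def _4pl_log(logc: np.ndarray, log_ic50: float, hill: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (logc - log_ic50)))


def fit_dose_response(
    panel: pd.DataFrame, fix_hill: float | None = None
) -> DoseResponseFit:
    """Least-squares four-parameter-logistic fit of a tidy dose–response
    panel (columns ``conc_M`` and ``signal``; replicates fitted jointly).

    The IC50 is parametrized on the log10 scale for stability; the Hill
    slope is free unless ``fix_hill`` is given.  Requires at least 4
    distinct concentrations.  Results with IC50 outside the tested
    concentration range, a flat signal, or a failed fit are returned
    flagged, never silently dropped.
    """
    c = panel["conc_M"].to_numpy(dtype=float)
    y = panel["signal"].to_numpy(dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("dose-response fitting requires >= 4 distinct concentrations")
    logc = np.log10(c)

    if y.max() == y.min():
        return DoseResponseFit(None, None, None, None, None, False, ["flat signal"])

    p0 = [float(np.median(logc)), 1.0, float(y.max()), float(y.min())]
    if fix_hill is not None:
        def model(lc, log_ic50, top, bottom):
            return _4pl_log(lc, log_ic50, fix_hill, top, bottom)
        p0 = [p0[0], p0[2], p0[3]]
    else:
        model = _4pl_log

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, logc, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return DoseResponseFit(None, None, None, None, None, False, ["fit did not converge"])

    if fix_hill is not None:
        log_ic50, top, bottom = popt
        hill = fix_hill
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    else:
        log_ic50, hill, top, bottom = popt
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf

    ic50 = 10.0 ** log_ic50
    ci = (10.0 ** (log_ic50 - 1.96 * se), 10.0 ** (log_ic50 + 1.96 * se))

    flags: list[str] = []
    if not np.isfinite(se):
        flags.append("ill-conditioned covariance")
    resid_sd = float(np.std(y - model(logc, *popt)))
    if top - bottom < 3.0 * resid_sd:
        flags.append("signal window indistinguishable from noise")
    if not c.min() <= ic50 <= c.max():
        flags.append("IC50 outside tested concentration range")
    ok = not flags
    return DoseResponseFit(
        ic50=ic50, hill=float(hill), top=float(top), bottom=float(bottom),
        ic50_ci=ci, ok=ok, flags=flags,
    )


def cheng_prusoff(ic50: float, probe: ProbeSpec, protein: str = "DF2") -> float:
    """K_d = IC50 / (1 + [L]/K_d^probe) for a competition assay with a
    labelled probe at concentration [L]."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    return ic50 / probe.divisor(protein)


def ligand_efficiency(
    ic50: float, hac: int, temperature: float = 300.0
) -> float:
    """LE = −RT ln(IC50) / HAC in kcal/(mol·heavy atom).

    IC50 in molar; R = 1.987e-3 kcal/(mol·K).  An IC50 ≥ 1 M yields LE ≤ 0,
    which is non-physical for this assay range and raises a warning.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hac < 1:
        raise ValueError("hac must be >= 1")
    le = -GAS_CONSTANT_KCAL * temperature * math.log(ic50) / hac
    if ic50 >= 1.0:
        warnings.warn(
            f"IC50 = {ic50:g} M gives LE = {le:.2f} <= 0 (non-physical for "
            "this assay range)",
            stacklevel=2,
        )
    return le


def selectivity(
    kds: Mapping[str, float | Censored], reference: str = "DF2"
) -> dict[str, float | Censored]:
    """Fold-selectivity vs the reference protein: ratio[p] = K_d[p] / K_d[ref].

    Ratios above 1 mean the compound prefers the reference.  A censored
    K_d (lower bound, e.g. ">400 μM") propagates to a censored ratio.
    """
    if reference not in kds:
        raise KeyError(f"reference protein {reference!r} missing from K_d map")
    ref = kds[reference]
    if isinstance(ref, Censored):
        raise ValueError("reference K_d must be an uncensored value")
    out: dict[str, float | Censored] = {}
    for p, kd in kds.items():
        if p == reference:
            continue
        if isinstance(kd, Censored):
            out[p] = Censored(kd.value / ref, lower_bound=kd.lower_bound)
        else:
            out[p] = kd / ref
    return out


def screen_summary(results: pd.DataFrame) -> dict:
    """Hit-rate report from a table with columns ``compound``, ``active``
    (bool: IC50 determined) and optionally ``campaign``.

    Hit rate is reported as percent rounded to the nearest integer; a
    per-campaign breakdown is included when campaigns are given.
    """
    n_tested = len(results)
    if n_tested == 0:
        raise ValueError("no compounds tested")
    n_active = int(results["active"].sum())
    rate = int(math.floor(100.0 * n_active / n_tested + 0.5))
    report = {
        "n_tested": n_tested,
        "n_active": n_active,
        "hit_rate_percent": rate,
    }
    if "campaign" in results.columns:
        per = {}
        for camp, grp in results.groupby("campaign"):
            na = int(grp["active"].sum())
            per[str(camp)] = {
                "n_tested": len(grp),
                "n_active": na,
                "hit_rate_percent": int(math.floor(100.0 * na / len(grp) + 0.5)),
            }
        report["per_campaign"] = per
    return report
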