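"""Non-compartmental analysis of concentration–time profiles.

Standard single-dose NCA: Cmax/Tmax from the observed maximum, AUC by the
linear trapezoid, terminal slope λz by log-linear regression over the best
(adjusted-R²) window of the last 3–6 post-Tmax points, AUC extrapolation to
infinity by C_last/λz, and apparent clearance CL/F = dose / AUC0–∞.

Units: time h, concentration ng/mL, dose mg, AUC ng·h/mL, clearance L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .pbpk_engine import ConcentrationProfile


class NCAError(ValueError):
    """Profile unsuitable for non-compartmental analysis."""


@dataclass(frozen=True)
class PKParameters:
    cmax_ng_ml: float
    tmax_h: float
    auc_last_ng_h_ml: float
    auc_inf_ng_h_ml: float
    lambda_z_per_h: float
    t_half_h: float
    cl_over_f_L_h: float
    extrapolated_fraction: float
    n_lambda_points: int
    subject_id: int = 0
    flagged: bool = False           # extrapolated fraction > 20%

    def to_dict(self) -> dict:
        return asdict(self)


def _best_terminal_fit(times: np.ndarray, conc: np.ndarray,
                       i_max: int) -> tuple[float, int]:
    """λz from the best adjusted-R² log-linear window (last 3–6 points)."""
    candidates = []
    n = len(times)
    for k in range(3, 7):
        start = n - k
        if start < i_max:            # window may begin at Tmax, not before
            continue
        t = times[start:]
        c = conc[start:]
        if np.any(c <= 0):
            continue
        logc = np.log(c)
        slope, intercept = np.polyfit(t, logc, 1)
        if slope >= 0:
            continue
        fitted = slope * t + intercept
        ss_res = float(np.sum((logc - fitted) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        candidates.append((adj_r2, -slope, k))
    if not candidates:
        raise NCAError("no valid terminal log-linear window")
    adj_r2, lam, k = max(candidates, key=lambda c: c[0])
    return lam, k


def compute_nca(profile: ConcentrationProfile,
                dose_mg: float | None = None) -> PKParameters:
    """Single-dose NCA for one profile.

    Requires at least 4 time points with at least 3 positive-concentration
    points after Tmax; raises :class:`NCAError` otherwise.
    """
    times = np.asarray(profile.times, dtype=float)
    conc = np.asarray(profile.concentrations, dtype=float)
    if dose_mg is None:
        dose_mg = profile.dose_mg
    if dose_mg <= 0:
        raise NCAError("dose must be positive")
    if len(times) < 4:
        raise NCAError("need at least 4 time points")
    if np.any(np.diff(times) <= 0):
        raise NCAError("times must be strictly ascending")

    i_max = int(np.argmax(conc))
    cmax = float(conc[i_max])
    tmax = float(times[i_max])
    if cmax <= 0:
        raise NCAError("all concentrations are zero")

    auc_last = float(np.trapezoid(conc, times))
    # drop any trailing non-positive (below-quantification) tail before the
    # terminal log-linear fit
    pos = np.nonzero(conc > 0)[0]
    last = int(pos[-1]) + 1
    lam, k = _best_terminal_fit(times[:last], conc[:last], i_max)
    c_last = float(conc[last - 1])
    if c_last <= 0:
        raise NCAError("non-positive terminal concentration")
    auc_inf = auc_last + c_last / lam
    extrap = (auc_inf - auc_last) / auc_inf
    # dose mg -> ng (1e6); AUC ng·h/mL -> CL mL/h -> L/h (1e-3)
    cl = dose_mg * 1e3 / auc_inf
    return PKParameters(
        cmax_ng_ml=cmax, tmax_h=tmax, auc_last_ng_h_ml=auc_last,
        auc_inf_ng_h_ml=auc_inf, lambda_z_per_h=lam,
        t_half_h=float(np.log(2.0) / lam), cl_over_f_L_h=cl,
        extrapolated_fraction=float(extrap), n_lambda_points=k,
        subject_id=profile.subject_id, flagged=extrap > 0.20)


def nca_table(profiles: list[ConcentrationProfile],
              dose_mg: float | None = None) -> pd.DataFrame:
    """Per-subject NCA results; failed subjects carry NaN and a flag."""
    rows = []
    for p in profiles:
        try:
            rows.append(compute_nca(p, dose_mg).to_dict())
        except NCAError as exc:
            rows.append({"subject_id": p.subject_id, "flagged": True,
                         "error": str(exc)})
    return pd.DataFrame(rows)


def summarize_population_pk(table: pd.DataFrame | list[PKParameters]
                            ) -> pd.DataFrame:
    """Arithmetic mean, SD, 5th/95th percentiles, min and max per parameter."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([p.to_dict() for p in table])
    if len(table) == 0:
        raise ValueError("empty PK parameter table")
    params = [c for c in table.columns
              if c not in ("subject_id", "flagged", "error", "n_lambda_points")]
    data = table[params].astype(float)
    return pd.DataFrame({
        "mean": data.mean(), "sd": data.std(ddof=1),
        "p5": data.quantile(0.05), "p95": data.quantile(0.95),
        "min": data.min(), "max": data.max(),
    })
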