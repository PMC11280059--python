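"""CKD dose adjustment: match CKD exposure to a healthy reference.

At therapeutic concentrations vildagliptin kinetics are linear (Cmax is two
orders of magnitude below Km), so exposure scales with dose and a bisection
on dose converges quickly; the closed-form one-step estimate
``dose × AUC_healthy / AUC_ckd`` serves as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExposureComparison:
    """Per-subject exposure distribution for one population/dose group."""

    label: str
    dose_mg: float
    auc_total: np.ndarray           # ng·h/mL per subject
    fu_effective: float

    def __post_init__(self) -> None:
        self.auc_total = np.asarray(self.auc_total, dtype=float)
        if self.auc_total.size == 0:
            raise ValueError(f"empty exposure group: {self.label}")

    @property
    def auc_unbound(self) -> np.ndarray:
        return self.auc_total * self.fu_effective

    def auc(self, metric: str) -> np.ndarray:
        if metric == "total":
            return self.auc_total
        if metric == "unbound":
            return self.auc_unbound
        raise ValueError(f"unknown metric: {metric!r}")


def unbound_auc(auc_total: float, fu_effective: float) -> float:
    """Unbound exposure = fu × total exposure."""
    if auc_total < 0 or not 0 < fu_effective <= 1:
        raise ValueError("auc_total must be >= 0 and fu in (0, 1]")
    return auc_total * fu_effective


@dataclass(frozen=True)
class DoseRecommendation:
    dose_mg: float
    percent_of_initial: float
    metric: str
    achieved_auc: float
    reference_auc: float
    converged: bool
    note: str = ""


def find_equivalent_dose(auc_at_dose, healthy_reference_auc: float,
                         initial_dose: float, metric: str = "total",
                         tolerance: float = 0.05,
                         max_iter: int = 40) -> DoseRecommendation:
    """Bisection on dose until the CKD mean AUC matches the healthy reference.

    ``auc_at_dose(dose_mg) -> mean AUC`` must evaluate the CKD population for
    the chosen metric. If the CKD exposure at the full dose does not exceed
    the reference (nothing to taper), the full dose is returned with a note.
    """
    if initial_dose <= 0:
        raise ValueError("initial_dose must be positive")
    if not 0 < tolerance <= 0.2:
        raise ValueError("tolerance must lie in (0, 0.2]")

    auc_full = auc_at_dose(initial_dose)
    if auc_full <= healthy_reference_auc:
        return DoseRecommendation(
            initial_dose, 100.0, metric, auc_full, healthy_reference_auc,
            converged=False,
            note="CKD exposure does not exceed the healthy reference at the "
                 "initial dose; no reduction required")

    lo, hi = 0.0, initial_dose
    dose, auc = hi, auc_full
    for _ in range(max_iter):
        dose = 0.5 * (lo + hi)
        auc = auc_at_dose(dose)
        if abs(auc - healthy_reference_auc) <= tolerance * healthy_reference_auc:
            return DoseRecommendation(dose, 100.0 * dose / initial_dose,
                                      metric, auc, healthy_reference_auc,
                                      converged=True)
        if auc > healthy_reference_auc:
            hi = dose
        else:
            lo = dose
    return DoseRecommendation(dose, 100.0 * dose / initial_dose, metric, auc,
                              healthy_reference_auc, converged=False,
                              note="bisection did not converge")


def exposure_boxplot_table(comparisons: list[ExposureComparison]
                           ) -> pd.DataFrame:
    """Median, quartiles and 5–95th whiskers per group and metric."""
    rows = []
    for comp in comparisons:
        for metric in ("total", "unbound"):
            a = comp.auc(metric)
            rows.append({
                "label": comp.label, "dose_mg": comp.dose_mg,
                "metric": metric, "n": a.size,
                "mean": a.mean(), "median": float(np.median(a)),
                "q1": float(np.percentile(a, 25)),
                "q3": float(np.percentile(a, 75)),
                "p5": float(np.percentile(a, 5)),
                "p95": float(np.percentile(a, 95)),
            })
    return pd.DataFrame(rows)
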