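"""Model-qualification statistics: R ratios, fold errors, AFE, VPC bands.

The predicted/observed ratio R and the fold error are the same quotient
(predicted ÷ observed); the average fold error is

    AFE = 10 ** (Σ log10 FE / N)            (signed convention)
    AFE = 10 ** |Σ log10 FE / N|            (magnitude convention, default)

The magnitude convention is the reporting default: a set of systematic
under-predictions then still yields an AFE ≥ 1 that reads as "x-fold average
deviation". Two-fold acceptance means 0.5 ≤ R ≤ 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TWO_FOLD = (0.5, 2.0)


def r_ratio(predicted: float, observed: float) -> float:
    """Predicted/observed ratio of a PK parameter (Eq. R)."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed


#: Fold error is defined with the identical quotient.
fold_error = r_ratio


def two_fold_pass(ratio: float) -> bool:
    return TWO_FOLD[0] <= ratio <= TWO_FOLD[1]


def afe(fold_errors, convention: str = "magnitude") -> float:
    """Average fold error over a set of predicted/observed ratios."""
    fe = np.asarray(list(fold_errors), dtype=float)
    if fe.size == 0:
        raise ValueError("fold error list is empty")
    if np.any(fe <= 0):
        raise ValueError("fold errors must be positive")
    mean_log = float(np.mean(np.log10(fe)))
    if convention == "signed":
        return 10.0 ** mean_log
    if convention == "magnitude":
        return 10.0 ** abs(mean_log)
    raise ValueError(f"unknown AFE convention: {convention!r}")


def mean_r_ratio(ratios, confidence: float = 0.95) -> dict:
    """Arithmetic mean of R ratios with a t-based confidence interval."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("ratio list is empty")
    mean = float(r.mean())
    if r.size == 1:
        return {"mean": mean, "ci_low": np.nan, "ci_high": np.nan,
                "n": 1, "ci_defined": False}
    sem = float(r.std(ddof=1) / np.sqrt(r.size))
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=r.size - 1)
    return {"mean": mean, "ci_low": mean - tcrit * sem,
            "ci_high": mean + tcrit * sem, "n": int(r.size),
            "ci_defined": True}


@dataclass
class EvaluationReport:
    """Per-profile ratios plus per-parameter summaries."""

    per_profile: pd.DataFrame       # parameter, observed, predicted, r_ratio,
                                    # fold_error, two_fold_pass
    per_parameter: pd.DataFrame     # afe (both conventions), mean R, CI

    def to_json_dict(self) -> dict:
        return {
            "per_profile": self.per_profile.to_dict(orient="records"),
            "per_parameter": self.per_parameter.reset_index()
                                 .to_dict(orient="records"),
        }


def evaluate_predictions(table: pd.DataFrame) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from observed/predicted pairs.

    ``table`` needs columns ``parameter``, ``observed``, ``predicted``;
    any other columns (labels, doses) pass through.
    """
    df = table.copy()
    bad = df["observed"] <= 0
    df["r_ratio"] = np.where(bad, np.nan, df["predicted"] / df["observed"])
    df["fold_error"] = df["r_ratio"]
    df["two_fold_pass"] = (df["r_ratio"] >= TWO_FOLD[0]) \
        & (df["r_ratio"] <= TWO_FOLD[1])
    df["flagged"] = bad

    rows = {}
    for param, grp in df[~bad].groupby("parameter"):
        ratios = grp["r_ratio"].to_numpy()
        m = mean_r_ratio(ratios) if len(ratios) else {"mean": np.nan,
                                                      "ci_low": np.nan,
                                                      "ci_high": np.nan}
        rows[param] = {
            "afe_magnitude": afe(ratios, "magnitude"),
            "afe_signed": afe(ratios, "signed"),
            "mean_r_ratio": m["mean"],
            "r_ratio_ci95_low": m["ci_low"],
            "r_ratio_ci95_high": m["ci_high"],
            "n": len(ratios),
            "all_two_fold": bool(grp["two_fold_pass"].all()),
        }
    return EvaluationReport(df, pd.DataFrame(rows).T)


def vpc(simulated_profiles, observed_profile=None) -> dict:
    """Visual-predictive-check bands from a set of simulated profiles.

    Returns per-time 5th/95th percentiles, arithmetic mean, min and max as a
    tidy frame, plus — when an observed profile is supplied — the fraction of
    observed points falling inside the 5–95 band (linear interpolation onto
    the observed sampling times).
    """
    if not simulated_profiles:
        raise ValueError("empty simulation set")
    t = np.asarray(simulated_profiles[0].times, dtype=float)
    mat = np.vstack([np.interp(t, p.times, p.concentrations)
                     for p in simulated_profiles])
    bands = pd.DataFrame({
        "time_h": t,
        "p5": np.percentile(mat, 5, axis=0),
        "p95": np.percentile(mat, 95, axis=0),
        "mean": mat.mean(axis=0),
        "min": mat.min(axis=0),
        "max": mat.max(axis=0),
    })
    out = {"bands": bands, "n_simulated": len(simulated_profiles)}
    if observed_profile is not None:
        t_obs = np.asarray(observed_profile.times, dtype=float)
        c_obs = np.asarray(observed_profile.concentrations, dtype=float)
        lo = np.interp(t_obs, t, bands["p5"].to_numpy())
        hi = np.interp(t_obs, t, bands["p95"].to_numpy())
        inside = (c_obs >= lo) & (c_obs <= hi)
        out["observed_inside_fraction"] = float(inside.mean())
        out["overlay"] = pd.DataFrame({
            "time_h": t_obs, "observed": c_obs, "p5": lo, "p95": hi,
            "inside": inside,
        })
    return out
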