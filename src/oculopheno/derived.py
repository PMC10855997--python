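"""Derived analysis indicators.

Regression-adjusted latencies, control-referenced z-scores for ocular-motor
indicators, normative z-scores for retinal nerve fibre layer thickness,
Snellen-to-LogMAR acuity conversion and qualitative severity labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import INDICATORS

#: Tasks whose latency carries a cognitive load on top of simple visual
#: processing; each is adjusted by visually guided latency.
COGNITIVE_LATENCIES = ["EC_LATENCY", "AS_LATENCY", "MG_LATENCY"]

#: Normative RNFL reference (configurable placeholders, not ground truth).
RNFL_NORM_MEAN = 97.0
RNFL_NORM_SD = 10.0


def adjust_latency(task_latency: pd.Series, vg_latency: pd.Series,
                   fit_mask: pd.Series | None = None) -> pd.Series:
    """Remove the simple-processing-speed component from a cognitive latency.

    Ordinary least squares of the task latency on visually guided latency
    is fitted over ``fit_mask`` (default: all complete pairs); the adjusted
    value is the residual plus the fitted value at the fit-sample mean VG
    latency, which keeps the original millisecond scale.  Every row
    (inside or outside the fit sample) is adjusted with the same fit, so
    patients and controls remain comparable.
    """
    y = pd.Series(task_latency, dtype=float)
    x = pd.Series(vg_latency, dtype=float)
    mask = pd.Series(True, index=y.index) if fit_mask is None \
        else fit_mask.reindex(y.index, fill_value=False)
    ok = mask & y.notna() & x.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs in the fit sample")
    xf, yf = x[ok].to_numpy(), y[ok].to_numpy()
    if np.var(xf) <= 0:
        raise ValueError("VG latency has zero variance in the fit sample")
    slope = np.cov(xf, yf, ddof=1)[0, 1] / np.var(xf, ddof=1)
    xbar = xf.mean()
    return y - slope * (x - xbar)


def adjust_latencies(metrics: pd.DataFrame,
                     fit_mask: pd.Series | None = None,
                     tasks: list[str] = COGNITIVE_LATENCIES) -> pd.DataFrame:
    """Adjust every cognitive-task latency column by VG latency in place
    (returns a copy)."""
    out = metrics.copy()
    for col in tasks:
        if col in out:
            out[col] = adjust_latency(out[col], out["VG_LATENCY"], fit_mask)
    return out


def zscore_metrics(patients: pd.DataFrame, controls: pd.DataFrame,
                   rnfl_norm_mean: float = RNFL_NORM_MEAN,
                   rnfl_norm_sd: float = RNFL_NORM_SD,
                   indicators: list[str] = INDICATORS) -> pd.DataFrame:
    """Standardize patient indicators.

    Ocular-motor indicators are z-scored against the healthy-control mean
    and standard deviation; RNFL is z-scored against a normative reference
    (OCT is not administered to controls).  Missing values propagate.
    """
    if rnfl_norm_sd <= 0:
        raise ValueError("rnfl_norm_sd must be positive")
    out = pd.DataFrame(index=patients.index)
    for col in indicators:
        if col not in patients:
            continue
        if col == "RNFL":
            out[col] = (patients[col] - rnfl_norm_mean) / rnfl_norm_sd
            continue
        ref = controls[col].dropna()
        if len(ref) < 2:
            raise ValueError(f"need >= 2 control values for {col}")
        sd = ref.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"zero control SD for indicator {col}")
        out[col] = (patients[col] - ref.mean()) / sd
    return out


def snellen_to_logmar(numerator: float, denominator: float) -> float:
    """LogMAR acuity from a Snellen fraction; 6/6 maps to 0."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen components must be positive")
    return float(np.log10(denominator / numerator))


def severity_label(z: float, inverted: bool = False) -> str:
    """Qualitative impairment label for a standardized indicator value.

    Ocular-motor indicators: z in (1, 2] mild, (2, 3] moderate, above 3
    severe (boundary values fall in the lower category).  Inverted
    indicators (RNFL) are dichotomous: impaired when z < -1, else intact.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if inverted:
        return "impaired" if z < -1 else "intact"
    if z > 3:
        return "severe"
    if z > 2:
        return "moderate"
    if z > 1:
        return "mild"
    return "none"
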