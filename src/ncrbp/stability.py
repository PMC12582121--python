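"""mRNA half-life estimation from transcription-arrest time courses.

After actinomycin-D treatment, transcript abundance relative to t = 0
follows first-order decay A * exp(-lambda * t); the half-life is
ln 2 / lambda. The default estimator is ordinary least squares of
log abundance on time (closed form, robust for the strictly positive
qPCR readout); a nonlinear exponential fit is available as refinement.
Replicates are normalized to their own t = 0 value and pooled into one
joint fit. A time-to-50% interpolation is reported alongside as a
model-free check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["DecayFit", "fit_decay", "halflife_ratio"]


@dataclass
class DecayFit:
    decay_rate: float        # per hour
    half_life: float         # hours; inf for non-decaying series
    se_half_life: float
    r_squared: float
    method: str
    half_life_interp: float  # time to 50% by linear interpolation


def _normalize_replicates(curve: pd.DataFrame) -> pd.DataFrame:
    out = []
    group_cols = [c for c in ("condition", "replicate") if c in curve.columns]
    groups = curve.groupby(group_cols) if group_cols else [((), curve)]
    for _, sub in groups:
        sub = sub.sort_values("time_h").copy()
        t0 = sub.loc[sub["time_h"] == sub["time_h"].min(), "rel_abundance"].mean()
        if t0 <= 0:
            raise ValueError("non-positive abundance at the first time point")
        sub["rel_abundance"] = sub["rel_abundance"] / t0
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _interp_half_life(t: np.ndarray, y: np.ndarray) -> float:
    """Model-free time at which the mean profile crosses 0.5."""
    prof = pd.DataFrame({"t": t, "y": y}).groupby("t")["y"].mean()
    tt, yy = prof.index.to_numpy(), prof.to_numpy()
    below = np.nonzero(yy <= 0.5)[0]
    if below.size == 0:
        return float("inf")
    i = below[0]
    if i == 0:
        return float(tt[0])
    return float(tt[i - 1] + (0.5 - yy[i - 1]) * (tt[i] - tt[i - 1]) / (yy[i] - yy[i - 1]))


def fit_decay(curve: pd.DataFrame, method: str = "loglinear") -> DecayFit:
    """Fit a single-exponential decay and return the half-life.

    ``curve`` needs columns time_h and rel_abundance (plus optional
    condition/replicate; each replicate is renormalized to its first time
    point and all points are fitted jointly). A non-decaying series
    (fitted slope >= 0) is flagged with an infinite half-life. Zero
    abundances under the log-linear method trigger a fallback to the
    nonlinear fit.
    """
    curve = _normalize_replicates(curve)
    t = curve["time_h"].to_numpy(dtype=float)
    y = curve["rel_abundance"].to_numpy(dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 time points")

    if method == "loglinear" and (y <= 0).any():
        warnings.warn("zero abundance encountered; switching to the nonlinear fit")
        method = "nonlinear"

    if method == "loglinear":
        fit = stats.linregress(t, np.log(y))
        lam = -fit.slope
        se_lam = fit.stderr
        r2 = fit.rvalue ** 2
    elif method == "nonlinear":
        popt, pcov = optimize.curve_fit(
            lambda tt, a, lam: a * np.exp(-lam * tt), t, y, p0=[1.0, 0.3], maxfev=20000
        )
        lam = popt[1]
        se_lam = float(np.sqrt(pcov[1, 1]))
        pred = popt[0] * np.exp(-lam * t)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")

    interp = _interp_half_life(t, y)
    if lam <= 0:
        return DecayFit(float(lam), float("inf"), float("nan"), float(r2), method, interp)
    half_life = np.log(2.0) / lam
    se_hl = np.log(2.0) * se_lam / lam**2  # delta method
    return DecayFit(float(lam), float(half_life), float(se_hl), float(r2), method, interp)


def halflife_ratio(fit_control: DecayFit, fit_kd: DecayFit) -> tuple[float, float]:
    """Fold reduction of half-life: control over knockdown, with delta-method SE.

    Returns (ratio, se). Either fit being non-decaying (infinite
    half-life) yields (nan, nan).
    """
    if not (np.isfinite(fit_control.half_life) and np.isfinite(fit_kd.half_life)):
        return float("nan"), float("nan")
    ratio = fit_control.half_life / fit_kd.half_life
    rel_var = 0.0
    for fit in (fit_control, fit_kd):
        if np.isfinite(fit.se_half_life):
            rel_var += (fit.se_half_life / fit.half_life) ** 2
    return float(ratio), float(ratio * np.sqrt(rel_var))
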