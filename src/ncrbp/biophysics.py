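"""Binding, mass-photometry, and enzyme-activity curve fitting.

Covers the plate-reader side of RBP characterization: one-site binding
isotherms from fluorescence polarization or EMSA fraction-bound tables
(hyperbolic, or quadratic with probe depletion), four-parameter logistic
competition curves, linear contrast-to-mass calibration and Gaussian
mixture fitting of mass-photometry events, and NADH-standard-curve
enzyme activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "BindingFit",
    "CompetitionFit",
    "MixtureFit",
    "ActivityResult",
    "fit_binding",
    "fit_competition",
    "calibrate_masses",
    "fit_mass_mixture",
    "mass_shift",
    "enzyme_activity",
]

# Default calibrant masses (monomeric BSA and thyroglobulin), overridable.
DEFAULT_CALIBRANTS_KDA = {"BSA": 66.5, "thyroglobulin": 660.0}


@dataclass
class BindingFit:
    kd: float            # nM
    response_free: float
    response_bound: float
    se_kd: float
    r_squared: float
    model: str


@dataclass
class CompetitionFit:
    ic50: float          # same units as the input concentrations
    max_inhibition: float
    hill: float
    upper: float
    lower: float
    r_squared: float
    inhibition_detected: bool


@dataclass
class MixtureFit:
    means_kDa: np.ndarray
    sds_kDa: np.ndarray
    weights: np.ndarray
    k: int
    bic: float
    assignment: np.ndarray = field(repr=False, default=None)


@dataclass
class ActivityResult:
    activity: float           # nmole NADH / min / mL
    standard_slope: float     # A450 per nmole
    standard_intercept: float
    kinetic_slope: float      # A450 per min


def _hyperbolic(conc, kd, r_free, r_bound):
    return r_free + (r_bound - r_free) * conc / (kd + conc)


def _quadratic(conc, kd, r_free, r_bound, probe):
    # exact fraction bound with ligand (probe) depletion
    s = conc + probe + kd
    frac = (s - np.sqrt(s * s - 4.0 * conc * probe)) / (2.0 * probe)
    return r_free + (r_bound - r_free) * frac


def fit_binding(
    curve: pd.DataFrame,
    model: str = "hyperbolic",
    noise_floor: float = 0.0,
    conc_col: str = "protein_conc_nM",
    response_col: str = "response_mP",
) -> BindingFit:
    """Least-squares fit of a one-site binding isotherm.

    ``model='hyperbolic'`` assumes the probe concentration is negligible
    against Kd; ``model='quadratic'`` accounts for probe depletion using
    the ``probe_conc_nM`` column. Kd is constrained positive; its standard
    error comes from the fit covariance.
    """
    conc = np.asarray(curve[conc_col], dtype=float)
    resp = np.asarray(curve[response_col], dtype=float)
    if conc.size < 5:
        raise ValueError("need >= 5 titration points")
    if (conc <= 0).any():
        raise ValueError("protein concentrations must be positive")
    if np.ptp(resp) <= noise_floor:
        raise ValueError("no binding signal (response range below noise floor)")

    order = np.argsort(conc)
    r_free0, r_bound0 = resp[order[0]], resp[order[-1]]
    half = (r_free0 + r_bound0) / 2.0
    kd0 = float(np.interp(half, resp[order], conc[order])) if r_bound0 != r_free0 else np.median(conc)
    kd0 = max(kd0, conc.min() / 10)

    if model == "hyperbolic":
        fun = _hyperbolic
    elif model == "quadratic":
        probe = float(np.asarray(curve["probe_conc_nM"], dtype=float)[0])
        def fun(c, kd, rf, rb):  # noqa: E306
            return _quadratic(c, kd, rf, rb, probe)
    else:
        raise ValueError(f"unknown model {model!r}")

    try:
        popt, pcov = optimize.curve_fit(
            fun, conc, resp, p0=[kd0, r_free0, r_bound0],
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"binding fit did not converge (p0 kd={kd0:.3g})") from exc
    pred = fun(conc, *popt)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    return BindingFit(
        kd=float(popt[0]),
        response_free=float(popt[1]),
        response_bound=float(popt[2]),
        se_kd=float(np.sqrt(pcov[0, 0])),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        model=model,
    )


def _four_pl(conc, ic50, hill, upper, lower):
    return lower + (upper - lower) / (1.0 + (conc / ic50) ** hill)


def fit_competition(
    inhibitor_conc: np.ndarray, response: np.ndarray, noise_floor: float = 0.0
) -> CompetitionFit:
    """Four-parameter logistic fit of a competition titration.

    Returns IC50 on the input concentration scale and the maximal
    inhibition 1 - lower/upper. Flat or monotonically increasing data are
    flagged as showing no inhibition (IC50 = NaN).
    """
    conc = np.asarray(inhibitor_conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.size < 5:
        raise ValueError("need >= 5 competition points")
    flat = np.ptp(resp) <= noise_floor
    rising = stats.linregress(np.log10(conc[conc > 0]), resp[conc > 0]).slope > 0 if not flat else False
    if flat or rising:
        upper = float(resp.mean()) if flat else float(resp[np.argsort(conc)][0])
        return CompetitionFit(
            ic50=float("nan"), max_inhibition=0.0, hill=float("nan"),
            upper=upper, lower=upper, r_squared=0.0, inhibition_detected=False,
        )
    order = np.argsort(conc)
    upper0, lower0 = resp[order[0]], resp[order[-1]]
    ic50_0 = float(np.exp(np.interp((upper0 + lower0) / 2, resp[order][::-1], np.log(conc[order])[::-1])))
    popt, _ = optimize.curve_fit(
        _four_pl, conc, resp, p0=[ic50_0, 1.0, upper0, lower0],
        bounds=([1e-12, 0.05, -np.inf, -np.inf], [np.inf, 20.0, np.inf, np.inf]),
        maxfev=20000,
    )
    pred = _four_pl(conc, *popt)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    ic50, hill, upper, lower = (float(v) for v in popt)
    return CompetitionFit(
        ic50=ic50,
        max_inhibition=1.0 - lower / upper,
        hill=hill,
        upper=upper,
        lower=lower,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        inhibition_detected=True,
    )


def calibrate_masses(
    standards: pd.DataFrame, contrasts: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Convert interferometric contrasts to molecular masses.

    Ordinary least squares of known mass on contrast over >= 2 standards
    with distinct contrasts; returns the calibrated event masses and the
    calibration line (slope, intercept, r_squared).
    """
    c = np.asarray(standards["contrast"], dtype=float)
    m = np.asarray(standards["known_mass_kDa"], dtype=float)
    if c.size < 2 or np.unique(m).size < 2:
        raise ValueError("need >= 2 standards with distinct masses")
    if np.unique(c).size < 2:
        raise ValueError("standard contrasts are collinear duplicates")
    fit = stats.linregress(c, m)
    masses = fit.slope * np.asarray(contrasts, dtype=float) + fit.intercept
    report = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
    }
    return masses, report


def fit_mass_mixture(
    masses: np.ndarray, k: int | None = None, seed: int = 0, k_max: int = 4
) -> MixtureFit:
    """Gaussian mixture fit of particle masses by EM.

    ``k=None`` selects the component count in 1..``k_max`` by BIC. The EM
    is initialized with seeded k-means++ and is bit-reproducible for a
    fixed seed. Component means are reported in ascending order.
    """
    x = np.asarray(masses, dtype=float).reshape(-1, 1)
    if x.size < 100:
        raise ValueError("need >= 100 events for mixture fitting")
    support = np.unique(x).size
    ks = range(1, k_max + 1) if k is None else [k]
    if max(ks) > support:
        raise ValueError(f"k={max(ks)} exceeds the {support} distinct mass values")
    best = None
    for kk in ks:
        gm = GaussianMixture(
            n_components=kk, covariance_type="full", random_state=seed,
            init_params="k-means++", max_iter=500, tol=1e-8, n_init=1, reg_covar=1e-10,
        ).fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, kk, gm)
    bic, kk, gm = best
    order = np.argsort(gm.means_.ravel())
    assignment = np.argsort(order)[gm.predict(x)]
    return MixtureFit(
        means_kDa=gm.means_.ravel()[order],
        sds_kDa=np.sqrt(gm.covariances_.reshape(kk, -1)[:, 0])[order],
        weights=gm.weights_[order],
        k=kk,
        bic=float(bic),
        assignment=assignment,
    )


def mass_shift(fit_a: MixtureFit, fit_b: MixtureFit, component: int | float = -1) -> float:
    """Mass difference of matched components between two mixture fits.

    ``component`` selects the reference component in ``fit_a`` either by
    index (int; -1 = heaviest) or by approximate mass (float); the partner
    in ``fit_b`` is the component with the nearest mean. Returns
    mean_b - mean_a in kDa.
    """
    if isinstance(component, float):
        ia = int(np.argmin(np.abs(fit_a.means_kDa - component)))
    else:
        ia = int(component)
    mean_a = fit_a.means_kDa[ia]
    ib = int(np.argmin(np.abs(fit_b.means_kDa - mean_a)))
    return float(fit_b.means_kDa[ib] - mean_a)


def enzyme_activity(
    kinetics: pd.DataFrame, standards: pd.DataFrame, sample_volume_mL: float
) -> ActivityResult:
    """Enzyme activity from a kinetic absorbance trace and a standard curve.

    activity = (kinetic slope [A450/min] / standard slope [A450/nmole])
    / sample volume [mL], in nmole NADH per minute per mL.
    """
    if len(kinetics) < 3 or len(standards) < 3:
        raise ValueError("need >= 3 kinetic points and >= 3 standards")
    std = stats.linregress(
        np.asarray(standards["nmole"], dtype=float), np.asarray(standards["A450"], dtype=float)
    )
    if std.slope == 0:
        raise ValueError("standard curve has zero slope")
    kin = stats.linregress(
        np.asarray(kinetics["time_min"], dtype=float), np.asarray(kinetics["A450"], dtype=float)
    )
    activity = kin.slope / std.slope / sample_volume_mL
    return ActivityResult(
        activity=float(activity),
        standard_slope=float(std.slope),
        standard_intercept=float(std.intercept),
        kinetic_slope=float(kin.slope),
    )
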