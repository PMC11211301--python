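"""Recovery-curve fitting and partial-volume-correction factors.

The recovery curve is modelled as

    f_RC(d) = (1 + (beta / d) ** gamma) ** -1

which rises monotonically from 0 to 1 with sphere diameter d and equals
0.5 at d = beta.  Diameters are expressed in centimeters for fitting,
which places beta in the 1-3 range typical of Lu-177 SPECT; gamma is
dimensionless.  The PVC factor for a spherical lesion of diameter d is
1 / f_RC(d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

MM_PER_CM = 10.0

_BETA_BOUNDS = (1e-6, 20.0)
_GAMMA_BOUNDS = (1e-6, 10.0)


def rc_model(d, beta, gamma):
    """Sigmoid recovery curve; d and beta in the same length unit."""
    d = np.asarray(d, dtype=float)
    return 1.0 / (1.0 + (beta / d) ** gamma)


@dataclass(frozen=True)
class RCFitResult:
    beta: float  # cm
    gamma: float
    r_squared: float
    converged: bool = True


@dataclass
class FitEnsemble:
    """Fits of all permutations of one (phantom, arm) cell.

    ``mean_curve``/``sigma_curve`` are the pointwise ensemble mean and
    sample standard deviation (N-1 denominator) of the member curves at
    ``eval_diameters_cm``; the envelope holds the pointwise extremes.
    """

    fits: list[RCFitResult]
    eval_diameters_cm: np.ndarray
    mean_curve: np.ndarray
    sigma_curve: np.ndarray
    envelope_min: np.ndarray
    envelope_max: np.ndarray
    beta_stats: dict
    gamma_stats: dict


def _initial_beta(d_cm: np.ndarray, rc: np.ndarray) -> float:
    """Diameter at which the interpolated RC crosses 0.5 (clipped)."""
    order = np.argsort(d_cm)
    d, r = d_cm[order], rc[order]
    if r[-1] < 0.5:
        return float(d[-1])
    if r[0] > 0.5:
        return float(d[0])
    return float(np.interp(0.5, r, d))


def fit_rc_curve(diameters_cm: Sequence[float], rcs: Sequence[float]) -> RCFitResult:
    """Unweighted non-linear least-squares fit of the recovery curve.

    Falls back on a small multistart grid when the default start does
    not converge.  Degenerate input (all RCs equal) is flagged
    non-identifiable rather than silently fitted.
    """
    d = np.asarray(diameters_cm, dtype=float)
    r = np.asarray(rcs, dtype=float)
    if d.size < 3:
        raise ValueError("at least three points are required")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    if np.ptp(r) < 1e-12:
        return RCFitResult(np.nan, np.nan, np.nan, converged=False)

    starts = [(_initial_beta(d, r), 2.0)]
    starts += [(b, g) for b in (0.5, 1.0, 2.0, 4.0) for g in (1.0, 2.0, 4.0)]
    bounds = ([_BETA_BOUNDS[0], _GAMMA_BOUNDS[0]], [_BETA_BOUNDS[1], _GAMMA_BOUNDS[1]])
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(rc_model, d, r, p0=p0, bounds=bounds, maxfev=5000)
        except RuntimeError:
            continue
        ss_res = float(np.sum((r - rc_model(d, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
        if ss_res < 1e-20:
            break
    if best is None:
        return RCFitResult(np.nan, np.nan, np.nan, converged=False)
    (beta, gamma), ss_res = best
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return RCFitResult(float(beta), float(gamma), r2, converged=True)


def evaluate_fit(fit: RCFitResult, d_cm) -> np.ndarray | float:
    """Recovery coefficient predicted by a fit at diameter d (cm)."""
    if np.any(np.asarray(d_cm) <= 0):
        raise ValueError("diameter must be positive")
    out = rc_model(d_cm, fit.beta, fit.gamma)
    return float(out) if np.isscalar(d_cm) else out


def pvc_factor(fit: RCFitResult, d_cm: float) -> float:
    """Partial-volume correction factor 1 / f_RC(d)."""
    rc = evaluate_fit(fit, d_cm)
    if rc == 0:
        raise ValueError("fitted RC is zero; correction factor undefined")
    return 1.0 / rc


def _param_stats(values: np.ndarray) -> dict:
    mean = float(values.mean())
    return dict(
        mean=mean,
        sd=float(values.std(ddof=1)),
        min=float(values.min()),
        max=float(values.max()),
        variation=(float(values.max()) - float(values.min())) / mean,
    )


def ensemble_stats(
    fits: Sequence[RCFitResult], eval_diameters_cm: Sequence[float]
) -> FitEnsemble:
    """Ensemble mean/sd curves and parameter spread across permutations."""
    fits = [f for f in fits]
    if len(fits) < 2:
        raise ValueError("at least two fits are required for ensemble statistics")
    d = np.asarray(eval_diameters_cm, dtype=float)
    curves = np.array([evaluate_fit(f, d) for f in fits])
    betas = np.array([f.beta for f in fits])
    gammas = np.array([f.gamma for f in fits])
    return FitEnsemble(
        fits=list(fits),
        eval_diameters_cm=d,
        mean_curve=curves.mean(axis=0),
        sigma_curve=curves.std(axis=0, ddof=1),
        envelope_min=curves.min(axis=0),
        envelope_max=curves.max(axis=0),
        beta_stats=_param_stats(betas),
        gamma_stats=_param_stats(gammas),
    )


def fit_sweep(records: pd.DataFrame) -> pd.DataFrame:
    """Fit one recovery curve per (phantom, permutation, arm, updates)."""
    rows = []
    keys = ["phantom_type", "permutation", "arm", "updates"]
    for key, g in records.groupby(keys, sort=True):
        fit = fit_rc_curve(g["diameter_mm"].to_numpy() / MM_PER_CM, g["rc"].to_numpy())
        rows.append(
            dict(
                zip(keys, key),
                beta=fit.beta,
                gamma=fit.gamma,
                r_squared=fit.r_squared,
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows)
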