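"""Global (non-specific) epistasis: logistic fit, AIC selection, detilting.

A landscape-wide nonlinear mapping between an additive latent trait and the
measured function inflates apparent epistasis without any specific residue
interaction.  The correction models the observed log10 fold-change F as a
four-parameter logistic of the first-order (additive) expectation F_add,

    F = U - (U - L) / (1 + exp((m - F_add) * s)),

selects it against a linear null by AIC, and, when chosen, inverts it:

    F' = m - (1/s) * ln((F - L) / (U - F)).

Landscapes whose corrected values collapse onto the bounds {U, L} are flagged
degenerate and excluded downstream.

The one-shot fit uses the first-order projection of the observed values as
the x-axis.  That projection is itself distorted by the nonlinearity, so
:func:`correct_global_epistasis` optionally refines the fit to
self-consistency by re-deriving F_add from the detilted values and refitting
until the parameters converge; on a noise-free squashed additive landscape
this recovers the bounds exactly and removes all epistasis of order >= 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import curve_fit

from .constants import CLAMP_DELTA, DEGENERACY_FRACTION
from .landscape_io import Landscape

__all__ = [
    "LogisticParams",
    "ModelSelection",
    "logistic",
    "fit_additive_firstorder",
    "fit_logistic",
    "select_model",
    "detilt",
    "detect_degenerate",
    "correct_global_epistasis",
    "GlobalEpistasisReport",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LogisticParams:
    """Upper bound U, lower bound L, mid-point m, slope s (log10 F units).

    U > L always; s may be negative (an increasing map), since the
    parameterisation (U, L, m, s) and (L, U, m, -s) describe the same curve.
    """

    U: float
    L: float
    m: float
    s: float

    def __post_init__(self) -> None:
        if not self.U > self.L:
            raise ValueError(f"require U > L, got U={self.U}, L={self.L}")
        if not (math.isfinite(self.s) and self.s != 0):
            raise ValueError(f"slope must be finite and nonzero, got {self.s}")


@dataclass(frozen=True)
class ModelSelection:
    aic_linear: float
    aic_logistic: float
    chosen: str  # "linear" or "logistic"
    params: LogisticParams | None = None
    converged: bool = True


def logistic(f_add: np.ndarray, params: LogisticParams) -> np.ndarray:
    """Forward map from additive expectation to observed function."""
    f_add = np.asarray(f_add, dtype=float)
    return params.U - (params.U - params.L) / (
        1.0 + np.exp((params.m - f_add) * params.s)
    )


def _design_firstorder(n: int) -> np.ndarray:
    g = np.arange(2 ** n)[:, None]
    bits = ((g >> np.arange(n)[None, :]) & 1).astype(float)
    return np.column_stack([np.ones(2 ** n), 2.0 * bits - 1.0])


def fit_additive_firstorder(landscape: Landscape) -> np.ndarray:
    """Fitted values of the first-order background-averaged model.

    Ordinary least squares of log10 F on an intercept plus one -1/+1 column
    per locus; for a complete landscape the design is orthogonal and full
    rank, so this is the projection onto the additive subspace.
    """
    X = _design_firstorder(landscape.n)
    beta, *_ = np.linalg.lstsq(X, landscape.values, rcond=None)
    return X @ beta


def _normalize(U: float, L: float, m: float, s: float) -> LogisticParams:
    if U < L:
        U, L, s = L, U, -s
    return LogisticParams(U=U, L=L, m=m, s=s)


def fit_logistic(
    f_add: np.ndarray, f_obs: np.ndarray, p0: LogisticParams | None = None
) -> LogisticParams:
    """Nonlinear least squares for (U, L, m, s) on (F_add, F) pairs.

    Deterministic: the starting point is U0 = max(F) + 0.05 range,
    L0 = min(F) - 0.05 range, m0 = median(F_add), s0 = 4 / range(F_add),
    unless an explicit p0 is given.  Raises RuntimeError on non-convergence.
    """
    f_add = np.asarray(f_add, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    if f_obs.size < 5:
        raise ValueError("need >= 5 pairs to fit 4 parameters plus a variance")

    def model(x, U, L, m, s):
        return U - (U - L) / (1.0 + np.exp(np.clip((m - x) * s, -500, 500)))

    if p0 is None:
        rf = float(np.ptp(f_obs)) or 1.0
        ra = float(np.ptp(f_add)) or 1.0
        start = [
            float(f_obs.max()) + 0.05 * rf,
            float(f_obs.min()) - 0.05 * rf,
            float(np.median(f_add)),
            4.0 / ra,
        ]
    else:
        start = [p0.U, p0.L, p0.m, p0.s]
    popt, _ = curve_fit(model, f_add, f_obs, p0=start, maxfev=20000)
    return _normalize(*popt)


def _gaussian_aic(rss: float, n_obs: int, k_mean_params: int) -> float:
    """AIC = 2k - 2 max log L under iid Gaussian errors; k counts the mean
    parameters plus one variance parameter."""
    rss = max(rss, 1e-300)
    max_ll = -0.5 * n_obs * (math.log(2 * math.pi * rss / n_obs) + 1.0)
    return 2.0 * (k_mean_params + 1) - 2.0 * max_ll


def select_model(landscape: Landscape) -> ModelSelection:
    """AIC choice between a linear and a logistic map of F on F_add.

    Both candidates are scored on the identical (F_add, F) pairs.  A
    non-converging logistic fit is treated as 'linear chosen' (fail-safe).
    """
    f_add = fit_additive_firstorder(landscape)
    f_obs = landscape.values
    n_obs = f_obs.size

    X = np.column_stack([np.ones(n_obs), f_add])
    beta, *_ = np.linalg.lstsq(X, f_obs, rcond=None)
    rss_lin = float(np.sum((f_obs - X @ beta) ** 2))
    aic_lin = _gaussian_aic(rss_lin, n_obs, 2)

    params: LogisticParams | None = None
    converged = True
    try:
        params = fit_logistic(f_add, f_obs)
        rss_logi = float(np.sum((f_obs - logistic(f_add, params)) ** 2))
        aic_logi = _gaussian_aic(rss_logi, n_obs, 4)
    except (RuntimeError, ValueError) as exc:
        log.warning("%s: logistic fit failed (%s); treating as linear",
                    landscape.label, exc)
        converged = False
        aic_logi = math.inf

    chosen = "logistic" if aic_logi < aic_lin else "linear"
    if chosen == "linear":
        params = params if converged else None
    return ModelSelection(
        aic_linear=aic_lin, aic_logistic=aic_logi, chosen=chosen,
        params=params, converged=converged,
    )


def detilt(
    landscape: Landscape, params: LogisticParams, recenter: bool = True
) -> Landscape:
    """Invert the logistic map to remove non-specific epistasis.

    Values outside (L, U) are clamped to L + delta / U - delta with
    delta = 1e-6 (U - L) and counted in flags['n_clamped'].  With
    ``recenter`` the transformed wt value is subtracted so value(wt) = 0
    again, keeping the wt-relative scale the SME/EE math assumes.
    """
    F = landscape.values
    delta = CLAMP_DELTA * (params.U - params.L)
    clamped = (F <= params.L + delta) | (F >= params.U - delta)
    z = np.clip(F, params.L + delta, params.U - delta)
    values = params.m - (1.0 / params.s) * np.log((z - params.L) / (params.U - z))
    if recenter:
        values = values - values[0]
    out = dc_replace(
        landscape,
        values=values,
        flags=dict(landscape.flags, detilted=True, n_clamped=int(clamped.sum())),
    )
    return out


def detect_degenerate(landscape: Landscape, params: LogisticParams) -> bool:
    """True when the correction collapses the landscape to binary values.

    Degenerate when more than 90% of the observed values lie within delta of
    either bound (equivalently, would be clamped by the inversion).
    """
    F = landscape.values
    delta = CLAMP_DELTA * (params.U - params.L)
    at_bounds = (F <= params.L + delta) | (F >= params.U - delta)
    return bool(np.mean(at_bounds) > DEGENERACY_FRACTION)


@dataclass(frozen=True)
class GlobalEpistasisReport:
    selection: ModelSelection
    degenerate: bool
    landscape: Landscape  # detilted if logistic chosen and not degenerate


def correct_global_epistasis(
    landscape: Landscape,
    refine: bool = True,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> GlobalEpistasisReport:
    """Full correction pipeline for one landscape.

    Fits both candidate maps, selects by AIC, and when the logistic wins
    detilts the values (after optional self-consistent refinement) and tests
    for degeneracy.  Degenerate landscapes are returned untransformed with
    the flag set so downstream stages can exclude them.
    """
    sel = select_model(landscape)
    if sel.chosen == "linear" or sel.params is None:
        out = dc_replace(landscape, flags=dict(landscape.flags, detilted=False,
                                               degenerate=False))
        return GlobalEpistasisReport(sel, False, out)

    params = sel.params
    if refine:
        f_obs = landscape.values
        for _ in range(max_iter):
            tilted = detilt(landscape, params)
            f_add = fit_additive_firstorder(tilted)
            try:
                new = fit_logistic(f_add, f_obs, p0=params)
            except (RuntimeError, ValueError):
                break
            drift = max(
                abs(new.U - params.U), abs(new.L - params.L),
                abs(new.m - params.m), abs(new.s - params.s),
            )
            params = new
            if drift < tol:
                break
        sel = dc_replace(sel, params=params)

    degenerate = detect_degenerate(landscape, params)
    if degenerate:
        out = dc_replace(landscape, flags=dict(landscape.flags, detilted=False,
                                               degenerate=True))
        log.warning("%s: degenerate after correction; excluded downstream",
                    landscape.label)
        return GlobalEpistasisReport(sel, True, out)

    out = detilt(landscape, params)
    out.flags["degenerate"] = False
    return GlobalEpistasisReport(sel, False, out)
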