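"""Climate-elasticity models (CEMs) and fire attribution of flow change.

Step 4 of the framework separates the climate contribution to the
observed 5-year change in mean annual flow from the residual attributed
to fire. Four candidate regressions of annual flow anomalies on annual
climate anomalies are fitted to pre-fire data only:

    CEM1: dQ ~ dP
    CEM2: dQ ~ dP + dPET
    CEM3: dQ ~ dP + d(sigma^2_Pm)   (monthly precipitation variance)
    CEM4: dQ ~ dP + dSWE            (snow water equivalent)

Anomalies are year values minus the pre-fire mean, so the models carry
no intercept. The best candidate is chosen by the Bayesian Information
Criterion, BIC = -2 ln(L_k) + k ln(n), with a Gaussian likelihood
(variance SSE/n) and k the number of regression coefficients.
Significance uses an overall F-test for multi-predictor models and a
coefficient t-test for the one-predictor model. The fitted model then
predicts the climate-expected change dQ_clim from the observed 5-year
climate deltas, and the disturbance attributed to fire is the identity

    dQ_dist = dQ_obs - dQ_clim,

presumed fire-caused in watersheds whose burned-area ratio reaches the
critical threshold BAR_t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CEM_PREDICTORS",
    "CEMFit",
    "Attribution",
    "fit_cems",
    "select_best_cem",
    "cem_significance",
    "predict_dq_clim",
    "attribute_disturbance",
]

#: Fixed predictor sets of the four candidate models (anomaly columns).
CEM_PREDICTORS: dict[str, tuple[str, ...]] = {
    "CEM1": ("P",),
    "CEM2": ("P", "PET"),
    "CEM3": ("P", "sigma2_Pm"),
    "CEM4": ("P", "SWE"),
}

_CEM_ORDER = ("CEM1", "CEM2", "CEM3", "CEM4")


@dataclass
class CEMFit:
    """One fitted climate-elasticity candidate.

    Coefficients are in mm of flow per unit predictor (mm for P, PET,
    SWE; mm^2 for the variance term). ``loglik`` is the maximized
    Gaussian log-likelihood with variance SSE/n; ``bic`` follows
    -2 ln(L) + k ln(n) with k = len(coefficients).
    """

    model_id: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    n: int
    k: int
    sse: float
    ssr: float
    loglik: float
    bic: float
    fittable: bool = True
    message: str = ""
    p_value: float | None = None
    test_type: str | None = None
    significant: bool | None = None


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_cems(annual_prefire: pd.DataFrame,
             candidates: Sequence[str] = _CEM_ORDER) -> list[CEMFit]:
    """Fit the candidate CEMs to pre-fire annual records.

    Parameters
    ----------
    annual_prefire:
        One row per pre-fire year with a ``Q`` column and whichever of
        P, PET, SWE, sigma2_Pm the candidates require. Values are
        converted to anomalies about their pre-fire means internally.
    candidates:
        Model ids to attempt. With fewer than 4 years only CEM1 is
        attempted; the rest are flagged insufficient.

    Candidates whose predictor columns are absent or rank-deficient are
    returned with ``fittable=False`` rather than dropped.
    """
    df = annual_prefire
    if "Q" not in df.columns:
        raise ValueError("annual records must contain a Q column")
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 pre-fire years")
    anomalies = df - df.mean()
    y = anomalies["Q"].to_numpy(dtype=float)

    fits: list[CEMFit] = []
    for model_id in candidates:
        preds = CEM_PREDICTORS[model_id]
        k = len(preds)
        if n < 4 and k > 1:
            fits.append(CEMFit(model_id, preds, {}, n, k, np.nan, np.nan,
                               np.nan, np.inf, fittable=False,
                               message="insufficient pre-fire years"))
            continue
        missing = [p for p in preds if p not in anomalies.columns]
        if missing:
            fits.append(CEMFit(model_id, preds, {}, n, k, np.nan, np.nan,
                               np.nan, np.inf, fittable=False,
                               message=f"missing predictors: {missing}"))
            continue
        x = anomalies[list(preds)].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(x)
        if rank < k or n <= k:
            fits.append(CEMFit(model_id, preds, {}, n, k, np.nan, np.nan,
                               np.nan, np.inf, fittable=False,
                               message="rank-deficient predictors"))
            continue
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        sse = float(((y - fitted) ** 2).sum())
        ssr = float((fitted**2).sum())
        loglik = _gaussian_loglik(sse, n)
        bic = -2.0 * loglik + k * math.log(n)
        fits.append(CEMFit(model_id, preds, dict(zip(preds, map(float, beta))),
                           n, k, sse, ssr, loglik, bic))
    return fits


def select_best_cem(fits: Sequence[CEMFit]) -> CEMFit:
    """Minimum-BIC candidate; ties go to fewer parameters, then CEM1-order."""
    ok = [f for f in fits if f.fittable]
    if not ok:
        raise ValueError("no fittable climate-elasticity candidate")
    return min(ok, key=lambda f: (f.bic, f.k, _CEM_ORDER.index(f.model_id)))


def cem_significance(fit: CEMFit, alpha: float = 0.05) -> CEMFit:
    """Attach a significance decision to a fitted CEM (in place).

    Multi-predictor models use the overall regression F-test,
    F = (SSR/k)/(SSE/df) on (k, df) degrees of freedom; the
    one-predictor model uses a coefficient t-test on df degrees of
    freedom. Because the anomaly form centres every variable at its
    sample mean, one degree of freedom is absorbed beyond the k slopes:
    df = n - k - 1. A fit with zero residual degrees of freedom is
    flagged untestable.
    """
    if not fit.fittable:
        raise ValueError(f"{fit.model_id} was not fittable: {fit.message}")
    df_resid = fit.n - fit.k - 1
    if df_resid < 1:
        fit.test_type = "untestable"
        fit.p_value = None
        fit.significant = None
        return fit
    if fit.k == 1:
        pred = fit.predictors[0]
        beta = fit.coefficients[pred]
        sxx = fit.ssr / beta**2 if beta != 0 else np.nan
        s2 = fit.sse / df_resid
        if fit.sse == 0.0 or not np.isfinite(sxx):
            # perfect fit (or zero slope with zero spread): decide by limits
            fit.test_type = "t"
            fit.p_value = 0.0 if beta != 0 else 1.0
            fit.significant = bool(beta != 0)
            return fit
        t = beta / math.sqrt(s2 / sxx)
        fit.p_value = float(2.0 * stats.t.sf(abs(t), df_resid))
        fit.test_type = "t"
    else:
        if fit.sse == 0.0:
            fit.p_value = 0.0
        else:
            f = (fit.ssr / fit.k) / (fit.sse / df_resid)
            fit.p_value = float(stats.f.sf(f, fit.k, df_resid))
        fit.test_type = "F"
    fit.significant = bool(fit.p_value < alpha)
    return fit


def predict_dq_clim(fit: CEMFit, deltas: Mapping[str, float]) -> float:
    """Climate-expected 5-year flow change, mm per year.

    ``deltas`` maps predictor names to observed post-minus-pre climate
    deltas (e.g. the ``delta`` mapping of a window summary). The anomaly
    form has no intercept, so all-zero deltas give exactly zero.
    """
    if not fit.fittable:
        raise ValueError(f"{fit.model_id} was not fittable: {fit.message}")
    total = 0.0
    for pred in fit.predictors:
        if pred not in deltas:
            raise KeyError(f"missing climate delta for predictor '{pred}'")
        total += fit.coefficients[pred] * float(deltas[pred])
    return float(total)


@dataclass
class Attribution:
    """Decomposition of observed flow change into climate and fire parts.

    All three changes satisfy ``dq_dist == dq_obs - dq_clim`` exactly.
    Percent forms are relative to the pre-fire mean annual flow and are
    suppressed (NaN, ``pct_defined=False``) when that mean is not
    positive. ``eligible`` marks watersheds whose burned-area ratio
    reaches the critical threshold BAR_t, for which the residual is
    presumed fire-caused.
    """

    dq_obs: float
    dq_clim: float
    dq_dist: float
    q_pre: float
    dq_obs_pct: float
    dq_clim_pct: float
    dq_dist_pct: float
    pct_defined: bool
    model_id: str | None = None
    eligible: bool | None = None
    flags: dict = field(default_factory=dict)


def attribute_disturbance(dq_obs: float, dq_clim: float, q_pre: float,
                          bar: float | None = None,
                          bar_t: float | None = None,
                          model_id: str | None = None) -> Attribution:
    """Attribute the flow change unexplained by climate to disturbance.

    dq_dist = dq_obs - dq_clim (mm per year); percentages are
    100*value/q_pre with q_pre the pre-fire mean annual flow. When both
    ``bar`` and ``bar_t`` are given (fractions or both percent), the
    eligibility flag records whether bar >= bar_t.
    """
    dq_dist = dq_obs - dq_clim
    pct_defined = q_pre > 0
    if pct_defined:
        pcts = tuple(100.0 * v / q_pre for v in (dq_obs, dq_clim, dq_dist))
    else:
        pcts = (float("nan"),) * 3
    eligible = None
    if bar is not None and bar_t is not None:
        eligible = bool(bar >= bar_t)
    return Attribution(
        dq_obs=float(dq_obs), dq_clim=float(dq_clim), dq_dist=float(dq_dist),
        q_pre=float(q_pre), dq_obs_pct=pcts[0], dq_clim_pct=pcts[1],
        dq_dist_pct=pcts[2], pct_defined=bool(pct_defined),
        model_id=model_id, eligible=eligible,
        flags={} if pct_defined else {"q_pre_nonpositive": True},
    )
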