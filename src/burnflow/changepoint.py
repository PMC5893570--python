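"""Nonparametric change-point detection in monthly river flow.

Step 1 of the framework: a change-point model (CPM) slides a candidate
split through the monthly flow series and compares the value
distributions on either side with the Lepage statistic, which combines a
standardized Mann-Whitney rank-sum component (location shift) with the
Mood component (scale shift). The split maximising the statistic is the
estimated change time; significance is assessed against a permutation
null of the max-split statistic, which accounts for the selection effect
of maximising over splits. Flow disturbance is declared when a
significant change point falls within twelve months after the fire.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ChangePointResult",
    "mann_whitney_components",
    "mood_statistic",
    "lepage_statistic",
    "detect_change",
    "test_flow_disturbance",
]


# ---------------------------------------------------------------------------
# two-sample rank statistics
# ---------------------------------------------------------------------------

def mann_whitney_components(pre, post):
    """Mann-Whitney U for two segments, via pooled mid-ranks.

    Returns ``(U_S, U_T, U)`` where

        U_S = n_S n_T + n_S (n_S + 1)/2 - sum of pooled ranks in S,
        U_T = n_S n_T + n_T (n_T + 1)/2 - sum of pooled ranks in T,
        U   = min(U_S, U_T),

    so that U_S + U_T = n_S n_T. Ties receive mid-ranks.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n_s, n_t = len(pre), len(post)
    if n_s < 2 or n_t < 2:
        raise ValueError("each segment needs at least 2 observations")
    ranks = rankdata(np.concatenate([pre, post]))
    r_s = ranks[:n_s].sum()
    r_t = ranks[n_s:].sum()
    u_s = n_s * n_t + n_s * (n_s + 1) / 2.0 - r_s
    u_t = n_s * n_t + n_t * (n_t + 1) / 2.0 - r_t
    return float(u_s), float(u_t), float(min(u_s, u_t))


def mood_statistic(pre, post):
    """Standardized Mood scale statistic M >= 0.

    M' sums the squared deviations of the pooled ranks of the first
    segment from the pooled mid-rank (n+1)/2; M is |M' - mu|/sigma with

        mu    = n_S (n^2 - 1) / 12,
        sigma^2 = n_S n_T (n + 1)(n^2 - 4) / 180.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n_s, n_t = len(pre), len(post)
    n = n_s + n_t
    if n < 4:
        raise ValueError("Mood statistic needs at least 4 pooled observations")
    ranks = rankdata(np.concatenate([pre, post]))
    m_prime = float(((ranks[:n_s] - (n + 1) / 2.0) ** 2).sum())
    mu = n_s * (n**2 - 1) / 12.0
    var = n_s * n_t * (n + 1) * (n**2 - 4) / 180.0
    return abs(m_prime - mu) / np.sqrt(var)


def lepage_statistic(pre, post):
    """Lepage statistic L = U*^2 + M^2.

    U* is the Mann-Whitney component centred at n_S n_T / 2 and scaled
    by its null standard deviation sqrt(n_S n_T (n+1)/12); M is the
    standardized Mood component. Under no distributional change L is
    asymptotically chi-squared with 2 degrees of freedom. A fully tied
    input carries no rank information and returns 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    pooled = np.concatenate([pre, post])
    if np.all(pooled == pooled[0]):
        return 0.0
    n_s, n_t = len(pre), len(post)
    n = n_s + n_t
    _, _, u = mann_whitney_components(pre, post)
    u_star = (u - n_s * n_t / 2.0) / np.sqrt(n_s * n_t * (n + 1) / 12.0)
    m = mood_statistic(pre, post)
    return float(u_star**2 + m**2)


# ---------------------------------------------------------------------------
# change-point model
# ---------------------------------------------------------------------------

def _lepage_profile(rank_rows: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Lepage statistic at every candidate split, for a batch of rank rows.

    ``rank_rows`` has shape (B, n): each row is the pooled-rank vector of
    one (possibly permuted) series. ``taus`` are split sizes n_S. Runs in
    O(B n) via prefix sums. Returns shape (B, len(taus)).
    """
    b, n = rank_rows.shape
    centred = rank_rows - (n + 1) / 2.0
    cum_r = np.cumsum(rank_rows, axis=1)
    cum_sq = np.cumsum(centred**2, axis=1)
    n_s = taus.astype(float)
    n_t = n - n_s
    r_s = cum_r[:, taus - 1]
    u_s = n_s * n_t + n_s * (n_s + 1) / 2.0 - r_s
    u = np.minimum(u_s, n_s * n_t - u_s)
    u_star = (u - n_s * n_t / 2.0) / np.sqrt(n_s * n_t * (n + 1) / 12.0)
    m_prime = cum_sq[:, taus - 1]
    mu = n_s * (n**2 - 1) / 12.0
    sd = np.sqrt(n_s * n_t * (n + 1) * (n**2 - 4) / 180.0)
    m = np.abs(m_prime - mu) / sd
    return u_star**2 + m**2


@dataclass
class ChangePointResult:
    """Outcome of the change-point model on one series.

    ``tau`` is the split size n_S maximising L, i.e. the change is
    estimated between positions tau-1 and tau (0-based); ``change_index``
    is the first index of the post-change regime. ``h_t`` is the
    permutation critical value of the max-split statistic at level
    ``alpha``; ``detected`` iff ``l_max > h_t``. ``fire_linked`` is set
    by :func:`test_flow_disturbance` when the change falls within twelve
    months after the fire.
    """

    lepage: np.ndarray
    taus: np.ndarray
    l_max: float
    tau: int
    h_t: float
    alpha: float
    detected: bool
    n_perm: int
    seed: int | None
    fire_linked: bool | None = None
    change_label: object = None

    @property
    def change_index(self) -> int:
        return self.tau


def detect_change(series, alpha: float = 0.05, min_segment: int = 12,
                  n_perm: int = 1999, seed: int | None = None) -> ChangePointResult:
    """Run the change-point model over a series of monthly values.

    The Lepage statistic is evaluated at every split leaving at least
    ``min_segment`` observations on each side; the critical value h_t is
    the permutation (1 - alpha) quantile of the max-split statistic,
    computed by permuting the pooled ranks ``n_perm`` times. With B
    permutations the detection rule L_max > h_t, h_t the m-th largest
    permuted maximum with m = floor(alpha (B+1)), has exact level
    m/(B+1) <= alpha for continuous data.

    A constant series carries no rank information and yields L = 0
    everywhere, hence no detection.
    """
    values = np.asarray(pd.Series(series).to_numpy(), dtype=float)
    index = pd.Series(series).index
    n = len(values)
    if n < 2 * min_segment:
        raise ValueError(f"series length {n} < 2*min_segment ({2 * min_segment})")
    taus = np.arange(min_segment, n - min_segment + 1)

    if np.all(values == values[0]):
        lep = np.zeros(len(taus))
        return ChangePointResult(lep, taus, 0.0, int(taus[0]), np.inf, alpha,
                                 False, n_perm, seed)

    ranks = rankdata(values)
    lep = _lepage_profile(ranks[None, :], taus)[0]
    i_max = int(np.argmax(lep))
    l_max = float(lep[i_max])
    tau_hat = int(taus[i_max])

    rng = np.random.default_rng(seed)
    # permuting the series permutes its rank vector: shuffle ranks directly
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_max = _lepage_profile(ranks[perm_idx], taus).max(axis=1)
    m = max(int(np.floor(alpha * (n_perm + 1))), 1)
    h_t = float(np.sort(perm_max)[-m])
    detected = l_max > h_t

    label = index[tau_hat] if len(index) == n else None
    return ChangePointResult(lep, taus, l_max, tau_hat, h_t, alpha,
                             bool(detected), n_perm, seed, change_label=label)


def test_flow_disturbance(q_monthly: pd.Series, fire_date, alpha: float = 0.05,
                          min_segment: int = 12, n_perm: int = 1999,
                          seed: int | None = None) -> ChangePointResult:
    """Decide the flow-disturbance null for one watershed.

    The null of no change in monthly flow is rejected only when the
    change-point model detects a change *and* its estimated timing falls
    within the twelve months following the fire date. The series is
    restricted to the 60 months on each side of the fire, so candidate
    split positions 60..71 are fire-linked.
    """
    if not isinstance(q_monthly.index, pd.PeriodIndex):
        raise TypeError("q_monthly must have a PeriodIndex (freq='M')")
    fire_month = pd.Period(fire_date, freq="M")
    pre = q_monthly[q_monthly.index < fire_month].iloc[-60:]
    post = q_monthly[q_monthly.index >= fire_month].iloc[:60]
    if len(pre) < 60 or len(post) < 60:
        raise ValueError("need 60 months of flow on each side of the fire date")
    window = pd.concat([pre, post])
    result = detect_change(window, alpha=alpha, min_segment=min_segment,
                           n_perm=n_perm, seed=seed)
    # change between positions tau-1 and tau: post regime starts at index tau;
    # fire-linked iff the post regime starts in months 60..71 of the window
    result.fire_linked = bool(result.detected and 60 <= result.tau < 72)
    return result
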