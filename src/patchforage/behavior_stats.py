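"""Statistical procedures over trial-level behavioral measures.

ROC discriminability between response-time distributions (rank formulation
of the Mann-Whitney statistic, with half credit for ties), permutation-tested
Spearman rank correlations, bootstrap percentile confidence intervals,
condition-mean variance decomposition of search duration into gaze
components, OLS fits of reward effects, and the reward-rate ratio (RRR): the
achieved reward rate divided by the theoretical rate had no-reward-trial
behavior matched reward-trial behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "roc_area",
    "spearman_perm",
    "bootstrap_diff_ci",
    "condition_means",
    "reward_variance_explained",
    "fit_reward_effects",
    "RewardEffectFit",
    "reward_rate_ratio",
    "RRRResult",
]

#: The component columns a trial table may carry, by component id.
COMPONENT_COLUMNS = {
    "environmental": "comp_environmental_s",
    "target": "comp_target_s",
    "start": "comp_start_s",
    "other": "comp_other_s",
}


def roc_area(group_a, group_b) -> float:
    """Area under the ROC for discriminating two distributions.

    Equals the probability that a random draw from ``group_a`` exceeds a
    random draw from ``group_b``, with half credit for ties — the
    Mann-Whitney U statistic divided by ``n_a * n_b``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def spearman_perm(x, y, n_perm: int = 10_000, seed=None) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    The two-sided p-value comes from shuffling the pairing ``n_perm`` times:
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)``, so p is never
    zero and never below ``1 / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman's rho is undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(rx @ ry / n)
    rng = np.random.default_rng(seed)
    exceed = 0
    block = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = rng.permuted(np.broadcast_to(ry, (b, n)).copy(), axis=1)
        rho_p = perm @ rx / n
        exceed += int((np.abs(rho_p) >= abs(rho) - 1e-12).sum())
        done += b
    return rho, (1 + exceed) / (n_perm + 1)


def bootstrap_diff_ci(
    statistic, samples_a, samples_b,
    n_boot: int = 20_000, level: float = 0.999, seed=None,
) -> tuple[float, float]:
    """Bootstrap percentile CI of ``statistic(a*) - statistic(b*)``.

    Resampling is within-group with replacement; the interval is the
    equal-tailed percentile interval at the requested coverage level.
    """
    a = np.asarray(samples_a)
    b = np.asarray(samples_b)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        diffs[i] = statistic(ra) - statistic(rb)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def condition_means(trials: pd.DataFrame, column: str) -> pd.Series:
    """Mean of ``column`` for each realized (target value, environment
    probability) combination.

    With the standard five environments exactly 8 combinations occur
    (reward targets cannot occur at 0% probability nor no-reward targets at
    100%).
    """
    g = trials.groupby(["target_value", "reward_probability"],
                       observed=True)[column].mean()
    if g.isna().any():
        raise ValueError("every condition must contain at least one trial")
    return g


def reward_variance_explained(trials: pd.DataFrame, component_id: str) -> float:
    """Percent of condition-mean search-duration variance carried by a component.

    The reward-related variance is the variance of the vector of per-condition
    mean total search durations; the component's share is the percentage by
    which that variance drops after subtracting the component from the total
    on every trial. Components can overlap, so shares may sum above 100%.
    """
    col = COMPONENT_COLUMNS[component_id]
    m_total = condition_means(trials, "search_dur_s")
    resid = trials.assign(
        _resid=trials["search_dur_s"] - trials[col])
    m_resid = condition_means(resid, "_resid")
    v_total = float(np.var(m_total.to_numpy()))
    if v_total == 0:
        raise ValueError("zero condition-mean variance: share undefined")
    v_resid = float(np.var(m_resid.to_numpy()))
    return 100.0 * (v_total - v_resid) / v_total


@dataclass(frozen=True)
class RewardEffectFit:
    """OLS fit of a duration measure on p(reward) and reward value."""

    intercept: float
    coef_preward: float
    coef_reward: float
    se: tuple[float, float, float]
    pvalues: tuple[float, float, float]

    def __iter__(self):
        return iter((self.intercept, self.coef_preward, self.coef_reward))


def fit_reward_effects(
    trials: pd.DataFrame, component_id: str | None = None
) -> RewardEffectFit:
    """Ordinary least squares of single-trial durations on reward variables.

    Two regressors plus an intercept: p(reward) as a probability in [0, 1]
    and reward as a 0/1 indicator of the target's value. Main effects only.
    ``component_id`` selects a gaze component's duration; None fits the
    total search duration.
    """
    y = trials["search_dur_s"] if component_id is None else \
        trials[COMPONENT_COLUMNS[component_id]]
    X = sm.add_constant(
        trials[["reward_probability", "target_value"]].astype(float))
    if (np.ptp(X["reward_probability"]) == 0
            or np.ptp(X["target_value"]) == 0):
        raise ValueError("both regressors must vary in the data")
    res = sm.OLS(y.astype(float), X).fit()
    return RewardEffectFit(
        intercept=float(res.params.iloc[0]),
        coef_preward=float(res.params.iloc[1]),
        coef_reward=float(res.params.iloc[2]),
        se=tuple(float(s) for s in res.bse),
        pvalues=tuple(float(p) for p in res.pvalues),
    )


@dataclass(frozen=True)
class RRRResult:
    """Reward-rate ratio with its bootstrap CI and both rates."""

    rrr: float
    ci_low: float
    ci_high: float
    actual_rate: float
    theoretical_rate: float


def _rate_terms(trials: pd.DataFrame, substitute: bool) -> float:
    """Reward rate per the expectation formula.

    ``E[reward | correct] / (E[post-array time | correct]
    + E[errors per correct] * E[post-array time | error])``.

    With ``substitute`` the no-reward trials' mean correct search duration
    and search-error rate are replaced by the reward trials' values (the
    "always behaved as on reward trials" counterfactual).
    """
    corr = trials[trials["outcome"] == "correct"]
    err = trials[trials["outcome"] != "correct"]
    if len(corr) == 0:
        raise ValueError("no correct trials: reward rate undefined")
    e_rew = corr["rewarded"].mean()
    t_err = err["post_array_s"].mean() if len(err) else 0.0
    if not substitute:
        e_post = corr["post_array_s"].mean()
        err_per_corr = len(err) / len(corr)
        return e_rew / (e_post + err_per_corr * t_err)

    v1 = trials[trials["target_value"] == 1]
    v1_corr = v1[v1["outcome"] == "correct"]
    if len(v1_corr) == 0:
        raise ValueError("no correct reward trials: substitution undefined")
    sub_search = v1_corr["search_dur_s"].mean()
    nonsearch = corr["post_array_s"] - corr["search_dur_s"]
    search = np.where(corr["target_value"] == 1,
                      corr["search_dur_s"], sub_search)
    e_post = float((nonsearch + search).mean())
    err_per_corr = (len(v1) - len(v1_corr)) / len(v1_corr)
    v1_err = v1[v1["outcome"] != "correct"]
    t_err_sub = v1_err["post_array_s"].mean() if len(v1_err) else t_err
    return e_rew / (e_post + err_per_corr * t_err_sub)


def reward_rate_ratio(
    trials: pd.DataFrame,
    n_boot: int = 20_000, level: float = 0.999, seed=None,
) -> RRRResult:
    """Reward-rate ratio: achieved rate over the reward-behavior counterfactual.

    Considers all trials that reached search-array onset (the given table);
    the actual rate uses observed outcomes and post-search-array times, the
    theoretical rate substitutes no-reward trials' mean correct search
    duration and error rate with the reward trials' values. Values below 1
    quantify the reward-rate cost of the reward-related behavioral bias.
    The CI is a trial-resampling bootstrap percentile interval.
    """
    actual = _rate_terms(trials, substitute=False)
    theo = _rate_terms(trials, substitute=True)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(trials)
    attempts = 0
    while len(boots) < n_boot and attempts < 2 * n_boot:
        attempts += 1
        resampled = trials.iloc[rng.integers(0, n, n)]
        try:
            boots.append(_rate_terms(resampled, False)
                         / _rate_terms(resampled, True))
        except ValueError:  # degenerate resample (no correct reward trials)
            continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha]) if boots else \
        (np.nan, np.nan)
    return RRRResult(actual / theo, float(lo), float(hi), actual, theo)
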