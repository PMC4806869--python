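"""Group-discrimination statistics: AUC with CI and p-value, t-test, mean ± CI.

The AUC is the Mann–Whitney estimator — the probability that a randomly
chosen ARDS (positive) subject scores higher than a randomly chosen
control, with ties credited 0.5.  Its 95% CI uses the Hanley–McNeil
standard error by default (a seeded percentile bootstrap is available),
and the p-value comes from the normal approximation to the Mann–Whitney U
statistic with tie and continuity corrections.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, InvalidParametersError


def _as_groups(scores_pos, scores_neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(scores_pos, dtype=float).ravel()
    neg = np.asarray(scores_neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("AUC needs at least one score in each group")
    return pos, neg


def _rank_u(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney U for the positive group, via midranks (handles ties)."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float(ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)


def auc(scores_pos, scores_neg) -> float:
    """Mann–Whitney AUC: fraction of (pos, neg) pairs with pos > neg, ties 0.5."""
    pos, neg = _as_groups(scores_pos, scores_neg)
    return _rank_u(pos, neg) / (pos.size * neg.size)


def auc_ci(
    auc_value: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley–McNeil normal-approximation CI for an AUC, clipped to [0, 1].

    SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋),
    Q₁ = A/(2−A), Q₂ = 2A²/(1+A).
    """
    a = float(auc_value)
    if not 0.0 <= a <= 1.0:
        raise InvalidParametersError(f"AUC must be in [0, 1], got {a}")
    if n_pos < 1 or n_neg < 1:
        raise InsufficientDataError("need n_pos, n_neg >= 1 for the AUC CI")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se2 = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = np.sqrt(max(se2, 0.0))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(a - z * se, 0.0, 1.0)), float(np.clip(a + z * se, 0.0, 1.0))


def bootstrap_auc_ci(
    scores_pos,
    scores_neg,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for the AUC (groups resampled independently)."""
    pos, neg = _as_groups(scores_pos, scores_neg)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = auc(rng.choice(pos, pos.size), rng.choice(neg, neg.size))
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(reps, alpha)), float(np.quantile(reps, 1.0 - alpha))


def auc_p_value(scores_pos, scores_neg) -> float:
    """Two-sided Mann–Whitney p, normal approximation with tie and continuity
    corrections.  Returns 1.0 when the tie-corrected variance vanishes
    (all scores identical)."""
    pos, neg = _as_groups(scores_pos, scores_neg)
    n1, n2 = pos.size, neg.size
    n = n1 + n2
    u = _rank_u(pos, neg)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([pos, neg]), return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0.0:
        return 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def unpaired_t_test(a, b, equal_var: bool = True) -> float:
    """Two-sided unpaired t-test p-value (Student's pooled-variance form by
    default; ``equal_var=False`` for Welch)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("t-test needs at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            raise DegenerateDataError("both groups constant and equal; t undefined")
        return 0.0
    return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


def group_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-based confidence interval: mean ± t_{level, n−1} · SD/√n."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise InsufficientDataError("mean CI needs at least 2 values")
    mean = float(values.mean())
    half = float(
        sps.t.ppf(0.5 + level / 2.0, values.size - 1)
        * values.std(ddof=1)
        / np.sqrt(values.size)
    )
    return mean, mean - half, mean + half
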