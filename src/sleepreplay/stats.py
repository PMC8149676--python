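"""Group-level inference and behavioral scoring.

Covers the cluster-based permutation test used on decoding maps (dependent-
samples t at each point, contiguity clustering, maxsum cluster statistic,
Monte-Carlo sign-flip null), signal-detection recognition scoring (d′ with
extreme-proportion correction), the cued-recall retention index, and the
(partial) Spearman correlations relating reactivation to behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .core import validate_behavior_table
from .decoding import DecodingMap

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Outcome of a cluster-based permutation test."""

    cluster_masks: list[np.ndarray]  # boolean, one per cluster, disjoint
    cluster_stats: np.ndarray  # maxsum of t values per cluster
    p_values: np.ndarray  # Monte-Carlo, two-tailed
    t_map: np.ndarray
    t_threshold: float
    n_permutations: int

    def significant_mask(self, alpha: float = 0.05, sign: str = "both") -> np.ndarray:
        """Union of clusters with p < alpha (all-False when none).

        ``sign`` restricts to ``"positive"`` or ``"negative"`` clusters —
        e.g. above-chance decoding only, excluding the below-chance stripes
        that whole-trial baselining induces in generalization maps.
        """
        mask = np.zeros(self.t_map.shape, dtype=bool)
        for m, stat, p in zip(self.cluster_masks, self.cluster_stats, self.p_values):
            if p >= alpha:
                continue
            if (sign == "positive" and stat < 0) or (sign == "negative" and stat > 0):
                continue
            mask |= m
        return mask


def _cluster_maxsums(t: np.ndarray, threshold: float):
    """Positive and negative supra-threshold clusters with their t-sums.

    Contiguity is adjacency in 1-D and 4-connectivity in 2-D.
    """
    masks, sums = [], []
    for sign in (1.0, -1.0):
        lab, n_lab = scipy.ndimage.label(sign * t > threshold)
        for k in range(1, n_lab + 1):
            m = lab == k
            masks.append(m)
            sums.append(float(t[m].sum()))
    return masks, np.asarray(sums)


def cluster_permutation(
    observed: np.ndarray,
    baseline: np.ndarray | float = 0.5,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    exact: bool | None = None,
    random_state: int | None = None,
) -> ClusterResult:
    """Two-sided cluster permutation test of observed vs. baseline maps.

    Parameters
    ----------
    observed : ndarray, shape (n_participants, ...) with 1-D or 2-D maps
        Per-participant observed values (e.g. AUC time courses or
        train×test matrices).
    baseline : ndarray of the same shape, or scalar
        Per-participant surrogate maps, or a chance constant.
    cluster_alpha : float
        Two-sided sample-level threshold (p = 0.05 ⇒ |t| > t_crit).
    n_permutations : int
        Monte-Carlo randomizations (participant-wise sign flips of the
        difference maps). With ``exact=True`` (default for ≤ 12 participants
        when it needs no more draws than ``n_permutations``) all 2^n sign
        patterns are enumerated instead.

    Notes
    -----
    Cluster p values compare each observed cluster's |maxsum| against the
    permutation distribution of the map-wide maximum |maxsum| (a max-statistic
    construction, so the family-wise error across clusters is controlled at
    the nominal level). Monte-Carlo p values include the observed statistic
    in the null set: p = (b + 1) / (m + 1).
    """
    diff = np.asarray(observed, dtype=float) - baseline
    n = diff.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    map_shape = diff.shape[1:]
    if len(map_shape) not in (1, 2):
        raise ValueError("maps must be 1-D or 2-D")

    t_threshold = float(scipy.stats.t.ppf(1 - cluster_alpha / 2, n - 1))

    flat = diff.reshape(n, -1)
    sumsq = (flat**2).sum(axis=0)

    def t_from_signs(signs: np.ndarray) -> np.ndarray:
        # signs: (m, n); returns t maps (m, n_points)
        s = signs @ flat
        mean = s / n
        var = (sumsq[None, :] - n * mean**2) / (n - 1)
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / n)

    t_obs = t_from_signs(np.ones((1, n)))[0].reshape(map_shape)
    masks, stats = _cluster_maxsums(t_obs, t_threshold)

    if exact is None:
        exact = n <= 12 and 2**n <= n_permutations
    if exact:
        bits = np.arange(2**n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        denom_extra = 0  # identity pattern is part of the enumeration
    else:
        rng = np.random.default_rng(random_state)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        denom_extra = 1

    t_perm = t_from_signs(signs.astype(float))
    null_max = np.zeros(t_perm.shape[0])
    for i in range(t_perm.shape[0]):
        tm = t_perm[i].reshape(map_shape)
        _, s = _cluster_maxsums(tm, t_threshold)
        if s.size:
            null_max[i] = np.abs(s).max()

    if stats.size:
        exceed = (null_max[None, :] >= np.abs(stats)[:, None]).sum(axis=1)
        p_values = (exceed + denom_extra) / (len(null_max) + denom_extra)
    else:
        p_values = np.empty(0)
    return ClusterResult(
        cluster_masks=masks,
        cluster_stats=stats,
        p_values=p_values,
        t_map=t_obs,
        t_threshold=t_threshold,
        n_permutations=len(null_max),
    )


# ---------------------------------------------------------------------------
# Behavioral scoring
# ---------------------------------------------------------------------------

def dprime(hits: int, false_alarms: int, n_old: int, n_new: int) -> float:
    """Signal-detection sensitivity d′ = z(hit rate) − z(false-alarm rate).

    Proportions of 0 and 1 are replaced by 1/(2N) and 1 − 1/(2N), with N the
    number of trials entering that proportion.
    """
    if n_old <= 0 or n_new <= 0:
        raise ValueError("n_old and n_new must be positive")
    if not (0 <= hits <= n_old and 0 <= false_alarms <= n_new):
        raise ValueError("counts out of bounds")

    def rate(count: int, n: int) -> float:
        r = count / n
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    return float(
        scipy.stats.norm.ppf(rate(hits, n_old))
        - scipy.stats.norm.ppf(rate(false_alarms, n_new))
    )


def recall_and_retention(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant memory scores, collapsed across sessions by averaging.

    Scores per session: d′ pre/post; cued recall as percent of recognition
    hits, pre and post; and the retention index
    ``(post recall-of-hits % / pre recall-of-hits %) × 100``. Sessions with a
    zero denominator yield a missing retention value and are logged; the
    participant average ignores missing sessions.
    """
    validate_behavior_table(table)
    rows = []
    for _, r in table.iterrows():
        rec = {
            "participant": r["participant"],
            "session": r["session"],
            "dprime_pre": dprime(r["hits_pre"], r["false_alarms_pre"], r["n_old"], r["n_new"]),
            "dprime_post": dprime(r["hits_post"], r["false_alarms_post"], r["n_old"], r["n_new"]),
        }
        rec["recall_pre_pct"] = (
            100.0 * r["recalled_pre"] / r["hits_pre"] if r["hits_pre"] > 0 else np.nan
        )
        rec["recall_post_pct"] = (
            100.0 * r["recalled_post"] / r["hits_post"] if r["hits_post"] > 0 else np.nan
        )
        if r["hits_pre"] > 0 and r["recalled_pre"] > 0 and r["hits_post"] > 0:
            rec["retention_index"] = 100.0 * rec["recall_post_pct"] / rec["recall_pre_pct"]
        else:
            rec["retention_index"] = np.nan
            logger.warning(
                "participant %s session %s: zero denominator, retention missing",
                r["participant"],
                r["session"],
            )
        rows.append(rec)
    per_session = pd.DataFrame(rows)
    return (
        per_session.drop(columns="session")
        .groupby("participant", as_index=False)
        .mean()
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman correlation: Pearson partial correlation on ranks.

    All three variables are rank-transformed (average ranks for ties), x and
    y are residualized on the ranked covariate, and the Pearson correlation
    of the residuals is returned with a t-approximation p value (df = n − 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations for a partial correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(covariate) == 0:
        raise ValueError("constant input")
    rx, ry, rc = (scipy.stats.rankdata(v) for v in (x, y, covariate))

    def residual(v: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(n), rc])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ex, ey = residual(rx), residual(ry)
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        return 0.0, 1.0
    r = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = float(2 * scipy.stats.t.sf(abs(t), df))
    return r, p


def dependent_corr_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Compare two dependent correlations sharing one variable (Steiger's z).

    Tests r12 vs r13 given their intercorrelation r23; returns (z, p).
    """
    if n < 4:
        raise ValueError("need at least 4 observations")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar2 = ((r12 + r13) / 2) ** 2
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    cov = (r23 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r23**2)) / (
        (1 - rbar2) ** 2
    )
    z = (z12 - z13) * np.sqrt((n - 3) / (2 - 2 * cov))
    return float(z), float(2 * scipy.stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Reactivation strength
# ---------------------------------------------------------------------------

def reactivation_strength(
    maps: np.ndarray | list[DecodingMap],
    mask: np.ndarray | None = None,
    train_window: tuple[float, float] | None = None,
    test_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-participant mean AUC over a cluster mask or a window specification.

    ``maps`` is either a stacked array (participants × map) or a list of
    :class:`DecodingMap`. Provide a boolean ``mask`` over the map, or train
    and test windows (DecodingMap input only).
    """
    if isinstance(maps, np.ndarray):
        stacked = maps
        if mask is None:
            raise ValueError("a mask is required with array input")
    else:
        stacked = np.stack([m.auc for m in maps])
        if mask is None:
            if train_window is None or test_window is None:
                raise ValueError("provide a mask or both windows")
            ref = maps[0]
            trm = (ref.train_times >= train_window[0]) & (ref.train_times <= train_window[1])
            tem = (ref.test_times >= test_window[0]) & (ref.test_times <= test_window[1])
            mask = np.outer(trm, tem)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stacked.shape[1:]:
        raise ValueError("mask shape does not match the maps")
    if not mask.any():
        raise ValueError("empty mask")
    return stacked[:, mask].mean(axis=1)
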