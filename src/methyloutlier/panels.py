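"""Single-marker and two-marker panel evaluation.

A two-marker panel is scored per sample by the cumulative methylation
value — the sum of the two β values (range [0, 2]) for array data, or
the sum of percent methylation for lab assays. Discrimination between
case and control groups is measured by the area under the ROC curve,
which equals the Mann–Whitney U statistic divided by the number of
case–control pairs; ties count half. Confidence intervals use the
DeLong placement-variance method by default, with a simulation-based
lower bound substituted at perfect separation (where the DeLong
variance degenerates to zero), or a stratified bootstrap.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import BetaMatrix, SampleGroups, ValidationError

__all__ = [
    "PanelScore",
    "auc_mann_whitney",
    "mann_whitney_exact_p",
    "auc_confidence_interval",
    "cumulative_panel_values",
    "enumerate_and_rank_panels",
    "group_summaries",
    "cluster_order",
]

#: Largest combined group size at which the exact Mann–Whitney null
#: distribution is used (when the pooled scores are tie-free).
EXACT_P_MAX_N = 20


def auc_mann_whitney(case_values, control_values) -> tuple[float, float, float]:
    """AUC, Mann–Whitney U (for the case group) and two-sided p-value.

    Higher scores are case-like. AUC = (#{case > control} + ½·ties) /
    (n1·n2), so U = AUC·n1·n2 exactly. The p-value is exact (full null
    distribution) when n1+n2 ≤ 20 and the pooled scores are tie-free,
    otherwise a normal approximation with tie and continuity correction.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n2)
    if np.ptp(pooled) == 0.0:
        # all scores identical: no evidence either way
        return auc, u, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_P_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return auc, u, float(min(res.pvalue, 1.0))


def mann_whitney_exact_p(case_values, control_values) -> float:
    """Two-sided exact Mann–Whitney p by full label enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled scores to the
    case group; ties contribute ½ to U, and two-sidedness is measured by
    |U − n1·n2/2|, which is exact because the permutation null of U is
    symmetric about its midpoint. Intended for small groups (the
    spike-in design uses 6 vs 6, i.e. 924 arrangements).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1 = x.size
    pooled = np.concatenate([x, y])
    n = pooled.size
    if math.comb(n, n1) > 2_000_000:
        raise ValidationError(
            f"enumeration over C({n},{n1}) arrangements is too large; "
            "use auc_mann_whitney instead"
        )
    # greater[i, j] = 1 if pooled[i] > pooled[j], 0.5 on ties
    greater = (pooled[:, None] > pooled[None, :]).astype(float)
    greater += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(greater, 0.0)
    mid = n1 * (n - n1) / 2.0
    u_obs = greater[:n1, n1:].sum()
    extreme = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(range(n), n1):
        members = np.zeros(n, dtype=bool)
        members[list(combo)] = True
        u = greater[np.ix_(idx[members], idx[~members])].sum()
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


@functools.lru_cache(maxsize=128)
def _sim_lower_bound(true_auc: float, n1: int, n2: int, seed: int, alpha: float) -> float:
    """Cached binormal-simulation bound (shared across panels of one run)."""
    from .design import auc_lower_bound_sim

    return auc_lower_bound_sim(true_auc, n1, n2, reps=10000, seed=seed, alpha=alpha)


def _delong_auc_variance(case_values, control_values) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    r_all = stats.rankdata(pooled)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    # placement of each case among controls, and vice versa (ties: ½)
    v10 = (r_all[:n1] - r_x) / n2
    v01 = 1.0 - (r_all[n1:] - r_y) / n1
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n2 > 1 else 0.0
    return auc, s10 / n1 + s01 / n2


def auc_confidence_interval(
    case_values,
    control_values,
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the ROC AUC, truncated to [0, 1].

    ``delong``: normal interval from the DeLong placement variance. At
    perfect separation the DeLong variance is zero, so the lower bound
    is instead taken from a binormal ROC simulation at the true AUC
    corresponding to one misclassified sample (1 − 1/(n1+n2)) — the
    same substitution used for the study's AUC = 1.00 panels.
    ``bootstrap``: percentile interval over stratified resamples.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if method == "delong":
        auc, var = _delong_auc_variance(x, y)
        if var == 0.0 and auc in (0.0, 1.0):
            near = 1.0 - 1.0 / (x.size + y.size)
            if near <= 0.5:  # one vs one: a single pair carries no precision
                return 0.0, 1.0
            bound = _sim_lower_bound(near, x.size, y.size, seed, 1.0 - level)
            return (bound, 1.0) if auc == 1.0 else (0.0, 1.0 - bound)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var)
        return max(0.0, auc - half), min(1.0, auc + half)
    if method == "bootstrap":
        if n_boot < 100:
            raise ValidationError("n_boot must be ≥ 100")
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            xb = rng.choice(x, size=x.size, replace=True)
            yb = rng.choice(y, size=y.size, replace=True)
            aucs[b] = auc_mann_whitney(xb, yb)[0]
        lo, hi = np.quantile(aucs, [(1 - level) / 2.0, 0.5 + level / 2.0])
        return float(lo), float(hi)
    raise ValidationError(f"unknown CI method {method!r}")


@dataclass
class PanelScore:
    """Evaluation of one two-marker panel against case/control labels."""

    panel: tuple[str, str]
    per_sample_value: pd.Series  # cumulative value; NaN if both members missing
    partial: pd.Series  # True where exactly one member was missing
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    u_statistic: float


def cumulative_panel_values(
    matrix: BetaMatrix, pair: tuple[str, str]
) -> tuple[pd.Series, pd.Series]:
    """Per-sample cumulative methylation value for a marker pair.

    Returns (values, partial_flags). The value is the sum of the two β
    values; if exactly one member is missing the observed value is used
    and the sample is flagged partial; if both are missing the value is
    NaN.
    """
    a, b = pair
    for m in (a, b):
        if m not in matrix.values.index:
            raise ValidationError(f"unknown marker id {m!r}")
    va = matrix.values.loc[a]
    vb = matrix.values.loc[b]
    values = va.fillna(0.0) + vb.fillna(0.0)
    both_missing = va.isna() & vb.isna()
    values[both_missing] = np.nan
    partial = va.isna() ^ vb.isna()
    return values, partial


def enumerate_and_rank_panels(
    matrix: BetaMatrix,
    groups: SampleGroups,
    marker_ids: list[str],
    ci_method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
) -> list[PanelScore]:
    """Evaluate every unordered two-marker panel, best AUC first.

    k markers yield k·(k−1)/2 panels (the study's 8 markers give 28).
    Samples whose panel members are both missing are excluded from the
    ROC; ordering is by descending AUC, then ascending p, then panel id
    so the ranking is deterministic.
    """
    if len(marker_ids) < 2:
        raise ValidationError("need at least 2 markers to form a panel")
    groups.validate_against(matrix)
    cases = [s for s in matrix.sample_ids if groups.group_of(s) == "case"]
    controls = [s for s in matrix.sample_ids if groups.group_of(s) == "control"]
    scores = []
    for pair in itertools.combinations(marker_ids, 2):
        values, partial = cumulative_panel_values(matrix, pair)
        case_v = values[cases].dropna().to_numpy()
        ctrl_v = values[controls].dropna().to_numpy()
        auc, u, p = auc_mann_whitney(case_v, ctrl_v)
        lo, hi = auc_confidence_interval(
            case_v, ctrl_v, method=ci_method, seed=seed, n_boot=n_boot
        )
        scores.append(
            PanelScore(
                panel=pair,
                per_sample_value=values,
                partial=partial,
                auc=auc,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                u_statistic=u,
            )
        )
    scores.sort(key=lambda s: (-s.auc, s.p_value, s.panel))
    return scores


def group_summaries(matrix: BetaMatrix, groups: SampleGroups) -> pd.DataFrame:
    """Per-marker medians and ranges within the case and control groups.

    Medians are over non-missing values (even counts: mean of the
    central pair, the usual convention).
    """
    groups.validate_against(matrix)
    cases = [s for s in matrix.sample_ids if groups.group_of(s) == "case"]
    controls = [s for s in matrix.sample_ids if groups.group_of(s) == "control"]
    cv = matrix.values[cases]
    kv = matrix.values[controls]
    return pd.DataFrame(
        {
            "case_median": cv.median(axis=1),
            "case_min": cv.min(axis=1),
            "case_max": cv.max(axis=1),
            "control_median": kv.median(axis=1),
            "control_min": kv.min(axis=1),
            "control_max": kv.max(axis=1),
        }
    )


def cluster_order(
    matrix: BetaMatrix,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> tuple[list[str], list[str]]:
    """Deterministic dendrogram leaf order for markers and samples.

    Missing values are mean-imputed within marker before computing
    Euclidean distances (an all-missing marker imputes to 0). Used to
    lay out heatmaps; cosmetic, not inferential.
    """
    if distance != "euclidean":
        raise ValidationError(f"unsupported distance {distance!r}")
    if linkage not in {"complete", "average"}:
        raise ValidationError(f"unsupported linkage {linkage!r}")
    df = matrix.values
    row_means = df.mean(axis=1).fillna(0.0)
    filled = df.T.fillna(row_means).T.to_numpy()

    def _leaf_order(data: np.ndarray, labels: list[str]) -> list[str]:
        if data.shape[0] < 2:
            return list(labels)
        link = hierarchy.linkage(pdist(data, metric="euclidean"), method=linkage)
        return [labels[i] for i in hierarchy.leaves_list(link)]

    marker_order = _leaf_order(filled, matrix.marker_ids)
    sample_order = _leaf_order(filled.T, matrix.sample_ids)
    return marker_order, sample_order
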