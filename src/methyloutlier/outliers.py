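"""Methylation outlier detection: hypermethylated-in-cases marker selection.

The detector encodes a deliberately simple heuristic that mirrors how
CpG markers useful for methylation-specific PCR behave on 450K array
data: a good marker is methylated (β above a case threshold) in *every*
case sample and essentially unmethylated (β below a control threshold)
in all — or all but a small tolerated fraction of — control samples.
Markers with too much missing data are removed first, and survivors are
ranked by the odds ratio of a 2×2 threshold-exceedance table with the
Haldane–Anscombe 0.5 correction (selected markers typically have zero
cells, so the correction keeps the ratio finite).

Selection pipeline: missingness filter → all-cases rule → controls
rule → odds-ratio sort. Every input marker receives a report carrying
its first failing rule, so nothing disappears silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleGroups, ValidationError
from .panels import auc_mann_whitney

__all__ = [
    "SelectionCriteria",
    "MarkerReport",
    "filter_missing",
    "case_positive_markers",
    "control_negative_filter",
    "marker_odds_ratio",
    "detect_outliers",
    "reports_to_frame",
]

REASON_NONE = "none"
REASON_MISSING = "missing"
REASON_CASE = "case_fail"
REASON_CONTROL = "control_fail"


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the outlier-selection heuristic.

    case_min_beta
        β that every case must strictly exceed (default 0.20).
    control_max_beta
        β that controls must not exceed (default 0.15); a value strictly
        above the threshold is a violation, so a control exactly at the
        threshold is tolerated (set ``control_strict_less`` for the
        stricter "below threshold in all controls" reading).
    control_violation_tolerance
        Fraction of controls allowed in violation (default 0.05;
        0.0 reproduces the all-controls study rule).
    max_missing_fraction
        Markers with a larger missing fraction are removed (default
        0.05; "more than 5%" is a strict comparison).
    """

    case_min_beta: float = 0.20
    control_max_beta: float = 0.15
    control_violation_tolerance: float = 0.05
    max_missing_fraction: float = 0.05
    control_strict_less: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.case_min_beta <= 1.0):
            raise ValidationError("case_min_beta must be in (0, 1]")
        if not (0.0 < self.control_max_beta <= 1.0):
            raise ValidationError("control_max_beta must be in (0, 1]")
        for name in ("control_violation_tolerance", "max_missing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")

    def strict(self) -> "SelectionCriteria":
        """Study-strict variant: no control violations tolerated."""
        return replace(self, control_violation_tolerance=0.0)


@dataclass
class MarkerReport:
    """Per-marker selection verdict with the summaries behind it."""

    marker_id: str
    selected: bool
    rejection_reason: str
    missing_fraction: float
    n_case_observed: int
    n_control_observed: int
    case_min: float
    case_median: float
    control_max: float
    control_median: float
    control_violation_fraction: float
    odds_ratio: float
    auc: float
    rank: Optional[int] = None


def filter_missing(
    matrix: BetaMatrix, max_missing_fraction: float = 0.05
) -> tuple[BetaMatrix, dict[str, float]]:
    """Remove markers whose missing fraction strictly exceeds the cap.

    Returns the retained matrix and {removed marker id: missing
    fraction}. A marker with exactly the cap's fraction missing is
    retained ("more than" is strict).
    """
    frac = matrix.missing_fraction()
    removed = frac[frac > max_missing_fraction]
    kept = matrix.values.loc[frac <= max_missing_fraction]
    return BetaMatrix(kept), dict(removed)


def case_positive_markers(
    matrix: BetaMatrix, groups: SampleGroups, case_min_beta: float = 0.20
) -> set[str]:
    """Markers with β strictly above the threshold in every observed case.

    Missing case values are skipped; a marker whose case values are all
    missing is excluded (there is no evidence it is methylated).
    """
    cases = [s for s in matrix.sample_ids if groups.group_of(s) == "case"]
    if not cases:
        raise ValidationError("no case samples")
    cv = matrix.values[cases]
    observed = cv.notna().sum(axis=1)
    all_above = (cv > case_min_beta) | cv.isna()
    passed = all_above.all(axis=1) & (observed > 0)
    return set(matrix.values.index[passed])


def control_negative_filter(
    control_values,
    control_max_beta: float = 0.15,
    tolerance: float = 0.05,
    strict_less: bool = False,
) -> tuple[bool, float]:
    """Keep decision and violation fraction for one marker's controls.

    A violation is a non-missing control value strictly above the
    threshold (``strict_less`` counts values equal to the threshold as
    violations too). Keep iff violation fraction ≤ tolerance.
    """
    v = np.asarray(control_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("no control samples with observed values")
    if strict_less:
        violations = int((v >= control_max_beta).sum())
    else:
        violations = int((v > control_max_beta).sum())
    frac = violations / v.size
    return frac <= tolerance, frac


def marker_odds_ratio(
    case_values,
    control_values,
    case_min_beta: float = 0.20,
    control_max_beta: float = 0.15,
) -> float:
    """Haldane-corrected odds ratio of the threshold-exceedance table.

    a = cases above the case threshold, b = cases at/below it,
    c = controls above the control threshold, d = controls at/below it;
    OR = ((a+½)(d+½)) / ((b+½)(c+½)). The ½ correction keeps the ratio
    finite for the zero cells a clean outlier marker produces.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must have observed values")
    a = int((x > case_min_beta).sum())
    b = x.size - a
    c = int((y > control_max_beta).sum())
    d = y.size - c
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def detect_outliers(
    matrix: BetaMatrix,
    groups: SampleGroups,
    criteria: SelectionCriteria | None = None,
) -> list[MarkerReport]:
    """Run the full selection pipeline; every marker gets a report.

    Selected markers come first, ranked 1..k by descending odds ratio
    (ties broken by higher per-marker AUC, then marker id); rejected
    markers follow, each carrying its first failing rule.
    """
    criteria = criteria or SelectionCriteria()
    groups.validate_against(matrix)
    cases = [s for s in matrix.sample_ids if groups.group_of(s) == "case"]
    controls = [s for s in matrix.sample_ids if groups.group_of(s) == "control"]

    kept, removed = filter_missing(matrix, criteria.max_missing_fraction)
    case_pass = (
        case_positive_markers(kept, groups, criteria.case_min_beta)
        if kept.n_markers
        else set()
    )

    reports: list[MarkerReport] = []
    for marker in matrix.marker_ids:
        row = matrix.values.loc[marker]
        cv = row[cases].to_numpy(dtype=float)
        kv = row[controls].to_numpy(dtype=float)
        cv_obs = cv[~np.isnan(cv)]
        kv_obs = kv[~np.isnan(kv)]
        missing_fraction = float(np.isnan(row.to_numpy(dtype=float)).mean())

        if kv_obs.size:
            _, violation = control_negative_filter(
                kv_obs,
                criteria.control_max_beta,
                criteria.control_violation_tolerance,
                criteria.control_strict_less,
            )
        else:
            violation = float("nan")

        if marker in removed:
            reason = REASON_MISSING
        elif marker not in case_pass:
            reason = REASON_CASE
        elif not violation <= criteria.control_violation_tolerance:
            reason = REASON_CONTROL
        else:
            reason = REASON_NONE

        if cv_obs.size and kv_obs.size:
            odds = marker_odds_ratio(
                cv_obs, kv_obs, criteria.case_min_beta, criteria.control_max_beta
            )
            auc, _, _ = auc_mann_whitney(cv_obs, kv_obs)
        else:
            odds, auc = float("nan"), float("nan")

        reports.append(
            MarkerReport(
                marker_id=marker,
                selected=reason == REASON_NONE,
                rejection_reason=reason,
                missing_fraction=missing_fraction,
                n_case_observed=int(cv_obs.size),
                n_control_observed=int(kv_obs.size),
                case_min=float(cv_obs.min()) if cv_obs.size else float("nan"),
                case_median=float(np.median(cv_obs)) if cv_obs.size else float("nan"),
                control_max=float(kv_obs.max()) if kv_obs.size else float("nan"),
                control_median=float(np.median(kv_obs)) if kv_obs.size else float("nan"),
                control_violation_fraction=violation,
                odds_ratio=odds,
                auc=auc,
            )
        )

    def sort_key(r: MarkerReport):
        odds = r.odds_ratio if np.isfinite(r.odds_ratio) else -np.inf
        auc = r.auc if np.isfinite(r.auc) else -np.inf
        return (-odds, -auc, r.marker_id)

    selected = sorted((r for r in reports if r.selected), key=sort_key)
    rejected = sorted((r for r in reports if not r.selected), key=sort_key)
    for rank, r in enumerate(selected, start=1):
        r.rank = rank
    return selected + rejected


def reports_to_frame(reports: list[MarkerReport]) -> pd.DataFrame:
    """Flatten marker reports into a DataFrame for TSV/JSON export."""
    return pd.DataFrame([vars(r) for r in reports])
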