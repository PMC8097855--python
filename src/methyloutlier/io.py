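"""Readers and writers for β-value matrices, sample sheets, and qPCR Ct tables.

The tabular formats here follow the conventions of HumanMethylation450
level-3 exports (markers in rows, one header row of sample identifiers,
β values in [0,1] with empty/"NA" cells for missing data) and of plain
long-form qPCR exports (one row per well, with a text token such as
"Undetermined" marking reactions that never crossed the cycle threshold).
All readers validate strictly and report the offending row/column on
failure; nothing is dropped silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "BetaMatrix",
    "SampleGroups",
    "CtTable",
    "DEFAULT_MISSING_TOKENS",
    "DEFAULT_NO_AMP_TOKENS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_ct_table",
    "write_ct_table",
    "write_report",
]

#: Missing-value tokens accepted in β matrices (matched case-insensitively).
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Tokens marking a qPCR reaction that never crossed the cycle threshold.
DEFAULT_NO_AMP_TOKENS = frozenset({"Undetermined", "NO_AMP"})

GROUP_CASE = "case"
GROUP_CONTROL = "control"
_ALLOWED_GROUPS = (GROUP_CASE, GROUP_CONTROL)


class ValidationError(ValueError):
    """Input violates a structural contract (range, uniqueness, consistency)."""


class ParseError(ValidationError):
    """A cell could not be interpreted; the message names the row/column."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Markers × samples matrix of methylation β values.

    β is the methylated-allele intensity fraction, so every non-missing
    entry lies in [0, 1]; missing entries are NaN. Marker and sample
    identifiers are opaque strings and must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        df = df.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate marker id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"β value {arr[i, j]!r} outside [0, 1] at marker "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.values = df

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the β value is missing."""
        return self.values.isna()

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing values."""
        return self.values.isna().mean(axis=1)

    def subset_markers(self, marker_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(marker_ids)
        unknown = set(ids) - set(self.values.index)
        if unknown:
            raise ValidationError(f"unknown marker id(s): {sorted(unknown)}")
        return BetaMatrix(self.values.loc[ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        unknown = set(ids) - set(self.values.columns)
        if unknown:
            raise ValidationError(f"unknown sample id(s): {sorted(unknown)}")
        return BetaMatrix(self.values.loc[:, ids])


def read_beta_matrix(
    path: str | Path,
    dialect: str = "markers_in_rows",
    missing_tokens: Iterable[str] | None = None,
) -> BetaMatrix:
    """Read a delimited β matrix (TSV or CSV by extension).

    ``dialect`` is ``markers_in_rows`` (TCGA/GEO level-3 convention,
    default) or ``markers_in_columns`` for transposed exports. Missing
    cells are empty or any of ``missing_tokens`` (case-insensitive).
    """
    path = Path(path)
    if dialect not in {"markers_in_rows", "markers_in_columns"}:
        raise ValidationError(f"unknown dialect {dialect!r}")
    tokens = {t.lower() for t in (missing_tokens or DEFAULT_MISSING_TOKENS)}
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False
    )
    if dialect == "markers_in_columns":
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    stripped = raw.apply(lambda col: col.str.strip())
    masked = stripped.mask(stripped.apply(lambda col: col.str.lower()).isin(tokens))
    values = masked.apply(pd.to_numeric, errors="coerce")
    unparsed = values.isna() & masked.notna()
    if unparsed.to_numpy().any():
        i, j = map(int, np.argwhere(unparsed.to_numpy())[0])
        raise ParseError(
            f"non-numeric β value {stripped.iat[i, j]!r} at marker "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r} in {path}"
        )
    return BetaMatrix(values)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, missing_token: str = "NA") -> None:
    """Write a β matrix markers-in-rows with 6 significant digits."""
    path = Path(path)
    matrix.values.to_csv(
        path, sep=_sep_for(path), na_rep=missing_token, float_format="%.6g",
        index_label="marker_id",
    )


# ---------------------------------------------------------------------------
# SampleGroups
# ---------------------------------------------------------------------------


@dataclass
class SampleGroups:
    """Assignment of each sample to a case/control group and a tumor type."""

    assignments: dict[str, tuple[str, str]]  # sample_id -> (group, tumor_type)

    def __post_init__(self) -> None:
        for sample, (group, _) in self.assignments.items():
            if group not in _ALLOWED_GROUPS:
                raise ValidationError(
                    f"sample {sample!r} has group {group!r}; allowed: {list(_ALLOWED_GROUPS)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def cases(self) -> list[str]:
        return [s for s, (g, _) in self.assignments.items() if g == GROUP_CASE]

    @property
    def controls(self) -> list[str]:
        return [s for s, (g, _) in self.assignments.items() if g == GROUP_CONTROL]

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    def tumor_type_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][1]

    def validate_against(self, matrix: BetaMatrix) -> None:
        """Every matrix sample assigned, with ≥1 case and ≥1 control."""
        unassigned = set(matrix.sample_ids) - set(self.assignments)
        if unassigned:
            raise ValidationError(f"samples without group assignment: {sorted(unassigned)}")
        cases = [s for s in matrix.sample_ids if self.group_of(s) == GROUP_CASE]
        controls = [s for s in matrix.sample_ids if self.group_of(s) == GROUP_CONTROL]
        if not cases:
            raise ValidationError("no case samples in matrix")
        if not controls:
            raise ValidationError("no control samples in matrix")


def read_sample_sheet(path: str | Path) -> SampleGroups:
    """Read a sample sheet CSV with columns sample_id, group, tumor_type.

    Group labels are normalized case-insensitively to {case, control}.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "tumor_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError(f"no samples in sample sheet {path}")
    assignments: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        sample = row["sample_id"].strip()
        group = row["group"].strip().lower()
        if group not in _ALLOWED_GROUPS:
            raise ValidationError(
                f"unknown group label {row['group']!r} for sample {sample!r}; "
                f"allowed: {list(_ALLOWED_GROUPS)}"
            )
        if sample in assignments:
            raise ValidationError(f"duplicate sample id {sample!r} in sample sheet")
        assignments[sample] = (group, row["tumor_type"].strip())
    return SampleGroups(assignments)


def write_sample_sheet(groups: SampleGroups, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s, g, t) for s, (g, t) in groups.assignments.items()],
        columns=["sample_id", "group", "tumor_type"],
    )
    df.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# CtTable
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Long-form qPCR records: one row per (sample, target, replicate).

    The ``ct`` column is NaN exactly where ``no_amp`` is True; a
    non-amplifying well is a distinct state, never a sentinel number.
    """

    records: pd.DataFrame  # columns: sample_id, target, replicate, ct, no_amp

    COLUMNS = ("sample_id", "target", "replicate", "ct", "no_amp")

    def __post_init__(self) -> None:
        df = self.records
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"Ct table missing column(s): {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        df["target"] = df["target"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = df["ct"].astype(float)
        df["no_amp"] = df["no_amp"].astype(bool)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be ≥ 1")
        dup = df.duplicated(subset=["sample_id", "target", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate record for ({row['sample_id']}, {row['target']}, "
                f"replicate {row['replicate']})"
            )
        numeric = ~df["no_amp"]
        if df.loc[numeric, "ct"].isna().any():
            raise ValidationError("amplified record lacks a numeric Ct")
        if (df.loc[numeric, "ct"] < 0).any():
            bad = df.loc[numeric & (df["ct"] < 0)].iloc[0]
            raise ValidationError(
                f"negative Ct {bad['ct']} for ({bad['sample_id']}, {bad['target']})"
            )
        df.loc[df["no_amp"], "ct"] = np.nan
        self.records = df

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.records["target"]))

    def for_sample(self, sample_id: str) -> "CtTable":
        sub = self.records[self.records["sample_id"] == sample_id]
        if sub.empty:
            raise ValidationError(f"no records for sample {sample_id!r}")
        return CtTable(sub.copy())

    @staticmethod
    def from_records(
        rows: Iterable[tuple[str, str, int, float | None]],
    ) -> "CtTable":
        """Build from (sample_id, target, replicate, ct-or-None) tuples."""
        recs = [
            {
                "sample_id": s,
                "target": t,
                "replicate": r,
                "ct": np.nan if ct is None else float(ct),
                "no_amp": ct is None,
            }
            for s, t, r, ct in rows
        ]
        return CtTable(pd.DataFrame(recs, columns=list(CtTable.COLUMNS)))


def read_ct_table(
    path: str | Path, no_amp_tokens: Iterable[str] | None = None
) -> CtTable:
    """Read a Ct table CSV with columns sample_id, target, replicate, ct."""
    path = Path(path)
    tokens = set(no_amp_tokens or DEFAULT_NO_AMP_TOKENS)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "target", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing column(s): {sorted(missing)}")
    rows = []
    for idx, row in df.iterrows():
        text = row["ct"].strip()
        if text in tokens:
            ct, no_amp = np.nan, True
        else:
            try:
                ct, no_amp = float(text), False
            except ValueError:
                raise ParseError(
                    f"unparseable Ct {text!r} at row {idx + 2} of {path} "
                    f"(not numeric, not in no-amplification tokens {sorted(tokens)})"
                ) from None
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise ParseError(
                f"non-integer replicate {row['replicate']!r} at row {idx + 2} of {path}"
            ) from None
        rows.append(
            {
                "sample_id": row["sample_id"].strip(),
                "target": row["target"].strip(),
                "replicate": replicate,
                "ct": ct,
                "no_amp": no_amp,
            }
        )
    return CtTable(pd.DataFrame(rows, columns=list(CtTable.COLUMNS)))


def write_ct_table(table: CtTable, path: str | Path, no_amp_token: str = "NO_AMP") -> None:
    df = table.records.copy()
    ct_text = df["ct"].map(lambda v: "" if np.isnan(v) else "%.6g" % v)
    ct_text[df["no_amp"]] = no_amp_token
    out = df[["sample_id", "target", "replicate"]].copy()
    out["ct"] = ct_text
    out.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    table: pd.DataFrame,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    metadata: Mapping | None = None,
) -> None:
    """Write a report as TSV plus an optional machine-readable JSON summary.

    The JSON carries the table records together with ``metadata`` (the
    criteria/seeds actually applied), so runs are auditable.
    """
    table.to_csv(Path(tsv_path), sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        payload = {
            "metadata": dict(metadata or {}),
            "records": json.loads(table.to_json(orient="records")),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
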