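"""Quantification mathematics for multiplexed methylation-specific qPCR.

Two-step multiplexed MSP assays quantify methylated DNA against a
beta-actin (ACTB) loading control:

* percent methylation by the ΔΔCt method,
  ``100 · 2^[(ΔCt_control) − (ΔCt_sample)]`` with
  ``ΔCt = Ct_marker − Ct_ACTB``, calibrated on fully methylated
  control DNA;
* absolute copies from the Ct difference to the fully methylated
  control at a known input (2 ng of human DNA ≈ 606 haploid genome
  equivalents at 3.3 pg per haploid genome);
* methylation allele frequency (MAF), 100 × marker copies / ACTB
  copies;
* the cumulative methylation index (CMI), the sum of percent
  methylation over the panel markers (uncapped, so a multi-marker CMI
  may exceed 100);
* standard-curve statistics (ΔCt vs log2 methylated fraction) and
  spike-in limit-of-detection summaries with exact Mann–Whitney
  p-values against the zero-copy level.

A well that never crosses the cycle threshold (NO_AMP) contributes
zero copies and zero percent methylation and raises a dropout flag; it
is never coerced to a sentinel Ct.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import CtTable, ValidationError
from .panels import mann_whitney_exact_p

__all__ = [
    "Calibration",
    "QuantResult",
    "MarkerQuant",
    "StandardCurve",
    "LodSummary",
    "percent_methylation_ddct",
    "copies_from_ct",
    "genome_equivalents",
    "maf",
    "quantify_sample",
    "quantify_all",
    "standard_curve_stats",
    "delta_ct_series",
    "lod_summary",
]

ACTB = "ACTB"


@dataclass
class Calibration:
    """Reference quantities tying Ct values to absolute copies.

    reference_ct_actb
        ACTB Ct of the fully methylated control DNA at the reference
        input (2 ng ≈ 606 copies). Instrument-specific; default 25.0
        cycles, a typical Ct for ~600 template copies.
    reference_copies
        Haploid genome equivalents in the reference input (606).
    control_delta_ct
        Per-marker (Ct_marker − Ct_ACTB) on the fully methylated
        control; the ΔΔCt anchor.
    haploid_genome_mass_pg
        Mass of one haploid genome (3.3 pg; 6.6 pg per diploid cell).
    cycle_limit
        PCR run length in cycles (40); numeric Cts at/above it are
        treated as non-amplification.
    """

    reference_ct_actb: float = 25.0
    reference_copies: float = 606.0
    control_delta_ct: dict[str, float] = field(default_factory=dict)
    haploid_genome_mass_pg: float = 3.3
    cycle_limit: float = 40.0

    def __post_init__(self) -> None:
        if self.reference_copies <= 0:
            raise ValidationError("reference_copies must be positive")
        if self.cycle_limit <= 0:
            raise ValidationError("cycle_limit must be positive")
        if self.haploid_genome_mass_pg <= 0:
            raise ValidationError("haploid_genome_mass_pg must be positive")

    def reference_ct(self, target: str) -> float:
        """Reference Ct for a target at ``reference_copies`` input.

        ACTB uses the measured reference Ct; markers are offset by their
        fully-methylated-control ΔCt.
        """
        if target == ACTB:
            return self.reference_ct_actb
        if target not in self.control_delta_ct:
            raise ValidationError(f"no control ΔCt calibrated for marker {target!r}")
        return self.reference_ct_actb + self.control_delta_ct[target]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Calibration":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            reference_ct_actb=float(data.get("reference_ct_actb", 25.0)),
            reference_copies=float(data.get("reference_copies", 606.0)),
            control_delta_ct={
                str(k): float(v) for k, v in (data.get("control_delta_ct") or {}).items()
            },
            haploid_genome_mass_pg=float(data.get("haploid_genome_mass_pg", 3.3)),
            cycle_limit=float(data.get("cycle_limit", 40.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "reference_ct_actb": self.reference_ct_actb,
                    "reference_copies": self.reference_copies,
                    "control_delta_ct": dict(self.control_delta_ct),
                    "haploid_genome_mass_pg": self.haploid_genome_mass_pg,
                    "cycle_limit": self.cycle_limit,
                },
                sort_keys=False,
            )
        )


def percent_methylation_ddct(
    sample_ct_marker: Optional[float],
    sample_ct_actb: Optional[float],
    cal: Calibration,
    marker_id: str,
) -> float:
    """Percent methylation by ΔΔCt; NO_AMP marker (None) → 0%.

    Returns ``100 · 2^[(ΔCt_control) − (ΔCt_sample)]`` with
    ``ΔCt = Ct_marker − Ct_ACTB``. Values above 100% (a sample
    amplifying earlier than the fully methylated control) are returned
    as computed, not clipped.
    """
    if sample_ct_actb is None:
        raise ValidationError("no loading control: ACTB did not amplify")
    if marker_id not in cal.control_delta_ct:
        raise ValidationError(f"no control ΔCt calibrated for marker {marker_id!r}")
    if sample_ct_marker is None:
        return 0.0
    ddct = cal.control_delta_ct[marker_id] - (sample_ct_marker - sample_ct_actb)
    return 100.0 * 2.0 ** ddct


def copies_from_ct(
    sample_ct: Optional[float], cal: Calibration, target: str = ACTB
) -> float:
    """Absolute copies from a Ct, via the fully methylated reference.

    ``copies = reference_copies · 2^(reference_ct − sample_ct)``, one
    doubling per cycle; a Ct equal to the reference Ct returns exactly
    ``reference_copies``. NO_AMP (None) → 0 copies. The value is
    unrounded; round for Table-style reporting.
    """
    if sample_ct is None:
        return 0.0
    return cal.reference_copies * 2.0 ** (cal.reference_ct(target) - sample_ct)


def genome_equivalents(mass_pg: float, genome_mass_pg: float = 3.3) -> float:
    """DNA mass → genome-equivalent copies (unrounded).

    2000 pg at 3.3 pg/haploid genome → 606 copies; 63 pg at 6.6 pg per
    diploid cell → ≈10 cell equivalents.
    """
    if genome_mass_pg <= 0:
        raise ValidationError("genome mass must be positive")
    if mass_pg < 0:
        raise ValidationError("mass must be non-negative")
    return mass_pg / genome_mass_pg


def maf(marker_copies: float, actb_copies: float) -> float:
    """Methylation allele frequency: 100 × marker copies / ACTB copies.

    Computed on unrounded copies; report to 2 decimals.
    """
    if actb_copies <= 0:
        raise ValidationError("no loading control signal (ACTB copies = 0)")
    if marker_copies < 0:
        raise ValidationError("marker copies must be non-negative")
    return 100.0 * marker_copies / actb_copies


@dataclass
class MarkerQuant:
    """One marker's quantities within a sample."""

    marker_id: str
    mean_ct: Optional[float]  # mean of numeric replicate Cts; None if all NO_AMP
    copies: float
    percent_methylation: float
    maf: float
    dropout: bool  # all replicates NO_AMP
    partial_dropout: bool  # some but not all replicates NO_AMP
    over_100: bool  # percent methylation exceeded 100%


@dataclass
class QuantResult:
    """Per-sample quantification across a marker panel."""

    sample_id: str
    actb_ct: float
    actb_copies: float
    markers: dict[str, MarkerQuant]
    cmi: float  # Σ percent methylation over the panel
    total_maf: float  # Σ per-marker MAF

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "actb_ct": self.actb_ct,
            "actb_copies": self.actb_copies,
            "cmi": self.cmi,
            "total_maf": self.total_maf,
        }
        for m, q in self.markers.items():
            row[f"{m}_copies"] = q.copies
            row[f"{m}_percent_methylation"] = q.percent_methylation
            row[f"{m}_maf"] = q.maf
            row[f"{m}_dropout"] = q.dropout
        return row


def _mean_numeric_ct(
    sub: pd.DataFrame, cal: Calibration
) -> tuple[Optional[float], bool, bool]:
    """(mean Ct, all-dropout, partial-dropout) over a replicate set.

    Numeric Cts at/above the cycle limit are coerced to NO_AMP with a
    warning; the mean is over the remaining numeric replicates.
    """
    no_amp = sub["no_amp"].to_numpy(copy=True)
    ct = sub["ct"].to_numpy(dtype=float)
    late = ~no_amp & (ct >= cal.cycle_limit)
    if late.any():
        warnings.warn(
            f"{int(late.sum())} Ct value(s) at/above the {cal.cycle_limit}-cycle "
            "limit treated as no amplification",
            stacklevel=3,
        )
        no_amp = no_amp | late
    numeric = ct[~no_amp]
    if numeric.size == 0:
        return None, True, False
    return float(numeric.mean()), False, bool(no_amp.any())


def quantify_sample(
    ct: CtTable,
    cal: Calibration,
    markers: Sequence[str],
    sample_id: str | None = None,
) -> QuantResult:
    """Quantify one sample: copies, percent methylation, MAF, CMI.

    Replicate Cts are averaged (numeric replicates only) before the
    ΔΔCt and copy-number formulas. A marker whose replicates are all
    NO_AMP contributes 0 with its dropout flag set; ACTB must amplify
    in at least one replicate.
    """
    if sample_id is None:
        ids = ct.sample_ids
        if len(ids) != 1:
            raise ValidationError(
                f"Ct table holds {len(ids)} samples; pass sample_id explicitly"
            )
        sample_id = ids[0]
    recs = ct.records[ct.records["sample_id"] == sample_id]
    if recs.empty:
        raise ValidationError(f"no records for sample {sample_id!r}")

    actb_recs = recs[recs["target"] == ACTB]
    if actb_recs.empty:
        raise ValidationError(f"no ACTB record for sample {sample_id!r}")
    actb_ct, actb_dropout, _ = _mean_numeric_ct(actb_recs, cal)
    if actb_dropout:
        raise ValidationError(f"no loading control: ACTB did not amplify in {sample_id!r}")
    actb_copies = copies_from_ct(actb_ct, cal, ACTB)

    quants: dict[str, MarkerQuant] = {}
    for marker in markers:
        m_recs = recs[recs["target"] == marker]
        if m_recs.empty:
            raise ValidationError(f"no records for marker {marker!r} in {sample_id!r}")
        mean_ct, dropout, partial = _mean_numeric_ct(m_recs, cal)
        pm = percent_methylation_ddct(mean_ct, actb_ct, cal, marker)
        copies = copies_from_ct(mean_ct, cal, marker)
        quants[marker] = MarkerQuant(
            marker_id=marker,
            mean_ct=mean_ct,
            copies=copies,
            percent_methylation=pm,
            maf=maf(copies, actb_copies),
            dropout=dropout,
            partial_dropout=partial,
            over_100=pm > 100.0,
        )

    return QuantResult(
        sample_id=sample_id,
        actb_ct=actb_ct,
        actb_copies=actb_copies,
        markers=quants,
        cmi=sum(q.percent_methylation for q in quants.values()),
        total_maf=sum(q.maf for q in quants.values()),
    )


def quantify_all(
    ct: CtTable, cal: Calibration, markers: Sequence[str]
) -> list[QuantResult]:
    """quantify_sample over every sample in the table, input order."""
    return [quantify_sample(ct, cal, markers, sample_id=s) for s in ct.sample_ids]


@dataclass
class StandardCurve:
    """Least-squares fit of mean ΔCt against log2 methylated fraction."""

    slope: float
    intercept: float
    r_squared: float
    cv_per_level: dict[float, float]  # nominal % → sd/mean of replicate ΔCts


def standard_curve_stats(
    series: Sequence[tuple[float, Sequence[float]]],
) -> StandardCurve:
    """Linearity and inter-assay variability of a dilution standard curve.

    ``series`` is [(nominal percent methylation, replicate ΔCts), ...].
    The fit regresses the per-level mean ΔCt on log2(nominal fraction):
    with perfect doubling chemistry the slope is −1 and R² = 1. The CV
    per level is sd/mean of the replicate ΔCts.
    """
    levels = [lvl for lvl, _ in series]
    if len(set(levels)) < 3:
        raise ValidationError("need ≥ 3 distinct dilution levels for a standard curve")
    xs, ys = [], []
    cv: dict[float, float] = {}
    for level, dcts in series:
        if level <= 0 or level > 100:
            raise ValidationError(f"nominal percent {level} outside (0, 100]")
        d = np.asarray(list(dcts), dtype=float)
        if d.size == 0:
            raise ValidationError(f"level {level} has no replicate ΔCts")
        xs.append(math.log2(level / 100.0))
        ys.append(float(d.mean()))
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        # identical replicates have CV 0 even when the mean ΔCt is 0
        cv[level] = 0.0 if sd == 0.0 else sd / abs(float(d.mean()))
    fit = stats.linregress(xs, ys)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        cv_per_level=cv,
    )


def delta_ct_series(
    ct: CtTable,
    marker: str,
    levels: Mapping[str, float] | None = None,
) -> list[tuple[float, list[float]]]:
    """Assemble standard-curve input from a dilution-series Ct table.

    ΔCt = Ct_marker − Ct_ACTB per replicate (non-amplifying replicates
    skipped). ``levels`` maps sample id → nominal percent; by default
    the level is parsed from a trailing ``_<number>`` in the sample id
    (the dilution simulator's convention).
    """
    out: list[tuple[float, list[float]]] = []
    for sample in ct.sample_ids:
        level = levels[sample] if levels is not None else _parse_level(sample)
        recs = ct.records[ct.records["sample_id"] == sample]
        dcts = []
        for rep in sorted(recs["replicate"].unique()):
            r = recs[recs["replicate"] == rep]
            m = r[r["target"] == marker]
            a = r[r["target"] == ACTB]
            if m.empty or a.empty or m["no_amp"].iloc[0] or a["no_amp"].iloc[0]:
                continue
            dcts.append(float(m["ct"].iloc[0] - a["ct"].iloc[0]))
        out.append((level, dcts))
    return out


def _parse_level(sample_id: str) -> float:
    m = re.search(r"_([0-9.]+)$", sample_id)
    if not m:
        raise ValidationError(
            f"cannot parse dilution/spike level from sample id {sample_id!r}; "
            "pass an explicit levels mapping"
        )
    return float(m.group(1))


@dataclass
class LodSummary:
    """Limit-of-detection summary of a spike-in dilution experiment."""

    dropout_counts: pd.DataFrame  # index level, columns markers, values NO_AMP counts
    total_maf: pd.DataFrame  # columns level, replicate, total_maf
    p_values: dict[float, float]  # level → exact two-sided p vs the 0-copy level


def lod_summary(
    spikein: CtTable,
    cal: Calibration,
    markers: Sequence[str],
    levels: Mapping[str, float] | None = None,
) -> LodSummary:
    """Summarize a spike-in experiment against its zero-copy blanks.

    Per level and marker: the count of non-amplifying replicates. Per
    replicate: the total MAF (sum over markers of per-replicate marker
    copies / ACTB copies × 100; a non-amplifying marker contributes 0).
    Each positive level's total MAF distribution is compared with the
    0-copy level by the exact two-sided Mann–Whitney test (full
    enumeration, valid with ties).
    """
    level_of = {
        s: (levels[s] if levels is not None else _parse_level(s))
        for s in spikein.sample_ids
    }
    if 0.0 not in level_of.values():
        raise ValidationError("spike-in experiment must include the 0-copy level")

    rep_counts = set()
    rows = []
    dropout: dict[float, dict[str, int]] = {}
    for sample, level in level_of.items():
        recs = spikein.records[spikein.records["sample_id"] == sample]
        reps = sorted(recs["replicate"].unique())
        rep_counts.add(len(reps))
        dropout.setdefault(level, {m: 0 for m in markers})
        for rep in reps:
            r = recs[recs["replicate"] == rep]
            a = r[r["target"] == ACTB]
            if a.empty or a["no_amp"].iloc[0]:
                raise ValidationError(
                    f"ACTB missing or non-amplifying in {sample!r} replicate {rep}"
                )
            actb_copies = copies_from_ct(float(a["ct"].iloc[0]), cal, ACTB)
            total = 0.0
            for marker in markers:
                m = r[r["target"] == marker]
                if m.empty or m["no_amp"].iloc[0]:
                    dropout[level][marker] += int(not m.empty and m["no_amp"].iloc[0])
                    continue
                copies = copies_from_ct(float(m["ct"].iloc[0]), cal, marker)
                total += maf(copies, actb_copies)
            rows.append({"level": level, "replicate": int(rep), "total_maf": total})
    if len(rep_counts) > 1:
        raise ValidationError(f"levels have unequal replicate counts: {sorted(rep_counts)}")

    total_maf = pd.DataFrame(rows).sort_values(["level", "replicate"]).reset_index(drop=True)
    zero = total_maf.loc[total_maf["level"] == 0.0, "total_maf"].to_numpy()
    p_values = {}
    for level in sorted({l for l in level_of.values() if l != 0.0}):
        vals = total_maf.loc[total_maf["level"] == level, "total_maf"].to_numpy()
        p_values[level] = mann_whitney_exact_p(vals, zero)

    dropout_counts = (
        pd.DataFrame.from_dict(dropout, orient="index").sort_index()[list(markers)]
    )
    dropout_counts.index.name = "level"
    return LodSummary(dropout_counts=dropout_counts, total_maf=total_maf, p_values=p_values)
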