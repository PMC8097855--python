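"""Synthetic data generators for methylation arrays and MSP qPCR runs.

Every downstream stage of the package can be exercised without any
external download:

* β matrices with *planted* outlier markers — hypermethylated in every
  case sample, essentially unmethylated in controls — buried among
  noise markers whose β distribution is shared by all samples, with
  optional missingness. The default configuration mirrors a discovery
  contrast of 48 cases against 656 controls with 8 planted markers
  among 992 noise markers.
* qPCR runs under an exponential-amplification model: Ct decreases by
  one cycle per template doubling (at 100% efficiency), with Gaussian
  Ct noise, and Poisson sampling of template molecules so that
  low-copy inputs stochastically drop out (zero sampled templates →
  no amplification), the mechanism behind replicate failures in
  low-copy spike-ins.
* ready-made spike-in (copies into a plasma background) and dilution
  (percent methylation) experiment layouts.

All generators are pure functions of their configuration, including
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, CtTable, SampleGroups, ValidationError
from .qpcr import ACTB, Calibration

__all__ = [
    "BetaSimConfig",
    "QpcrSimConfig",
    "simulate_beta_matrix",
    "simulate_qpcr_run",
    "simulate_spikein_experiment",
    "simulate_dilution_series",
]


def _check_shape(name: str, params: tuple) -> None:
    a, b, lo, hi = params
    if a <= 0 or b <= 0:
        raise ValidationError(f"{name}: Beta shape parameters must be positive")
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError(f"{name}: rescale range must satisfy 0 ≤ lo < hi ≤ 1")


@dataclass(frozen=True)
class BetaSimConfig:
    """β-matrix generator configuration.

    Each distribution is (a, b, lo, hi): a Beta(a, b) draw rescaled to
    [lo, hi]. The defaults make a *clean* discovery fixture: planted
    markers have case β in [0.25, 1] (all above a 0.20 case threshold)
    and control β in [0, 0.10] (all below a 0.15 control threshold),
    while noise markers share one background distribution across all
    samples, so the planted set is exactly recoverable.
    """

    n_case: int = 48
    n_control: int = 656
    n_planted: int = 8
    n_noise: int = 992
    case_beta_params: tuple[float, float, float, float] = (20.0, 5.0, 0.25, 1.0)
    control_beta_params: tuple[float, float, float, float] = (2.0, 40.0, 0.0, 0.10)
    noise_beta_params: tuple[float, float, float, float] = (0.8, 3.0, 0.0, 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("need at least one case and one control")
        if self.n_planted < 0 or self.n_noise < 0:
            raise ValidationError("marker counts must be non-negative")
        for name in ("case_beta_params", "control_beta_params", "noise_beta_params"):
            _check_shape(name, getattr(self, name))
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must be in [0, 1]")

    def case_mass_above(self, threshold: float) -> float:
        """P(planted case β > threshold); ≥ 0.999 for a clean fixture."""
        a, b, lo, hi = self.case_beta_params
        if threshold <= lo:
            return 1.0
        if threshold >= hi:
            return 0.0
        return float(stats.beta.sf((threshold - lo) / (hi - lo), a, b))


def _draw(rng: np.random.Generator, params: tuple, size) -> np.ndarray:
    a, b, lo, hi = params
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def simulate_beta_matrix(
    config: BetaSimConfig,
) -> tuple[BetaMatrix, SampleGroups, list[str]]:
    """Generate (matrix, groups, planted marker ids) from the config."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control
    case_ids = [f"case_{i + 1:03d}" for i in range(config.n_case)]
    control_ids = [f"ctrl_{i + 1:03d}" for i in range(config.n_control)]
    planted_ids = [f"cgP{i + 1:07d}" for i in range(config.n_planted)]
    noise_ids = [f"cgN{i + 1:07d}" for i in range(config.n_noise)]

    planted = np.empty((config.n_planted, n_samples))
    planted[:, : config.n_case] = _draw(
        rng, config.case_beta_params, (config.n_planted, config.n_case)
    )
    planted[:, config.n_case :] = _draw(
        rng, config.control_beta_params, (config.n_planted, config.n_control)
    )
    noise = _draw(rng, config.noise_beta_params, (config.n_noise, n_samples))

    values = np.vstack([planted, noise]) if config.n_noise else planted
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = BetaMatrix(
        pd.DataFrame(values, index=planted_ids + noise_ids, columns=case_ids + control_ids)
    )
    groups = SampleGroups(
        {
            **{s: ("case", "lymphoma") for s in case_ids},
            **{s: ("control", "glioma") for s in control_ids},
        }
    )
    return matrix, groups, planted_ids


@dataclass(frozen=True)
class QpcrSimConfig:
    """qPCR run generator configuration.

    true_copies
        sample id → {target: expected template copies}.
    efficiency
        Per-cycle amplification efficiency in (0, 1]; 1.0 gives exactly
        one Ct per template doubling, lower values stretch the
        Ct-per-log2 slope to 1/log2(1 + efficiency).
    ct_noise_sd
        Gaussian noise added to each well's Ct, in cycles.
    poisson_sampling
        Draw the template count per well from Poisson(true copies); a
        zero draw is a non-amplifying well. Off → deterministic counts.
    """

    true_copies: Mapping[str, Mapping[str, float]]
    efficiency: float = 1.0
    ct_noise_sd: float = 0.2
    calibration: Calibration = field(default_factory=Calibration)
    poisson_sampling: bool = True
    replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValidationError("efficiency must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValidationError("ct_noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValidationError("replicates must be ≥ 1")
        for sample, targets in self.true_copies.items():
            for target, copies in targets.items():
                if copies < 0:
                    raise ValidationError(
                        f"negative copies for ({sample}, {target}): {copies}"
                    )


def simulate_qpcr_run(config: QpcrSimConfig) -> CtTable:
    """Simulate Cts for every (sample, target, replicate) well.

    Ct = reference_ct(target) − log2(T / reference_copies) / log2(1 +
    efficiency) + N(0, ct_noise_sd), where T is the (possibly Poisson-
    sampled) template count; T = 0 or Ct ≥ cycle limit → NO_AMP.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.calibration
    slope = 1.0 / np.log2(1.0 + config.efficiency)
    rows: list[tuple[str, str, int, float | None]] = []
    for sample, targets in config.true_copies.items():
        for target, copies in targets.items():
            ref_ct = cal.reference_ct(target)
            for rep in range(1, config.replicates + 1):
                t = rng.poisson(copies) if config.poisson_sampling else copies
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                if t <= 0:
                    rows.append((sample, target, rep, None))
                    continue
                ct = ref_ct - slope * np.log2(t / cal.reference_copies) + noise
                rows.append((sample, target, rep, None if ct >= cal.cycle_limit else ct))
    return CtTable.from_records(rows)


def simulate_spikein_experiment(
    levels: Sequence[float] = (40, 20, 10, 5, 0),
    replicates: int = 6,
    calibration: Calibration | None = None,
    markers: Sequence[str] = ("cg054", "SCG3"),
    marker_background: float = 0.0,
    actb_background: float = 1500.0,
    ct_noise_sd: float = 0.2,
    efficiency: float = 1.0,
    seed: int = 0,
) -> CtTable:
    """Spike-in limit-of-detection layout: copies into a plasma background.

    Each level spikes that many methylated copies into the background;
    markers receive level + ``marker_background`` copies and ACTB a
    large constant background (default 1500 copies) so the loading
    control always amplifies. Sample ids are ``spike_<level>``, read
    back by ``lod_summary``.
    """
    if replicates < 2:
        raise ValidationError("spike-in experiment needs ≥ 2 replicates per level")
    if 0 not in {float(l) for l in levels}:
        raise ValidationError("spike-in levels must include the 0-copy blank")
    cal = calibration or _default_marker_calibration(markers)
    true_copies = {
        f"spike_{level:g}": {
            ACTB: actb_background,
            **{m: float(level) + marker_background for m in markers},
        }
        for level in levels
    }
    config = QpcrSimConfig(
        true_copies=true_copies,
        efficiency=efficiency,
        ct_noise_sd=ct_noise_sd,
        calibration=cal,
        poisson_sampling=True,
        replicates=replicates,
        seed=seed,
    )
    return simulate_qpcr_run(config)


def simulate_dilution_series(
    levels: Sequence[float] = (100, 50, 25, 12.5, 6.25, 3),
    replicates: int = 6,
    calibration: Calibration | None = None,
    marker: str = "cg054",
    total_copies: float = 606.0,
    ct_noise_sd: float = 0.2,
    efficiency: float = 1.0,
    poisson_sampling: bool = False,
    seed: int = 0,
) -> CtTable:
    """Standard-curve layout: percent methylation at fixed total DNA.

    Each level mixes fully methylated with fully unmethylated DNA to
    the nominal percent; the marker sees ``total_copies × level/100``
    methylated templates while ACTB sees all ``total_copies``. Sample
    ids are ``dil_<level>``; feed the result to ``delta_ct_series`` +
    ``standard_curve_stats``.
    """
    for level in levels:
        if level <= 0 or level > 100:
            raise ValidationError(f"dilution level {level} outside (0, 100]")
    cal = calibration or _default_marker_calibration([marker])
    true_copies = {
        f"dil_{level:g}": {ACTB: total_copies, marker: total_copies * level / 100.0}
        for level in levels
    }
    config = QpcrSimConfig(
        true_copies=true_copies,
        efficiency=efficiency,
        ct_noise_sd=ct_noise_sd,
        calibration=cal,
        poisson_sampling=poisson_sampling,
        replicates=replicates,
        seed=seed,
    )
    return simulate_qpcr_run(config)


def _default_marker_calibration(markers: Sequence[str]) -> Calibration:
    """Calibration with a zero control ΔCt for each requested marker."""
    return Calibration(control_delta_ct={m: 0.0 for m in markers})
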