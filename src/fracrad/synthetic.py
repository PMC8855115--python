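"""Seeded generator of microscopy-like confluence datasets with known truth.

The generator emulates a two-arm fractionation experiment: two glioma cell
lines, six daily-fraction schedules (2x8, 3x5.3, 4x4 Gy totaling 16 Gy;
2x10, 3x6.7, 4x5 Gy totaling 20 Gy), seeding densities spanning a ~10x
range, samples every 4-6 h out to ~330 h, and multiplicative measurement
noise with a default 21% coefficient of variation (the magnitude of typical
segmentation error in live-cell microscopy pipelines). Ground-truth
parameters are configurable and recorded so recovery can be scored exactly.

Ground-truth values are synthetic: chosen to satisfy the qualitative
constraints of the modeled biology (most DSBs repaired within 24 h, late
mitotic catastrophe dominating early apoptosis, the "C6" preset more
radiosensitive than "9L", and the rise / post-treatment decline / late
regrowth curve morphology), not measured from any particular experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import dynamics
from .data import ConfluenceCurve
from .exceptions import ConfigurationError
from .family import ModelSpec, model_family
from .params import GrowthParams, RadiationParams
from .repair import RepairKinetics
from .schedules import SCHEDULE_PRESETS, get_schedule

__all__ = [
    "CellLineTruth",
    "TruthConfig",
    "SyntheticDataset",
    "DEFAULT_REPAIR_KINETICS",
    "default_truth",
    "generate_replicate",
    "generate_dataset",
    "train_validation_split",
]

#: Synthetic dose -> repair-rate table (1/hr). Rates decrease mildly with
#: dose and all satisfy >80% repair within 24 h (exp(-24 k) < 0.2).
DEFAULT_REPAIR_KINETICS = RepairKinetics(
    doses=(2.0, 4.0, 8.0, 16.0), rates=(0.115, 0.10, 0.085, 0.07)
)

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class CellLineTruth:
    """Ground truth for one cell line: growth, radiation response, repair."""

    growth: GrowthParams
    radiation: RadiationParams
    kinetics: RepairKinetics = DEFAULT_REPAIR_KINETICS


@dataclass(frozen=True)
class TruthConfig:
    """Study design + ground truth driving the generator.

    ``n0_levels`` are the discrete seeding confluences (a ~10x range, like
    seeding 1k-10k cells per well); each replicate draws one level uniformly.
    ``heterogeneity_cv`` scatters the per-replicate death coefficients; the
    optional media-change artifact applies a persistent fractional cell loss
    every ``media_period`` hours. Both are off by default.
    """

    cell_lines: dict  # name -> CellLineTruth
    generating_model: int = 3
    schedules: tuple = ("16x2", "16x3", "16x4", "20x2", "20x3", "20x4")
    replicates_per_condition: int = 8
    n0_levels: tuple = (0.03, 0.0646, 0.139, 0.3)
    noise_cv: float = 0.21
    heterogeneity_cv: float = 0.0
    sampling_interval: tuple = (4.0, 6.0)
    horizon: float = 330.0
    media_period: Optional[float] = None
    media_loss_range: tuple = (0.05, 0.15)
    dt: float = dynamics.DEFAULT_DT
    gate_sharpness: float = dynamics.DEFAULT_GATE_SHARPNESS

    def __post_init__(self):
        if self.noise_cv < 0 or self.heterogeneity_cv < 0:
            raise ConfigurationError("coefficients of variation must be >= 0")
        if self.replicates_per_condition < 1:
            raise ConfigurationError("need at least one replicate per condition")
        for name in self.schedules:
            sched = get_schedule(name)
            if self.horizon <= sched.fraction_times[-1]:
                raise ConfigurationError("horizon must exceed the last fraction time")
        for name, truth in self.cell_lines.items():
            theta = truth.growth.theta
            for n0 in self.n0_levels:
                if not 0 < n0 < theta:
                    raise ConfigurationError(
                        f"N0 level {n0} outside (0, theta={theta}) for {name}"
                    )

    @property
    def total_doses(self) -> tuple:
        return tuple(sorted({get_schedule(s).total_dose for s in self.schedules}))

    def generating_spec(self) -> ModelSpec:
        return model_family(self.total_doses)[self.generating_model - 1]


def default_truth(**overrides) -> TruthConfig:
    """The default two-cell-line ground truth ("9L" hardier, "C6" more sensitive)."""
    nine_l = CellLineTruth(
        growth=GrowthParams(k_p=0.03, theta=0.9, A=1.0),
        radiation=RadiationParams(
            alpha_acute_N=3.0,
            k_acute_D=3e-3,
            k_acute_N=0.25,
            alpha_accum_N=2.0,
            k_accum_D=2e-4,
            k_accum_N=0.02,
            r=0.02,
            k_ps={16.0: 0.04, 20.0: 0.065},
        ),
    )
    c6 = CellLineTruth(
        growth=GrowthParams(k_p=0.04, theta=0.9, A=0.8),
        radiation=RadiationParams(
            alpha_acute_N=3.5,
            k_acute_D=5e-3,
            k_acute_N=0.5,
            alpha_accum_N=2.5,
            k_accum_D=3.5e-4,
            k_accum_N=0.035,
            r=0.022,
            k_ps={16.0: 0.07, 20.0: 0.10},
        ),
    )
    config = TruthConfig(cell_lines={"9L": nine_l, "C6": c6})
    return replace(config, **overrides) if overrides else config


@dataclass
class SyntheticDataset:
    """Generated curves plus everything needed to score recovery."""

    curves: list
    truth: TruthConfig
    realized: dict  # replicate_id -> {"params": ..., "true_values": ..., "n0_level": ...}
    seed: int


def _sample_times(rng, interval, horizon) -> np.ndarray:
    lo, hi = interval
    times = [0.0]
    while times[-1] < horizon:
        times.append(times[-1] + rng.uniform(lo, hi))
    if times[-1] > horizon:
        times.pop()
    return np.asarray(times)


def _heterogeneous(radiation: RadiationParams, cv: float, rng) -> RadiationParams:
    if cv == 0:
        return radiation
    factors = {}
    for group in (("k_acute_N", "k_acute_D"), ("k_accum_N", "k_accum_D")):
        f = max(1.0 + cv * rng.standard_normal(), 0.05)
        for name in group:
            factors[name] = f
    kwargs = {}
    for name, f in factors.items():
        value = getattr(radiation, name)
        if value is not None:
            kwargs[name] = value * f
    return replace(radiation, **kwargs)


def generate_replicate(
    truth: TruthConfig,
    cell_line: str,
    schedule,
    N0: float,
    seed,
    replicate_id: str | None = None,
):
    """One noisy replicate curve; returns ``(curve, record)``.

    ``record`` holds the realized per-replicate radiation parameters and the
    noise-free model output, for recovery scoring.
    """
    if cell_line not in truth.cell_lines:
        raise ConfigurationError(f"unknown cell line {cell_line!r}")
    if isinstance(schedule, str):
        schedule = get_schedule(schedule)
    line = truth.cell_lines[cell_line]
    if not 0 < N0 < line.growth.theta:
        raise ValueError(f"N0={N0} outside (0, theta={line.growth.theta})")
    rng = np.random.default_rng(seed)
    times = _sample_times(rng, truth.sampling_interval, truth.horizon)
    radiation = _heterogeneous(line.radiation, truth.heterogeneity_cv, rng)
    spec = truth.generating_spec()
    traj = dynamics.simulate(
        spec,
        line.growth,
        radiation,
        schedule,
        N0,
        horizon=float(times[-1]),
        dt=truth.dt,
        output_times=times,
        kinetics=line.kinetics,
        gate_sharpness=truth.gate_sharpness,
    )
    true_values = traj.N_total
    measured = true_values * (1.0 + truth.noise_cv * rng.standard_normal(times.size))
    if truth.media_period:
        factor = 1.0
        media_times = np.arange(truth.media_period, times[-1], truth.media_period)
        loss_at = {mt: rng.uniform(*truth.media_loss_range) for mt in media_times}
        factors = np.ones_like(times)
        for mt, loss in loss_at.items():
            factors[times >= mt] *= 1.0 - loss
        measured = measured * factors
    measured = np.maximum(measured, 0.0)
    measured[0] = max(measured[0], 1e-6)  # keep the initial condition usable
    rid = replicate_id or f"{cell_line}-{schedule.name}-{N0:g}"
    curve = ConfluenceCurve(
        replicate_id=rid,
        cell_line=cell_line,
        schedule_id=schedule.name,
        times=times,
        confluence=measured,
    )
    record = {
        "params": radiation,
        "true_values": true_values,
        "n0_level": float(N0),
    }
    return curve, record


def generate_dataset(truth: TruthConfig, seed: int) -> SyntheticDataset:
    """Full factorial over cell lines x schedules x replicates, seeded."""
    master = np.random.default_rng(seed)
    curves = []
    realized = {}
    for cell_line in sorted(truth.cell_lines):
        for sched_name in truth.schedules:
            for i in range(truth.replicates_per_condition):
                sub_seed = int(master.integers(0, _SEED_CAP))
                # cycle the seeding-density levels so every condition spans
                # the full ~10x range (like plating several density groups)
                level = truth.n0_levels[i % len(truth.n0_levels)]
                rid = f"{cell_line}-{sched_name}-r{i:02d}"
                curve, record = generate_replicate(
                    truth, cell_line, sched_name, level, sub_seed, replicate_id=rid
                )
                curves.append(curve)
                realized[rid] = record
    return SyntheticDataset(curves=curves, truth=truth, realized=realized, seed=seed)


def train_validation_split(dataset, fraction: float = 0.75, seed: int = 0):
    """Stratified random split by (cell line, schedule, seeding-density stratum).

    ``round(fraction * n)`` replicates of each stratum go to training; a
    single-replicate stratum is assigned to training with a warning. The two
    halves are disjoint and exhaustive.
    """
    import logging

    logger = logging.getLogger(__name__)
    curves = dataset.curves if isinstance(dataset, SyntheticDataset) else list(dataset)
    # density stratum: below/above the condition's median seeding confluence
    medians: dict = {}
    for c in curves:
        medians.setdefault((c.cell_line, c.schedule_id), []).append(c.N0)
    medians = {k: float(np.median(v)) for k, v in medians.items()}
    stratum = lambda c: (
        c.cell_line,
        c.schedule_id,
        c.N0 > medians[(c.cell_line, c.schedule_id)],
    )
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    groups: dict = {}
    for c in sorted(curves, key=lambda c: c.replicate_id):
        groups.setdefault(stratum(c), []).append(c)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for key in sorted(groups, key=str):
        members = groups[key]
        if len(members) == 1:
            logger.warning("stratum %s has a single replicate; assigned to training", key)
            train.extend(members)
            continue
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members))
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n_train])
        val.extend(members[i] for i in order[n_train:])
    key = lambda c: c.replicate_id
    return sorted(train, key=key), sorted(val, key=key)
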