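"""Growth and radiation-response dynamics, and the forward-Euler simulator.

The untreated population follows logistic growth with an Allee factor,

    dN/dt = k_p * N * (N/theta + A) * (1 - N/theta).

Radiation adds three mechanisms. Acute (early) death, driven by unrepaired
double-strand breaks, removes proliferative cells at rate

    k_ed(t) = sum_i k_acute(D, N0) * f_DSB(t_i, D) * tanh(s * f_DSB(t_i, D)),

summed over delivered fractions (t_i = time since fraction i); the tanh
factor is a smooth gate that keeps the term continuous. Accumulation (late)
death, representing mitotic catastrophe from accumulated misrepair, reduces
the effective proliferation rate by

    k_ld(t) = sum_i k_accum(D, N0) * t_i * exp(-r * t_i),

which starts at zero, peaks at t_i = 1/r and decays as the radiation
efficacy wanes. Senescent conversion moves cells irreversibly from the
proliferative compartment N_p to a non-dividing compartment N_s at rate
``k_ps(D_total) * N0``; both compartments share the carrying capacity:

    dN_p/dt = (k_p - k_ld) * ((N_p+N_s)/theta + A) * N_p * (1 - (N_p+N_s)/theta)
              - k_ed * N_p - k_ps * N0 * N_p
    dN_s/dt = k_ps * N0 * N_p.

Integration is fully explicit forward Euler with a default step of 0.01 hr;
an adaptive Runge-Kutta reference integrator (`simulate_reference`) is
provided as an independent accuracy check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, NumericalError
from .family import ModelSpec
from .params import GrowthParams, RadiationParams
from .repair import RepairKinetics
from .schedules import DoseSchedule

__all__ = [
    "Trajectory",
    "untreated_rhs",
    "acute_coefficient",
    "accum_coefficient",
    "early_death_rate",
    "late_death_rate",
    "treated_rhs",
    "simulate",
    "simulate_reference",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.01  # hr
DEFAULT_GATE_SHARPNESS = 1.0


@dataclass(frozen=True)
class Trajectory:
    """Simulated confluence at requested output times."""

    times: np.ndarray
    N_p: np.ndarray
    N_s: np.ndarray

    @property
    def N_total(self) -> np.ndarray:
        return self.N_p + self.N_s


def untreated_rhs(N: float, growth: GrowthParams) -> float:
    """dN/dt for untreated logistic + Allee growth."""
    if N < 0:
        raise ValueError("N must be >= 0")
    return growth.k_p * N * (N / growth.theta + growth.A) * (1.0 - N / growth.theta)


def acute_coefficient(
    spec: ModelSpec, params: RadiationParams, dose_per_fraction: float, N0: float
) -> float:
    """The per-fraction acute death coefficient k_acute(D, N0) for a spec."""
    form = spec.early_death_form
    if form == "none":
        return 0.0
    if form == "full":
        _require(params, "alpha_acute_N", "k_acute_D")
        return (params.alpha_acute_N * N0 + 1.0) * params.k_acute_D * dose_per_fraction
    if form == "dose_only":
        _require(params, "k_acute_D")
        return params.k_acute_D * dose_per_fraction
    _require(params, "k_acute_N")
    return params.k_acute_N * N0


def accum_coefficient(
    spec: ModelSpec, params: RadiationParams, dose_per_fraction: float, N0: float
) -> float:
    """The per-fraction accumulation (late death) coefficient k_accum(D, N0)."""
    form = spec.late_death_form
    if form == "none":
        return 0.0
    if form == "full":
        _require(params, "alpha_accum_N", "k_accum_D")
        return (params.alpha_accum_N * N0 + 1.0) * params.k_accum_D * dose_per_fraction
    if form == "dose_only":
        _require(params, "k_accum_D")
        return params.k_accum_D * dose_per_fraction
    _require(params, "k_accum_N")
    return params.k_accum_N * N0


def _require(params: RadiationParams, *names: str) -> None:
    for name in names:
        if getattr(params, name) is None:
            raise ConfigurationError(f"active parameter {name} is missing")


def early_death_rate(
    t: float,
    spec: ModelSpec,
    params: RadiationParams,
    schedule: DoseSchedule,
    N0: float,
    kinetics: RepairKinetics,
    gate_sharpness: float = DEFAULT_GATE_SHARPNESS,
) -> float:
    """Acute death rate k_ed(t) in 1/hr, summed over delivered fractions."""
    if t < 0:
        raise ValueError("t must be >= 0")
    coeff = acute_coefficient(spec, params, schedule.dose_per_fraction, N0)
    if coeff == 0.0:
        return 0.0
    k_rep = kinetics.rate_at(schedule.dose_per_fraction)
    total = 0.0
    for ft in schedule.fraction_times:
        if t < ft:
            continue
        f = math.exp(-k_rep * (t - ft))
        total += f * math.tanh(gate_sharpness * f)
    return coeff * total


def late_death_rate(
    t: float,
    spec: ModelSpec,
    params: RadiationParams,
    schedule: DoseSchedule,
    N0: float,
) -> float:
    """Accumulation death rate k_ld(t) in 1/hr (zero until each fraction)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    coeff = accum_coefficient(spec, params, schedule.dose_per_fraction, N0)
    if coeff == 0.0:
        return 0.0
    _require(params, "r")
    total = 0.0
    for ft in schedule.fraction_times:
        ti = t - ft
        if ti <= 0:
            continue
        total += ti * math.exp(-params.r * ti)
    return coeff * total


def treated_rhs(
    state,
    t: float,
    spec: ModelSpec,
    growth: GrowthParams,
    params: RadiationParams,
    schedule: DoseSchedule,
    N0: float,
    kinetics: RepairKinetics,
    gate_sharpness: float = DEFAULT_GATE_SHARPNESS,
):
    """(dN_p/dt, dN_s/dt) of the treated two-species model at time t."""
    n_p, n_s = state
    k_ed = early_death_rate(t, spec, params, schedule, N0, kinetics, gate_sharpness)
    k_ld = late_death_rate(t, spec, params, schedule, N0)
    k_ps = params.k_ps_at(schedule.total_dose) if spec.senescence else 0.0
    n_tot = n_p + n_s
    growth_term = (
        (growth.k_p - k_ld)
        * (n_tot / growth.theta + growth.A)
        * n_p
        * (1.0 - n_tot / growth.theta)
    )
    conversion = k_ps * N0 * n_p
    return growth_term - k_ed * n_p - conversion, conversion


# ---------------------------------------------------------------------------
# fixed-step forward Euler path: death-rate grids are precomputed, the state
# update runs in a compiled kernel


def death_rate_grids(
    schedule: DoseSchedule,
    kinetics: RepairKinetics,
    n_steps: int,
    dt: float,
    gate_sharpness: float = DEFAULT_GATE_SHARPNESS,
):
    """Parameter-independent pieces of the death rates on the Euler grid.

    Returns ``(early_base, ti_stack)`` where ``early_base[k]`` is
    ``sum_i f_DSB * tanh(s f_DSB)`` at step k (multiply by the acute
    coefficient to get k_ed) and ``ti_stack[i, k]`` is the time since
    fraction i, floored at 0 (so ``coeff * sum_i ti * exp(-r ti)`` is k_ld).
    """
    tgrid = np.arange(n_steps) * dt
    k_rep = kinetics.rate_at(schedule.dose_per_fraction)
    early = np.zeros(n_steps)
    ti_stack = np.zeros((schedule.n_fractions, n_steps))
    for i, ft in enumerate(schedule.fraction_times):
        ti = np.maximum(tgrid - ft, 0.0)
        delivered = tgrid >= ft
        f = np.where(delivered, np.exp(-k_rep * ti), 0.0)
        early += f * np.tanh(gate_sharpness * f)
        ti_stack[i] = ti
    return early, ti_stack


def late_grid(ti_stack: np.ndarray, r: float) -> np.ndarray:
    """``sum_i t_i * exp(-r t_i)`` on the Euler grid (zero before delivery)."""
    return np.einsum("ik->k", ti_stack * np.exp(-r * ti_stack))


@njit(cache=False)
def euler_kernel(n0, k_p, theta, allee, kps_eff, ked, kld, dt, out_idx):  # pragma: no cover
    n_steps = ked.shape[0]
    m = out_idx.shape[0]
    out_p = np.empty(m)
    out_s = np.empty(m)
    n_p = n0
    n_s = 0.0
    j = 0
    clips = 0
    for step in range(n_steps + 1):
        while j < m and out_idx[j] == step:
            out_p[j] = n_p
            out_s[j] = n_s
            j += 1
        if step == n_steps:
            break
        n_tot = n_p + n_s
        growth = (
            (k_p - kld[step])
            * (n_tot / theta + allee)
            * n_p
            * (1.0 - n_tot / theta)
        )
        conv = kps_eff * n_p
        n_p = n_p + dt * (growth - ked[step] * n_p - conv)
        n_s = n_s + dt * conv
        if n_p < 0.0:
            n_p = 0.0
            clips += 1
        if n_s < 0.0:
            n_s = 0.0
            clips += 1
    return out_p, out_s, clips


def _output_indices(output_times: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    # Euler grid point at or before each requested time (dt << sampling interval)
    idx = np.floor(np.asarray(output_times, dtype=float) / dt + 1e-9).astype(np.int64)
    if np.any(idx < 0) or np.any(idx > n_steps):
        raise ValueError("output times outside simulated horizon")
    return idx


def simulate(
    spec: ModelSpec,
    growth: GrowthParams,
    rad_params: RadiationParams,
    schedule: DoseSchedule,
    N0: float,
    horizon: float,
    dt: float = DEFAULT_DT,
    output_times=None,
    kinetics: RepairKinetics | None = None,
    gate_sharpness: float = DEFAULT_GATE_SHARPNESS,
) -> Trajectory:
    """Forward-Euler simulation from N_p(0) = N0, N_s(0) = 0.

    ``output_times`` defaults to an hourly grid over [0, horizon]. Values at
    output times are taken from the Euler grid point at or before each
    requested time. The state is clipped at zero from below; clipping events
    are counted and logged at debug level.
    """
    if N0 <= 0:
        raise ValueError("N0 must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if output_times is None:
        output_times = np.arange(0.0, horizon + 0.5 * dt, 1.0)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.size and output_times.max() > horizon + 1e-9:
        raise ValueError("horizon must cover max(output_times)")
    if spec.early_death_form != "none" and kinetics is None:
        raise ConfigurationError("kinetics required when acute death is active")

    n_steps = int(np.floor(horizon / dt + 1e-9))
    if kinetics is not None:
        early_base, ti_stack = death_rate_grids(
            schedule, kinetics, n_steps, dt, gate_sharpness
        )
    else:
        early_base = np.zeros(n_steps)
        ti_stack = np.zeros((schedule.n_fractions, n_steps))
        for i, ft in enumerate(schedule.fraction_times):
            ti_stack[i] = np.maximum(np.arange(n_steps) * dt - ft, 0.0)

    c_early = acute_coefficient(spec, rad_params, schedule.dose_per_fraction, N0)
    c_late = accum_coefficient(spec, rad_params, schedule.dose_per_fraction, N0)
    ked = c_early * early_base
    if c_late != 0.0:
        _require(rad_params, "r")
        kld = c_late * late_grid(ti_stack, rad_params.r)
    else:
        kld = np.zeros(n_steps)
    kps_eff = (rad_params.k_ps_at(schedule.total_dose) if spec.senescence else 0.0) * N0

    out_idx = _output_indices(output_times, dt, n_steps)
    out_p, out_s, clips = euler_kernel(
        float(N0),
        growth.k_p,
        growth.theta,
        growth.A,
        kps_eff,
        ked,
        kld,
        dt,
        out_idx,
    )
    if clips:
        logger.debug(
            "Euler state clipped at zero %d time(s) (%s, N0=%g)", clips, spec.label, N0
        )
    if not (np.all(np.isfinite(out_p)) and np.all(np.isfinite(out_s))):
        raise NumericalError(
            f"non-finite state in Euler simulation ({spec.label}, N0={N0}, dt={dt})"
        )
    return Trajectory(times=output_times, N_p=out_p, N_s=out_s)


def simulate_reference(
    spec: ModelSpec,
    growth: GrowthParams,
    rad_params: RadiationParams,
    schedule: DoseSchedule,
    N0: float,
    output_times,
    kinetics: RepairKinetics | None = None,
    gate_sharpness: float = DEFAULT_GATE_SHARPNESS,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """High-accuracy adaptive Runge-Kutta reference solution.

    Integrates piecewise between fraction times (where the acute-death term
    switches on) with `scipy.integrate.solve_ivp`; used as an independent
    accuracy oracle for the fixed-step Euler path.
    """
    output_times = np.asarray(output_times, dtype=float)
    horizon = float(output_times.max())

    def rhs(t, y):
        return treated_rhs(
            y, t, spec, growth, rad_params, schedule, N0, kinetics, gate_sharpness
        )

    breakpoints = sorted({ft for ft in schedule.fraction_times if 0.0 < ft < horizon})
    segments = [0.0] + breakpoints + [horizon]
    state = np.array([float(N0), 0.0])
    out_p = np.empty_like(output_times)
    out_s = np.empty_like(output_times)
    done = np.zeros(output_times.shape, dtype=bool)
    at_zero = np.isclose(output_times, 0.0)
    out_p[at_zero], out_s[at_zero] = state
    done |= at_zero
    for a, b in zip(segments[:-1], segments[1:]):
        if b <= a:
            continue
        sol = solve_ivp(
            rhs, (a, b), state, method="RK45", rtol=rtol, atol=atol, dense_output=True
        )
        if not sol.success:
            raise NumericalError(
                f"reference integration failed on [{a}, {b}]: {sol.message}"
            )
        inside = (~done) & (output_times > a) & (output_times <= b + 1e-12)
        if np.any(inside):
            values = sol.sol(output_times[inside])
            out_p[inside] = values[0]
            out_s[inside] = values[1]
            done[inside] = True
        state = sol.y[:, -1]
    return Trajectory(times=output_times, N_p=out_p, N_s=out_s)
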