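"""Global calibration of a radiation-response model against confluence curves.

`FractionatedRadiationModel` holds a training set of curves plus the fixed
per-cell-line growth parameters and repair kinetics; `fit` minimizes the sum
of squared (model - data) residuals over all curves simultaneously -- every
curve is simulated with its own measured initial confluence and schedule
under one shared radiation-parameter vector (``k_ps`` selected by the
curve's total dose) -- subject to nonnegativity bounds, and returns a
`CalibrationResult` carrying estimates, covariance, confidence intervals
and delta-method predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, t as student_t

from . import dynamics
from .exceptions import ConfigurationError, NumericalError
from .family import ModelSpec
from .schedules import SCHEDULE_PRESETS

__all__ = [
    "FractionatedRadiationModel",
    "CalibrationResult",
    "PredictionResult",
    "residuals",
    "calibrate_global",
    "compare_cell_lines",
]

logger = logging.getLogger(__name__)

# start-draw ranges (log-uniform): dimensionless alpha scales vs. rate-like params
_ALPHA_RANGE = (1e-2, 1e2)
_RATE_RANGE = (1e-5, 1e-1)

_HEURISTIC_START = {
    "alpha_acute_N": 1.0,
    "k_acute_D": 5e-3,
    "k_acute_N": 0.1,
    "alpha_accum_N": 1.0,
    "k_accum_D": 3e-4,
    "k_accum_N": 5e-3,
    "r": 0.02,
}
_HEURISTIC_KPS = 0.03


def _as_map(value, cell_lines, kind):
    if isinstance(value, dict):
        missing = [c for c in cell_lines if c not in value]
        if missing:
            raise ConfigurationError(f"missing {kind} for cell line(s) {missing}")
        return value
    return {c: value for c in cell_lines}


class _CurveWorkspace:
    """Per-curve precomputed grids shared across parameter evaluations."""

    __slots__ = (
        "replicate_id", "growth", "kinetics", "schedule", "N0", "y", "out_idx",
        "n_steps", "early_base", "ti_stack", "dose", "total_dose",
    )

    def __init__(self, times, y, N0, replicate_id, growth, kinetics, schedule,
                 dt, gate_sharpness):
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.replicate_id = replicate_id
        self.growth = growth
        self.kinetics = kinetics
        self.schedule = schedule
        self.N0 = float(N0)
        self.y = y
        horizon = float(times[-1])
        self.n_steps = int(np.floor(horizon / dt + 1e-9))
        self.out_idx = np.floor(times / dt + 1e-9).astype(np.int64)
        self.early_base, self.ti_stack = dynamics.death_rate_grids(
            schedule, kinetics, self.n_steps, dt, gate_sharpness
        )
        self.dose = schedule.dose_per_fraction
        self.total_dose = schedule.total_dose


class FractionatedRadiationModel:
    """Two-compartment fractionated-radiation response model bound to data.

    Parameters
    ----------
    curves : iterable of ConfluenceCurve (the training set).
    spec : ModelSpec choosing active death/senescence terms.
    growth : GrowthParams or mapping cell line -> GrowthParams (fixed; they
        come from a prior untreated-control fit, not from this calibration).
    kinetics : RepairKinetics or mapping cell line -> RepairKinetics.
    schedules : optional mapping schedule_id -> DoseSchedule (defaults to
        the built-in presets).
    dt : Euler step in hours.
    gate_sharpness : sharpness of the tanh gate on the acute-death term.
    """

    def __init__(
        self,
        curves,
        spec: ModelSpec,
        growth,
        kinetics,
        schedules=None,
        dt: float = dynamics.DEFAULT_DT,
        gate_sharpness: float = dynamics.DEFAULT_GATE_SHARPNESS,
        workspace_cache: dict | None = None,
    ):
        curves = sorted(curves, key=lambda c: c.replicate_id)
        if not curves:
            raise ConfigurationError("training set is empty")
        self.spec = spec
        self.dt = float(dt)
        self.gate_sharpness = float(gate_sharpness)
        self.schedules = dict(SCHEDULE_PRESETS)
        if schedules:
            self.schedules.update(schedules)
        cell_lines = sorted({c.cell_line for c in curves})
        self.growth_map = _as_map(growth, cell_lines, "growth parameters")
        self.kinetics_map = _as_map(kinetics, cell_lines, "repair kinetics")
        self.param_names = spec.free_parameter_names
        self._ix = {name: i for i, name in enumerate(self.param_names)}
        self._workspaces = []
        for curve in curves:
            key = (curve.replicate_id, self.dt)
            if workspace_cache is not None and key in workspace_cache:
                ws = workspace_cache[key]
            else:
                if curve.schedule_id not in self.schedules:
                    raise ConfigurationError(
                        f"replicate {curve.replicate_id}: unknown schedule "
                        f"{curve.schedule_id!r}"
                    )
                ws = _CurveWorkspace(
                    curve.times,
                    curve.confluence,
                    curve.N0,
                    curve.replicate_id,
                    self.growth_map[curve.cell_line],
                    self.kinetics_map[curve.cell_line],
                    self.schedules[curve.schedule_id],
                    self.dt,
                    self.gate_sharpness,
                )
                if workspace_cache is not None:
                    workspace_cache[key] = ws
            self._workspaces.append(ws)
        self.curves = curves
        self.n_obs = int(sum(len(c) for c in curves))

    # -- parameter plumbing -------------------------------------------------

    def _rates_for(self, theta, ws):
        """(c_early, c_late, r, kps_eff) for one curve at raw vector theta."""
        ix = self._ix
        form = self.spec.early_death_form
        if form == "none":
            c_early = 0.0
        elif form == "full":
            c_early = (theta[ix["alpha_acute_N"]] * ws.N0 + 1.0) * theta[
                ix["k_acute_D"]
            ] * ws.dose
        elif form == "dose_only":
            c_early = theta[ix["k_acute_D"]] * ws.dose
        else:
            c_early = theta[ix["k_acute_N"]] * ws.N0
        form = self.spec.late_death_form
        if form == "none":
            c_late = 0.0
        elif form == "full":
            c_late = (theta[ix["alpha_accum_N"]] * ws.N0 + 1.0) * theta[
                ix["k_accum_D"]
            ] * ws.dose
        elif form == "dose_only":
            c_late = theta[ix["k_accum_D"]] * ws.dose
        else:
            c_late = theta[ix["k_accum_N"]] * ws.N0
        r = theta[ix["r"]] if "r" in ix else 0.0
        if self.spec.senescence:
            kps_eff = theta[ix[f"k_ps_{ws.total_dose:g}"]] * ws.N0
        else:
            kps_eff = 0.0
        return c_early, c_late, r, kps_eff

    def _simulate_ws(self, theta, ws):
        """Total-confluence prediction at the curve's sampled times."""
        c_early, c_late, r, kps_eff = self._rates_for(theta, ws)
        ked = c_early * ws.early_base
        if c_late != 0.0:
            kld = c_late * dynamics.late_grid(ws.ti_stack, r)
        else:
            kld = np.zeros(ws.n_steps)
        out_p, out_s, _ = dynamics.euler_kernel(
            ws.N0,
            ws.growth.k_p,
            ws.growth.theta,
            ws.growth.A,
            kps_eff,
            ked,
            kld,
            self.dt,
            ws.out_idx,
        )
        return out_p + out_s

    def residuals(self, theta) -> np.ndarray:
        """Concatenated (model - data) over curves in canonical replicate order."""
        theta = np.asarray(theta, dtype=float)
        pieces = []
        for ws in self._workspaces:
            pred = self._simulate_ws(theta, ws)
            if not np.all(np.isfinite(pred)):
                raise NumericalError(
                    f"simulation failed for replicate {ws.replicate_id} "
                    f"at theta={theta.tolist()}"
                )
            pieces.append(pred - ws.y)
        return np.concatenate(pieces)

    def rss(self, theta) -> float:
        res = self.residuals(theta)
        return float(res @ res)

    # -- fitting ------------------------------------------------------------

    def _heuristic_start(self) -> np.ndarray:
        return np.array(
            [
                _HEURISTIC_KPS if n.startswith("k_ps_") else _HEURISTIC_START[n]
                for n in self.param_names
            ]
        )

    def _draw_start(self, rng) -> np.ndarray:
        values = []
        for name in self.param_names:
            lo, hi = _ALPHA_RANGE if name.startswith("alpha_") else _RATE_RANGE
            values.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return np.array(values)

    def fit(
        self,
        start=None,
        n_starts: int = 8,
        seed: int = 0,
        max_nfev: int = 2000,
        ftol: float = 1e-10,
        xtol: float = 1e-10,
        gtol: float = 1e-10,
        method: str = "trf",
    ) -> "CalibrationResult":
        """Bounded (>= 0) trust-region least squares with seeded multi-start.

        The first start is a fixed heuristic vector (plus ``start`` if
        supplied); the remainder are log-uniform draws. The best final RSS
        across starts wins.

        ``method='lm'`` runs classical unbounded Levenberg-Marquardt for
        comparison, with the nonnegativity constraint imposed softly by
        clipping the parameter vector at zero inside the residual function.
        """
        if method not in ("trf", "lm"):
            raise ValueError("method must be 'trf' or 'lm'")
        if self.spec.n_free >= self.n_obs:
            raise ConfigurationError(
                f"{self.spec.n_free} free parameters but only "
                f"{self.n_obs} observations"
            )
        rng = np.random.default_rng(seed)
        starts = []
        if start is not None:
            start = np.asarray(start, dtype=float)
            if np.any(start < 0):
                raise ValueError("start must respect the nonnegativity bounds")
            starts.append(start)
        starts.append(self._heuristic_start())
        while len(starts) < max(n_starts, len(starts)):
            starts.append(self._draw_start(rng))

        if method == "lm":
            objective = lambda theta: self.residuals(np.maximum(theta, 0.0))
            kwargs = dict(method="lm")
        else:
            objective = self.residuals
            kwargs = dict(method="trf", bounds=(0.0, np.inf), x_scale="jac")

        best = None
        records = []
        for k, x0 in enumerate(starts):
            sol = least_squares(
                objective,
                x0,
                jac="2-point",
                ftol=ftol,
                xtol=xtol,
                gtol=gtol,
                max_nfev=max_nfev,
                **kwargs,
            )
            records.append(
                {
                    "start": x0.tolist(),
                    "rss": float(2.0 * sol.cost),
                    "status": int(sol.status),
                    "nfev": int(sol.nfev),
                }
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if method == "lm":
            # report the clipped (feasible) parameters the residuals used
            best.x = np.maximum(best.x, 0.0)
        converged = best.status > 0
        if not converged:
            logger.warning("calibration did not converge after %d start(s)", len(starts))
        return CalibrationResult(self, best, records, seed)


class CalibrationResult:
    """Estimates, uncertainty and diagnostics from a global calibration.

    The covariance is the standard nonlinear-least-squares estimate
    ``(J'J)^{-1} * RSS / (m - p)`` from the Jacobian at the optimum;
    confidence intervals use the t quantile with ``m - p`` degrees of
    freedom, matching the usual regression semantics.
    """

    def __init__(self, model, solution, start_records, seed):
        self.model = model
        self.spec = model.spec
        self.param_names = model.param_names
        self.params = np.asarray(solution.x, dtype=float)
        self.resid = np.asarray(solution.fun, dtype=float)
        self.rss = float(self.resid @ self.resid)
        self.jac = np.asarray(solution.jac, dtype=float)
        self.n_obs = int(self.resid.size)
        self.n_free = int(self.params.size)
        self.df_resid = self.n_obs - self.n_free
        self.scale = self.rss / self.df_resid if self.df_resid > 0 else np.nan
        self.converged = solution.status > 0
        self.start_records = start_records
        self.seed = seed
        self.cov_is_pseudo = False
        jtj = self.jac.T @ self.jac
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e12:
            self.cov_is_pseudo = True
            logger.warning(
                "J'J ill-conditioned (cond=%.3g); using pseudo-inverse covariance",
                cond,
            )
            unscaled = np.linalg.pinv(jtj)
        else:
            unscaled = np.linalg.inv(jtj)
        self._cov = unscaled * self.scale

    # -- uncertainty --------------------------------------------------------

    def cov_params(self) -> np.ndarray:
        return self._cov.copy()

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self._cov), 0.0, np.inf))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        tq = student_t.ppf(1.0 - alpha / 2.0, self.df_resid)
        half = tq * self.bse
        return np.column_stack([self.params - half, self.params + half])

    def correlation_matrix(self) -> np.ndarray:
        sd = self.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = self._cov / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        return corr

    def high_correlations(self, threshold: float = 0.99) -> list:
        """Parameter pairs whose estimate correlation exceeds ``threshold``."""
        corr = self.correlation_matrix()
        pairs = []
        for i in range(self.n_free):
            for j in range(i + 1, self.n_free):
                if abs(corr[i, j]) > threshold:
                    pairs.append(
                        (self.param_names[i], self.param_names[j], float(corr[i, j]))
                    )
        if pairs:
            logger.info("highly correlated parameter pairs: %s", pairs)
        return pairs

    # -- prediction ---------------------------------------------------------

    def _resolve(self, schedule, cell_line):
        if isinstance(schedule, str):
            schedule = self.model.schedules[schedule]
        if cell_line is None:
            lines = sorted(self.model.growth_map)
            if len(lines) != 1:
                raise ValueError("cell_line required for a multi-line calibration")
            cell_line = lines[0]
        return schedule, cell_line

    def _mean_curve(self, theta, N0, schedule, cell_line, times):
        growth = self.model.growth_map[cell_line]
        kinetics = self.model.kinetics_map[cell_line]
        ws = _CurveWorkspace(
            times, None, N0, "_pred", growth, kinetics, schedule,
            self.model.dt, self.model.gate_sharpness,
        )
        return self.model._simulate_ws(np.asarray(theta, dtype=float), ws)

    def predict(
        self,
        N0: float,
        schedule,
        times,
        cell_line: str | None = None,
        level: float = 0.95,
        interval: str = "mean",
    ) -> "PredictionResult":
        """Forward prediction with pointwise delta-method intervals.

        ``interval='mean'`` propagates parameter uncertainty only
        (half-width ``t * sqrt(g' Cov g)`` with g the central-finite-
        difference gradient of the predicted confluence); ``'observation'``
        additionally includes the residual variance, giving an interval for
        a new noisy measurement.
        """
        schedule, cell_line = self._resolve(schedule, cell_line)
        times = np.asarray(times, dtype=float)
        if N0 <= 0:
            raise ValueError("N0 must be > 0")
        if interval not in ("mean", "observation"):
            raise ValueError("interval must be 'mean' or 'observation'")
        mean = self._mean_curve(self.params, N0, schedule, cell_line, times)
        grad = np.empty((times.size, self.n_free))
        for k in range(self.n_free):
            base = self.params[k]
            h = 1e-6 * max(abs(base), 1e-4)
            lo = base - h
            if lo < 0.0:  # keep evaluations inside the parameter domain
                up = self.params.copy()
                up[k] = base + h
                grad[:, k] = (
                    self._mean_curve(up, N0, schedule, cell_line, times) - mean
                ) / h
            else:
                up = self.params.copy()
                dn = self.params.copy()
                up[k] = base + h
                dn[k] = lo
                grad[:, k] = (
                    self._mean_curve(up, N0, schedule, cell_line, times)
                    - self._mean_curve(dn, N0, schedule, cell_line, times)
                ) / (2.0 * h)
        var = np.einsum("ij,jk,ik->i", grad, self._cov, grad)
        var = np.clip(var, 0.0, np.inf)
        if interval == "observation":
            var = var + self.scale
        tq = student_t.ppf(0.5 + level / 2.0, self.df_resid)
        half = tq * np.sqrt(var)
        return PredictionResult(
            times=times,
            mean=mean,
            half_width=half,
            lower=mean - half,
            upper=mean + half,
            level=level,
            interval=interval,
            source=self,
        )

    def fitted(self) -> list:
        """Fitted total-confluence values per training curve (canonical order)."""
        return [
            self.model._simulate_ws(self.params, ws) for ws in self.model._workspaces
        ]

    # -- reporting ----------------------------------------------------------

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        lines = [
            "Fractionated radiation response calibration",
            "=" * 62,
            f"{self.spec.label}",
            f"curves: {len(self.model.curves)}   observations: {self.n_obs}   "
            f"free parameters: {self.n_free}",
            f"RSS: {self.rss:.6g}   scale (RSS/dof): {self.scale:.6g}   "
            f"converged: {self.converged}",
            "-" * 62,
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}"
            f"{'[' + f'{(1-alpha)*100:.0f}% conf. int.]':>22}",
        ]
        for name, est, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"{name:<16}{est:>12.5g}{se:>12.3g}{lo:>11.4g}{hi:>11.4g}")
        if self.cov_is_pseudo:
            lines.append("warning: covariance from pseudo-inverse (ill-conditioned J'J)")
        high = self.high_correlations()
        for a, b, c in high:
            lines.append(f"note: |corr({a}, {b})| = {abs(c):.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "model_id": self.spec.id,
            "parameters": {
                name: {
                    "estimate": float(est),
                    "se": float(se),
                    "ci95": [float(lo), float(hi)],
                }
                for name, est, se, (lo, hi) in zip(
                    self.param_names, self.params, self.bse, ci
                )
            },
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": bool(self.converged),
            "cov_is_pseudo": bool(self.cov_is_pseudo),
            "seed": self.seed,
            "starts": self.start_records,
        }


@dataclass(frozen=True)
class PredictionResult:
    """Mean predicted confluence and pointwise interval half-widths."""

    times: np.ndarray
    mean: np.ndarray
    half_width: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    interval: str
    source: CalibrationResult

    def to_frame(self):
        """Tabular export: time, mean, lower, upper."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_hr": self.times,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def residuals(params, spec, training_set, growth_by_cell_line, kinetics,
              schedules=None, dt=dynamics.DEFAULT_DT):
    """Model-minus-data residual vector for a raw parameter vector."""
    model = FractionatedRadiationModel(
        training_set, spec, growth_by_cell_line, kinetics, schedules=schedules, dt=dt
    )
    return model.residuals(np.asarray(params, dtype=float))


def calibrate_global(spec, training_set, growth, kinetics, init=None,
                     schedules=None, dt=dynamics.DEFAULT_DT, **fit_options):
    """Convenience wrapper: build the model and fit it in one call."""
    model = FractionatedRadiationModel(
        training_set, spec, growth, kinetics, schedules=schedules, dt=dt
    )
    return model.fit(start=init, **fit_options)


def compare_cell_lines(result_a: CalibrationResult, result_b: CalibrationResult,
                       parameter: str, alpha: float = 0.05):
    """Two-sided z-test for a parameter differing between two calibrations.

    Returns ``(z, p_value, significant)`` with
    ``z = (est_a - est_b) / sqrt(se_a^2 + se_b^2)``.
    """
    for res in (result_a, result_b):
        if parameter not in res.param_names:
            raise ValueError(f"parameter {parameter!r} not free in both results")
    ia = result_a.param_names.index(parameter)
    ib = result_b.param_names.index(parameter)
    se = np.hypot(result_a.bse[ia], result_b.bse[ib])
    if se == 0:
        raise ValueError(f"zero standard error for {parameter!r}; z undefined")
    z = (result_a.params[ia] - result_b.params[ib]) / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p), bool(p < alpha)
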