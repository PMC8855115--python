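"""Prediction-accuracy metrics and held-out validation.

Agreement between predicted and measured confluence is scored per replicate
with the Pearson correlation coefficient (PCC, linear association) and
Lin's concordance correlation coefficient (CCC, agreement — it additionally
penalizes scale and location shifts):

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2),

with population (divide-by-n) moments. |CCC| <= |PCC| always. Replicate
scores are aggregated per condition (cell line x schedule) as
mean +/- standard error over replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UndefinedMetricError
from .schedules import SCHEDULE_PRESETS

__all__ = ["pearson", "concordance", "validate", "ValidationMetrics"]


def pearson(x, y) -> float:
    """Sample Pearson correlation; requires length >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedMetricError("Pearson correlation undefined: zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def concordance(x, y) -> float:
    """Lin's concordance correlation with population moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise UndefinedMetricError(
            "concordance undefined: zero variances and equal means"
        )
    return float(np.clip(2.0 * sxy / denom, -1.0, 1.0))


class ValidationMetrics:
    """Per-replicate PCC/CCC plus mean +/- SE aggregations."""

    def __init__(self, per_replicate: pd.DataFrame, excluded: list):
        self.per_replicate = per_replicate
        self.excluded = excluded  # (replicate_id, reason) pairs

    @staticmethod
    def _aggregate(frame: pd.DataFrame, keys) -> pd.DataFrame:
        metric_cols = ["pcc_mean", "pcc_se", "ccc_mean", "ccc_se", "n_replicates"]
        if frame.empty:
            return pd.DataFrame(columns=list(keys) + metric_cols)

        def agg(grp):
            out = {}
            for metric in ("pcc", "ccc"):
                vals = grp[metric].to_numpy()
                out[f"{metric}_mean"] = vals.mean()
                out[f"{metric}_se"] = (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
                )
            out["n_replicates"] = len(grp)
            return pd.Series(out)

        result = frame.groupby(keys).apply(agg, include_groups=False).reset_index()
        result["n_replicates"] = result["n_replicates"].astype(int)
        return result

    def by_condition(self) -> pd.DataFrame:
        """Rows = cell line x schedule; columns = PCC/CCC mean, SE, n."""
        return self._aggregate(self.per_replicate, ["cell_line", "schedule_id"])

    def by_total_dose(self) -> pd.DataFrame:
        return self._aggregate(self.per_replicate, ["cell_line", "total_dose"])

    def overall(self) -> pd.DataFrame:
        return self._aggregate(self.per_replicate, ["cell_line"])

    def to_csv(self, path) -> None:
        self.by_condition().to_csv(path, index=False)


def validate(calib_by_cell_line, validation_set, schedules=None) -> ValidationMetrics:
    """Predict every held-out replicate from its N0 and schedule alone.

    Each validation curve is predicted with its cell line's calibrated
    parameters (``k_ps`` chosen by the curve's total dose — the same
    parameter set regardless of schedule or seeding density), scored with
    PCC and CCC against its measurements, and aggregated per condition.
    Replicates on which a metric is undefined are reported and excluded.
    """
    schedules = dict(SCHEDULE_PRESETS) | (dict(schedules) if schedules else {})
    rows = []
    excluded = []
    for curve in sorted(validation_set, key=lambda c: c.replicate_id):
        if curve.cell_line not in calib_by_cell_line:
            raise ConfigurationError(f"no calibration for cell line {curve.cell_line!r}")
        if curve.schedule_id not in schedules:
            raise ConfigurationError(
                f"replicate {curve.replicate_id}: unknown schedule {curve.schedule_id!r}"
            )
        calib = calib_by_cell_line[curve.cell_line]
        schedule = schedules[curve.schedule_id]
        pred = calib.predict(
            curve.N0, schedule, curve.times, cell_line=curve.cell_line
        )
        try:
            pcc = pearson(pred.mean, curve.confluence)
            ccc = concordance(pred.mean, curve.confluence)
        except UndefinedMetricError as err:
            excluded.append((curve.replicate_id, str(err)))
            continue
        rows.append(
            {
                "replicate_id": curve.replicate_id,
                "cell_line": curve.cell_line,
                "schedule_id": curve.schedule_id,
                "total_dose": schedule.total_dose,
                "pcc": pcc,
                "ccc": ccc,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["replicate_id", "cell_line", "schedule_id", "total_dose", "pcc", "ccc"],
    )
    return ValidationMetrics(per_replicate=frame, excluded=excluded)
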