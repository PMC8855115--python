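"""Confluence-curve container and CSV round-tripping.

The on-disk format is a plain CSV with header
``replicate_id,cell_line,schedule_id,time_hr,confluence``; lines starting
with ``#`` are treated as provenance comments and ignored on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataFormatError

__all__ = ["ConfluenceCurve", "read_curves", "write_curves", "curves_to_frame"]

CURVE_COLUMNS = ("replicate_id", "cell_line", "schedule_id", "time_hr", "confluence")


@dataclass(frozen=True)
class ConfluenceCurve:
    """One replicate's measured live-cell confluence time series."""

    replicate_id: str
    cell_line: str
    schedule_id: str
    times: np.ndarray = field(compare=False)
    confluence: np.ndarray = field(compare=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        conf = np.asarray(self.confluence, dtype=float)
        if times.ndim != 1 or times.shape != conf.shape:
            raise DataFormatError("times and confluence must be matching 1-d arrays")
        if times.size == 0:
            raise DataFormatError("curve must contain at least one measurement")
        if times[0] != 0.0:
            raise DataFormatError(
                f"replicate {self.replicate_id}: first measurement must be at t = 0"
            )
        if np.any(np.diff(times) <= 0):
            raise DataFormatError(
                f"replicate {self.replicate_id}: times must be strictly increasing"
            )
        if np.any(conf < 0):
            raise DataFormatError(
                f"replicate {self.replicate_id}: confluence must be >= 0"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "confluence", conf)

    @property
    def N0(self) -> float:
        """Initial confluence (the measurement at t = 0)."""
        return float(self.confluence[0])

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other):
        if not isinstance(other, ConfluenceCurve):
            return NotImplemented
        return (
            self.replicate_id == other.replicate_id
            and self.cell_line == other.cell_line
            and self.schedule_id == other.schedule_id
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.confluence, other.confluence)
        )


def read_curves(path) -> list:
    """Read curves from CSV, grouped by replicate with times sorted.

    Raises :class:`DataFormatError` on missing columns or duplicated
    ``(replicate_id, time_hr)`` rows (naming the offending line).
    """
    frame = pd.read_csv(
        path,
        comment="#",
        dtype={"replicate_id": str, "cell_line": str},
        float_precision="round_trip",
    )
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")
    frame["_line"] = np.arange(2, len(frame) + 2)  # 1-based, after header
    dup = frame.duplicated(subset=["replicate_id", "time_hr"], keep=False)
    if dup.any():
        first = frame.loc[dup].iloc[1]
        raise DataFormatError(
            f"{path}: duplicated (replicate_id, time_hr) at line {first['_line']} "
            f"(replicate {first['replicate_id']!r}, t={first['time_hr']})"
        )
    curves = []
    for rid, grp in frame.groupby("replicate_id", sort=True):
        grp = grp.sort_values("time_hr")
        cell_lines = grp["cell_line"].unique()
        schedules = grp["schedule_id"].unique()
        if len(cell_lines) > 1 or len(schedules) > 1:
            raise DataFormatError(
                f"{path}: replicate {rid!r} mixes cell lines or schedules"
            )
        curves.append(
            ConfluenceCurve(
                replicate_id=str(rid),
                cell_line=str(cell_lines[0]),
                schedule_id=str(schedules[0]),
                times=grp["time_hr"].to_numpy(),
                confluence=grp["confluence"].to_numpy(),
            )
        )
    return curves


def curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for curve in sorted(curves, key=lambda c: c.replicate_id):
        for t, y in zip(curve.times, curve.confluence):
            rows.append(
                (curve.replicate_id, curve.cell_line, curve.schedule_id, t, y)
            )
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def write_curves(curves, path, provenance: str | None = None) -> None:
    """Write curves as CSV (optionally with a leading ``#`` provenance line)."""
    frame = curves_to_frame(curves)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, index=False)
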