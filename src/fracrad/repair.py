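"""DNA double-strand-break (DSB) repair kinetics.

Ionizing radiation induces DSBs whose repair is well approximated by
first-order (exponential) decay: the fraction of breaks still unrepaired a
time ``t`` after a fraction of dose ``D`` is ``exp(-k_repair(D) * t)``.
``k_repair`` is measured (via a gamma-H2AX assay) at a handful of doses and
linearly interpolated in between; outside the tabulated dose range the
nearest endpoint rate is used, since all experimental doses fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

__all__ = [
    "RepairKinetics",
    "repair_rate_at_dose",
    "fraction_unrepaired",
    "time_since_fraction",
]

_KINETICS_COLUMNS = ("dose_gy", "k_repair_per_hr")


@dataclass(frozen=True)
class RepairKinetics:
    """Dose -> DSB repair-rate table with linear interpolation.

    Parameters
    ----------
    doses : strictly increasing dose values in Gy, all > 0.
    rates : matching repair rates ``k_repair`` in 1/hr, all >= 0.
    """

    doses: tuple
    rates: tuple

    def __post_init__(self):
        doses = tuple(float(d) for d in self.doses)
        rates = tuple(float(r) for r in self.rates)
        if len(doses) != len(rates):
            raise ConfigurationError("doses and rates must have equal length")
        if len(doses) < 2:
            raise ConfigurationError(
                "repair-kinetics table needs at least two (dose, rate) entries"
            )
        if any(d <= 0 for d in doses):
            raise ConfigurationError("all tabulated doses must be > 0 Gy")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ConfigurationError("tabulated doses must be strictly increasing")
        if any(r < 0 for r in rates):
            raise ConfigurationError("repair rates must be >= 0")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "rates", rates)

    def rate_at(self, dose: float) -> float:
        """Interpolated repair rate (1/hr) at ``dose`` (Gy), clamped at the ends."""
        if dose <= 0:
            raise ValueError(f"dose must be > 0 Gy, got {dose}")
        return float(np.interp(dose, self.doses, self.rates))

    @classmethod
    def from_csv(cls, path) -> "RepairKinetics":
        """Read a two-column CSV ``dose_gy,k_repair_per_hr`` (header required)."""
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        missing = [c for c in _KINETICS_COLUMNS if c not in frame.columns]
        if missing:
            raise DataFormatError(f"{path}: missing column(s) {missing}")
        return cls(tuple(frame["dose_gy"]), tuple(frame["k_repair_per_hr"]))

    def to_csv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write(",".join(_KINETICS_COLUMNS) + "\n")
            for d, r in zip(self.doses, self.rates):
                fh.write(f"{d!r},{r!r}\n")


def repair_rate_at_dose(kinetics: RepairKinetics, dose: float) -> float:
    """Piecewise-linear repair rate at ``dose``; clamps outside the table."""
    return kinetics.rate_at(dose)


def fraction_unrepaired(k_repair: float, t):
    """Fraction of DSBs still unrepaired after time ``t`` (hr): ``exp(-k t)``.

    Accepts scalar or array ``t``; equals 1 at t = 0 and decreases strictly
    in ``t`` when ``k_repair > 0``.
    """
    if k_repair < 0:
        raise ValueError(f"k_repair must be >= 0, got {k_repair}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-k_repair * t)
    return float(out) if out.ndim == 0 else out


def time_since_fraction(t: float, fraction_times: Iterable[float], i: int) -> float:
    """Time elapsed since the ``i``-th fraction (1-based), floored at 0.

    With the conventional 24 h spacing and the first fraction at t = 0 this
    reduces to ``max(t - 24*(i-1), 0)``.
    """
    times = list(fraction_times)
    if not 1 <= i <= len(times):
        raise IndexError(f"fraction index {i} out of range 1..{len(times)}")
    ft = times[i - 1]
    return t - ft if t > ft else 0.0
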