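"""Fractionation schedules: ordered fraction times and per-fraction doses.

The six built-in presets mirror a 16 Gy / 20 Gy two-arm design delivered in
2, 3 or 4 daily fractions (24 h apart): 2x8, 3x5.3, 4x4 Gy and 2x10, 3x6.7,
4x5 Gy. Preset names are ``<total>x<fractions>``, e.g. ``16x3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError

__all__ = ["DoseSchedule", "SCHEDULE_PRESETS", "get_schedule"]

# rounded per-fraction doses (5.3, 6.7 Gy) make n*D differ from the nominal
# total by <1%; admit up to 2%
_TOTAL_DOSE_RTOL = 0.02


@dataclass(frozen=True)
class DoseSchedule:
    """Equal-dose fractions at given times (hr), first fraction at t = 0."""

    fraction_times: tuple
    dose_per_fraction: float
    total_dose: float
    name: str = field(default="", compare=False)

    def __post_init__(self):
        times = tuple(float(t) for t in self.fraction_times)
        if len(times) < 1:
            raise ConfigurationError("schedule needs at least one fraction")
        if times[0] != 0.0:
            raise ConfigurationError("first fraction must be at t = 0 hr")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigurationError("fraction times must be nondecreasing")
        if self.dose_per_fraction <= 0:
            raise ConfigurationError("dose per fraction must be > 0 Gy")
        nominal = self.dose_per_fraction * len(times)
        if abs(nominal - self.total_dose) > _TOTAL_DOSE_RTOL * self.total_dose:
            raise ConfigurationError(
                f"total dose {self.total_dose} Gy inconsistent with "
                f"{len(times)} x {self.dose_per_fraction} Gy"
            )
        object.__setattr__(self, "fraction_times", times)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_times)


def _daily(n: int, dose: float, total: float, name: str) -> DoseSchedule:
    return DoseSchedule(tuple(24.0 * i for i in range(n)), dose, total, name)


SCHEDULE_PRESETS = {
    "16x2": _daily(2, 8.0, 16.0, "16x2"),
    "16x3": _daily(3, 5.3, 16.0, "16x3"),
    "16x4": _daily(4, 4.0, 16.0, "16x4"),
    "20x2": _daily(2, 10.0, 20.0, "20x2"),
    "20x3": _daily(3, 6.7, 20.0, "20x3"),
    "20x4": _daily(4, 5.0, 20.0, "20x4"),
}


def get_schedule(name: str) -> DoseSchedule:
    """Look up a preset schedule by name (e.g. ``'16x4'``)."""
    try:
        return SCHEDULE_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown schedule {name!r}; valid presets: {sorted(SCHEDULE_PRESETS)}"
        ) from None
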