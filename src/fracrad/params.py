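"""Parameter containers for the growth and radiation-response models.

Units follow dimensional consistency of the governing equations rather than
any loose tabulation: confluence is a dimensionless fraction in (0, 1], all
times are hours, doses are Gy. In particular ``k_accum_D`` multiplies both a
dose (Gy) and an elapsed time (hr) inside the late-death rate (1/hr), so its
unit is 1/(hr^2 Gy); ``k_accum_N`` analogously is 1/hr^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Optional

from .exceptions import ConfigurationError

__all__ = ["GrowthParams", "RadiationParams"]


@dataclass(frozen=True)
class GrowthParams:
    """Untreated-growth parameters (fixed per cell line during calibration).

    k_p : proliferation rate, 1/hr.
    theta : carrying capacity as a confluence fraction, in (0, 1].
    A : dimensionless Allee coefficient (>= 0); the per-capita growth factor
        is ``(N/theta + A)``, so at low density growth is ~ ``k_p * A * N``.
    """

    k_p: float
    theta: float
    A: float

    def __post_init__(self):
        if self.k_p < 0:
            raise ConfigurationError("k_p must be >= 0")
        if not 0 < self.theta <= 1:
            raise ConfigurationError("theta must lie in (0, 1]")
        if self.A < 0:
            raise ConfigurationError("A must be >= 0")


@dataclass(frozen=True)
class RadiationParams:
    """Radiation-response parameters; only the fields a ModelSpec activates are used.

    alpha_acute_N : dimensionless density scale in the full acute term
        ``(alpha_acute_N * N0 + 1) * k_acute_D * D``.
    k_acute_D : acute death per dose, 1/(hr Gy).
    k_acute_N : acute death per initial confluence, 1/hr (density-only form
        ``k_acute_N * N0``).
    alpha_accum_N : dimensionless density scale in the accumulation (late
        death) coefficient ``(alpha_accum_N * N0 + 1) * k_accum_D * D``.
    k_accum_D : late death per dose per elapsed hour, 1/(hr^2 Gy).
    k_accum_N : late death per initial confluence per elapsed hour, 1/hr^2.
    r : decay rate of radiation efficacy, 1/hr; the late-death kernel is
        ``t_i * exp(-r t_i)`` which peaks at t_i = 1/r.
    k_ps : mapping total dose (Gy) -> proliferative-to-senescent conversion
        rate, 1/hr (one free value per total-dose arm).
    """

    alpha_acute_N: Optional[float] = None
    k_acute_D: Optional[float] = None
    k_acute_N: Optional[float] = None
    alpha_accum_N: Optional[float] = None
    k_accum_D: Optional[float] = None
    k_accum_N: Optional[float] = None
    r: Optional[float] = None
    k_ps: Optional[Mapping[float, float]] = field(default=None)

    def __post_init__(self):
        for f in fields(self):
            if f.name == "k_ps":
                continue
            value = getattr(self, f.name)
            if value is not None and value < 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {value}")
        if self.k_ps is not None:
            cleaned = {float(d): float(v) for d, v in dict(self.k_ps).items()}
            if any(v < 0 for v in cleaned.values()):
                raise ConfigurationError("k_ps rates must be >= 0")
            object.__setattr__(self, "k_ps", cleaned)

    def k_ps_at(self, total_dose: float) -> float:
        """Conversion rate for a schedule's total dose; 0 if senescence inactive."""
        if not self.k_ps:
            return 0.0
        key = float(total_dose)
        if key not in self.k_ps:
            raise ConfigurationError(
                f"no k_ps entry for total dose {total_dose} Gy "
                f"(have {sorted(self.k_ps)})"
            )
        return self.k_ps[key]
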