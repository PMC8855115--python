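"""The candidate model family for selection.

Starting from the full two-species model (density- and dose-dependent acute
death, density- and dose-dependent accumulation death, senescent
conversion), one or two parameters are removed at a time, giving eight
candidates:

===  ===================  ===================  ==========
id   acute (early) death  accumulation (late)  senescence
===  ===================  ===================  ==========
1    full                 full                 yes
2    dose only            full                 yes
3    density only         full                 yes
4    none                 full                 yes
5    full                 dose only            yes
6    full                 density only         yes
7    full                 none (r dropped)     yes
8    full                 full                 no
===  ===================  ===================  ==========

Model 3 (acute death driven by seeding density only) is the parsimonious
member typically selected on glioma confluence data; with two total-dose
arms it has six free parameters: ``k_acute_N``, ``alpha_accum_N``,
``k_accum_D``, ``r`` and one ``k_ps`` per total dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .params import RadiationParams

__all__ = ["ModelSpec", "model_family", "DEATH_FORMS"]

DEATH_FORMS = ("full", "dose_only", "density_only", "none")

_EARLY_PARAMS = {
    "full": ("alpha_acute_N", "k_acute_D"),
    "dose_only": ("k_acute_D",),
    "density_only": ("k_acute_N",),
    "none": (),
}
_LATE_PARAMS = {
    "full": ("alpha_accum_N", "k_accum_D"),
    "dose_only": ("k_accum_D",),
    "density_only": ("k_accum_N",),
    "none": (),
}


def _kps_name(dose: float) -> str:
    return f"k_ps_{dose:g}"


@dataclass(frozen=True)
class ModelSpec:
    """One family member: which death/senescence terms are active."""

    id: int
    early_death_form: str
    late_death_form: str
    senescence: bool
    k_ps_doses: tuple = (16.0, 20.0)

    def __post_init__(self):
        if self.early_death_form not in DEATH_FORMS:
            raise ConfigurationError(f"bad early_death_form {self.early_death_form!r}")
        if self.late_death_form not in DEATH_FORMS:
            raise ConfigurationError(f"bad late_death_form {self.late_death_form!r}")
        object.__setattr__(
            self, "k_ps_doses", tuple(float(d) for d in self.k_ps_doses)
        )

    @property
    def free_parameter_names(self) -> tuple:
        names = list(_EARLY_PARAMS[self.early_death_form])
        names += list(_LATE_PARAMS[self.late_death_form])
        if self.late_death_form != "none":
            names.append("r")
        if self.senescence:
            names += [_kps_name(d) for d in self.k_ps_doses]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_parameter_names)

    def params_from_vector(self, vector) -> RadiationParams:
        """Build RadiationParams from an ordered free-parameter vector."""
        vector = np.asarray(vector, dtype=float)
        names = self.free_parameter_names
        if vector.shape != (len(names),):
            raise ConfigurationError(
                f"expected {len(names)} parameters {names}, got shape {vector.shape}"
            )
        kwargs = {}
        k_ps = {}
        for name, value in zip(names, vector):
            if name.startswith("k_ps_"):
                k_ps[float(name[len("k_ps_"):])] = float(value)
            else:
                kwargs[name] = float(value)
        if self.senescence:
            kwargs["k_ps"] = k_ps
        return RadiationParams(**kwargs)

    def vector_from_params(self, params: RadiationParams) -> np.ndarray:
        values = []
        for name in self.free_parameter_names:
            if name.startswith("k_ps_"):
                values.append(params.k_ps_at(float(name[len("k_ps_"):])))
            else:
                value = getattr(params, name)
                if value is None:
                    raise ConfigurationError(f"params missing active field {name}")
                values.append(value)
        return np.asarray(values, dtype=float)

    @property
    def label(self) -> str:
        bits = []
        if self.early_death_form != "full":
            bits.append(f"early:{self.early_death_form}")
        if self.late_death_form != "full":
            bits.append(f"late:{self.late_death_form}")
        if not self.senescence:
            bits.append("no senescence")
        return f"model {self.id} ({', '.join(bits) if bits else 'full'})"


def model_family(k_ps_doses=(16.0, 20.0)) -> list:
    """The eight candidate specs, ordered by id (1 = full model)."""
    doses = tuple(float(d) for d in k_ps_doses)
    return [
        ModelSpec(1, "full", "full", True, doses),
        ModelSpec(2, "dose_only", "full", True, doses),
        ModelSpec(3, "density_only", "full", True, doses),
        ModelSpec(4, "none", "full", True, doses),
        ModelSpec(5, "full", "dose_only", True, doses),
        ModelSpec(6, "full", "density_only", True, doses),
        ModelSpec(7, "full", "none", True, doses),
        ModelSpec(8, "full", "full", False, doses),
    ]
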