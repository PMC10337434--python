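"""Clinical variable schema for the synthetic emergency-department cohort.

The default schema emulates the forty commonly abstracted EHR variables used
for phenotype derivation: three demographics/statics, eight vital-sign
channels, twenty-eight laboratory values and the Charlson comorbidity index.
The exact variable list used on the real cohorts is not public, so this
schema is a declared stand-in; every downstream algorithm is schema-agnostic
and accepts a user-supplied :class:`VariableSchema`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Variable", "VariableSchema", "default_schema", "SchemaError"]

STATIC = "static"
DYNAMIC = "dynamic"

_FAMILIES = ("normal", "lognormal", "binary")


class SchemaError(ValueError):
    """Raised when a table refers to variables absent from the schema."""


@dataclass(frozen=True)
class Variable:
    """One clinical variable.

    Parameters
    ----------
    name : str
        Unique variable name (column identifier in the long tables).
    kind : {"static", "dynamic"}
        Statics are abstracted once at triage and held constant; dynamics are
        sampled at hourly intervals.
    family : {"normal", "lognormal", "binary"}
        Marginal distribution family used by the generator. Lognormal
        variables are right-skewed (e.g. lactate, creatinine) and exercise
        the normality-transform step of preprocessing.
    plausible_range : tuple of float
        (low, high) plausible clinical range on the natural scale; the
        generator centres the variable at the mid-range and scales spread to
        roughly a tenth of the range.
    hourly_rate : float
        Probability per hour bin that a measured patient has an observation
        of this variable in that bin (dynamics only; statics use 1.0).
    """

    name: str
    kind: str
    family: str
    plausible_range: tuple[float, float]
    hourly_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (STATIC, DYNAMIC):
            raise ValueError(f"kind must be static|dynamic, got {self.kind!r}")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        lo, hi = self.plausible_range
        if not lo < hi:
            raise ValueError(f"{self.name}: empty plausible range {self.plausible_range}")
        if self.family == "lognormal" and lo <= 0:
            raise ValueError(f"{self.name}: lognormal range must be positive")
        if not 0.0 <= self.hourly_rate <= 1.0:
            raise ValueError(f"{self.name}: hourly_rate outside [0, 1]")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of :class:`Variable` entries with unique names."""

    entries: tuple[Variable, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [v.name for v in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.entries]

    @property
    def static_names(self) -> list[str]:
        return [v.name for v in self.entries if v.kind == STATIC]

    @property
    def dynamic_names(self) -> list[str]:
        return [v.name for v in self.entries if v.kind == DYNAMIC]

    def __getitem__(self, name: str) -> Variable:
        for v in self.entries:
            if v.name == name:
                return v
        raise SchemaError(f"unknown variable {name!r}")

    def index(self, name: str) -> int:
        for i, v in enumerate(self.entries):
            if v.name == name:
                return i
        raise SchemaError(f"unknown variable {name!r}")


def default_schema() -> VariableSchema:
    """Forty-variable default schema (stand-in; see module docstring)."""
    V = Variable
    entries = (
        # --- statics -----------------------------------------------------
        V("age", STATIC, "normal", (18.0, 100.0)),
        V("sex_male", STATIC, "binary", (0.0, 1.0)),
        V("weight", STATIC, "normal", (40.0, 150.0)),
        V("charlson_index", STATIC, "normal", (0.0, 12.0)),
        # --- vitals (frequent) -------------------------------------------
        V("heart_rate", DYNAMIC, "normal", (40.0, 180.0), 0.9),
        V("sbp", DYNAMIC, "normal", (60.0, 200.0), 0.9),
        V("dbp", DYNAMIC, "normal", (30.0, 120.0), 0.9),
        V("map", DYNAMIC, "normal", (40.0, 140.0), 0.9),
        V("resp_rate", DYNAMIC, "normal", (8.0, 45.0), 0.9),
        V("spo2", DYNAMIC, "normal", (70.0, 100.0), 0.9),
        V("temperature", DYNAMIC, "normal", (34.0, 41.5), 0.9),
        V("gcs", DYNAMIC, "normal", (3.0, 15.0), 0.7),
        # --- chemistry / haematology (drawn once or twice in the ED) -----
        V("wbc", DYNAMIC, "lognormal", (1.0, 40.0), 0.25),
        V("hemoglobin", DYNAMIC, "normal", (5.0, 18.0), 0.25),
        V("hematocrit", DYNAMIC, "normal", (15.0, 55.0), 0.25),
        V("platelets", DYNAMIC, "lognormal", (20.0, 700.0), 0.25),
        V("sodium", DYNAMIC, "normal", (120.0, 160.0), 0.25),
        V("potassium", DYNAMIC, "normal", (2.5, 7.0), 0.25),
        V("chloride", DYNAMIC, "normal", (85.0, 120.0), 0.25),
        V("bicarbonate", DYNAMIC, "normal", (10.0, 35.0), 0.25),
        V("bun", DYNAMIC, "lognormal", (3.0, 120.0), 0.25),
        V("creatinine", DYNAMIC, "lognormal", (0.3, 10.0), 0.25),
        V("glucose", DYNAMIC, "lognormal", (40.0, 600.0), 0.3),
        V("calcium", DYNAMIC, "normal", (6.0, 12.0), 0.25),
        V("magnesium", DYNAMIC, "normal", (1.0, 4.0), 0.2),
        V("phosphate", DYNAMIC, "normal", (1.0, 8.0), 0.2),
        V("albumin", DYNAMIC, "normal", (1.5, 5.5), 0.2),
        V("bilirubin_total", DYNAMIC, "lognormal", (0.2, 15.0), 0.2),
        V("ast", DYNAMIC, "lognormal", (10.0, 1000.0), 0.2),
        V("alt", DYNAMIC, "lognormal", (10.0, 1000.0), 0.2),
        # --- sepsis-oriented labs (severity-dependent ordering) ----------
        V("lactate", DYNAMIC, "lognormal", (0.5, 12.0), 0.3),
        V("inr", DYNAMIC, "lognormal", (0.8, 6.0), 0.2),
        V("fibrinogen", DYNAMIC, "lognormal", (80.0, 800.0), 0.15),
        V("troponin", DYNAMIC, "lognormal", (0.01, 5.0), 0.15),
        V("crp", DYNAMIC, "lognormal", (1.0, 300.0), 0.15),
        V("procalcitonin", DYNAMIC, "lognormal", (0.05, 50.0), 0.15),
        V("band_neutrophils", DYNAMIC, "lognormal", (0.5, 40.0), 0.15),
        V("ph_arterial", DYNAMIC, "normal", (6.9, 7.6), 0.2),
        V("pco2", DYNAMIC, "normal", (20.0, 80.0), 0.2),
        V("po2", DYNAMIC, "normal", (40.0, 300.0), 0.2),
    )
    schema = VariableSchema(entries)
    assert len(schema) == 40
    return schema
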