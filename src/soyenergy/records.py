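"""Domain record types for total-collection feed evaluation trials.

All chemical composition values are stored on a dry-matter (DM) basis,
which is the basis on which energy values of feed ingredients are
conventionally reported. Use :func:`as_fed_to_dm` to convert assay
results reported on an as-fed basis.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "SampleAssay",
    "ProcessingRecord",
    "DietSpec",
    "PigRecord",
    "CollectionRecord",
    "as_fed_to_dm",
]

#: tolerance for the hemicellulose = NDF - ADF additivity check, percentage points
HEMICELLULOSE_TOL = 0.2


def as_fed_to_dm(value: float, dm_pct: float) -> float:
    """Convert an as-fed concentration to a dry-matter basis.

    Parameters
    ----------
    value
        Concentration on an as-fed basis (any per-mass unit).
    dm_pct
        Dry-matter content of the material, percent (0 < dm_pct <= 100).
    """
    if not 0 < dm_pct <= 100:
        raise ValueError(f"dm_pct must be in (0, 100], got {dm_pct}")
    return value * 100.0 / dm_pct


class _Record(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SampleAssay(_Record):
    """Chemical composition, quality indicators and gross energy of one
    soybean batch, DM basis.

    ``ua`` is ureatic activity (ΔpH rise from urease-released ammonia, a
    residual-antinutritional-factor proxy); ``ps`` is protein solubility in
    dilute KOH (%, a heat-damage proxy).
    """

    sample_id: str
    plant_id: str
    dehulled: bool
    cp: float
    ee: float
    ash: float
    cf: float
    adf: float
    ndf: float
    hemicellulose: float
    ca: float
    p: float
    phytic_p: float
    ua: float
    ps: float
    soluble_protein: float
    ge: float
    amino_acids: Optional[dict[str, float]] = None

    _PCT_FIELDS = (
        "cp", "ee", "ash", "cf", "adf", "ndf", "hemicellulose",
        "ca", "p", "phytic_p", "ps", "soluble_protein",
    )

    @model_validator(mode="after")
    def _check(self) -> "SampleAssay":
        for f in self._PCT_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{f} must be in [0, 100], got {v}")
        if self.ua < 0:
            raise ValueError(f"ua must be >= 0, got {self.ua}")
        if self.ge <= 0:
            raise ValueError(f"ge must be > 0, got {self.ge}")
        if self.ndf < self.adf:
            raise ValueError(f"ndf ({self.ndf}) must be >= adf ({self.adf})")
        if abs(self.hemicellulose - (self.ndf - self.adf)) > HEMICELLULOSE_TOL:
            raise ValueError(
                f"hemicellulose ({self.hemicellulose}) inconsistent with "
                f"ndf - adf ({self.ndf - self.adf:.3f})"
            )
        return self


class ProcessingRecord(_Record):
    """Thermal-processing parameters of one industrial plant.

    Time in seconds, temperature in °C, steam pressure in kgf/cm², final
    grain moisture in percent.
    """

    plant_id: str
    time_s: float
    temperature_c: float
    pressure: float
    final_moisture: float

    @model_validator(mode="after")
    def _check(self) -> "ProcessingRecord":
        if self.time_s <= 0:
            raise ValueError(f"time_s must be > 0, got {self.time_s}")
        if self.temperature_c <= 0:
            raise ValueError(
                f"temperature_c must be > 0, got {self.temperature_c}")
        if not 0 <= self.final_moisture < 100:
            raise ValueError(
                f"final_moisture must be in [0, 100), got {self.final_moisture}")
        return self


class DietSpec(_Record):
    """A reference diet or a test diet in which the ingredient under
    evaluation replaces fraction ``p`` of the reference diet."""

    diet_id: str
    role: Literal["reference", "test"]
    experiment_id: str
    reference_diet_id: Optional[str] = None
    p: float = 0.30
    sample_id: Optional[str] = None
    cp: float
    ge: float

    @model_validator(mode="after")
    def _check(self) -> "DietSpec":
        if self.role == "test":
            if not 0 < self.p < 1:
                raise ValueError(f"test diet p must be in (0, 1), got {self.p}")
            if self.sample_id is None:
                raise ValueError("test diet requires sample_id")
            if self.reference_diet_id is None:
                raise ValueError("test diet requires reference_diet_id")
        else:
            if self.sample_id is not None:
                raise ValueError("reference diet must not carry a sample_id")
        return self


class PigRecord(_Record):
    """One pig of a balance trial; ``metabolic_weight`` is BW^0.75, the
    allometric base used for feed allocation."""

    pig_id: str
    block_id: str
    diet_id: str
    body_weight: float
    metabolic_weight: Optional[float] = None
    adaptation_intake: float

    @model_validator(mode="after")
    def _check(self) -> "PigRecord":
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        mw = self.body_weight ** 0.75
        if self.metabolic_weight is None:
            object.__setattr__(self, "__dict__",
                               {**self.__dict__, "metabolic_weight": mw})
        elif abs(self.metabolic_weight - mw) > 1e-9:
            raise ValueError(
                f"metabolic_weight ({self.metabolic_weight}) != "
                f"body_weight^0.75 ({mw})"
            )
        return self


class CollectionRecord(_Record):
    """Totals of one pig over the collection period: feed intake (kg DM),
    feed GE (kcal/kg DM) and N (g/kg DM), fecal DM (kg) with its GE and N
    per kg fecal DM, and total urinary GE (kcal) and N (g)."""

    pig_id: str
    feed_intake_dm: float
    feed_ge: float
    feed_n: float
    fecal_dm: float
    fecal_ge: float
    fecal_n: float
    urine_ge: float
    urine_n: float

    @field_validator("feed_ge", "feed_n", "fecal_ge", "fecal_n",
                     "urine_ge", "urine_n", "fecal_dm")
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CollectionRecord":
        if self.feed_intake_dm <= 0:
            raise ValueError(
                f"feed_intake_dm must be > 0, got {self.feed_intake_dm}")
        if self.fecal_dm > self.feed_intake_dm:
            raise ValueError(
                f"fecal_dm ({self.fecal_dm}) exceeds feed_intake_dm "
                f"({self.feed_intake_dm})"
            )
        return self
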