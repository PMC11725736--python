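"""Processing energy: moisture-dependent specific heat and the energy
applied per kg of sample (EAS) during thermal deactivation.

SH(kJ/kg) = 0.391 + 0.461·M/(100+M), with M the final grain moisture in
percent; EAS(cal/kg) = SH(cal/kg) × time(min) × temperature(°C).
Temperature enters in °C and time in minutes, exactly as the formula is
defined for hermetic-reactor deactivation; plant processing times are
recorded in seconds and converted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import ProcessingRecord

__all__ = ["KJ_TO_CAL", "EasResult", "specific_heat", "energy_applied", "eas_table"]

#: kJ -> cal conversion, 4.1868 x 1000
KJ_TO_CAL = 4186.8


@dataclass(frozen=True)
class EasResult:
    """Specific heat (kJ/kg and cal/kg) and energy applied (Mcal/kg)."""

    sh_kj: float
    sh_cal: float
    eas_mcal: float


def specific_heat(moisture: float) -> float:
    """Specific heat of the grain, kJ/kg, from moisture M in percent."""
    if not 0 <= moisture < 100:
        raise ValueError(f"moisture must be in [0, 100), got {moisture}")
    return 0.391 + 0.461 * moisture / (100.0 + moisture)


def energy_applied(record: ProcessingRecord) -> EasResult:
    """Energy applied per kg of sample for one plant's processing regime.

    ``eas_mcal = SH(cal/kg) × time(min) × temperature(°C) / 10^6``.
    """
    if record.time_s <= 0:
        raise ValueError(f"time_s must be > 0, got {record.time_s}")
    if record.temperature_c <= 0:
        raise ValueError(
            f"temperature_c must be > 0, got {record.temperature_c}")
    sh_kj = specific_heat(record.final_moisture)
    sh_cal = sh_kj * KJ_TO_CAL
    eas_mcal = sh_cal * (record.time_s / 60.0) * record.temperature_c / 1e6
    return EasResult(sh_kj=sh_kj, sh_cal=sh_cal, eas_mcal=eas_mcal)


def eas_table(records: list[ProcessingRecord]) -> pd.DataFrame:
    """EAS per plant as a tidy frame: plant_id, sh_kj, sh_cal, eas_mcal."""
    rows = []
    for rec in records:
        r = energy_applied(rec)
        rows.append({"plant_id": rec.plant_id, "sh_kj": r.sh_kj,
                     "sh_cal": r.sh_cal, "eas_mcal": r.eas_mcal})
    return pd.DataFrame(rows)
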