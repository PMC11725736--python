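"""Packaged reference data from a published multi-plant survey of
full-fat deactivated soybeans fed to growing pigs.

Four small CSVs ship with the package:

- ``plant_processing``: standard processing regimes (time, temperature,
  pressure, final moisture) of five industrial hermetic-reactor plants.
- ``diet_energy``: diet-level feed intake, crude protein and DE/ME/MEn
  of the 10 reference diets and 14 test diets of the survey's ten
  total-collection experiments.
- ``composition_stats``: mean/SD/min/max of the chemical composition,
  quality indicators, processing energy and energy values of the 14
  soybean samples (DM basis); these parameterise the synthetic
  generator's defaults.
- ``equations`` / ``equation_terms``: the survey's published AIC-ranked
  prediction equations for DE, ME and MEn with their coefficients.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import ProcessingRecord

__all__ = [
    "load_plant_processing",
    "plant_records",
    "load_diet_energy",
    "load_composition_stats",
    "load_equations",
    "load_equation_terms",
    "equation_coefficients",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("soyenergy.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_plant_processing() -> pd.DataFrame:
    """Processing regimes of the five plants (one row per plant)."""
    df = _read("plant_processing.csv")
    df["plant_id"] = df["plant_id"].astype(str)
    return df


def plant_records() -> list[ProcessingRecord]:
    """Plant regimes as validated :class:`ProcessingRecord` objects."""
    return [
        ProcessingRecord(
            plant_id=str(r.plant_id), time_s=r.time_s,
            temperature_c=r.temperature_c, pressure=r.pressure_kgf_cm2,
            final_moisture=r.final_moisture_pct,
        )
        for r in load_plant_processing().itertuples()
    ]


def load_diet_energy() -> pd.DataFrame:
    """Diet-level DFI (kg/d), CP (% DM) and energy values (kcal/kg DM)."""
    return _read("diet_energy.csv")


def load_composition_stats() -> pd.DataFrame:
    """Descriptive statistics of the 14 samples, indexed by variable."""
    return _read("composition_stats.csv").set_index("variable")


def load_equations() -> pd.DataFrame:
    """Published equation summaries: response, number, AIC, R², UA maximum."""
    return _read("equations.csv")


def load_equation_terms() -> pd.DataFrame:
    """Published equation coefficients in long form (response, eq_no, term)."""
    return _read("equation_terms.csv")


def equation_coefficients(response: str, eq_no: int) -> dict[str, float]:
    """Coefficient map (term -> value) of one published equation."""
    df = load_equation_terms()
    sel = df[(df["response"] == response) & (df["eq_no"] == eq_no)]
    if sel.empty:
        raise KeyError(f"no published equation {response} #{eq_no}")
    return dict(zip(sel["term"], sel["coefficient"]))
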