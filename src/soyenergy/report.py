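"""Pipeline orchestration and publication-style report tables.

``run_pipeline`` takes validated trial tables and executes the full
analysis: plant processing energy → per-pig/per-diet energy balance →
substitution-method sample energies → descriptive statistics →
unpeeled-vs-dehulled comparison → correlations → AIC-ranked equation
search. Outputs are full-precision CSVs plus a JSON manifest (seed,
config hash, package version); display rounding is applied only by the
``report`` CLI subcommand.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .balance import K_N_DEFAULT, DietBalance, diet_energy, ingredient_energy
from .io import read_table
from .modeling import (
    FitResult,
    compare_groups,
    correlate,
    pvalue_table,
    ranking_table,
    search,
)
from .processing import eas_table
from .records import CollectionRecord, DietSpec, PigRecord, SampleAssay

log = logging.getLogger("soyenergy")

__all__ = ["SearchConfig", "RunConfig", "diet_results", "sample_energy_table",
           "predictor_table", "run_pipeline"]

DEFAULT_POOL = ("CF", "UA", "P", "CP", "NDF", "PS", "PP", "EAS", "ASH")

#: sample/processing field -> predictor column name used in equations
PREDICTOR_MAP = {
    "cp": "CP", "ee": "EE", "ash": "ASH", "cf": "CF", "adf": "ADF",
    "ndf": "NDF", "hemicellulose": "HEM", "ca": "CA", "p": "P",
    "phytic_p": "PPHY", "ua": "UA", "ps": "PS", "soluble_protein": "SOLP",
    "ge": "GE",
}


class SearchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pool: tuple[str, ...] = DEFAULT_POOL
    quadratic: tuple[str, ...] = ("UA",)
    interactions: tuple[tuple[str, str], ...] = ()
    max_terms: Optional[int] = 5


class RunConfig(BaseModel):
    """Paths and options of one pipeline run (YAML-serialisable)."""

    model_config = ConfigDict(extra="forbid")

    samples: str
    processing: str
    diets: str
    pigs: str
    collection: str
    outdir: str = "out"
    k_n: float = K_N_DEFAULT
    substitution_mode: Literal["naive", "dm_corrected"] = "naive"
    dm_fracs: Optional[tuple[float, float]] = None
    search: SearchConfig = SearchConfig()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def diet_results(pigs: Sequence[PigRecord],
                 collections: Sequence[CollectionRecord],
                 k_n: float = K_N_DEFAULT) -> dict[str, DietBalance]:
    """Per-diet balance results keyed by diet_id."""
    diet_of = {p.pig_id: p.diet_id for p in pigs}
    by_diet: dict[str, list[CollectionRecord]] = {}
    for rec in collections:
        if rec.pig_id not in diet_of:
            raise ValueError(f"collection row for unknown pig '{rec.pig_id}'")
        by_diet.setdefault(diet_of[rec.pig_id], []).append(rec)
    return {d: diet_energy(recs, k_n=k_n) for d, recs in sorted(by_diet.items())}


def sample_energy_table(diets: Sequence[DietSpec],
                        results: dict[str, DietBalance],
                        mode: str = "naive",
                        dm_fracs: Optional[tuple[float, float]] = None,
                        ) -> pd.DataFrame:
    """Substitution-method DE/ME/MEn per sample (kcal/kg DM).

    Samples evaluated in more than one experiment are averaged over
    their test diets.
    """
    spec_by_id = {d.diet_id: d for d in diets}
    rows = []
    for d in diets:
        if d.role != "test" or d.diet_id not in results:
            continue
        rd = results[spec_by_id[d.reference_diet_id].diet_id]
        td = results[d.diet_id]
        row = {"sample_id": d.sample_id, "experiment_id": d.experiment_id}
        for attr in ("de", "me", "men"):
            row[attr] = ingredient_energy(
                getattr(td.energy, attr), getattr(rd.energy, attr),
                d.p, mode=mode, dm_fracs=dm_fracs)
        rows.append(row)
    df = pd.DataFrame(rows)
    return (df.groupby("sample_id", as_index=False)[["de", "me", "men"]]
            .mean().sort_values("sample_id", ignore_index=True))


def predictor_table(samples: Sequence[SampleAssay],
                    processing: Sequence, energies: pd.DataFrame) -> pd.DataFrame:
    """Merged sample-level table of responses and predictors.

    Composition fields map to the conventional predictor names (CF, UA,
    P, ...); plant processing contributes TIM (s), TPT (°C), PP
    (kgf/cm²) and EAS (Mcal/kg); responses are DE/ME/MEn.
    """
    plant_rec = {p.plant_id: p for p in processing}
    plant_eas = eas_table(list(plant_rec.values())
                          ).set_index("plant_id")["eas_mcal"]
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "dehulled": s.dehulled}
        for f, name in PREDICTOR_MAP.items():
            row[name] = getattr(s, f)
        proc = plant_rec[s.plant_id]
        row.update({"TIM": proc.time_s, "TPT": proc.temperature_c,
                    "PP": proc.pressure, "EAS": float(plant_eas[s.plant_id])})
        rows.append(row)
    df = pd.DataFrame(rows)
    merged = df.merge(energies.rename(
        columns={"de": "DE", "me": "ME", "men": "MEn"}), on="sample_id")
    return merged


def _descriptive(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in cols:
        v = table[c].to_numpy(float)
        rows.append({"variable": c, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=1), "minimum": v.min(),
                     "maximum": v.max()})
    return pd.DataFrame(rows)


def _comparison(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    unp = table[~table["dehulled"]]
    deh = table[table["dehulled"]]
    rows = []
    for c in cols:
        res = compare_groups(unp[c], deh[c], assumption="pooled")
        rows.append({"variable": c,
                     "unpeeled_mean": res.mean_a, "unpeeled_se": res.se_a,
                     "dehulled_mean": res.mean_b, "dehulled_se": res.se_b,
                     "t": res.t, "p": res.p})
    return pd.DataFrame(rows)


def _correlations(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in predictors:
        row = {"variable": c}
        for resp in ("DE", "ME", "MEn"):
            res = correlate(table[c], table[resp])
            row[f"r_{resp}"] = res.r
            row[f"p_{resp}"] = res.p
        rows.append(row)
    return pd.DataFrame(rows)


def _curve_table(fit: FitResult, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted response over the observed UA range, other predictors at
    their means (figure analogue)."""
    ua = np.linspace(table["UA"].min(), table["UA"].max(), 101)
    y = np.zeros_like(ua)
    for term, b in fit.coefficients.items():
        if term == "intercept":
            y += b
        elif term == "UA":
            y += b * ua
        elif term == "UA^2":
            y += b * ua ** 2
        else:
            y += b * float(table[term].mean())
    return pd.DataFrame({"UA": ua, "predicted": y})


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a name -> path map of the written artifacts. Every stage
    failure is re-raised with the stage name prepended.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}': {exc}") from exc

    samples = stage("read samples", read_table, config.samples, "samples")
    processing = stage("read processing", read_table, config.processing,
                       "processing")
    diets = stage("read diets", read_table, config.diets, "diets")
    pigs = stage("read pigs", read_table, config.pigs, "pigs")
    collections = stage("read collection", read_table, config.collection,
                        "collection")

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    emit("plant_eas", stage("processing energy", eas_table, processing))

    results = stage("energy balance", diet_results, pigs, collections,
                    config.k_n)
    spec_by_id = {d.diet_id: d for d in diets}
    diet_rows = []
    for diet_id, res in results.items():
        spec = spec_by_id[diet_id]
        diet_rows.append({
            "experiment_id": spec.experiment_id, "diet_id": diet_id,
            "role": spec.role, "sample_id": spec.sample_id,
            "intake_dm_kg": float(np.mean(
                [r.feed_intake_dm for r in
                 [c for c in collections
                  if {p.pig_id: p.diet_id for p in pigs}[c.pig_id] == diet_id]])),
            "cp": spec.cp, "de": res.energy.de, "me": res.energy.me,
            "men": res.energy.men, "me_de": res.energy.me_de_ratio,
            "men_de": res.energy.men_de_ratio, "caddm": res.balance.caddm,
            "cadcp": res.balance.cadcp, "n_balance": res.balance.n_balance,
            "bv": res.balance.bv,
        })
    emit("diet_energy", pd.DataFrame(diet_rows).sort_values(
        ["experiment_id", "role", "diet_id"],
        ascending=[True, False, True], ignore_index=True))

    energies = stage("substitution", sample_energy_table, diets, results,
                     config.substitution_mode, config.dm_fracs)
    emit("sample_energy", energies)

    table = stage("predictor table", predictor_table, samples, processing,
                  energies)
    emit("predictor_table", table)

    numeric = [c for c in table.columns if c not in ("sample_id", "dehulled")]
    emit("descriptive_stats", stage("descriptive stats", _descriptive,
                                    table, numeric))
    emit("group_comparison", stage("group comparison", _comparison,
                                   table, numeric))
    predictors = [c for c in numeric if c not in ("DE", "ME", "MEn")]
    emit("correlations", stage("correlations", _correlations, table,
                               predictors))

    sc = config.search
    for resp in ("DE", "ME", "MEn"):
        fits = stage(f"model search {resp}", search, table, resp,
                     list(sc.pool), list(sc.quadratic),
                     [tuple(i) for i in sc.interactions], sc.max_terms)
        emit(f"equations_{resp}", ranking_table(fits))
        emit(f"pvalues_{resp}", pvalue_table(fits))
        best_quad = next((f for f in fits if f.ua_opt is not None), None)
        if best_quad is not None:
            emit(f"curve_{resp}", _curve_table(best_quad, table))

    manifest = {
        "package": "soyenergy",
        "version": __version__,
        "seed": config.seed,
        "k_n": config.k_n,
        "substitution_mode": config.substitution_mode,
        "config_sha256": hashlib.sha256(
            config.model_dump_json().encode()).hexdigest(),
        "tables": {k: str(v) for k, v in written.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    log.info("wrote %d artifacts to %s", len(written), outdir)
    return written
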