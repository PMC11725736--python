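"""Synthetic soybean samples, processing records and pig balance trials.

The generator emulates the structure of a multi-plant survey: samples
drawn from truncated normals at published composition means/SDs, plants
assigned round-robin from the packaged processing regimes, and a
ten-experiment total-collection trial layout (1–3 samples per
experiment, a reference diet in every experiment, eight pigs per diet,
feed allotted per kg of metabolic weight within weight blocks).

A planted "true" MEn surface — linear in protein solubility (PS) and
crude fiber (CF), quadratic in ureatic activity (UA) with a concave
maximum — defines each sample's energy value; the pig-level collection
records are back-solved from the target diet energies plus pig noise, so
running the balance and substitution pipeline on a noise-free trial
returns the planted truths exactly. This makes the generator an
inverse-consistency oracle for the analysis rather than a mechanistic
digestion model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import truncnorm

from . import datasets
from .balance import K_N_DEFAULT, allocate_feed
from .io import write_table
from .records import (
    CollectionRecord,
    DietSpec,
    PigRecord,
    ProcessingRecord,
    SampleAssay,
)

__all__ = ["TrueModel", "GeneratorConfig", "gen_samples", "gen_true_energy",
           "gen_trial", "simulate_bundle"]

#: experiment sizes (samples per experiment), cycled; the first 14 samples
#: fall into ten experiments as in the survey design
EXPERIMENT_PATTERN = (2, 1, 1, 2, 1, 1, 1, 1, 3, 1)

#: truncation bounds per composition field (generator policy, not biology)
_BOUNDS = {
    "ua": (0.005, 0.2),
    "ps": (60.0, 95.0),
    "ge": (4000.0, 8000.0),
}
_PCT_BOUNDS = (0.0, 100.0)

# fields drawn directly; ndf is derived as adf + hemicellulose
_DRAWN_FIELDS = ("cp", "ee", "ash", "cf", "adf", "hemicellulose", "ca", "p",
                 "phytic_p", "ua", "ps", "soluble_protein", "ge")


def _default_moments() -> tuple[dict[str, float], dict[str, float]]:
    stats = datasets.load_composition_stats()
    means = {f: float(stats.loc[f, "mean"]) for f in _DRAWN_FIELDS}
    sds = {f: float(stats.loc[f, "sd"]) for f in _DRAWN_FIELDS}
    return means, sds


class TrueModel(BaseModel):
    """Planted MEn surface and the DE/ME offsets above it (kcal/kg DM).

    Defaults place the concave UA maximum at 0.045 ΔpH with slopes of
    the magnitude seen in published prediction equations, and anchor the
    mean energy near the published survey means (DE−MEn = 214,
    ME−MEn = 113 kcal/kg DM).
    """

    model_config = ConfigDict(extra="forbid")

    intercept: float = 2827.0       # kcal/kg DM
    ps_slope: float = 18.5          # kcal per % PS
    cf_slope: float = -51.0         # kcal per % CF
    ua_lin: float = 10500.0         # kcal per ΔpH
    ua_quad: float = -116666.667    # kcal per ΔpH²
    sample_noise_sd: float = 30.0   # kcal/kg DM
    de_gap: float = 214.0           # DE − MEn
    me_gap: float = 113.0           # ME − MEn

    @property
    def planted_optimum(self) -> float:
        return -self.ua_lin / (2.0 * self.ua_quad)

    @model_validator(mode="after")
    def _check(self) -> "TrueModel":
        if self.sample_noise_sd < 0:
            raise ValueError("sample_noise_sd must be >= 0")
        if self.ua_quad < 0 and not 0 < self.planted_optimum < 0.2:
            raise ValueError(
                f"planted UA optimum {self.planted_optimum:.4f} outside (0, 0.2)")
        if not self.de_gap >= self.me_gap >= 0:
            raise ValueError("need de_gap >= me_gap >= 0")
        return self

    def men(self, ps, cf, ua):
        return (self.intercept + self.ps_slope * ps + self.cf_slope * cf
                + self.ua_lin * ua + self.ua_quad * ua ** 2)


class GeneratorConfig(BaseModel):
    """Study conditions of the synthetic trial.

    Counts, body weights and the inclusion rate default to the survey
    design (14 samples, 8 pigs per diet, BW 51.4±5.4 kg, 30%
    substitution); composition moments default to the published
    per-sample descriptive statistics.
    """

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n_samples: int = 14
    n_pigs_per_diet: int = 8
    seed: int = 0
    composition_means: Optional[dict[str, float]] = None
    composition_sds: Optional[dict[str, float]] = None
    plant_params: Optional[list[ProcessingRecord]] = None
    true_model: TrueModel = TrueModel()
    pig_noise_sd: float = 30.0      # kcal/kg DM, per-pig energy noise
    bw_mean: float = 51.4           # kg
    bw_sd: float = 5.4
    inclusion: float = 0.30         # substitution fraction p
    k_n: float = K_N_DEFAULT        # kcal/g retained N used to back-solve
    # reference-diet constants (corn–soybean-meal diet, DM basis)
    rd_de: float = 3870.0
    rd_me: float = 3775.0
    rd_men: float = 3690.0
    rd_cp: float = 18.2             # % DM
    rd_ge: float = 4400.0           # kcal/kg DM
    collection_days: int = 5
    diet_dm_frac: float = 0.88      # kg DM per kg as-fed feed
    fecal_ge: float = 4300.0        # kcal/kg fecal DM
    fecal_n_frac: float = 0.13      # fecal N as fraction of N intake
    cmw_mean: float = 88.0          # g feed / kg^0.75 / d, block-level
    cmw_sd: float = 4.0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_samples <= 0 or self.n_pigs_per_diet <= 0:
            raise ValueError("counts must be > 0")
        if self.pig_noise_sd < 0 or self.bw_sd < 0 or self.cmw_sd < 0:
            raise ValueError("sds must be >= 0")
        if not 0 < self.inclusion < 1:
            raise ValueError(f"inclusion must be in (0, 1), got {self.inclusion}")
        if not self.rd_de >= self.rd_me >= self.rd_men:
            raise ValueError("need rd_de >= rd_me >= rd_men")
        if self.composition_sds is not None:
            if any(v < 0 for v in self.composition_sds.values()):
                raise ValueError("composition sds must be >= 0")
        return self

    def moments(self) -> tuple[dict[str, float], dict[str, float]]:
        means, sds = _default_moments()
        if self.composition_means:
            means.update(self.composition_means)
        if self.composition_sds:
            sds.update(self.composition_sds)
        return means, sds

    def plants(self) -> list[ProcessingRecord]:
        return self.plant_params or datasets.plant_records()


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_samples(config: GeneratorConfig,
                rng: Optional[np.random.Generator] = None,
                ) -> tuple[list[SampleAssay], list[ProcessingRecord]]:
    """Draw sample assays and their plant processing records.

    Per-field truncated normals (percentages clipped to [0, 100], UA to
    [0.005, 0.2], PS to [60, 95]); NDF is built as ADF + hemicellulose so
    the fiber additivity invariant holds by construction. Plants are
    assigned round-robin; unpeeled/dehulled alternates.
    """
    rng = rng or np.random.default_rng(config.seed)
    means, sds = config.moments()
    n = config.n_samples
    draws = {}
    for f in _DRAWN_FIELDS:
        lo, hi = _BOUNDS.get(f, _PCT_BOUNDS)
        draws[f] = _tnorm(rng, means[f], sds[f], lo, hi, n)
    ndf = np.minimum(draws["adf"] + draws["hemicellulose"], 100.0)

    plants = config.plants()
    samples = []
    for i in range(n):
        plant = plants[i % len(plants)]
        samples.append(SampleAssay(
            sample_id=f"S{i + 1:02d}", plant_id=plant.plant_id,
            dehulled=bool(i % 2),
            cp=draws["cp"][i], ee=draws["ee"][i], ash=draws["ash"][i],
            cf=draws["cf"][i], adf=draws["adf"][i], ndf=float(ndf[i]),
            hemicellulose=draws["hemicellulose"][i], ca=draws["ca"][i],
            p=draws["p"][i], phytic_p=draws["phytic_p"][i],
            ua=draws["ua"][i], ps=draws["ps"][i],
            soluble_protein=draws["soluble_protein"][i], ge=draws["ge"][i],
        ))
    used = [plants[i % len(plants)] for i in range(n)]
    return samples, used


def gen_true_energy(samples: Sequence[SampleAssay], config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-sample true energies: MEn from the planted surface plus sample
    noise, with DE and ME at fixed offsets above it."""
    rng = rng or np.random.default_rng(config.seed + 1)
    tm = config.true_model
    rows = []
    noise = rng.normal(0.0, tm.sample_noise_sd, len(samples)) \
        if tm.sample_noise_sd > 0 else np.zeros(len(samples))
    for s, eps in zip(samples, noise):
        men = tm.men(s.ps, s.cf, s.ua) + float(eps)
        rows.append({"sample_id": s.sample_id, "men": men,
                     "me": men + tm.me_gap, "de": men + tm.de_gap})
    return pd.DataFrame(rows)


@dataclass
class _Diet:
    spec: DietSpec
    de: float
    me: float
    men: float


def _experiment_chunks(n: int) -> list[list[int]]:
    chunks, i, k = [], 0, 0
    while i < n:
        size = min(EXPERIMENT_PATTERN[k % len(EXPERIMENT_PATTERN)], n - i)
        chunks.append(list(range(i, i + size)))
        i += size
        k += 1
    return chunks


def gen_trial(samples: Sequence[SampleAssay], truths: pd.DataFrame,
              config: GeneratorConfig,
              rng: Optional[np.random.Generator] = None,
              ) -> tuple[list[PigRecord], list[CollectionRecord], list[DietSpec]]:
    """Back-solve a full balance trial from the planted sample energies.

    Test-diet energies invert the naive substitution formula,
    ``e_td = (1−p)·e_rd + p·e_sample``; each pig's collection record is
    then solved from its target energies (diet truth + noise) so that the
    balance equations return those targets identically. Draws that would
    imply negative masses are resampled (up to 100 attempts per pig).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    truth_map = truths.set_index("sample_id")
    p = config.inclusion
    k_n = config.k_n

    pigs: list[PigRecord] = []
    collections: list[CollectionRecord] = []
    diet_specs: list[DietSpec] = []

    for e_idx, chunk in enumerate(_experiment_chunks(len(samples)), start=1):
        exp_id = f"E{e_idx:02d}"
        rd_id = f"{exp_id}-RD"
        diets = [_Diet(
            spec=DietSpec(diet_id=rd_id, role="reference", experiment_id=exp_id,
                          cp=config.rd_cp, ge=config.rd_ge),
            de=config.rd_de, me=config.rd_me, men=config.rd_men)]
        for i in chunk:
            s = samples[i]
            t = truth_map.loc[s.sample_id]
            diets.append(_Diet(
                spec=DietSpec(
                    diet_id=f"{exp_id}-TD-{s.sample_id}", role="test",
                    experiment_id=exp_id, reference_diet_id=rd_id, p=p,
                    sample_id=s.sample_id,
                    cp=(1 - p) * config.rd_cp + p * s.cp,
                    ge=(1 - p) * config.rd_ge + p * s.ge),
                de=(1 - p) * config.rd_de + p * float(t["de"]),
                me=(1 - p) * config.rd_me + p * float(t["me"]),
                men=(1 - p) * config.rd_men + p * float(t["men"])))
        diet_specs.extend(d.spec for d in diets)

        # one weight block per replicate, one pig per diet in each block
        for b in range(1, config.n_pigs_per_diet + 1):
            block_id = f"{exp_id}-B{b}"
            bw = _tnorm(rng, config.bw_mean, config.bw_sd, 20.0, 120.0,
                        len(diets))
            cmw = float(_tnorm(rng, config.cmw_mean, config.cmw_sd,
                               50.0, 130.0, 1)[0])
            block_pigs = [
                PigRecord(pig_id=f"{block_id}-{d.spec.diet_id}",
                          block_id=block_id, diet_id=d.spec.diet_id,
                          body_weight=float(w),
                          adaptation_intake=cmw * float(w) ** 0.75)
                for d, w in zip(diets, bw)
            ]
            lightest = min(block_pigs, key=lambda q: q.body_weight)
            plan = allocate_feed(block_pigs, lightest.adaptation_intake)
            pigs.extend(block_pigs)

            for pig, diet in zip(block_pigs, diets):
                dmi = (plan.allocations[pig.pig_id] / 1000.0
                       * config.collection_days * config.diet_dm_frac)
                collections.append(_solve_collection(
                    pig, diet, dmi, config, k_n, rng))
    return pigs, collections, diet_specs


def _solve_collection(pig: PigRecord, diet: _Diet, dmi: float,
                      config: GeneratorConfig, k_n: float,
                      rng: np.random.Generator) -> CollectionRecord:
    feed_n = diet.spec.cp * 10.0 / 6.25  # g N per kg DM
    for _ in range(100):
        me_pig = diet.me + (rng.normal(0.0, config.pig_noise_sd)
                            if config.pig_noise_sd > 0 else 0.0)
        de_pig = me_pig + (diet.de - diet.me)
        men_pig = me_pig - (diet.me - diet.men)

        fecal_dm = (diet.spec.ge - de_pig) * dmi / config.fecal_ge
        urine_ge = (de_pig - me_pig) * dmi
        nb = (me_pig - men_pig) * dmi / k_n if k_n > 0 else 0.0
        n_in = feed_n * dmi
        n_fec_total = config.fecal_n_frac * n_in
        urine_n = n_in - n_fec_total - nb
        if (0 <= fecal_dm <= dmi and urine_ge >= 0 and urine_n >= 0
                and n_fec_total >= 0):
            return CollectionRecord(
                pig_id=pig.pig_id, feed_intake_dm=dmi, feed_ge=diet.spec.ge,
                feed_n=feed_n, fecal_dm=fecal_dm, fecal_ge=config.fecal_ge,
                fecal_n=(n_fec_total / fecal_dm if fecal_dm > 0 else 0.0),
                urine_ge=urine_ge, urine_n=urine_n)
    raise RuntimeError(
        f"could not back-solve nonnegative masses for pig {pig.pig_id} "
        f"after 100 attempts")


def simulate_bundle(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full trial and write the five CSV tables plus truths.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples, plants = gen_samples(config, rng)
    truths = gen_true_energy(samples, config, rng)
    pigs, collections, diets = gen_trial(samples, truths, config, rng)

    unique_plants = list({pl.plant_id: pl for pl in plants}.values())
    paths = {
        "samples": write_table(samples, outdir / "samples.csv"),
        "processing": write_table(unique_plants, outdir / "processing.csv"),
        "diets": write_table(diets, outdir / "diets.csv"),
        "pigs": write_table(pigs, outdir / "pigs.csv"),
        "collection": write_table(collections, outdir / "collection.csv"),
    }
    truths_path = outdir / "truths.csv"
    truths.to_csv(truths_path, index=False)
    paths["truths"] = truths_path
    return paths
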