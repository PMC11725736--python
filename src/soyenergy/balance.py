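"""Energy and nitrogen balance from total-collection records.

Implements the classical total-collection equations: digestible energy
(DE) as gross energy intake minus fecal gross energy, metabolizable
energy (ME) as DE minus urinary gross energy, and ME corrected to zero
nitrogen retention (MEn) by subtracting ``k_n`` kcal per g of retained
nitrogen. Ingredient energy is obtained by the substitution method from
a reference diet (RD) and a test diet (TD) in which the ingredient
replaces fraction ``p`` of the RD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .records import CollectionRecord, PigRecord

__all__ = [
    "K_N_DEFAULT",
    "AllocationPlan",
    "BalanceResult",
    "EnergyValues",
    "PigBalance",
    "DietBalance",
    "allocate_feed",
    "pig_balance",
    "diet_energy",
    "ingredient_energy",
]

#: nitrogen-correction constant, kcal per g retained N (swine convention)
K_N_DEFAULT = 7.45


@dataclass(frozen=True)
class AllocationPlan:
    """Feed allocation of one weight block: grams/day per pig, all pigs
    receiving the same amount per kg of metabolic weight (CMW)."""

    block_id: str
    cmw: float                      # g feed per kg^0.75 per day
    allocations: dict[str, float]   # pig_id -> g/d


@dataclass(frozen=True)
class BalanceResult:
    """Digestibility coefficients and nitrogen balance of one pig."""

    caddm: float        # apparent DM digestibility, %
    cadcp: float        # apparent CP digestibility, %
    n_intake: float     # g
    n_feces: float      # g
    n_urine: float      # g
    n_balance: float    # g retained
    bv: Optional[float]  # biological value of protein, %; None if undefined


@dataclass(frozen=True)
class EnergyValues:
    """DE/ME/MEn (kcal/kg DM) with ME/DE and MEn/DE ratio diagnostics."""

    de: float
    me: float
    men: float
    me_de_ratio: float = field(init=False)
    men_de_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "me_de_ratio", 100.0 * self.me / self.de)
        object.__setattr__(self, "men_de_ratio", 100.0 * self.men / self.de)


@dataclass(frozen=True)
class PigBalance:
    pig_id: str
    energy: EnergyValues
    balance: BalanceResult


@dataclass(frozen=True)
class DietBalance:
    """Per-pig results plus unweighted diet means."""

    pigs: list[PigBalance]
    energy: EnergyValues        # mean DE/ME/MEn over pigs
    balance: BalanceResult      # mean balance (BV over defined pigs only)


def allocate_feed(pigs: Sequence[PigRecord], lightest_intake: float) -> AllocationPlan:
    """Daily feed for each pig of a block from the voluntary intake of the
    block's lightest pig: CMW = intake / BW_min^0.75, allocation = CMW × BW^0.75."""
    if not pigs:
        raise ValueError("block is empty")
    if lightest_intake <= 0:
        raise ValueError(f"lightest_intake must be > 0, got {lightest_intake}")
    blocks = {p.block_id for p in pigs}
    if len(blocks) != 1:
        raise ValueError(f"pigs span multiple blocks: {sorted(blocks)}")
    lightest = min(pigs, key=lambda p: p.body_weight)
    cmw = lightest_intake / lightest.metabolic_weight
    return AllocationPlan(
        block_id=lightest.block_id,
        cmw=cmw,
        allocations={p.pig_id: cmw * p.metabolic_weight for p in pigs},
    )


def pig_balance(rec: CollectionRecord, k_n: float = K_N_DEFAULT) -> PigBalance:
    """Energy values and nitrogen balance of a single pig."""
    if k_n < 0:
        raise ValueError(f"k_n must be >= 0, got {k_n}")
    dmi = rec.feed_intake_dm
    ge_in = dmi * rec.feed_ge
    ge_fecal = rec.fecal_dm * rec.fecal_ge
    de = (ge_in - ge_fecal) / dmi
    me = (ge_in - ge_fecal - rec.urine_ge) / dmi

    n_in = dmi * rec.feed_n
    n_fec = rec.fecal_dm * rec.fecal_n
    nb = n_in - n_fec - rec.urine_n
    men = me - k_n * nb / dmi

    caddm = 100.0 * (dmi - rec.fecal_dm) / dmi
    cadcp = 100.0 * (n_in - n_fec) / n_in if n_in > 0 else math.nan
    absorbed = n_in - n_fec
    bv = 100.0 * nb / absorbed if absorbed != 0 else None

    return PigBalance(
        pig_id=rec.pig_id,
        energy=EnergyValues(de=de, me=me, men=men),
        balance=BalanceResult(caddm=caddm, cadcp=cadcp, n_intake=n_in,
                              n_feces=n_fec, n_urine=rec.urine_n,
                              n_balance=nb, bv=bv),
    )


def diet_energy(records: Sequence[CollectionRecord],
                k_n: float = K_N_DEFAULT) -> DietBalance:
    """Per-pig energy/balance for one diet plus unweighted means.

    Pigs whose biological value is undefined (N intake equals fecal N) are
    flagged with ``bv=None`` and excluded from the BV mean only.
    """
    if not records:
        raise ValueError("no collection records for diet")
    pigs = [pig_balance(r, k_n=k_n) for r in records]
    n = len(pigs)

    def mean(vals):
        return sum(vals) / len(vals)

    energy = EnergyValues(
        de=mean([p.energy.de for p in pigs]),
        me=mean([p.energy.me for p in pigs]),
        men=mean([p.energy.men for p in pigs]),
    )
    bvs = [p.balance.bv for p in pigs if p.balance.bv is not None]
    balance = BalanceResult(
        caddm=mean([p.balance.caddm for p in pigs]),
        cadcp=mean([p.balance.cadcp for p in pigs]),
        n_intake=mean([p.balance.n_intake for p in pigs]),
        n_feces=mean([p.balance.n_feces for p in pigs]),
        n_urine=mean([p.balance.n_urine for p in pigs]),
        n_balance=mean([p.balance.n_balance for p in pigs]),
        bv=mean(bvs) if bvs else None,
    )
    return DietBalance(pigs=pigs, energy=energy, balance=balance)


def ingredient_energy(e_td: float, e_rd: float, p: float,
                      mode: Literal["naive", "dm_corrected"] = "naive",
                      dm_fracs: Optional[tuple[float, float]] = None) -> float:
    """Ingredient energy (kcal/kg DM) by the substitution method.

    ``naive`` applies the as-fed inclusion fraction ``p`` directly to the
    DM-basis diet energies: ``(e_td - (1-p)·e_rd) / p``. ``dm_corrected``
    first re-expresses ``p`` on a DM basis from ``dm_fracs =
    (dm_ingredient, dm_rd)`` (fractions in (0, 1]).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if mode == "dm_corrected":
        if dm_fracs is None:
            raise ValueError("dm_corrected mode requires dm_fracs")
        dm_ing, dm_rd = dm_fracs
        if not (0 < dm_ing <= 1 and 0 < dm_rd <= 1):
            raise ValueError(f"dm_fracs must be in (0, 1], got {dm_fracs}")
        p = p * dm_ing / (p * dm_ing + (1 - p) * dm_rd)
    elif mode != "naive":
        raise ValueError(f"unknown mode '{mode}'")
    return (e_td - (1.0 - p) * e_rd) / p


def diet_table(results: dict[str, DietBalance]) -> pd.DataFrame:
    """Tidy frame of diet means: diet_id, de, me, men, ratios, balance."""
    rows = []
    for diet_id, res in results.items():
        rows.append({
            "diet_id": diet_id,
            "de": res.energy.de, "me": res.energy.me, "men": res.energy.men,
            "me_de": res.energy.me_de_ratio, "men_de": res.energy.men_de_ratio,
            "caddm": res.balance.caddm, "cadcp": res.balance.cadcp,
            "n_balance": res.balance.n_balance, "bv": res.balance.bv,
        })
    return pd.DataFrame(rows)
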