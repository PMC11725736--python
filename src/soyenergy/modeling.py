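"""Exhaustive linear-model search with AIC ranking.

Candidate prediction equations for DE/ME/MEn are enumerated from a
predictor pool, fitted by maximum likelihood under normal errors
(equivalently ordinary least squares), and ranked by the Akaike
information criterion. The AIC parameter count includes the residual
variance, k = n_terms + intercept + 1, so AIC = n·ln(2πσ̂²) + n + 2k
with σ̂² = RSS/n; alternative conventions differ only by a constant
offset per model and do not change the ranking among models of equal
size. Quadratic ureatic-activity (UA) terms enter only together with the
linear term, and a fitted concave UA response yields the activity at
which the predicted energy value is maximal, −b₁/(2·b₂).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CandidateModel",
    "FitResult",
    "CorrelationResult",
    "ComparisonResult",
    "enumerate_candidates",
    "fit_ml",
    "ua_optimum",
    "rank_by_aic",
    "correlate",
    "compare_groups",
    "search",
]

QUAD_SUFFIX = "^2"


def _quad(term: str) -> str:
    return term + QUAD_SUFFIX


@dataclass(frozen=True)
class CandidateModel:
    """One candidate equation: a response name and an ordered term tuple."""

    response: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in {self.terms}")
        for t in self.terms:
            if t.endswith(QUAD_SUFFIX) and t[: -len(QUAD_SUFFIX)] not in self.terms:
                raise ValueError(
                    f"hierarchy violation: {t} without {t[:-len(QUAD_SUFFIX)]}")

    def equation(self, coefficients: dict[str, float] | None = None) -> str:
        if coefficients is None:
            return " + ".join(("intercept",) + self.terms)
        parts = [f"{coefficients['intercept']:.1f}"]
        for t in self.terms:
            b = coefficients[t]
            parts.append(f"{'-' if b < 0 else '+'}{abs(b):.1f}{t}")
        return "Y = " + "".join(parts)


@dataclass
class FitResult:
    """Coefficients, fit statistics and error summaries of one candidate."""

    model: CandidateModel
    coefficients: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    aic: float
    r2: float
    abs_err: dict[str, float]   # mean, sd, min, max (kcal)
    rel_err: dict[str, float]   # mean, sd, min, max (%)
    n: int
    loglik: float
    ua_opt: Optional[float] = None


def enumerate_candidates(
    pool: Sequence[str],
    response: str = "Y",
    quadratic: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
    max_terms: Optional[int] = None,
) -> list[CandidateModel]:
    """All distinct candidate equations from a predictor pool.

    Each name in ``quadratic`` contributes a bundled unit (linear +
    squared term entering together, honouring the hierarchy rule); every
    other pool member is a single-term unit. Whitelisted interaction
    pairs ``(A, B)`` may optionally join any subset containing both
    parents. Models exceeding ``max_terms`` terms are dropped; the empty
    (intercept-only) model is excluded. Order is deterministic: by term
    count, then lexicographic.
    """
    if not pool:
        raise ValueError("predictor pool is empty")
    pool = list(dict.fromkeys(pool))
    units: list[tuple[str, ...]] = [
        (name, _quad(name)) if name in quadratic else (name,) for name in pool
    ]

    models: list[CandidateModel] = []
    for r in range(1, len(units) + 1):
        for combo in itertools.combinations(units, r):
            base = tuple(t for unit in combo for t in unit)
            present = set(base)
            optional = [
                f"{a}:{b}" for a, b in interactions
                if a in present and b in present
            ]
            for k in range(len(optional) + 1):
                for extra in itertools.combinations(optional, k):
                    terms = base + extra
                    if max_terms is not None and len(terms) > max_terms:
                        continue
                    models.append(CandidateModel(response=response, terms=terms))
    models.sort(key=lambda m: (len(m.terms), m.terms))
    return models


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for t in terms:
        if t in data.columns:
            cols.append(data[t].to_numpy(float))
        elif t.endswith(QUAD_SUFFIX) and t[: -len(QUAD_SUFFIX)] in data.columns:
            cols.append(data[t[: -len(QUAD_SUFFIX)]].to_numpy(float) ** 2)
        elif ":" in t:
            a, b = t.split(":", 1)
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            raise KeyError(f"predictor '{t}' not in data")
    return np.column_stack(cols)


def fit_ml(data: pd.DataFrame, response: np.ndarray | pd.Series | str,
           model: CandidateModel | Sequence[str]) -> FitResult:
    """Fit one candidate by maximum likelihood (normal errors).

    ``data`` holds the predictor columns; squared (``X^2``) and
    interaction (``A:B``) terms are built from them. ``response`` may be a
    column name or a vector. Raises on a singular design, naming the
    collinear terms.
    """
    if not isinstance(model, CandidateModel):
        resp_name = response if isinstance(response, str) else "Y"
        model = CandidateModel(response=resp_name, terms=tuple(model))
    y = (data[response].to_numpy(float) if isinstance(response, str)
         else np.asarray(response, float))
    X = _design(data, model.terms)
    n, ncol = X.shape
    if n < ncol + 1:
        raise ValueError(
            f"need at least {ncol + 1} rows to fit {ncol - 1} terms, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < ncol:
        names = ("intercept",) + model.terms
        # identify columns not adding rank, left to right
        bad, keep = [], np.empty((n, 0))
        for j, name in enumerate(names):
            trial = np.column_stack([keep, X[:, j]])
            if np.linalg.matrix_rank(trial) == keep.shape[1]:
                bad.append(name)
            else:
                keep = trial
        raise ValueError(f"singular design; collinear term(s): {bad}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else math.nan

    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = ncol + 1  # coefficients + error variance
    aic = 2.0 * k - 2.0 * loglik

    names = ("intercept",) + model.terms
    dof = n - ncol
    if dof > 0 and rss > 0:
        cov = rss / dof * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    else:
        se = np.full(ncol, math.nan)
        pvals = np.full(ncol, math.nan)

    abs_res = np.abs(resid)
    rel_res = 100.0 * abs_res / np.abs(y)

    def summary(v: np.ndarray) -> dict[str, float]:
        return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                "min": float(v.min()), "max": float(v.max())}

    coeffs = dict(zip(names, beta.tolist()))
    ua_opt = None
    for t in model.terms:
        if t.endswith(QUAD_SUFFIX):
            lin = t[: -len(QUAD_SUFFIX)]
            if coeffs[t] < 0:
                ua_opt = ua_optimum(coeffs[lin], coeffs[t])
            break

    return FitResult(
        model=model,
        coefficients=coeffs,
        se=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, np.asarray(pvals).tolist())),
        aic=aic, r2=r2,
        abs_err=summary(abs_res), rel_err=summary(rel_res),
        n=n, loglik=loglik, ua_opt=ua_opt,
    )


def ua_optimum(b1: float, b2: float) -> Optional[float]:
    """Ureatic activity at the stationary maximum of a concave quadratic
    response, −b₁/(2·b₂); ``None`` when ``b2 >= 0`` (no interior maximum)."""
    if b2 >= 0:
        return None
    return -b1 / (2.0 * b2)


def rank_by_aic(fits: Sequence[FitResult]) -> list[FitResult]:
    """Ascending-AIC order; ties broken by fewer terms, then term names."""
    if not fits:
        return []
    responses = {f.model.response for f in fits}
    if len(responses) != 1:
        raise ValueError(f"fits mix responses: {sorted(responses)}")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits computed on different sample sizes: {sorted(ns)}")
    return sorted(fits, key=lambda f: (f.aic, len(f.model.terms), f.model.terms))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    undefined: bool = False


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t distribution
    (n−2 df). Zero variance in either variable is flagged, not raised."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, p=math.nan, n=len(x), undefined=True)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t: float
    p: float
    assumption: str
    n_a: int
    n_b: int


def compare_groups(a: Sequence[float], b: Sequence[float],
                   assumption: Literal["pooled", "unequal"] = "pooled",
                   ) -> ComparisonResult:
    """Two-sided unpaired t-test; group means ± standard errors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=(assumption == "pooled"))
    return ComparisonResult(
        mean_a=float(a.mean()), se_a=float(a.std(ddof=1) / math.sqrt(len(a))),
        mean_b=float(b.mean()), se_b=float(b.std(ddof=1) / math.sqrt(len(b))),
        t=float(res.statistic), p=float(res.pvalue),
        assumption=assumption, n_a=len(a), n_b=len(b),
    )


def search(data: pd.DataFrame, response: str, pool: Sequence[str],
           quadratic: Sequence[str] = ("UA",),
           interactions: Sequence[tuple[str, str]] = (),
           max_terms: Optional[int] = None) -> list[FitResult]:
    """Enumerate, fit and AIC-rank every candidate for one response."""
    candidates = enumerate_candidates(
        pool, response=response, quadratic=quadratic,
        interactions=interactions, max_terms=max_terms)
    fits = []
    for cand in candidates:
        try:
            fits.append(fit_ml(data, response, cand))
        except ValueError:
            continue  # singular or over-parameterised candidates are skipped
    return rank_by_aic(fits)


def ranking_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Ranked report mirroring the published equation tables.

    p-values are unadjusted single-fit values; with many candidates
    examined they carry the usual multiplicity caveat.
    """
    rows = []
    for f in fits:
        rows.append({
            "equation": f.model.equation(f.coefficients),
            "terms": " + ".join(f.model.terms),
            "aic": f.aic, "r2": f.r2,
            "abs_err_mean": f.abs_err["mean"], "abs_err_sd": f.abs_err["sd"],
            "abs_err_min": f.abs_err["min"], "abs_err_max": f.abs_err["max"],
            "rel_err_mean": f.rel_err["mean"], "rel_err_sd": f.rel_err["sd"],
            "rel_err_min": f.rel_err["min"], "rel_err_max": f.rel_err["max"],
            "ua_max": f.ua_opt,
        })
    return pd.DataFrame(rows)


def pvalue_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Coefficient p-values per equation (unadjusted)."""
    rows = []
    for f in fits:
        row = {"equation": f.model.equation(f.coefficients)}
        row.update({t: f.p_values[t] for t in f.model.terms})
        rows.append(row)
    return pd.DataFrame(rows)
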