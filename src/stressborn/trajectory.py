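"""Candidate age-trajectory models and AIC selection.

The shape of the age-specific reproduction curve is found by comparing, on
the full bin table, a null model (no age terms), polynomial models (linear,
quadratic, cubic in scaled age) and broken-stick models: continuous
piecewise-linear predictors (linear splines) with one or two free breakpoints
placed on a grid of bin mid-ages.  All candidates share the same base fixed
effects (birth season, birth decade, censoring and age-at-last-sighting
terms) and random intercepts, so AIC differences reflect the age
parameterisation alone.  The best two-threshold model's second break is the
age at which senescence begins and defines the subset for the downstream
interaction analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glmm import FitResult, GlmmError, ModelSpec, fit_glmm

__all__ = [
    "ThresholdGrid",
    "CandidateSpec",
    "CandidateModel",
    "SelectionTable",
    "piecewise_basis",
    "enumerate_candidates",
    "select_trajectory",
    "DEFAULT_BASE_TERMS",
]

DEFAULT_BASE_TERMS = (
    "high_stress_born",
    "C(birth_decade)",
    "censored",
    "last_age_scaled",
    "last_age_scaled_sq",
)


@dataclass(frozen=True)
class ThresholdGrid:
    """Breakpoint search grid (ages in years, inclusive ranges with step).

    ``min_points_per_segment`` requires at least that many bin mid-ages in
    every segment of a two-threshold candidate (inclusive of the breakpoints);
    ``min_gap_years`` keeps more than one full age bin between the two
    breakpoints.
    """

    single_range: tuple = (9, 45, 3)
    double_first: tuple = (12, 39, 3)
    double_second: tuple = (18, 45, 3)
    min_points_per_segment: int = 3
    min_gap_years: int = 6

    def singles(self) -> list:
        lo, hi, step = self.single_range
        return list(range(lo, hi + 1, step))

    def firsts(self) -> list:
        lo, hi, step = self.double_first
        return list(range(lo, hi + 1, step))

    def seconds(self) -> list:
        lo, hi, step = self.double_second
        return list(range(lo, hi + 1, step))


@dataclass(frozen=True)
class CandidateSpec:
    label: str
    thresholds: tuple = ()


@dataclass
class CandidateModel:
    spec: CandidateSpec
    fit: Optional[FitResult]
    converged: bool

    @property
    def aic(self) -> float:
        return np.inf if self.fit is None else self.fit.aic


@dataclass
class SelectionTable:
    """All candidates ranked by AIC (ties broken by fewer parameters)."""

    candidates: list
    table: pd.DataFrame

    @property
    def best(self) -> CandidateModel:
        label = self.table.iloc[0]["label"]
        return next(c for c in self.candidates if c.spec.label == label)


def piecewise_basis(age, thresholds: Sequence[float]) -> np.ndarray:
    """Linear-spline (truncated line) basis: columns ``[a, (a-T1)+, ...]``.

    Thresholds must be sorted ascending and on the same scale as ``age``; the
    resulting piecewise-linear predictor is continuous with one free slope per
    segment.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError(f"thresholds must be sorted ascending, got {thresholds}")
    a = np.asarray(age, dtype=float)
    cols = [a] + [np.clip(a - t, 0.0, None) for t in thresholds]
    return np.column_stack(cols)


def enumerate_candidates(
    grid: ThresholdGrid,
    available_mids: Optional[Sequence[int]] = None,
    *,
    prune_segments: bool = True,
) -> list:
    """Deterministically ordered candidate list: null, polynomials, single
    thresholds, then ordered threshold pairs obeying the gap rule and (when
    ``prune_segments`` and the observed bin mid-ages are given) the
    minimum-points-per-segment rule."""
    singles = grid.singles()
    firsts, seconds = grid.firsts(), grid.seconds()
    if available_mids is not None:
        mids = sorted(set(int(m) for m in available_mids))
        if not mids:
            raise GlmmError("no bin mid-ages available")
        singles = [t for t in singles if t in mids]
        firsts = [t for t in firsts if t in mids]
        seconds = [t for t in seconds if t in mids]
    if not singles and not firsts:
        raise GlmmError("threshold grid is empty")

    out = [
        CandidateSpec("null"),
        CandidateSpec("linear"),
        CandidateSpec("quadratic"),
        CandidateSpec("cubic"),
    ]
    out += [CandidateSpec(f"thr({t})", (t,)) for t in singles]

    def seg_ok(t1, t2):
        if available_mids is None or not prune_segments:
            return True
        n_lo = sum(1 for m in mids if m <= t1)
        n_mid = sum(1 for m in mids if t1 <= m <= t2)
        n_hi = sum(1 for m in mids if m >= t2)
        k = grid.min_points_per_segment
        return n_lo >= k and n_mid >= k and n_hi >= k

    for t1 in firsts:
        for t2 in seconds:
            if t2 - t1 >= grid.min_gap_years and seg_ok(t1, t2):
                out.append(CandidateSpec(f"thr({t1},{t2})", (t1, t2)))
    return out


def _age_columns(table: pd.DataFrame, cand: CandidateSpec, scale: float):
    """Columns and formula terms implementing one candidate's age effect."""
    df = {}
    a = table["age_scaled"].to_numpy()
    if cand.label == "null":
        terms = []
    elif cand.label == "linear":
        terms = ["age_scaled"]
    elif cand.label == "quadratic":
        df["age_scaled_2"] = a ** 2
        terms = ["age_scaled", "age_scaled_2"]
    elif cand.label == "cubic":
        df["age_scaled_2"] = a ** 2
        df["age_scaled_3"] = a ** 3
        terms = ["age_scaled", "age_scaled_2", "age_scaled_3"]
    else:
        basis = piecewise_basis(a, [t / scale for t in cand.thresholds])
        terms = ["age_scaled"]
        for j in range(1, basis.shape[1]):
            name = f"age_spline_{j}"
            df[name] = basis[:, j]
            terms.append(name)
    return df, terms


def select_trajectory(
    table: pd.DataFrame,
    grid: ThresholdGrid = ThresholdGrid(),
    *,
    base_terms: Sequence[str] = DEFAULT_BASE_TERMS,
    groups: tuple = ("id", "region"),
    scale: float = 100.0,
    prune_segments: bool = True,
    candidates: Optional[list] = None,
) -> SelectionTable:
    """Fit every candidate trajectory and rank by AIC.

    All candidates share ``base_terms`` and the random-intercept structure.
    Non-converged candidates are kept in the table but excluded from the
    ranking, with a warning.  The ordering is total and deterministic:
    ascending AIC, ties (below 1e-6) to the model with fewer parameters.
    """
    mids = table["bin_mid_age"].unique()
    if candidates is None:
        candidates = enumerate_candidates(grid, mids, prune_segments=prune_segments)
    fitted = []
    for cand in candidates:
        extra, age_terms = _age_columns(table, cand, scale)
        work = table.assign(**extra) if extra else table
        rhs = " + ".join(list(base_terms) + age_terms) or "1"
        spec = ModelSpec(f"reproduced ~ {rhs}", tuple(groups), "binomial")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_glmm(spec, work)
            fitted.append(CandidateModel(cand, fit, fit.converged))
        except Exception as e:  # noqa: BLE001 - candidate failure is data, not fatal
            warnings.warn(f"candidate {cand.label} failed: {e}")
            fitted.append(CandidateModel(cand, None, False))
    if not any(c.converged for c in fitted):
        raise GlmmError("no trajectory candidate converged")
    bad = [c.spec.label for c in fitted if not c.converged]
    if bad:
        warnings.warn(f"excluding non-converged candidates from selection: {bad}")

    rows = []
    for c in fitted:
        rows.append(
            {
                "label": c.spec.label,
                "t1": c.spec.thresholds[0] if c.spec.thresholds else np.nan,
                "t2": c.spec.thresholds[1] if len(c.spec.thresholds) > 1 else np.nan,
                "k": np.nan if c.fit is None else c.fit.k_params,
                "loglik": np.nan if c.fit is None else c.fit.loglik,
                "aic": np.nan if c.fit is None else c.fit.aic,
                "converged": c.converged,
            }
        )
    tab = pd.DataFrame(rows)
    ok = tab["converged"]
    # rank: AIC rounded at 1e-6 to make the tie rule explicit, then fewer params
    tab["_aic_key"] = np.where(ok, np.round(tab["aic"].fillna(np.inf) * 1e6) / 1e6, np.inf)
    tab = tab.sort_values(["_aic_key", "k"], kind="mergesort").drop(columns="_aic_key")
    tab["delta_aic"] = tab["aic"] - tab.loc[tab["converged"], "aic"].min()
    return SelectionTable(fitted, tab.reset_index(drop=True))
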