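"""Transportable cut-off derivation across multiple cohorts.

The central procedure: on a designated *derivation* cohort, Youden's
J = Se + Sp - 1 is profiled over all candidate integer cut-offs and the
near-optimal plateau ``P = {c : J(c) >= Jmax - epsilon}`` identified
(default epsilon 0.01 — cut-offs whose discrimination is practically
indistinguishable from the maximum). A cut-off in P is *admissible* when its
specificity clears a floor tau (default 0.75) in a strict majority of all K
cohorts; the transportable cut-off is the smallest admissible one,
``c_star = min(A)``, favouring sensitivity for a screening, rule-out use.

A second, prevalence-agnostic consensus criterion is the aggregate Index of
Union. Per cohort k with AUC A_k, ``IU_k(c) = |Se_k(c) - A_k| +
|Sp_k(c) - A_k|`` measures how far both margins sit from the cohort's
overall separability; ``IU_agg(c) = sum_k w_k IU_k(c)`` (equal weights by
default) gives a multi-cohort consensus whose argmin can be compared with
c_star.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortDataset
from .roc import OperatingPoint, ROCResult, empirical_roc

__all__ = [
    "YoudenProfile",
    "PlateauSelection",
    "IUProfile",
    "NoAdmissibleCutoffError",
    "youden_profile",
    "near_optimal_plateau",
    "admissible_set",
    "transportable_cutoff",
    "iu_profile",
    "per_dataset_optimal_table",
]


class NoAdmissibleCutoffError(ValueError):
    """No plateau cut-off met the specificity floor in a majority of cohorts."""

    def __init__(self, plateau: tuple[int, ...], floor_table: pd.DataFrame):
        self.plateau = plateau
        self.floor_table = floor_table
        super().__init__(
            "no admissible cut-off: the specificity floor failed in a "
            f"majority of cohorts at every plateau cut-off {list(plateau)}"
        )


@dataclass(frozen=True)
class YoudenProfile:
    dataset_id: str
    j_by_cutoff: Mapping[int, float]
    jmax_cutoff: int
    jmax_value: float

    def plateau(self, epsilon: float = 0.01) -> tuple[int, ...]:
        return near_optimal_plateau(self, epsilon)


@dataclass(frozen=True)
class PlateauSelection:
    """Complete decision trail of one derivation run."""

    derivation_id: str
    epsilon: float
    profile: YoudenProfile
    plateau: tuple[int, ...]
    plateau_contiguous: bool
    spec_floor: float
    majority_threshold: float
    admissible: tuple[int, ...]
    c_star: int
    floor_pass_table: pd.DataFrame  # index: cutoff; columns: dataset ids (bool)

    def as_dict(self) -> dict:
        return {
            "derivation": self.derivation_id,
            "epsilon": self.epsilon,
            "jmax_cutoff": self.profile.jmax_cutoff,
            "jmax_value": self.profile.jmax_value,
            "plateau": list(self.plateau),
            "plateau_contiguous": self.plateau_contiguous,
            "spec_floor": self.spec_floor,
            "majority_threshold": self.majority_threshold,
            "admissible": list(self.admissible),
            "c_star": self.c_star,
            "floor_pass_table": {
                str(c): {k: bool(v) for k, v in row.items()}
                for c, row in self.floor_pass_table.iterrows()
            },
        }


@dataclass(frozen=True)
class IUProfile:
    per_dataset: pd.DataFrame  # index: cutoff; columns: dataset ids
    auc_targets: Mapping[str, float]
    weights: Mapping[str, float]
    iu_agg: Mapping[int, float]
    iu_agg_argmin: int
    per_dataset_minima: Mapping[str, int]


def youden_profile(
    cohort: CohortDataset,
    candidates: Sequence[int] | None = None,
    roc: ROCResult | None = None,
) -> YoudenProfile:
    """J at each candidate cut-off with the lower-c tie-break at the max.

    Ties on J are resolved toward the lower cut-off: a lower threshold flags
    more respondents, preserving sensitivity — the natural choice for a
    screening rule.
    """
    if roc is None:
        roc = empirical_roc(cohort, None if candidates is None else np.asarray(candidates))
    j_map = {p.cutoff: p.j for p in roc.points}
    cutoffs = sorted(j_map)
    jmax = max(j_map.values())
    jmax_cutoff = min(c for c in cutoffs if j_map[c] == jmax)
    return YoudenProfile(
        dataset_id=roc.dataset_id,
        j_by_cutoff=j_map,
        jmax_cutoff=jmax_cutoff,
        jmax_value=jmax,
    )


def near_optimal_plateau(profile: YoudenProfile, epsilon: float = 0.01) -> tuple[int, ...]:
    """Cut-offs within epsilon of the profile maximum, in ascending order.

    The set need not be contiguous; contiguity is reported downstream, not
    enforced.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    thr = profile.jmax_value - epsilon
    return tuple(sorted(c for c, j in profile.j_by_cutoff.items() if j >= thr))


def _specificities(
    cohorts: Sequence[CohortDataset],
    cutoffs: Sequence[int],
    rocs: Mapping[str, ROCResult] | None = None,
) -> pd.DataFrame:
    cols = {}
    for cohort in cohorts:
        roc = rocs[cohort.dataset_id] if rocs else empirical_roc(
            cohort, np.asarray(sorted(cutoffs))
        )
        sp = {p.cutoff: p.sp for p in roc.points}
        cols[cohort.dataset_id] = [sp[c] for c in cutoffs]
    return pd.DataFrame(cols, index=list(cutoffs))


def admissible_set(
    plateau: Sequence[int],
    cohorts: Sequence[CohortDataset] | None,
    tau: float = 0.75,
    majority_threshold: float = 0.5,
    rocs: Mapping[str, ROCResult] | None = None,
    sp_table: pd.DataFrame | None = None,
) -> tuple[tuple[int, ...], pd.DataFrame]:
    """Plateau cut-offs whose specificity clears tau in >majority of cohorts.

    The comparison is strict (``pass fraction > majority_threshold``), so with
    the default 0.5 a cut-off needs a strict majority of the K cohorts. The
    per-(cutoff, cohort) pass flags are returned for transparency; an empty
    admissible set is a legal outcome here (callers decide the fallback).

    ``sp_table`` (cut-offs as index, one column of specificities per cohort)
    substitutes for raw cohorts when only published summary rates are
    available.
    """
    if not plateau:
        raise ValueError("plateau must be non-empty")
    plateau = sorted(int(c) for c in plateau)
    if sp_table is not None:
        sp = sp_table.loc[plateau]
    else:
        if not cohorts:
            raise ValueError("need at least one cohort or an sp_table")
        sp = _specificities(cohorts, plateau, rocs)
    passes = sp >= tau
    frac = passes.mean(axis=1)
    admissible = tuple(c for c in plateau if frac.loc[c] > majority_threshold)
    return admissible, passes


def transportable_cutoff(
    derivation: CohortDataset,
    all_cohorts: Sequence[CohortDataset],
    epsilon: float = 0.01,
    tau: float = 0.75,
    candidates: Sequence[int] | None = None,
    majority_threshold: float = 0.5,
) -> PlateauSelection:
    """Derive the transportable cut-off c_star = min(A) with its full trail.

    The derivation cohort contributes to the specificity-floor count like any
    other cohort (it is one of the K datasets). Raises
    :class:`NoAdmissibleCutoffError` — carrying the plateau and the floor
    table — when no plateau cut-off is admissible.
    """
    cohort_list = list(all_cohorts)
    if derivation.dataset_id not in {c.dataset_id for c in cohort_list}:
        cohort_list = [derivation] + cohort_list
    cand = None if candidates is None else np.asarray(sorted(candidates))
    rocs = {c.dataset_id: empirical_roc(c, cand) for c in cohort_list}
    profile = youden_profile(derivation, roc=rocs[derivation.dataset_id])
    plateau = near_optimal_plateau(profile, epsilon)
    admissible, table = admissible_set(
        plateau, cohort_list, tau, majority_threshold, rocs=rocs
    )
    if not admissible:
        raise NoAdmissibleCutoffError(plateau, table)
    contiguous = len(plateau) == (plateau[-1] - plateau[0] + 1)
    return PlateauSelection(
        derivation_id=derivation.dataset_id,
        epsilon=epsilon,
        profile=profile,
        plateau=plateau,
        plateau_contiguous=contiguous,
        spec_floor=tau,
        majority_threshold=majority_threshold,
        admissible=admissible,
        c_star=min(admissible),
        floor_pass_table=table,
    )


def _iu_argmin(
    cutoffs: Sequence[int],
    iu: Mapping[int, float],
    se: Mapping[int, float] | None,
    sp: Mapping[int, float] | None,
) -> int:
    """Tie-break cascade: min IU, then min |Se - Sp| (when available), then lower c."""

    def key(c: int):
        balance = abs(se[c] - sp[c]) if se is not None and sp is not None else 0.0
        return (iu[c], balance, c)

    return min(cutoffs, key=key)


def iu_profile(
    cohorts: Sequence[CohortDataset] | None,
    candidates: Sequence[int],
    weights: Mapping[str, float] | None = None,
    rates: pd.DataFrame | None = None,
    auc_targets: Mapping[str, float] | None = None,
) -> IUProfile:
    """Index-of-Union curves per cohort and their equal-weight aggregate.

    Either pass ``cohorts`` (Se/Sp/AUC computed here), or a precomputed
    ``rates`` table with columns ``dataset, cutoff, sensitivity,
    specificity`` plus ``auc_targets`` — the latter path reproduces the
    criterion from published summary tables without raw data.

    Default weights are 1 per cohort (an unnormalised sum, not a mean), so
    the aggregate is on the "sum of per-cohort deviations" scale.
    """
    candidates = sorted(int(c) for c in candidates)
    se_tab: dict[str, dict[int, float]] = {}
    sp_tab: dict[str, dict[int, float]] = {}
    aucs: dict[str, float] = {}
    if rates is not None:
        if auc_targets is None:
            raise ValueError("auc_targets required with a precomputed rates table")
        for ds, grp in rates.groupby("dataset", sort=True):
            se_tab[ds] = dict(zip(grp["cutoff"].astype(int), grp["sensitivity"]))
            sp_tab[ds] = dict(zip(grp["cutoff"].astype(int), grp["specificity"]))
            aucs[ds] = float(auc_targets[ds])
    else:
        if not cohorts:
            raise ValueError("need cohorts or a rates table")
        for cohort in cohorts:
            roc = empirical_roc(cohort, np.asarray(candidates))
            se_tab[cohort.dataset_id] = {p.cutoff: p.se for p in roc.points}
            sp_tab[cohort.dataset_id] = {p.cutoff: p.sp for p in roc.points}
            aucs[cohort.dataset_id] = roc.auc

    ds_ids = sorted(se_tab)
    w = {k: 1.0 for k in ds_ids} if weights is None else dict(weights)
    iu_cols = {}
    minima = {}
    for ds in ds_ids:
        a = aucs[ds]
        iu = {c: abs(se_tab[ds][c] - a) + abs(sp_tab[ds][c] - a) for c in candidates}
        iu_cols[ds] = [iu[c] for c in candidates]
        minima[ds] = _iu_argmin(candidates, iu, se_tab[ds], sp_tab[ds])
    per_dataset = pd.DataFrame(iu_cols, index=candidates)
    agg = {
        c: float(sum(w[ds] * per_dataset.loc[c, ds] for ds in ds_ids))
        for c in candidates
    }
    # aggregate tie-break uses the weighted |Se-Sp| balance, then lower c
    bal_se = {
        c: sum(w[ds] * se_tab[ds][c] for ds in ds_ids) for c in candidates
    }
    bal_sp = {
        c: sum(w[ds] * sp_tab[ds][c] for ds in ds_ids) for c in candidates
    }
    argmin = _iu_argmin(candidates, agg, bal_se, bal_sp)
    return IUProfile(
        per_dataset=per_dataset,
        auc_targets=aucs,
        weights=w,
        iu_agg=agg,
        iu_agg_argmin=argmin,
        per_dataset_minima=minima,
    )


def per_dataset_optimal_table(
    cohorts: Sequence[CohortDataset],
    c_star: int,
    candidates: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Contrast each cohort's J-maximising operating point with the fixed c_star.

    One row per cohort: the J-max cut-off (lower-c tie-break), the full
    operating point there, the operating point at c_star, and
    ``delta_j = J(jmax) - J(c_star) >= 0`` — the discrimination given up by
    adopting the shared cut-off.
    """
    rows = []
    cand = None if candidates is None else np.asarray(sorted(candidates))
    for cohort in cohorts:
        roc = empirical_roc(cohort, cand)
        prof = youden_profile(cohort, roc=roc)
        opt: OperatingPoint = roc.point_at(prof.jmax_cutoff)
        fixed: OperatingPoint = roc.point_at(c_star)
        row = {"dataset": cohort.dataset_id, "optimal_cutoff": prof.jmax_cutoff}
        row.update({f"optimal_{k}": v for k, v in opt.as_dict().items() if k != "cutoff"})
        row.update({f"fixed_{k}": v for k, v in fixed.as_dict().items() if k != "cutoff"})
        row["fixed_cutoff"] = c_star
        row["delta_j"] = opt.j - fixed.j
        rows.append(row)
    return pd.DataFrame(rows)
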