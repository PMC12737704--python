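"""Empirical ROC over integer cut-offs, tie-corrected AUC, and bootstrap CIs.

Classification convention: a respondent is screen-positive when
``score >= c``. Because summated Likert totals live on a coarse integer grid,
ties between cases and non-cases are frequent; the AUC is therefore computed
as the tie-corrected pairwise concordance (0.5 credit for a tied pair), which
equals the trapezoidal area under the empirical ROC polyline including the
degenerate corners.

Confidence intervals for the AUC come from a stratified bootstrap: resampling
with replacement *within* outcome strata, preserving each stratum's size, so
no resample can lose an outcome class. Optionally the resampling unit is a
participant cluster (for cohorts with repeated assessments of the same
person), stratified by the cluster's outcome. Both percentile and
bias-corrected-and-accelerated (BCa) intervals are available; BCa adjusts the
percentile end-points for median bias (z0) and for skewness via a jackknife
acceleration term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import CohortDataset

__all__ = [
    "OperatingPoint",
    "ROCResult",
    "BootstrapCI",
    "confusion_at_cutoff",
    "operating_characteristics",
    "characteristics_from_rates",
    "empirical_auc",
    "empirical_roc",
    "bootstrap_auc_ci",
    "round_report",
]


class SingleClassError(ValueError):
    """Cohort contains only one outcome class; AUC undefined."""


@dataclass(frozen=True)
class OperatingPoint:
    """Full operating characteristics of the rule ``score >= cutoff``."""

    cutoff: int | None
    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    j: float
    balanced_accuracy: float
    lr_pos: float  # math.inf when sp == 1
    lr_neg: float  # math.inf when sp == 0
    prevalence: float
    ppv: float
    npv: float

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.se,
            "specificity": self.sp,
            "youden_j": self.j,
            "balanced_accuracy": self.balanced_accuracy,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "prevalence": self.prevalence,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class ROCResult:
    dataset_id: str
    points: tuple[OperatingPoint, ...]
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([p.as_dict() for p in self.points])
        df.insert(0, "dataset", self.dataset_id)
        return df

    def point_at(self, cutoff: int) -> OperatingPoint:
        for p in self.points:
            if p.cutoff == cutoff:
                return p
        raise KeyError(f"cutoff {cutoff} not among candidates")


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    method: str  # "bca" or "percentile"
    level: float
    lower: float
    upper: float
    n_boot: int
    seed: int | None
    stratified: bool
    clustered: bool
    fallback_percentile: bool = False
    boot_values: np.ndarray | None = field(default=None, repr=False, compare=False)


def confusion_at_cutoff(cohort: CohortDataset, c: int) -> tuple[int, int, int, int]:
    """Cross-tabulate ``score >= c`` against the outcome.

    Returns ``(tp, fp, tn, fn)``.
    """
    pred = cohort.scores >= c
    pos = cohort.outcomes == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, tn, fn


def characteristics_from_rates(
    se: float,
    sp: float,
    prevalence: float,
    cutoff: int | None = None,
    counts: tuple[int, int, int, int] = (0, 0, 0, 0),
) -> OperatingPoint:
    """Build an operating point from sensitivity/specificity directly.

    PPV and NPV follow Bayes' rule at the supplied prevalence:
    ``ppv = se*p / (se*p + (1-sp)(1-p))`` and
    ``npv = sp*(1-p) / (sp*(1-p) + (1-se)*p)``. This makes prevalence a
    swappable argument — useful both for transporting a cut-off to a new
    setting and for recomputing published table cells from their printed
    sensitivity/specificity.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    p = prevalence
    j = se + sp - 1.0
    ba = (se + sp) / 2.0
    lr_pos = se / (1.0 - sp) if sp < 1.0 else math.inf
    lr_neg = (1.0 - se) / sp if sp > 0.0 else math.inf
    ppv_den = se * p + (1.0 - sp) * (1.0 - p)
    npv_den = sp * (1.0 - p) + (1.0 - se) * p
    ppv = se * p / ppv_den if ppv_den > 0 else math.nan
    npv = sp * (1.0 - p) / npv_den if npv_den > 0 else math.nan
    tp, fp, tn, fn = counts
    return OperatingPoint(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        se=se,
        sp=sp,
        j=j,
        balanced_accuracy=ba,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        prevalence=p,
        ppv=ppv,
        npv=npv,
    )


def operating_characteristics(
    counts: tuple[int, int, int, int],
    prevalence: float,
    cutoff: int | None = None,
) -> OperatingPoint:
    """Operating point from confusion counts at an externally supplied prevalence."""
    tp, fp, tn, fn = counts
    if tp + fn < 1 or tn + fp < 1:
        raise SingleClassError("need at least one record of each outcome class")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return characteristics_from_rates(
        se, sp, prevalence, cutoff=cutoff, counts=(tp, fp, tn, fn)
    )


def _auc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    n1, n0 = len(pos_scores), len(neg_scores)
    ranks = stats.rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def empirical_auc(cohort: CohortDataset) -> float:
    """Tie-corrected concordance AUC (midrank Mann-Whitney form)."""
    if cohort.n_pos == 0 or cohort.n_neg == 0:
        raise SingleClassError(
            f"cohort {cohort.dataset_id!r}: AUC undefined for a single-class cohort"
        )
    pos = cohort.scores[cohort.outcomes == 1]
    neg = cohort.scores[cohort.outcomes == 0]
    return _auc_from_scores(pos.astype(float), neg.astype(float))


def empirical_roc(
    cohort: CohortDataset,
    candidate_cutoffs: np.ndarray | None = None,
    prevalence: float | None = None,
) -> ROCResult:
    """One operating point per candidate cut-off plus the cohort AUC.

    ``prevalence`` defaults to the cohort's observed case rate; pass a
    different value to transport PPV/NPV to another setting.
    """
    if cohort.n_pos == 0 or cohort.n_neg == 0:
        raise SingleClassError(
            f"cohort {cohort.dataset_id!r}: AUC undefined for a single-class cohort"
        )
    if candidate_cutoffs is None:
        candidate_cutoffs = cohort.scale.candidate_cutoffs()
    candidates = np.sort(np.asarray(candidate_cutoffs, dtype=int))
    p = cohort.prevalence if prevalence is None else prevalence
    points = tuple(
        operating_characteristics(confusion_at_cutoff(cohort, int(c)), p, cutoff=int(c))
        for c in candidates
    )
    return ROCResult(
        dataset_id=cohort.dataset_id,
        points=points,
        auc=empirical_auc(cohort),
        n_pos=cohort.n_pos,
        n_neg=cohort.n_neg,
    )


# ---------------------------------------------------------------------------
# bootstrap machinery


def _pairwise_contributions(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-record concordance totals against the opposite class.

    ``u[i]`` counts negatives below positive i (+0.5 per tie); ``v[j]``
    counts positives above negative j (+0.5 per tie). Used for O(n log n)
    delete-one jackknife AUCs.
    """
    sneg = np.sort(neg)
    lo = np.searchsorted(sneg, pos, side="left")
    hi = np.searchsorted(sneg, pos, side="right")
    u = lo + 0.5 * (hi - lo)
    spos = np.sort(pos)
    lo2 = np.searchsorted(spos, neg, side="right")
    v = (len(pos) - lo2) + 0.5 * (lo2 - np.searchsorted(spos, neg, side="left"))
    return u.astype(float), v.astype(float)


def _jackknife_aucs(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    n1, n0 = len(pos), len(neg)
    u, v = _pairwise_contributions(pos, neg)
    total = u.sum()
    out = np.empty(n1 + n0)
    if n1 > 1:
        out[:n1] = (total - u) / ((n1 - 1) * n0)
    else:
        out[:n1] = total / (n1 * n0)
    if n0 > 1:
        out[n1:] = (total - v) / (n1 * (n0 - 1))
    else:
        out[n1:] = total / (n1 * n0)
    return out


def _stratified_boot_aucs(
    pos: np.ndarray, neg: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """AUC of ``n_boot`` stratified resamples, vectorised over replicates."""
    n1, n0 = len(pos), len(neg)
    out = np.empty(n_boot)
    # Batch to bound memory at ~ a few hundred MB even for B=10000, n~2500.
    batch = max(1, min(n_boot, int(2_000_000 / max(n1 + n0, 1)) + 1))
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        ps = pos[rng.integers(0, n1, size=(b, n1))]
        ns = neg[rng.integers(0, n0, size=(b, n0))]
        ranks = stats.rankdata(np.concatenate([ps, ns], axis=1), axis=1)
        u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
        out[done : done + b] = u / (n1 * n0)
        done += b
    return out


def _cluster_table(
    cohort: CohortDataset,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Member-row indices per cluster, plus each cluster's outcome stratum.

    A cluster is stratified by its maximum outcome (a cluster containing any
    case resamples with the case stratum).
    """
    ids = cohort.participant_ids
    order: dict[object, int] = {}
    members: list[list[int]] = []
    for i, pid in enumerate(ids):
        if pid not in order:
            order[pid] = len(members)
            members.append([])
        members[order[pid]].append(i)
    idx = [np.asarray(m, dtype=int) for m in members]
    strata = np.array([int(cohort.outcomes[m].max()) for m in idx])
    return idx, strata


def _cluster_boot_aucs(
    cohort: CohortDataset, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    members, strata = _cluster_table(cohort)
    pos_clusters = np.flatnonzero(strata == 1)
    neg_clusters = np.flatnonzero(strata == 0)
    if len(pos_clusters) == 0 or len(neg_clusters) == 0:
        raise SingleClassError("cluster bootstrap needs clusters in both strata")
    scores = cohort.scores.astype(float)
    outcomes = cohort.outcomes
    out = np.empty(n_boot)
    for b in range(n_boot):
        chosen = np.concatenate(
            [
                pos_clusters[rng.integers(0, len(pos_clusters), len(pos_clusters))],
                neg_clusters[rng.integers(0, len(neg_clusters), len(neg_clusters))],
            ]
        )
        rows = np.concatenate([members[c] for c in chosen])
        s, o = scores[rows], outcomes[rows]
        if o.min() == o.max():  # mixed clusters could, in principle, collapse
            out[b] = np.nan
            continue
        out[b] = _auc_from_scores(s[o == 1], s[o == 0])
    return out[~np.isnan(out)]


def _cluster_jackknife_aucs(cohort: CohortDataset) -> np.ndarray:
    members, _ = _cluster_table(cohort)
    scores = cohort.scores.astype(float)
    outcomes = cohort.outcomes
    vals = []
    for m in members:
        keep = np.ones(len(scores), dtype=bool)
        keep[m] = False
        s, o = scores[keep], outcomes[keep]
        if o.min() == o.max():
            continue
        vals.append(_auc_from_scores(s[o == 1], s[o == 0]))
    return np.asarray(vals)


def _percentile(boot: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def bootstrap_auc_ci(
    cohort: CohortDataset,
    n_boot: int = 10_000,
    method: str = "bca",
    level: float = 0.95,
    seed: int | None = None,
    cluster: bool = False,
    _boot_cache: np.ndarray | None = None,
) -> BootstrapCI:
    """Stratified (optionally clustered) bootstrap CI for the AUC.

    ``method`` is ``"bca"`` or ``"percentile"``. BCa falls back to the
    percentile interval, flagged on the result, when the bias-correction
    z0 is infinite (every bootstrap value on one side of the estimate —
    typically a degenerate AUC of exactly 1).
    """
    if method not in ("bca", "percentile"):
        raise ValueError(f"unknown method {method!r}")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = empirical_auc(cohort)
    rng = np.random.default_rng(seed)
    if _boot_cache is not None:
        boot = _boot_cache
    elif cluster:
        boot = _cluster_boot_aucs(cohort, n_boot, rng)
    else:
        pos = cohort.scores[cohort.outcomes == 1].astype(float)
        neg = cohort.scores[cohort.outcomes == 0].astype(float)
        boot = _stratified_boot_aucs(pos, neg, n_boot, rng)

    fallback = False
    if method == "percentile":
        lower, upper = _percentile(boot, level)
    else:
        prop_below = np.mean(boot < est)
        if prop_below in (0.0, 1.0):
            lower, upper = _percentile(boot, level)
            fallback = True
        else:
            z0 = stats.norm.ppf(prop_below)
            if cluster:
                jack = _cluster_jackknife_aucs(cohort)
            else:
                pos = cohort.scores[cohort.outcomes == 1].astype(float)
                neg = cohort.scores[cohort.outcomes == 0].astype(float)
                jack = _jackknife_aucs(pos, neg)
            diffs = jack.mean() - jack
            denom = (diffs**2).sum() ** 1.5
            accel = (diffs**3).sum() / (6.0 * denom) if denom > 0 else 0.0
            alpha = 1.0 - level
            z_lo, z_hi = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
            a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
            a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
            lower = float(np.quantile(boot, a1, method="linear"))
            upper = float(np.quantile(boot, a2, method="linear"))
    return BootstrapCI(
        estimate=est,
        method="percentile" if fallback else method,
        level=level,
        lower=lower,
        upper=upper,
        n_boot=len(boot),
        seed=seed,
        stratified=True,
        clustered=cluster,
        fallback_percentile=fallback,
        boot_values=boot,
    )


def round_report(x: float, decimals: int = 3) -> float:
    """Half-away-from-zero rounding used only at presentation time."""
    if not math.isfinite(x):
        return x
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)
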