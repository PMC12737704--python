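"""Test-retest reliability: absolute-agreement ICCs, SEM, and SDC.

The reliability model is the two-way crossed ANOVA (subjects x
administrations, one observation per cell) behind the absolute-agreement
intraclass correlations of the McGraw-Wong taxonomy:

* ``ICC(A,1)`` — reliability of a *single* administration, penalising any
  systematic mean shift between timepoints as disagreement (the conservative
  choice when asking whether one administration can stand in for another);
* ``ICC(A,k)`` — reliability of the *mean* of the k administrations, larger
  than ICC(A,1) by the Spearman-Brown averaging gain.

Confidence intervals use the F-distribution construction with
Satterthwaite-style degrees of freedom for the absolute-agreement case.
Measurement precision follows the standard chain
``SEM = SD_t1 * sqrt(1 - ICC(A,1))``, ``SDC_individual = 1.96 * sqrt(2) * SEM``
and ``SDC_group = SDC_individual / sqrt(n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import PairedCohort, ScaleSpec

__all__ = [
    "AnovaDecomposition",
    "ICCReport",
    "ChangeMetrics",
    "DegenerateDataError",
    "two_way_anova",
    "icc_absolute_agreement",
    "icc_from_paired",
    "change_metrics",
    "sdc_from_sem",
    "subscale_reliability",
    "pairs_from_items",
]


class DegenerateDataError(ValueError):
    """Data carry no usable variance structure for the requested statistic."""


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way crossed decomposition (one obs per cell)."""

    n: int  # subjects
    k: int  # administrations
    ms_rows: float  # between-subject
    ms_cols: float  # between-administration
    ms_error: float  # residual
    grand_mean: float


@dataclass(frozen=True)
class ICCReport:
    icc_a1: float
    icc_a1_ci: tuple[float, float]
    icc_a2: float
    icc_a2_ci: tuple[float, float]
    level: float
    anova: AnovaDecomposition
    interpretation_band: str


@dataclass(frozen=True)
class ChangeMetrics:
    sd_t1: float
    sem: float
    sdc_individual: float
    sdc_group: float
    n: int


def two_way_anova(paired: PairedCohort | np.ndarray) -> AnovaDecomposition:
    """Subjects x administrations mean squares from an n x k score matrix.

    Requires n >= 3 complete rows. A matrix with zero total variance is legal
    and yields the all-zero degenerate decomposition.
    """
    data = paired.matrix() if isinstance(paired, PairedCohort) else np.asarray(paired, float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    n, k = data.shape
    if n < 3:
        raise DegenerateDataError(f"need at least 3 complete pairs, got {n}")
    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_total = ((data - gm) ** 2).sum()
    ss_resid = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        n=n,
        k=k,
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_resid / ((n - 1) * (k - 1)),
        grand_mean=float(gm),
    )


def _band(icc: float) -> str:
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def _spearman_brown(r: float, k: int) -> float:
    return k * r / (1.0 + (k - 1) * r)


def icc_absolute_agreement(anova: AnovaDecomposition, level: float = 0.95) -> ICCReport:
    """ICC(A,1) and ICC(A,k) with F-based confidence intervals.

    Point estimates::

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
        ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)

    Interval end-points follow the absolute-agreement F construction with a
    Satterthwaite-style denominator degrees-of-freedom for the compound
    variance; the average-measure bounds are the single-measure bounds pushed
    through the Spearman-Brown step-up. Negative estimates are reported as-is
    (band "poor"), never truncated.
    """
    n, k = anova.n, anova.k
    msr, msc, mse = anova.ms_rows, anova.ms_cols, anova.ms_error
    denom1 = msr + (k - 1) * mse + (k / n) * (msc - mse)
    denomk = msr + (msc - mse) / n
    if denom1 <= 0 or denomk <= 0:
        raise DegenerateDataError("non-positive ICC denominator; no variance to rate")
    icc1 = (msr - mse) / denom1
    icck = (msr - mse) / denomk

    alpha = 1.0 - level
    if icc1 >= 1.0 or mse == 0 and msc == 0:
        lo1, up1 = icc1, icc1
    else:
        a = k * icc1 / (n * (1.0 - icc1))
        b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else float(n - 1)
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo1 = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        up1 = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    lok = _spearman_brown(lo1, k) if lo1 > -1 else lo1
    upk = _spearman_brown(up1, k) if up1 > -1 else up1
    return ICCReport(
        icc_a1=float(icc1),
        icc_a1_ci=(float(lo1), float(up1)),
        icc_a2=float(icck),
        icc_a2_ci=(float(lok), float(upk)),
        level=level,
        anova=anova,
        interpretation_band=_band(icc1),
    )


def icc_from_paired(paired: PairedCohort, level: float = 0.95) -> ICCReport:
    """Convenience: ANOVA + ICC in one call."""
    return icc_absolute_agreement(two_way_anova(paired), level)


def change_metrics(sd_t1: float, icc_a1: float, n: int) -> ChangeMetrics:
    """SEM and smallest-detectable-change statistics from SD and ICC.

    The anchor is the first-administration SD. A negative ICC is refused
    here (it has no meaningful measurement-error decomposition); report it
    upstream instead.
    """
    if not 0.0 <= icc_a1 <= 1.0:
        raise ValueError(f"icc_a1 must be within [0, 1], got {icc_a1}")
    if sd_t1 <= 0:
        raise ValueError("sd_t1 must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    sem = sd_t1 * math.sqrt(1.0 - icc_a1)
    sdc_ind = 1.96 * math.sqrt(2.0) * sem
    return ChangeMetrics(
        sd_t1=sd_t1,
        sem=sem,
        sdc_individual=sdc_ind,
        sdc_group=sdc_ind / math.sqrt(n),
        n=n,
    )


def sdc_from_sem(sem: float, n: int | None = None) -> tuple[float, float | None]:
    """SDC_individual (and SDC_group when n given) from an SEM value.

    Useful for reproducing published chains where the SEM is reported
    rounded and the SDC was derived from the rounded value.
    """
    sdc_ind = 1.96 * math.sqrt(2.0) * sem
    return sdc_ind, (sdc_ind / math.sqrt(n) if n else None)


def _apply_reverse(items: pd.DataFrame, scale: ScaleSpec) -> pd.DataFrame:
    out = items.copy()
    for idx in scale.reverse_keyed:
        col = out.columns[idx - 1]
        out[col] = scale.item_min + scale.item_max - out[col]
    return out


def pairs_from_items(
    participant_ids: np.ndarray,
    items_t1: pd.DataFrame,
    items_t2: pd.DataFrame,
    scale: ScaleSpec,
) -> dict[str, PairedCohort]:
    """Total and per-subscale paired cohorts from item-level responses.

    ``items_t1``/``items_t2`` are n x n_items frames in item order, aligned
    row-wise with ``participant_ids``. Requires ``scale.subscale_map`` for
    the per-subscale entries (the total is always produced).
    """
    if items_t1.shape != items_t2.shape or items_t1.shape[1] != scale.n_items:
        raise ValueError("item frames must be aligned n x n_items")
    t1 = _apply_reverse(items_t1, scale)
    t2 = _apply_reverse(items_t2, scale)
    blocks: dict[str, tuple[int, ...]] = {"total": tuple(range(1, scale.n_items + 1))}
    if scale.subscale_map:
        blocks.update(scale.subscale_map)
    out = {}
    for name, idx in blocks.items():
        cols = [t1.columns[i - 1] for i in idx]
        cols2 = [t2.columns[i - 1] for i in idx]
        sub_scale = ScaleSpec(
            n_items=len(idx), item_min=scale.item_min, item_max=scale.item_max
        )
        out[name] = PairedCohort(
            dataset_id=name,
            participant_ids=np.asarray(participant_ids, dtype=object),
            scores_t1=t1[cols].sum(axis=1).to_numpy(),
            scores_t2=t2[cols2].sum(axis=1).to_numpy(),
            scale=sub_scale,
        )
    return out


def subscale_reliability(
    pairs: Mapping[str, PairedCohort], level: float = 0.95
) -> pd.DataFrame:
    """One single- and average-measure ICC row pair per (sub)scale.

    ``pairs`` maps scale names (e.g. ``total`` plus subscales) to paired
    cohorts; typically built with :func:`pairs_from_items` or from
    subscale-score files. Output is a tidy long table: scale, measure,
    icc, ci_lower, ci_upper, band.
    """
    if not pairs:
        raise ValueError("subscale_map/pairs must be non-empty")
    rows = []
    for name, paired in pairs.items():
        rep = icc_from_paired(paired, level)
        rows.append(
            {
                "scale": name,
                "measure": "single",
                "icc": rep.icc_a1,
                "ci_lower": rep.icc_a1_ci[0],
                "ci_upper": rep.icc_a1_ci[1],
                "band": rep.interpretation_band,
            }
        )
        rows.append(
            {
                "scale": name,
                "measure": "average",
                "icc": rep.icc_a2,
                "ci_lower": rep.icc_a2_ci[0],
                "ci_upper": rep.icc_a2_ci[1],
                "band": _band(rep.icc_a2),
            }
        )
    return pd.DataFrame(rows)
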