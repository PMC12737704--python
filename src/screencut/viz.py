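"""Diagnostic figures and publication-style tables.

Two bespoke visuals support the cut-off derivation:

* a multi-sample two-graph ROC (TG-ROC) plot — sensitivity (dashed) and
  specificity (solid) against the integer cut-off per cohort, with a vertical
  reference at the fixed cut-off: the crossover band visualises the
  Se/Sp trade-off and where the fixed rule sits in it;
* a cohorts-by-cut-offs Youden heatmap with dashed guides at the plateau
  bounds and an open circle at each cohort's J-maximising cut-off
  (first occurrence, lower cut-off on ties).

Every plotted or tabulated number is taken from the metrics layer; nothing
is recomputed here, so the tidy tables returned alongside each figure are
the test surface and the images are presentation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohorts import CohortDataset
from .cutoffs import IUProfile, PlateauSelection, per_dataset_optimal_table, youden_profile
from .roc import BootstrapCI, ROCResult, empirical_roc, round_report

__all__ = [
    "TGROCSpec",
    "HeatmapSpec",
    "tg_roc_table",
    "tg_roc_plot",
    "youden_matrix",
    "youden_heatmap",
    "write_report_tables",
]


@dataclass(frozen=True)
class TGROCSpec:
    cutoff_lo: int = 32
    cutoff_hi: int = 40
    fixed_cutoff_line: int | None = None
    sensitivity_style: str = "--"
    specificity_style: str = "-"

    def cutoffs(self) -> np.ndarray:
        if self.cutoff_hi < self.cutoff_lo:
            raise ValueError("empty cut-off range")
        return np.arange(self.cutoff_lo, self.cutoff_hi + 1)


@dataclass(frozen=True)
class HeatmapSpec:
    plateau_bounds: tuple[int, int] | None = None
    mark_jmax: bool = True
    cmap: str = "viridis"


def _colors(dataset_ids: Sequence[str]) -> dict[str, tuple]:
    # deterministic assignment by label sort order
    cmap = plt.get_cmap("tab10")
    return {ds: cmap(i % 10) for i, ds in enumerate(sorted(dataset_ids))}


def _rocs_for(
    cohorts: Sequence[CohortDataset],
    cutoffs: np.ndarray,
    rocs: Mapping[str, ROCResult] | None,
) -> dict[str, ROCResult]:
    if rocs is not None:
        return dict(rocs)
    return {c.dataset_id: empirical_roc(c, cutoffs) for c in cohorts}


def tg_roc_table(
    cohorts: Sequence[CohortDataset],
    spec: TGROCSpec = TGROCSpec(),
    rocs: Mapping[str, ROCResult] | None = None,
) -> pd.DataFrame:
    """Tidy (dataset, cutoff, sensitivity, specificity) table for the TG-ROC plot."""
    cutoffs = spec.cutoffs()
    rocs = _rocs_for(cohorts, cutoffs, rocs)
    rows = []
    for ds in sorted(rocs):
        points = {p.cutoff: p for p in rocs[ds].points}
        for c in cutoffs:
            p = points[int(c)]
            rows.append(
                {
                    "dataset": ds,
                    "cutoff": int(c),
                    "sensitivity": p.se,
                    "specificity": p.sp,
                }
            )
    return pd.DataFrame(rows)


def _save(fig, out: str | Path) -> list[Path]:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if out.suffix:
        fig.savefig(out, bbox_inches="tight")
        written.append(out)
    else:
        for ext in (".svg", ".png"):
            p = out.with_suffix(ext)
            fig.savefig(p, bbox_inches="tight", dpi=150)
            written.append(p)
    plt.close(fig)
    return written


def tg_roc_plot(
    cohorts: Sequence[CohortDataset],
    spec: TGROCSpec = TGROCSpec(),
    out: str | Path | None = None,
    rocs: Mapping[str, ROCResult] | None = None,
) -> tuple[pd.DataFrame, list[Path]]:
    """Render the multi-sample TG-ROC figure; returns (tidy table, paths).

    Observed points are connected without smoothing or interpolation. When
    ``out`` has no suffix both SVG and PNG are written.
    """
    table = tg_roc_table(cohorts, spec, rocs)
    colors = _colors(table["dataset"].unique())
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for ds, grp in table.groupby("dataset"):
        ax.plot(
            grp["cutoff"],
            grp["sensitivity"],
            spec.sensitivity_style,
            color=colors[ds],
            label=f"{ds} Se",
        )
        ax.plot(
            grp["cutoff"],
            grp["specificity"],
            spec.specificity_style,
            color=colors[ds],
            label=f"{ds} Sp",
        )
    if spec.fixed_cutoff_line is not None:
        ax.axvline(spec.fixed_cutoff_line, color="black", lw=1, alpha=0.7)
    ax.set_xlabel("cut-off (score >= c)")
    ax.set_ylabel("sensitivity (dashed) / specificity (solid)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7, ncol=2, frameon=False)
    paths = _save(fig, out) if out is not None else []
    return table, paths


def youden_matrix(
    cohorts: Sequence[CohortDataset],
    cutoffs: Sequence[int],
    rocs: Mapping[str, ROCResult] | None = None,
) -> pd.DataFrame:
    """Datasets x cut-offs matrix of Youden's J."""
    cutoffs = np.asarray(sorted(int(c) for c in cutoffs))
    rocs = _rocs_for(cohorts, cutoffs, rocs)
    data = {}
    for ds in sorted(rocs):
        j = {p.cutoff: p.j for p in rocs[ds].points}
        data[ds] = [j[int(c)] for c in cutoffs]
    return pd.DataFrame(data, index=[int(c) for c in cutoffs]).T


def youden_heatmap(
    cohorts: Sequence[CohortDataset],
    selection: PlateauSelection,
    spec: HeatmapSpec = HeatmapSpec(),
    out: str | Path | None = None,
    cutoffs: Sequence[int] | None = None,
    rocs: Mapping[str, ROCResult] | None = None,
) -> tuple[pd.DataFrame, list[Path]]:
    """Cross-dataset J heatmap highlighting the derivation plateau."""
    if cutoffs is None:
        lo, hi = min(selection.plateau) - 2, max(selection.plateau) + 2
        cutoffs = range(lo, hi + 1)
    matrix = youden_matrix(cohorts, cutoffs, rocs)
    bounds = spec.plateau_bounds or (min(selection.plateau), max(selection.plateau))

    fig, ax = plt.subplots(figsize=(7, 3.5))
    cols = list(matrix.columns)
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=spec.cmap)
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for b, shift in ((bounds[0], -0.5), (bounds[1], 0.5)):
        if b in cols:
            ax.axvline(cols.index(b) + shift, ls="--", color="white", lw=1.2)
    if spec.mark_jmax:
        for yi, ds in enumerate(matrix.index):
            cohort = next(c for c in cohorts if c.dataset_id == ds)
            roc = rocs[ds] if rocs else None
            jmax_c = youden_profile(cohort, roc=roc).jmax_cutoff
            if jmax_c in cols:
                ax.scatter(
                    cols.index(jmax_c), yi, s=80, facecolors="none",
                    edgecolors="white", linewidths=1.5,
                )
    fig.colorbar(im, ax=ax, label="Youden's J")
    ax.set_xlabel("cut-off")
    paths = _save(fig, out) if out is not None else []
    return matrix, paths


_METRIC_ROWS = [
    ("Prevalence", "prevalence"),
    ("Sensitivity", "sensitivity"),
    ("Specificity", "specificity"),
    ("Youden J", "youden_j"),
    ("Balanced accuracy", "balanced_accuracy"),
    ("LR+", "lr_pos"),
    ("LR-", "lr_neg"),
    ("PPV", "ppv"),
    ("NPV", "npv"),
]


def _round_frame(df: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    def f(x):
        if isinstance(x, float):
            return round_report(x, decimals)
        return x

    return df.map(f)


def write_report_tables(
    cohorts: Sequence[CohortDataset],
    selection: PlateauSelection,
    iu: IUProfile | None,
    icc_table: pd.DataFrame | None,
    out_dir: str | Path,
    auc_cis: Mapping[str, Sequence[BootstrapCI]] | None = None,
) -> dict[str, Path]:
    """Write the four study-style tables as CSV plus a full-precision JSON.

    Table layouts: (1) per-cohort AUC with bootstrap CIs; (2) operating
    characteristics at the fixed cut-off; (3) each cohort's J-optimal
    operating point vs the fixed cut-off with delta J; (4) single- and
    average-measure ICCs. Proportions are rounded half-away-from-zero to 3
    decimals in the CSVs only; the JSON keeps full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    c_star = selection.c_star
    rocs = {c.dataset_id: empirical_roc(c) for c in cohorts}
    paths: dict[str, Path] = {}
    payload: dict = {"selection": selection.as_dict()}

    # Table 1 style: discriminative performance
    rows = []
    for ds in sorted(rocs):
        row = {"dataset": ds, "n": len(next(c for c in cohorts if c.dataset_id == ds)),
               "auc": rocs[ds].auc}
        if auc_cis and ds in auc_cis:
            for ci in auc_cis[ds]:
                row[f"ci_lower_{ci.method}"] = ci.lower
                row[f"ci_upper_{ci.method}"] = ci.upper
        rows.append(row)
    t1 = pd.DataFrame(rows)
    payload["auc_table"] = t1.to_dict(orient="records")
    paths["auc_table"] = out_dir / "table_auc.csv"
    _round_frame(t1).to_csv(paths["auc_table"], index=False)

    # Table 2 style: fixed cut-off operating characteristics, metrics as rows
    per_ds = {
        ds: rocs[ds].point_at(c_star).as_dict() for ds in sorted(rocs)
    }
    t2 = pd.DataFrame(
        {ds: [per_ds[ds][key] for _, key in _METRIC_ROWS] for ds in per_ds},
        index=[label for label, _ in _METRIC_ROWS],
    )
    t2.index.name = f"Metric (cut-off >= {c_star})"
    payload["fixed_cutoff_table"] = per_ds
    paths["fixed_cutoff_table"] = out_dir / "table_fixed_cutoff.csv"
    _round_frame(t2).to_csv(paths["fixed_cutoff_table"])

    # Table 3 style: per-dataset optimal vs fixed
    t3 = per_dataset_optimal_table(cohorts, c_star)
    payload["optimal_vs_fixed_table"] = t3.to_dict(orient="records")
    paths["optimal_vs_fixed_table"] = out_dir / "table_optimal_vs_fixed.csv"
    _round_frame(t3).to_csv(paths["optimal_vs_fixed_table"], index=False)

    if iu is not None:
        iu_df = iu.per_dataset.copy()
        iu_df["iu_agg"] = [iu.iu_agg[c] for c in iu_df.index]
        iu_df.index.name = "cutoff"
        payload["iu"] = {
            "per_dataset": iu.per_dataset.to_dict(),
            "iu_agg": {str(k): v for k, v in iu.iu_agg.items()},
            "iu_agg_argmin": iu.iu_agg_argmin,
            "per_dataset_minima": dict(iu.per_dataset_minima),
            "auc_targets": dict(iu.auc_targets),
        }
        paths["iu_table"] = out_dir / "table_iu.csv"
        _round_frame(iu_df.reset_index()).to_csv(paths["iu_table"], index=False)

    if icc_table is not None:
        payload["icc"] = icc_table.to_dict(orient="records")
        paths["icc_table"] = out_dir / "table_icc.csv"
        _round_frame(icc_table).to_csv(paths["icc_table"], index=False)

    paths["json"] = out_dir / "report.json"

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        raise TypeError(f"not serialisable: {o!r}")

    with open(paths["json"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_default)
    return paths
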