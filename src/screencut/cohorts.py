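"""Cohort data containers, scoring rules, and delimited-text I/O.

This module is the single source of truth for the score and outcome
conventions used everywhere else in the package:

* a *scale* is a fixed-length Likert questionnaire whose total score is the
  sum of its item responses (optionally reverse-keyed), so the total lives on
  an integer grid ``[n_items * item_min, n_items * item_max]``;
* an *outcome* is binary, coded ``1`` for the event the scale is screening
  for (the "case" whose detection rate is sensitivity) and ``0`` otherwise;
* missing data are handled by listwise deletion with an explicit exclusion
  log — no imputation.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleSpec",
    "CohortDataset",
    "PairedCohort",
    "ColumnSchema",
    "ReadResult",
    "ValidationError",
    "score_items",
    "read_cohorts",
    "read_paired",
    "write_cohorts",
    "write_paired",
    "load_schema",
]


class ValidationError(ValueError):
    """Raised when input data violate the scale or outcome contract."""


@dataclass(frozen=True)
class ScaleSpec:
    """Static description of a summated Likert scale.

    Parameters
    ----------
    n_items
        Number of items; the default (13) matches a 13-item hesitancy
        questionnaire with total scores 13-65.
    item_min, item_max
        Admissible response values per item (default 1-5).
    subscale_map
        Optional named partition of item indices (1-based) into subscales.
    reverse_keyed
        Item indices whose responses are reflected
        (``r -> item_min + item_max - r``) before summing.
    """

    n_items: int = 13
    item_min: int = 1
    item_max: int = 5
    subscale_map: Mapping[str, tuple[int, ...]] | None = None
    reverse_keyed: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValidationError("n_items must be >= 1")
        if self.item_max <= self.item_min:
            raise ValidationError("item_max must exceed item_min")
        object.__setattr__(self, "reverse_keyed", frozenset(self.reverse_keyed))
        bad = [i for i in self.reverse_keyed if not 1 <= i <= self.n_items]
        if bad:
            raise ValidationError(f"reverse_keyed indices out of range: {bad}")
        if self.subscale_map is not None:
            flat: list[int] = []
            frozen = {k: tuple(v) for k, v in self.subscale_map.items()}
            object.__setattr__(self, "subscale_map", frozen)
            for name, idx in frozen.items():
                if not idx:
                    raise ValidationError(f"subscale {name!r} is empty")
                flat.extend(idx)
            if sorted(flat) != list(range(1, self.n_items + 1)):
                raise ValidationError(
                    "subscale_map must partition item indices "
                    f"1..{self.n_items}; got {sorted(flat)}"
                )

    @property
    def score_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.item_max

    @property
    def midpoint(self) -> float:
        """Theoretical neutral total (all items at the response midpoint)."""
        return self.n_items * (self.item_min + self.item_max) / 2

    def candidate_cutoffs(self) -> np.ndarray:
        """Default integer cut-off grid ``score_min .. score_max + 1``.

        The extra top value makes the degenerate "nobody positive" corner of
        the ROC reachable under the ``score >= c`` classification rule.
        """
        return np.arange(self.score_min, self.score_max + 2)


def score_items(items: Sequence[int], scale: ScaleSpec) -> int:
    """Total score for one respondent's item responses.

    Reverse-keyed items are reflected before summation. Raises
    :class:`ValidationError` naming the offending item for out-of-range
    responses or a wrong-length vector.
    """
    arr = np.asarray(items)
    if arr.shape != (scale.n_items,):
        raise ValidationError(
            f"expected {scale.n_items} item responses, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("item responses must be integers")
        arr = arr.astype(int)
    for pos, r in enumerate(arr, start=1):
        if not scale.item_min <= r <= scale.item_max:
            raise ValidationError(
                f"item {pos} response {r} outside "
                f"[{scale.item_min}, {scale.item_max}]"
            )
    vals = arr.copy()
    if scale.reverse_keyed:
        rev = np.array(sorted(scale.reverse_keyed)) - 1
        vals[rev] = scale.item_min + scale.item_max - vals[rev]
    return int(vals.sum())


@dataclass(frozen=True)
class CohortDataset:
    """One cohort of single-timepoint assessments.

    ``outcomes`` uses 1 for the screening-positive reference event (e.g. a
    history of vaccine refusal) and 0 otherwise; sensitivity is always the
    detection rate of outcome 1.
    """

    dataset_id: str
    participant_ids: np.ndarray
    scores: np.ndarray
    outcomes: np.ndarray
    scale: ScaleSpec = field(default_factory=ScaleSpec)

    def __post_init__(self) -> None:
        ids = np.asarray(self.participant_ids, dtype=object)
        scores = np.asarray(self.scores)
        outcomes = np.asarray(self.outcomes)
        if not (len(ids) == len(scores) == len(outcomes)):
            raise ValidationError("ids, scores and outcomes must align")
        if len(scores) == 0:
            raise ValidationError(f"cohort {self.dataset_id!r} is empty")
        if not np.issubdtype(scores.dtype, np.integer):
            if np.any(scores != np.floor(scores)):
                raise ValidationError("scores must be integers")
            scores = scores.astype(np.int64)
        lo, hi = self.scale.score_min, self.scale.score_max
        bad = (scores < lo) | (scores > hi)
        if bad.any():
            raise ValidationError(
                f"cohort {self.dataset_id!r}: {int(bad.sum())} score(s) "
                f"outside [{lo}, {hi}]"
            )
        if not np.isin(outcomes, (0, 1)).all():
            raise ValidationError(
                f"cohort {self.dataset_id!r}: outcomes must be 0/1"
            )
        if any(not str(x) for x in ids):
            raise ValidationError("participant ids must be non-empty")
        object.__setattr__(self, "participant_ids", ids)
        object.__setattr__(self, "scores", scores.astype(np.int64))
        object.__setattr__(self, "outcomes", outcomes.astype(np.int64))

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_pos(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos

    @property
    def prevalence(self) -> float:
        return self.n_pos / len(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": self.dataset_id,
                "participant_id": self.participant_ids,
                "score": self.scores,
                "outcome": self.outcomes,
            }
        )


@dataclass(frozen=True)
class PairedCohort:
    """Two administrations of the scale to the same participants."""

    dataset_id: str
    participant_ids: np.ndarray
    scores_t1: np.ndarray
    scores_t2: np.ndarray
    scale: ScaleSpec = field(default_factory=ScaleSpec)
    interval_weeks: float | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.participant_ids, dtype=object)
        t1 = np.asarray(self.scores_t1).astype(np.int64)
        t2 = np.asarray(self.scores_t2).astype(np.int64)
        if not (len(ids) == len(t1) == len(t2)):
            raise ValidationError("paired columns must align")
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = list(dupes[dupes > 1].index)
            raise ValidationError(f"duplicate participant ids: {dupes}")
        lo, hi = self.scale.score_min, self.scale.score_max
        for name, col in (("t1", t1), ("t2", t2)):
            if ((col < lo) | (col > hi)).any():
                raise ValidationError(f"{name} scores outside [{lo}, {hi}]")
        object.__setattr__(self, "participant_ids", ids)
        object.__setattr__(self, "scores_t1", t1)
        object.__setattr__(self, "scores_t2", t2)

    def __len__(self) -> int:
        return len(self.scores_t1)

    def matrix(self) -> np.ndarray:
        """n x 2 score matrix (subjects by administrations)."""
        return np.column_stack([self.scores_t1, self.scores_t2]).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": self.dataset_id,
                "participant_id": self.participant_ids,
                "score_t1": self.scores_t1,
                "score_t2": self.scores_t2,
            }
        )


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from a file's column names onto the canonical roles.

    ``outcome_map`` recodes raw outcome values onto {0, 1}; values absent
    from the map raise. Item columns, when given, are summed through
    :func:`score_items` instead of reading a total-score column.
    """

    dataset: str = "dataset"
    participant_id: str = "participant_id"
    score: str = "score"
    outcome: str = "outcome"
    items: tuple[str, ...] | None = None
    score_t1: str = "score_t1"
    score_t2: str = "score_t2"
    outcome_map: Mapping[object, int] | None = None


@dataclass(frozen=True)
class ReadResult:
    cohorts: list[CohortDataset]
    exclusions: pd.DataFrame  # columns: row, dataset, reason


def load_schema(path: str) -> tuple[ColumnSchema, ScaleSpec]:
    """Read a YAML config declaring column names and the scale geometry."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    scale_cfg = cfg.get("scale", {})
    subs = scale_cfg.get("subscale_map")
    scale = ScaleSpec(
        n_items=scale_cfg.get("n_items", 13),
        item_min=scale_cfg.get("item_min", 1),
        item_max=scale_cfg.get("item_max", 5),
        subscale_map={k: tuple(v) for k, v in subs.items()} if subs else None,
        reverse_keyed=frozenset(scale_cfg.get("reverse_keyed", ())),
    )
    col_cfg = dict(cfg.get("columns", {}))
    if "items" in col_cfg and col_cfg["items"] is not None:
        col_cfg["items"] = tuple(col_cfg["items"])
    if "outcome_map" in col_cfg and col_cfg["outcome_map"] is not None:
        col_cfg["outcome_map"] = dict(col_cfg["outcome_map"])
    return ColumnSchema(**col_cfg), scale


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python", dtype=object)
    return pd.read_csv(path, sep=delimiter, dtype=object)


def _coerce_outcome(raw: object, schema: ColumnSchema) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if schema.outcome_map is not None:
        if raw in schema.outcome_map:
            return int(schema.outcome_map[raw])
        raise ValidationError(f"outcome value {raw!r} not in outcome_map")
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"outcome value {raw!r} is not coercible to 0/1")
    if val not in (0.0, 1.0):
        raise ValidationError(f"outcome value {raw!r} outside {{0, 1}}")
    return int(val)


def read_cohorts(
    path,
    schema: ColumnSchema | None = None,
    scale: ScaleSpec | None = None,
    delimiter: str | None = None,
) -> ReadResult:
    """Read a long-format delimited file into per-dataset cohorts.

    One :class:`CohortDataset` is produced per distinct dataset label. Rows
    missing any required field are dropped (complete-case) and recorded in
    the exclusion log; malformed values in present fields raise with row
    numbers.
    """
    schema = schema or ColumnSchema()
    scale = scale or ScaleSpec()
    df = _read_table(path, delimiter)

    needed = [schema.dataset, schema.participant_id, schema.outcome]
    score_cols = list(schema.items) if schema.items else [schema.score]
    missing_cols = [c for c in needed + score_cols if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")

    rows: list[dict] = []
    dropped: list[dict] = []
    for i, rec in df.iterrows():
        row_no = int(i) + 2  # header is line 1
        label = rec[schema.dataset]
        pid = rec[schema.participant_id]
        fields = [label, pid, rec[schema.outcome]] + [rec[c] for c in score_cols]
        if any(pd.isna(v) for v in fields):
            dropped.append(
                {
                    "row": row_no,
                    "dataset": None if pd.isna(label) else str(label),
                    "reason": "missing required field",
                }
            )
            continue
        outcome = _coerce_outcome(rec[schema.outcome], schema)
        if schema.items:
            try:
                responses = [int(float(rec[c])) for c in score_cols]
            except (TypeError, ValueError):
                raise ValidationError(f"row {row_no}: non-integer item response")
            score = score_items(responses, scale)
        else:
            raw_score = rec[schema.score]
            try:
                fscore = float(raw_score)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {row_no}: score {raw_score!r} is not numeric"
                )
            if fscore != int(fscore):
                raise ValidationError(
                    f"row {row_no}: score {raw_score!r} is not an integer"
                )
            score = int(fscore)
        rows.append(
            {
                "dataset": str(label),
                "participant_id": str(pid),
                "score": score,
                "outcome": outcome,
            }
        )

    kept = pd.DataFrame(rows, columns=["dataset", "participant_id", "score", "outcome"])
    cohorts = []
    if len(kept):
        for label, grp in kept.groupby("dataset", sort=True):
            cohorts.append(
                CohortDataset(
                    dataset_id=str(label),
                    participant_ids=grp["participant_id"].to_numpy(object),
                    scores=grp["score"].to_numpy(np.int64),
                    outcomes=grp["outcome"].to_numpy(np.int64),
                    scale=scale,
                )
            )
    exclusions = pd.DataFrame(dropped, columns=["row", "dataset", "reason"])
    return ReadResult(cohorts=cohorts, exclusions=exclusions)


def read_paired(
    path,
    schema: ColumnSchema | None = None,
    scale: ScaleSpec | None = None,
    delimiter: str | None = None,
    dataset_id: str = "paired",
    interval_weeks: float | None = None,
) -> tuple[PairedCohort, pd.DataFrame]:
    """Read a two-administration file keyed by participant id.

    Accepts either wide rows (``score_t1``/``score_t2`` columns; rows missing
    either administration are excluded and logged) or a long layout with a
    ``timepoint`` column taking values 1/2, which is pivoted and inner-joined
    on participant id. Duplicate ids within a timepoint raise.
    """
    schema = schema or ColumnSchema()
    scale = scale or ScaleSpec()
    df = _read_table(path, delimiter)

    if schema.score_t1 in df.columns and schema.score_t2 in df.columns:
        wide = df[[schema.participant_id, schema.score_t1, schema.score_t2]].copy()
        wide.columns = ["participant_id", "score_t1", "score_t2"]
    elif "timepoint" in df.columns:
        long = df[[schema.participant_id, "timepoint", schema.score]].copy()
        long.columns = ["participant_id", "timepoint", "score"]
        long["timepoint"] = long["timepoint"].astype(float).astype(int)
        for tp, grp in long.groupby("timepoint"):
            dupes = grp["participant_id"][grp["participant_id"].duplicated()]
            if len(dupes):
                raise ValidationError(
                    f"duplicate participant ids at timepoint {tp}: "
                    f"{sorted(set(dupes))}"
                )
        wide = long.pivot(index="participant_id", columns="timepoint", values="score")
        wide = wide.rename(columns={1: "score_t1", 2: "score_t2"}).reset_index()
        if "score_t1" not in wide.columns or "score_t2" not in wide.columns:
            raise ValidationError("timepoint column must contain both 1 and 2")
    else:
        raise ValidationError(
            f"need columns {schema.score_t1}/{schema.score_t2} or a "
            "'timepoint' column"
        )

    incomplete = wide["score_t1"].isna() | wide["score_t2"].isna()
    log = pd.DataFrame(
        {
            "participant_id": wide.loc[incomplete, "participant_id"],
            "reason": "missing one administration",
        }
    ).reset_index(drop=True)
    wide = wide[~incomplete]
    if not len(wide):
        raise ValidationError("no overlapping participants across timepoints")
    dupes = wide["participant_id"][wide["participant_id"].duplicated()]
    if len(dupes):
        raise ValidationError(
            f"duplicate participant ids: {sorted(set(dupes))}"
        )
    return (
        PairedCohort(
            dataset_id=dataset_id,
            participant_ids=wide["participant_id"].astype(str).to_numpy(object),
            scores_t1=wide["score_t1"].astype(float).to_numpy(),
            scores_t2=wide["score_t2"].astype(float).to_numpy(),
            scale=scale,
            interval_weeks=interval_weeks,
        ),
        log,
    )


def write_cohorts(cohorts: Iterable[CohortDataset], path) -> None:
    """Write cohorts in the canonical long CSV layout (round-trips exactly)."""
    frame = pd.concat([c.to_frame() for c in cohorts], ignore_index=True)
    if isinstance(path, io.TextIOBase):
        frame.to_csv(path, index=False)
    else:
        frame.to_csv(path, index=False)


def write_paired(paired: PairedCohort, path) -> None:
    paired.to_frame().to_csv(path, index=False)
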