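"""Placement-combination experiments with participant-exclusive nested CV.

Enumerates the non-empty placement subsets (31 for five wear sites), builds
nested cross-validation plans that never let a participant's windows cross
a train/validation/test boundary, and runs random-forest models — three
binary category tasks, individual-activity recognition, and MET regression
— per combination. Hyperparameters are tuned on inner folds only; the final
model per outer fold is refit on the full development set and predictions
are emitted for that fold's held-out test participants exclusively.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import evaluation
from .features import FEATURE_NAMES
from .placements import PLACEMENTS, placements_to_code

logger = logging.getLogger(__name__)

DEFAULT_HYPER_GRID: dict[str, list] = {
    "n_estimators": [300],
    "max_features": ["sqrt", 0.3333],
    "min_samples_leaf": [1, 5],
}


@dataclass(frozen=True)
class PlacementSet:
    members: tuple[str, ...]
    code: str

    @classmethod
    def from_members(cls, members) -> "PlacementSet":
        ordered = tuple(p for p in PLACEMENTS if p in set(members))
        return cls(members=ordered, code=placements_to_code(ordered))

    def feature_columns(self) -> list[str]:
        return [f"{p}_{f}" for p in self.members for f in FEATURE_NAMES]


@dataclass(frozen=True)
class TaskSpec:
    """A modeling task: what to predict and how to score it."""

    name: str
    kind: str  # "binary" | "multiclass" | "regression"
    label_column: str
    metric: str  # "balanced_accuracy" | "accuracy" | "rmse"

    def __post_init__(self):
        expected = {"binary": "balanced_accuracy", "multiclass": "accuracy", "regression": "rmse"}
        if expected[self.kind] != self.metric:
            raise ValueError(f"task {self.name!r}: metric {self.metric!r} does not match kind")


DEFAULT_TASKS: tuple[TaskSpec, ...] = (
    TaskSpec("sedentary_vs_non", "binary", "is_sedentary", "balanced_accuracy"),
    TaskSpec("locomotion_vs_non", "binary", "is_locomotion", "balanced_accuracy"),
    TaskSpec("lifestyle_vs_non", "binary", "is_lifestyle", "balanced_accuracy"),
    TaskSpec("individual", "multiclass", "activity", "accuracy"),
    TaskSpec("met_regression", "regression", "met", "rmse"),
)


@dataclass
class CvPlan:
    """Participant-exclusive nested CV assignment."""

    outer_folds: list[tuple[tuple[str, ...], tuple[str, ...]]]  # (dev, test)
    inner_folds: list[list[tuple[tuple[str, ...], tuple[str, ...]]]]  # per outer: (train, val)

    def validate(self) -> None:
        all_ids: set[str] = set()
        seen_test: set[str] = set()
        for (dev, test), inners in zip(self.outer_folds, self.inner_folds, strict=True):
            dev_s, test_s = set(dev), set(test)
            if dev_s & test_s:
                raise ValueError("development and test sets overlap")
            if seen_test & test_s:
                raise ValueError("participant appears in two outer test sets")
            seen_test |= test_s
            all_ids |= dev_s | test_s
            covered: set[str] = set()
            for train, val in inners:
                train_s, val_s = set(train), set(val)
                if train_s & val_s:
                    raise ValueError("train and validation sets overlap")
                if not (train_s | val_s) <= dev_s:
                    raise ValueError("inner fold leaks outside the development set")
                if covered & val_s:
                    raise ValueError("participant appears in two validation sets")
                covered |= val_s
            if covered != dev_s:
                raise ValueError("inner validation sets do not partition development set")
        if seen_test != all_ids:
            raise ValueError("outer test sets do not partition the participants")


def enumerate_placement_sets(placements=PLACEMENTS) -> list[PlacementSet]:
    """All non-empty subsets, ordered by size then lexicographic code
    (31 sets for the five wear sites)."""
    placements = list(placements)
    if not placements:
        raise ValueError("need at least one placement")
    if len(set(placements)) != len(placements) or len(placements) > 5:
        raise ValueError("placements must be 1-5 distinct wear sites")
    sets = []
    for size in range(1, len(placements) + 1):
        for combo in itertools.combinations(placements, size):
            sets.append(PlacementSet.from_members(combo))
    sets.sort(key=lambda s: (len(s.code), s.code))
    return sets


def make_cv_plan(
    participant_ids,
    n_outer: int = 6,
    n_inner: int = 5,
    seed: int = 0,
) -> CvPlan:
    """Random participant partition into ``n_outer`` near-equal outer test
    sets; each development set is partitioned into ``n_inner`` near-equal
    validation sets. Deterministic given ``seed``."""
    ids = list(participant_ids)
    if len(ids) < n_outer:
        raise ValueError(f"{len(ids)} participants < {n_outer} outer folds")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCF01)))
    shuffled = list(rng.permutation(ids))
    outer_groups = [sorted(map(str, g)) for g in np.array_split(shuffled, n_outer)]

    outer_folds = []
    inner_folds = []
    for i, test in enumerate(outer_groups):
        dev = sorted(itertools.chain.from_iterable(
            g for j, g in enumerate(outer_groups) if j != i
        ))
        if len(dev) < n_inner:
            raise ValueError(
                f"development set of {len(dev)} participants < {n_inner} inner folds"
            )
        dev_shuffled = list(rng.permutation(dev))
        val_groups = [sorted(map(str, g)) for g in np.array_split(dev_shuffled, n_inner)]
        inners = []
        for k, val in enumerate(val_groups):
            train = sorted(itertools.chain.from_iterable(
                g for m, g in enumerate(val_groups) if m != k
            ))
            inners.append((tuple(train), tuple(val)))
        outer_folds.append((tuple(dev), tuple(test)))
        inner_folds.append(inners)
    plan = CvPlan(outer_folds=outer_folds, inner_folds=inner_folds)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def expand_grid(grid: dict[str, list]) -> list[dict]:
    """Cartesian product of a parameter grid into a list of parameter dicts."""
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _make_model(kind: str, params: dict, seed: int):
    cls = RandomForestRegressor if kind == "regression" else RandomForestClassifier
    return cls(random_state=seed, n_jobs=1, **params)


def _score(task: TaskSpec, y_true, y_pred) -> float:
    if task.metric == "balanced_accuracy":
        return evaluation.balanced_accuracy(y_true, y_pred)
    if task.metric == "accuracy":
        return evaluation.accuracy(y_true, y_pred)
    return evaluation.rmse(y_true, y_pred)


def _task_frame(feature_table: pd.DataFrame, task: TaskSpec, columns: list[str]) -> pd.DataFrame:
    df = feature_table
    if task.kind == "regression":
        df = df[df[task.label_column].notna()]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:3]}...")
    return df


def train_and_predict(
    feature_table: pd.DataFrame,
    task: TaskSpec,
    placement_set: PlacementSet,
    cv_plan: CvPlan,
    hyper_grid: dict[str, list] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-CV fit/predict for one task × placement combination.

    Per outer fold, hyperparameters are chosen by the mean inner-fold
    validation metric across the grid, a final model is refit on the whole
    development set, and predictions are emitted for the outer test set
    only. Returns prediction records with columns participant_id,
    window_id, task, code, fold, y_true, y_pred. Outer folds whose training
    data lack a class are flagged and skipped.
    """
    grid = expand_grid(hyper_grid if hyper_grid is not None else DEFAULT_HYPER_GRID)
    columns = placement_set.feature_columns()
    df = _task_frame(feature_table, task, columns)
    higher_better = evaluation.HIGHER_IS_BETTER[task.metric]

    X_all = df[columns].to_numpy(dtype=float)
    y_all = df[task.label_column].to_numpy()
    pid_all = df["participant_id"].to_numpy()
    window_ids = (
        df["participant_id"].astype(str)
        + "|" + df["activity"].astype(str)
        + "|" + df["window_index"].astype(str)
    ).to_numpy()
    n_classes_total = len(np.unique(y_all)) if task.kind != "regression" else 0

    records = []
    for fold_idx, ((dev, test), inners) in enumerate(
        zip(cv_plan.outer_folds, cv_plan.inner_folds, strict=True)
    ):
        fold_seed = int(
            zlib.crc32(f"{task.name}|{placement_set.code}|{fold_idx}|{seed}".encode())
            % (2**31)
        )
        dev_mask = np.isin(pid_all, dev)
        test_mask = np.isin(pid_all, test)
        if not dev_mask.any() or not test_mask.any():
            logger.warning(
                "fold %d of %s/%s has empty development or test data; skipped",
                fold_idx, task.name, placement_set.code,
            )
            continue
        if task.kind != "regression" and len(np.unique(y_all[dev_mask])) < n_classes_total:
            logger.warning(
                "fold %d of %s/%s: class absent from development data; skipped",
                fold_idx, task.name, placement_set.code,
            )
            continue

        if len(grid) == 1:
            best_params = grid[0]
        else:
            mean_scores = []
            for params in grid:
                scores = []
                for train, val in inners:
                    tr = np.isin(pid_all, train)
                    va = np.isin(pid_all, val)
                    if not tr.any() or not va.any():
                        continue
                    if task.kind != "regression" and len(np.unique(y_all[tr])) < 2:
                        logger.warning(
                            "inner fold with single-class training data skipped"
                        )
                        continue
                    model = _make_model(task.kind, params, fold_seed)
                    model.fit(X_all[tr], y_all[tr])
                    try:
                        scores.append(_score(task, y_all[va], model.predict(X_all[va])))
                    except ValueError:
                        continue  # metric undefined on this validation fold
                mean_scores.append(np.mean(scores) if scores else np.nan)
            mean_scores = np.asarray(mean_scores, dtype=float)
            if np.all(np.isnan(mean_scores)):
                best_params = grid[0]
            elif higher_better:
                best_params = grid[int(np.nanargmax(mean_scores))]
            else:
                best_params = grid[int(np.nanargmin(mean_scores))]

        model = _make_model(task.kind, best_params, fold_seed)
        model.fit(X_all[dev_mask], y_all[dev_mask])
        y_pred = model.predict(X_all[test_mask])
        for pid, wid, yt, yp in zip(
            pid_all[test_mask], window_ids[test_mask], y_all[test_mask], y_pred
        ):
            records.append(
                {
                    "participant_id": pid,
                    "window_id": wid,
                    "task": task.name,
                    "code": placement_set.code,
                    "fold": fold_idx,
                    "y_true": yt,
                    "y_pred": yp,
                }
            )
    return pd.DataFrame(
        records,
        columns=["participant_id", "window_id", "task", "code", "fold", "y_true", "y_pred"],
    )


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    predictions: pd.DataFrame
    metrics: pd.DataFrame  # per-fold rows plus pooled rows (fold == -1)

    def cells(self) -> pd.DataFrame:
        """Pooled per (task, code) performance cells for the evaluation stage."""
        return self.metrics[self.metrics["fold"] == -1].reset_index(drop=True)


def _metrics_for_cell(task: TaskSpec, preds: pd.DataFrame) -> list[dict]:
    rows = []
    folds = sorted(preds["fold"].unique())
    for fold in folds + [-1]:
        sub = preds if fold == -1 else preds[preds["fold"] == fold]
        try:
            value = _score(task, sub["y_true"].to_numpy(), sub["y_pred"].to_numpy())
        except ValueError as exc:
            logger.warning("metric undefined for %s fold %s: %s", task.name, fold, exc)
            value = np.nan
        rows.append(
            {
                "task": task.name,
                "code": preds["code"].iloc[0],
                "fold": fold,
                "metric_name": task.metric,
                "value": value,
                "n_windows": len(sub),
                "n_participants": sub["participant_id"].nunique(),
            }
        )
    return rows


def run_full_experiment(
    feature_table: pd.DataFrame,
    cv_plan: CvPlan,
    tasks: tuple[TaskSpec, ...] = DEFAULT_TASKS,
    placement_sets: list[PlacementSet] | None = None,
    hyper_grid: dict[str, list] | None = None,
    seed: int = 0,
    store_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run every task × placement combination through nested CV.

    When ``store_dir`` is given, each cell's prediction records are persisted
    as CSV and previously stored cells are loaded instead of recomputed, so
    an interrupted run resumes where it stopped.
    """
    if placement_sets is None:
        available = [
            p for p in PLACEMENTS
            if f"{p}_{FEATURE_NAMES[0]}" in feature_table.columns
        ]
        placement_sets = enumerate_placement_sets(available)
    store = Path(store_dir) if store_dir is not None else None
    if store is not None:
        store.mkdir(parents=True, exist_ok=True)

    all_preds = []
    metric_rows = []
    for task in tasks:
        for pset in placement_sets:
            missing = [c for c in pset.feature_columns() if c not in feature_table.columns]
            if missing:
                logger.warning(
                    "cell %s/%s skipped: missing features for %s",
                    task.name, pset.code, missing[0],
                )
                continue
            cell_path = store / f"cell_{task.name}_{pset.code}.csv" if store else None
            if cell_path is not None and cell_path.exists():
                preds = pd.read_csv(cell_path)
            else:
                preds = train_and_predict(
                    feature_table, task, pset, cv_plan, hyper_grid, seed
                )
                if cell_path is not None:
                    preds.to_csv(cell_path, index=False)
            if preds.empty:
                logger.warning("cell %s/%s produced no predictions", task.name, pset.code)
                continue
            all_preds.append(preds)
            metric_rows.extend(_metrics_for_cell(task, preds))

    predictions = (
        pd.concat(all_preds, ignore_index=True)
        if all_preds
        else pd.DataFrame(
            columns=["participant_id", "window_id", "task", "code", "fold", "y_true", "y_pred"]
        )
    )
    metrics = pd.DataFrame(
        metric_rows,
        columns=["task", "code", "fold", "metric_name", "value", "n_windows", "n_participants"],
    )
    return ExperimentResult(predictions=predictions, metrics=metrics)
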