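"""Metrics, placement-combination rankings and the guideline-table rule.

Provides balanced accuracy (mean of sensitivity and specificity), total
accuracy, RMSE, multiclass confusion matrices, difference-vs-all-placements
ranking tables, and the most-efficient-combination selection rule that
condenses per-combination performance into one guideline row per task
(most accurate combination, most accurate single placement, most efficient
combination under a similarity margin with a wearability tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .placements import DEFAULT_USABILITY_ORDER, code_to_placements

#: Metric direction: True when larger is better.
HIGHER_IS_BETTER = {"balanced_accuracy": True, "accuracy": True, "rmse": False}


def balanced_accuracy(y_true, y_pred, *, pos_label=True) -> float:
    """Mean of sensitivity and specificity for a binary task.

    Raises ValueError when the truth contains only one class (either rate
    would be undefined).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    pos = y_true == pos_label
    if pos.all() or (~pos).all():
        raise ValueError("balanced accuracy undefined: only one class in truth")
    sensitivity = float(np.mean(y_pred[pos] == pos_label))
    specificity = float(np.mean(y_pred[~pos] != pos_label))
    return (sensitivity + specificity) / 2.0


def accuracy(y_true, y_pred) -> float:
    """Fraction of exactly correct labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty records")
    return float(np.mean(y_true == y_pred))


def rmse(y_true, y_pred) -> float:
    """Root mean squared error of predicted minus measured values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty records")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def chance_level(n_classes: int) -> float:
    """Expected percent accuracy of a uniform random guesser, rounded to one
    decimal for display (32 classes -> 3.1)."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return round(100.0 / n_classes, 1)


def confusion_matrix(y_true, y_pred, class_list) -> pd.DataFrame:
    """Counts with rows = actual and columns = predicted classes.

    Raises ValueError naming any label outside ``class_list``.
    """
    class_list = list(class_list)
    index = {c: i for i, c in enumerate(class_list)}
    mat = np.zeros((len(class_list), len(class_list)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred), strict=True):
        if t not in index:
            raise ValueError(f"actual label {t!r} not in class list")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class list")
        mat[index[t], index[p]] += 1
    return pd.DataFrame(mat, index=class_list, columns=class_list)


# ---------------------------------------------------------------------------
# combination rankings and the guideline rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuidelineRow:
    task: str
    most_accurate_combination: tuple[str, float]
    most_accurate_single: tuple[tuple[str, ...], float]
    most_efficient: tuple[str, float]


def _task_cells(cells: pd.DataFrame, task: str) -> pd.DataFrame:
    sub = cells[cells["task"] == task]
    if sub.empty:
        raise ValueError(f"no cells for task {task!r}")
    if sub["code"].duplicated().any():
        raise ValueError(f"duplicate combination codes for task {task!r}")
    return sub


def difference_vs_full(
    cells: pd.DataFrame, task: str, *, full_code: str = "ABCDE"
) -> pd.DataFrame:
    """Rank combinations against the all-placements reference.

    ``cells`` needs columns task, code, metric_name, value. The output adds
    ``difference`` (value minus the all-placements value) and ``n_members``,
    grouped by member count and sorted within each group — decreasing for
    accuracy-type metrics, increasing for RMSE. Sorting uses unrounded
    values; display rounding is left to the caller.
    """
    sub = _task_cells(cells, task)
    full = sub[sub["code"] == full_code]
    if full.empty:
        raise ValueError(f"missing {full_code} cell for task {task!r}")
    ref = float(full["value"].iloc[0])
    metric = str(sub["metric_name"].iloc[0])
    higher_better = HIGHER_IS_BETTER[metric]

    out = sub.copy()
    out["difference"] = out["value"] - ref
    out["n_members"] = out["code"].str.len()
    out = out.sort_values(
        ["n_members", "value", "code"],
        ascending=[True, not higher_better, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def _usability_ranks(code: str, usability_order) -> tuple[int, int]:
    """(best member rank, worst member rank) under the usability preference;
    lower is more usable."""
    rank = {p: i for i, p in enumerate(usability_order)}
    ranks = [rank[p] for p in code_to_placements(code)]
    return min(ranks), max(ranks)


def select_most_efficient(
    cells: pd.DataFrame,
    task: str,
    *,
    margin: float = 0.10,
    margin_mode: str = "relative",
    rule: str = "fewest_first",
    usability_order=DEFAULT_USABILITY_ORDER,
) -> GuidelineRow:
    """Apply the guideline rule to one task's per-combination cells.

    Candidates are combinations whose metric is within the similarity margin
    of the best value: for accuracy-type metrics at least ``best × (1 −
    margin)`` (relative mode) or ``best − margin`` (absolute mode); for RMSE
    at most ``best × (1 + margin)`` or ``best + margin``.

    ``rule`` orders the candidates:

    * ``"fewest_first"`` — fewest members, then wearability of the most
      usable member, then code (the literal fewest-sensors reading);
    * ``"usability_first"`` — wearability of the *least* usable member (a
      combination is only as wearable as its most burdensome sensor), then
      wearability of the most usable member, then fewest members, then code.
    """
    if margin_mode not in ("relative", "absolute"):
        raise ValueError(f"unknown margin_mode {margin_mode!r}")
    if rule not in ("fewest_first", "usability_first"):
        raise ValueError(f"unknown rule {rule!r}")
    sub = _task_cells(cells, task)
    metric = str(sub["metric_name"].iloc[0])
    higher_better = HIGHER_IS_BETTER[metric]

    values = dict(zip(sub["code"], sub["value"].astype(float)))
    best_code = max(values, key=lambda c: values[c]) if higher_better else min(
        values, key=lambda c: values[c]
    )
    best = values[best_code]

    if higher_better:
        cutoff = best * (1 - margin) if margin_mode == "relative" else best - margin
        candidates = [c for c, v in values.items() if v >= cutoff]
    else:
        cutoff = best * (1 + margin) if margin_mode == "relative" else best + margin
        candidates = [c for c, v in values.items() if v <= cutoff]
    if not candidates:  # the best is always its own candidate
        raise RuntimeError("internal error: empty candidate set")

    def sort_key(code: str):
        best_rank, worst_rank = _usability_ranks(code, usability_order)
        if rule == "fewest_first":
            return (len(code), best_rank, code)
        return (worst_rank, best_rank, len(code), code)

    efficient = min(candidates, key=sort_key)

    singles = {c: v for c, v in values.items() if len(c) == 1}
    if singles:
        single_best = max(singles.values()) if higher_better else min(singles.values())
        single_codes = tuple(sorted(c for c, v in singles.items() if v == single_best))
    else:
        single_best = float("nan")
        single_codes = ()

    return GuidelineRow(
        task=task,
        most_accurate_combination=(best_code, best),
        most_accurate_single=(single_codes, single_best),
        most_efficient=(efficient, values[efficient]),
    )


def guideline_table(
    cells: pd.DataFrame,
    tasks: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One guideline row per task, as a display-ready table."""
    if tasks is None:
        tasks = list(dict.fromkeys(cells["task"]))
    rows = []
    for task in tasks:
        g = select_most_efficient(cells, task, **kwargs)
        rows.append(
            {
                "task": task,
                "most_accurate_combination": g.most_accurate_combination[0],
                "most_accurate_value": g.most_accurate_combination[1],
                "most_accurate_single": "; ".join(g.most_accurate_single[0]),
                "most_accurate_single_value": g.most_accurate_single[1],
                "most_efficient_combination": g.most_efficient[0],
                "most_efficient_value": g.most_efficient[1],
            }
        )
    return pd.DataFrame(rows)
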