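"""Apply a decision tree to a cohort: cascade accounting and error rates.

Each record is run down the tree: at every step its composite-index score is
compared with the frozen threshold under the step's direction, and the first
positive comparison assigns the step's target group; a record that survives
every step receives the terminal non-target label. With the ``"strict"``
boundary convention (the published tree's), a score exactly at a threshold
follows the non-target branch.

Evaluation retains misclassified records at each step — a record wrongly
peeled at step 1 can never be recovered later — and reports the 4×4
confusion matrix, per-group correct-classification rates (one decimal,
half-up) and per-step branch tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_model import Cohort, Group, PatientRecord
from .logistic_index import evaluate_index
from .tree_builder import DecisionTree

__all__ = ["ConfusionMatrix", "EvaluationReport", "classify", "evaluate", "percent"]


def percent(correct: int, total: int) -> float:
    """Percentage ``100·correct/total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100 * int(correct)) / Decimal(int(total))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _fires(score: float, threshold: float, direction: str, boundary: str) -> bool:
    if direction == "higher_is_positive":
        return score >= threshold if boundary == "inclusive" else score > threshold
    return score <= threshold if boundary == "inclusive" else score < threshold


def classify(tree: DecisionTree, record: PatientRecord) -> Group:
    """Assign exactly one group label to a record by walking the tree."""
    for step in tree.steps:
        score = evaluate_index(step.index, record)
        if _fires(score, step.threshold, step.direction, tree.boundary):
            return step.target_group
    return tree.terminal_pair[1]


def step_scores(tree: DecisionTree, record: PatientRecord) -> list[float]:
    """Index score at every step (for per-record reporting)."""
    return [evaluate_index(step.index, record) for step in tree.steps]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts over the true × assigned label grid."""

    labels: tuple[Group, ...]
    counts: np.ndarray  # shape (len(labels), len(labels)), ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels), len(self.labels)) or (c < 0).any():
            raise ValueError("counts must be a non-negative square matrix over labels")

    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def row_totals(self) -> dict[Group, int]:
        return {g: int(np.asarray(self.counts)[i].sum()) for i, g in enumerate(self.labels)}

    def correct(self, group: Group) -> int:
        i = self.labels.index(group)
        return int(np.asarray(self.counts)[i, i])

    def to_frame(self) -> pd.DataFrame:
        idx = [g.value for g in self.labels]
        return pd.DataFrame(np.asarray(self.counts), index=idx, columns=idx)


@dataclass(frozen=True)
class EvaluationReport:
    """Cascade evaluation: confusion matrix, per-group rates, branch tallies.

    ``branch_tallies[k]`` maps each true group to ``{"reached": r,
    "positive": p}``: of the *r* records of that group surviving to step k,
    *p* took the step's target branch.
    """

    confusion: ConfusionMatrix
    per_group: Mapping[Group, tuple[int, int, float]]  # correct, total, pct
    branch_tallies: tuple[Mapping[Group, dict], ...]

    def overall_pct(self) -> float:
        correct = sum(c for c, _, _ in self.per_group.values())
        return percent(correct, self.confusion.total())

    def to_dict(self) -> dict:
        return {
            "confusion": {
                g.value: {
                    h.value: int(self.confusion.counts[i, j])
                    for j, h in enumerate(self.confusion.labels)
                }
                for i, g in enumerate(self.confusion.labels)
            },
            "per_group": {
                g.value: {"correct": c, "total": t, "percent": p}
                for g, (c, t, p) in self.per_group.items()
            },
            "branch_tallies": [
                {g.value: dict(v) for g, v in tally.items()} for tally in self.branch_tallies
            ],
            "overall_percent": self.overall_pct(),
        }


def evaluate(tree: DecisionTree, cohort: Cohort) -> EvaluationReport:
    """Classify every record and account for the full cascade.

    Every record must be labelled and complete for the tree's markers;
    misclassified records are retained downstream exactly as the cascade
    dictates.
    """
    unlabeled = [r.id for r in cohort if r.group is None]
    if unlabeled:
        raise ValueError(
            f"evaluation requires ground-truth labels; unlabeled record(s): {unlabeled[:5]}"
        )
    labels = tuple(g for g in Group if g in cohort.groups()) or tuple(Group)

    assigned: dict[str, Group] = {}
    surviving = list(cohort.records)
    tallies: list[dict[Group, dict]] = []
    for step in tree.steps:
        tally: dict[Group, dict] = {
            g: {"reached": 0, "positive": 0} for g in labels
        }
        next_surviving = []
        for r in surviving:
            score = evaluate_index(step.index, r)
            tally[r.group]["reached"] += 1
            if _fires(score, step.threshold, step.direction, tree.boundary):
                tally[r.group]["positive"] += 1
                assigned[r.id] = step.target_group
            else:
                next_surviving.append(r)
        tallies.append(tally)
        surviving = next_surviving
    for r in surviving:
        assigned[r.id] = tree.terminal_pair[1]

    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for r in cohort:
        i = labels.index(r.group)
        j = labels.index(assigned[r.id])
        counts[i, j] += 1
    confusion = ConfusionMatrix(labels=labels, counts=counts)
    per_group = {
        g: (
            confusion.correct(g),
            confusion.row_totals()[g],
            percent(confusion.correct(g), confusion.row_totals()[g]),
        )
        for g in labels
    }
    return EvaluationReport(
        confusion=confusion, per_group=per_group, branch_tallies=tuple(tallies)
    )


def assignments_frame(tree: DecisionTree, cohort: Cohort) -> pd.DataFrame:
    """Per-record assignment table: id, true group, assigned group, step scores."""
    rows = []
    for r in cohort:
        scores = step_scores(tree, r)
        rows.append(
            {
                "id": r.id,
                "true_group": r.group.value if r.group else "",
                "assigned_group": classify(tree, r).value,
                **{f"step{k + 1}_score": s for k, s in enumerate(scores)},
            }
        )
    return pd.DataFrame(rows)
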