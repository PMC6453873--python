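"""Greedy group-peeling construction of the sequential diagnostic tree.

The algorithm discriminates one diagnostic group at a time. At each step,
for every remaining group a marker set is grown one-vs-rest by C-statistic
gated forward selection: start from the single marker with the best
(orientation-corrected) AUC, then repeatedly refit the logistic model with
each unused candidate added, keeping the addition with the largest AUC gain
only if DeLong's paired test against the current model is significant at
``alpha``. The group whose selected set discriminates best becomes the
step's target; its composite index and Youden-optimal threshold are frozen,
its records are removed ("peeled"), and the procedure repeats. When exactly
two groups remain, the last step's index splits them and both become leaves
— for the four study groups this yields a three-step tree.

Everything is deterministic given the cohort: records are canonically
ordered by patient id before any fit, and ties in AUC are broken toward the
smaller marker set, then a fixed group order (T1D, T2D, HNF1A, GCK).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .cohort_model import BIOMARKER_FIELDS, Cohort, Group, PatientRecord, marker_frame
from .exceptions import (
    DegenerateDiscriminationError,
    SeparationError,
    SingularDesignError,
    SmallSampleError,
)
from .logistic_index import (
    CompositeIndex,
    LogisticFit,
    evaluate_index_frame,
    fit_logistic,
    index_from_fit,
)
from .roc_stats import AucResult, auc_from_labels, roc_curve, select_threshold

__all__ = [
    "TreeStep",
    "DecisionTree",
    "forward_select_markers",
    "build_tree",
    "published_tree",
    "tree_to_json",
    "tree_from_json",
    "GROUP_TIE_ORDER",
]

#: fixed group order used only to break exact AUC ties reproducibly
GROUP_TIE_ORDER: tuple[Group, ...] = (Group.T1D, Group.T2D, Group.HNF1A, Group.GCK)

_MIN_GROUP_N = 10
_AUC_EPS = 1e-6


@dataclass(frozen=True)
class TreeStep:
    """One peel: a target group, its composite index and frozen threshold."""

    target_group: Group
    index: CompositeIndex
    threshold: float
    direction: str
    auc: AucResult
    sensitivity: float | None = None
    specificity: float | None = None


@dataclass(frozen=True)
class DecisionTree:
    """Ordered steps plus the terminal two-group split.

    ``boundary`` fixes how a score exactly at a threshold is handled:
    ``"strict"`` sends it down the non-target branch (the published tree's
    convention), ``"inclusive"`` counts it as a target call (the convention
    under which build-time Youden sensitivity/specificity are exact).
    """

    steps: tuple[TreeStep, ...]
    terminal_pair: tuple[Group, Group]
    candidate_markers: tuple[str, ...]
    boundary: str = "strict"
    version: str = "1"

    def __post_init__(self) -> None:
        targets = [s.target_group for s in self.steps]
        if len(set(targets)) != len(targets):
            raise ValueError("a group may be targeted by at most one step")
        if self.boundary not in ("strict", "inclusive"):
            raise ValueError(f"unknown boundary convention {self.boundary!r}")
        if self.steps and self.steps[-1].target_group != self.terminal_pair[0]:
            raise ValueError("the last step must target the first terminal group")

    def groups(self) -> tuple[Group, ...]:
        """Every group reachable as a leaf, in step order."""
        return tuple(s.target_group for s in self.steps) + (self.terminal_pair[1],)

    def markers_used(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.steps:
            for m in s.index.markers:
                if m not in seen:
                    seen.append(m)
        return tuple(seen)


def _canonical_pool(pool: Sequence[str]) -> list[str]:
    """Sort a marker pool into the canonical order (pool-order invariance)."""
    canon = list(BIOMARKER_FIELDS)
    return sorted(set(pool), key=lambda m: (canon.index(m) if m in canon else len(canon), m))


def forward_select_markers(
    records: Sequence[PatientRecord] | Cohort,
    target: Group,
    pool: Sequence[str],
    alpha: float = 0.05,
) -> tuple[tuple[str, ...], LogisticFit | None, AucResult]:
    """C-statistic gated forward selection of markers for target-vs-rest.

    Returns the selected markers (in order of addition), the final logistic
    fit (``None`` when the set is a single marker whose logistic fit
    separates — the marker itself is then the score) and the AUC of the
    selected model. Candidate fits that hit separation are skipped with a
    warning rather than aborting the search.
    """
    from .roc_stats import delong_paired_test

    if isinstance(records, Cohort):
        records = records.records
    pool = _canonical_pool(pool)
    if not pool:
        raise ValueError("marker pool must be non-empty")
    y = np.array([r.group == target for r in records], dtype=bool)
    if not y.any():
        raise ValueError(f"target group {target.value} absent from the records")
    df = marker_frame(records, pool)

    # rank single markers by orientation-corrected AUC
    oriented: dict[str, tuple[float, bool]] = {}
    for m in pool:
        a = auc_from_labels(df[m].to_numpy(), y).auc
        oriented[m] = (max(a, 1.0 - a), a >= 0.5)
    best = max(pool, key=lambda m: (oriented[m][0], -pool.index(m)))
    higher = oriented[best][1]
    selected = [best]
    scores = df[best].to_numpy() if higher else -df[best].to_numpy()

    fit: LogisticFit | None = None
    try:
        fit = fit_logistic(df, y, selected)
        scores = fit.linear_predictor(df[selected].to_numpy())
    except (SeparationError, SingularDesignError) as exc:
        warnings.warn(f"single-marker fit for {best!r} failed ({exc}); using the raw marker")

    if len(pool) > 1:
        while True:
            remaining = [m for m in pool if m not in selected]
            if not remaining:
                break
            candidates = []
            for m in remaining:
                try:
                    cand_fit = fit_logistic(df, y, selected + [m])
                except (SeparationError, SingularDesignError) as exc:
                    warnings.warn(f"candidate {m!r} skipped: {exc}")
                    continue
                cand_scores = cand_fit.linear_predictor(df[selected + [m]].to_numpy())
                cand_auc = auc_from_labels(cand_scores, y).auc
                candidates.append((cand_auc, m, cand_fit, cand_scores))
            if not candidates:
                break
            cand_auc, m, cand_fit, cand_scores = max(candidates, key=lambda t: t[0])
            current_auc = auc_from_labels(scores, y).auc
            if cand_auc <= current_auc:
                break
            _, p = delong_paired_test(cand_scores, scores, y)
            if p >= alpha:
                break
            selected.append(m)
            fit, scores = cand_fit, cand_scores

    return tuple(selected), fit, auc_from_labels(scores, y)


def _step_from_selection(
    records: Sequence[PatientRecord],
    target: Group,
    markers: tuple[str, ...],
    fit: LogisticFit | None,
    auc: AucResult,
) -> TreeStep:
    """Freeze a composite index and Youden threshold for a selected set."""
    y = np.array([r.group == target for r in records], dtype=bool)
    df = marker_frame(records, markers)
    if fit is not None and fit.converged:
        index = index_from_fit(fit)
    elif len(markers) == 1:
        # single marker whose logistic fit separated: weight 1, direction
        # from the AUC orientation (monotone-equivalent to any fit)
        a = auc_from_labels(df[markers[0]].to_numpy(), y).auc
        direction = "higher_is_positive" if a >= 0.5 else "lower_is_positive"
        index = CompositeIndex(markers=markers, weights=(1.0,), direction=direction)
    else:
        raise ValueError("multi-marker selection requires a converged logistic fit")
    raw = evaluate_index_frame(index, df)
    oriented = raw if index.direction == "higher_is_positive" else -raw
    choice = select_threshold(roc_curve(oriented, y))
    threshold = choice.threshold if index.direction == "higher_is_positive" else -choice.threshold
    index = replace(index, threshold=float(threshold))
    return TreeStep(
        target_group=target,
        index=index,
        threshold=float(threshold),
        direction=index.direction,
        auc=auc,
        sensitivity=choice.sensitivity,
        specificity=choice.specificity,
    )


def build_tree(
    cohort: Cohort,
    pool: Sequence[str] = BIOMARKER_FIELDS,
    alpha: float = 0.05,
) -> DecisionTree:
    """Build the full peeling tree from a labelled cohort.

    Requires at least three groups and at least ``10`` records per group at
    every step. Deterministic given the cohort content (record order is
    canonicalized internally).
    """
    pool = tuple(_canonical_pool(pool))
    records = sorted(cohort.records, key=lambda r: r.id)
    groups_present = {r.group for r in records}
    if None in groups_present:
        raise ValueError("every record must carry a group label to build a tree")
    if len(groups_present) < 3:
        raise ValueError("tree building requires at least 3 groups")

    remaining = [g for g in GROUP_TIE_ORDER if g in groups_present]
    steps: list[TreeStep] = []
    while len(remaining) >= 2:
        sizes = {g: sum(r.group == g for r in records) for g in remaining}
        small = [g for g, n in sizes.items() if n < _MIN_GROUP_N]
        if small:
            raise SmallSampleError(
                f"group(s) below the minimum of {_MIN_GROUP_N} records at this step: "
                + ", ".join(f"{g.value} (n={sizes[g]})" for g in small)
            )
        results = {}
        for g in remaining:
            results[g] = forward_select_markers(records, g, pool, alpha=alpha)
        # highest AUC wins; ties -> fewer markers, then fixed group order
        best_group = min(
            remaining,
            key=lambda g: (-results[g][2].auc, len(results[g][0]), GROUP_TIE_ORDER.index(g)),
        )
        markers, fit, auc = results[best_group]
        if auc.auc <= 0.5 + _AUC_EPS:
            raise DegenerateDiscriminationError(
                f"best achievable AUC {auc.auc:.3f} is not better than chance"
            )
        steps.append(_step_from_selection(records, best_group, markers, fit, auc))
        if len(remaining) == 2:
            other = next(g for g in remaining if g != best_group)
            return DecisionTree(
                steps=tuple(steps),
                terminal_pair=(best_group, other),
                candidate_markers=pool,
                boundary="inclusive",
            )
        records = [r for r in records if r.group != best_group]
        remaining = [g for g in remaining if g != best_group]
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization and the published tree
# ---------------------------------------------------------------------------

def _auc_to_dict(a: AucResult) -> dict:
    return {
        "auc": a.auc,
        "variance": a.variance,
        "ci_low": a.ci_low,
        "ci_high": a.ci_high,
        "n_pos": a.n_pos,
        "n_neg": a.n_neg,
    }


def _auc_from_dict(d: dict) -> AucResult:
    var = d.get("variance")
    if var is None:
        # reconstruct from the Wald CI width
        var = ((d["ci_high"] - d["ci_low"]) / (2 * 1.959963984540054)) ** 2
    return AucResult(
        auc=d["auc"],
        variance=float(var),
        ci_low=d["ci_low"],
        ci_high=d["ci_high"],
        n_pos=int(d["n_pos"]),
        n_neg=int(d["n_neg"]),
    )


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "version": tree.version,
        "boundary": tree.boundary,
        "candidate_markers": list(tree.candidate_markers),
        "terminal_pair": [g.value for g in tree.terminal_pair],
        "steps": [
            {
                "target_group": s.target_group.value,
                "markers": list(s.index.markers),
                "weights": list(s.index.weights),
                "direction": s.direction,
                "threshold": s.threshold,
                "auc": _auc_to_dict(s.auc),
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
            }
            for s in tree.steps
        ],
    }


def tree_from_dict(d: dict) -> DecisionTree:
    steps = []
    for sd in d["steps"]:
        index = CompositeIndex(
            markers=tuple(sd["markers"]),
            weights=tuple(float(w) for w in sd["weights"]),
            direction=sd["direction"],
            threshold=float(sd["threshold"]),
        )
        steps.append(
            TreeStep(
                target_group=Group(sd["target_group"]),
                index=index,
                threshold=float(sd["threshold"]),
                direction=sd["direction"],
                auc=_auc_from_dict(sd["auc"]),
                sensitivity=sd.get("sensitivity"),
                specificity=sd.get("specificity"),
            )
        )
    return DecisionTree(
        steps=tuple(steps),
        terminal_pair=tuple(Group(g) for g in d["terminal_pair"]),  # type: ignore[arg-type]
        candidate_markers=tuple(d["candidate_markers"]),
        boundary=d.get("boundary", "strict"),
        version=str(d.get("version", "1")),
    )


def tree_to_json(tree: DecisionTree, path=None) -> str:
    text = json.dumps(tree_to_dict(tree), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def tree_from_json(source) -> DecisionTree:
    """Load a tree from a JSON string or file path."""
    text = str(source)
    if not text.lstrip().startswith("{"):
        with open(source) as fh:
            text = fh.read()
    return tree_from_dict(json.loads(text))


def published_tree() -> DecisionTree:
    """The published three-step tree, shipped as a versioned JSON fixture.

    Step 1: C-peptide < 0.6 ng/ml → type 1 diabetes.
    Step 2: C-peptide + 0.16·BMI > 6.29 → type 2 diabetes.
    Step 3: 1,5-AG + 1.56·hsCRP < 10.16 → HNF1A MODY, otherwise GCK MODY.
    """
    text = resources.files("modytree").joinpath("data/published_tree.json").read_text()
    return tree_from_dict(json.loads(text))
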