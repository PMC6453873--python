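"""Forward selection and greedy group-peeling tree construction."""

import json
import random

import numpy as np
import pytest

import modytree as mt
from modytree.tree_builder import tree_from_dict, tree_to_dict


def _record(i, group, **markers):
    defaults = dict(c_peptide=1.0, bmi=25.0, ag15=5.0, hscrp=1.0, fasting_glucose=6.0)
    defaults.update(markers)
    return mt.PatientRecord(id=f"r{i:04d}", group=group, **defaults)


def _noise_cohort(rng, groups, n_per_group, shifts=None):
    """Cohort with iid lognormal noise markers, plus optional per-group shifts."""
    records = []
    i = 0
    for g in groups:
        for _ in range(n_per_group):
            vals = {
                m: float(np.exp(rng.normal(0, 0.3)))
                for m in ("c_peptide", "bmi", "ag15", "hscrp", "fasting_glucose")
            }
            if shifts and g in shifts:
                for m, s in shifts[g].items():
                    vals[m] += s
            records.append(_record(i, g, **vals))
            i += 1
    return mt.Cohort(records)


def test_pool_of_one_returns_that_marker(default_cohort):
    markers, fit, auc = mt.forward_select_markers(
        default_cohort, mt.Group.T2D, ["bmi"], alpha=0.05
    )
    assert markers == ("bmi",)
    assert auc.auc > 0.5


def test_perfect_marker_selected_alone_with_noise_pool():
    """A marker that separates the target perfectly wins on its own; pure
    noise markers never pass the significance gate."""
    rng = np.random.default_rng(77)
    cohort = _noise_cohort(
        rng,
        [mt.Group.T1D, mt.Group.T2D, mt.Group.HNF1A],
        40,
        shifts={mt.Group.T1D: {"c_peptide": 50.0}},
    )
    markers, fit, auc = mt.forward_select_markers(
        cohort, mt.Group.T1D, mt.BIOMARKER_FIELDS, alpha=0.05
    )
    assert markers == ("c_peptide",)
    assert auc.auc == 1.0


def test_complementary_markers_both_selected():
    """Two markers each ~0.75 AUC alone but ~0.95 jointly (negatively
    correlated bivariate normal shifts) are both retained, lead first."""
    rng = np.random.default_rng(2024)
    n = 400
    y = np.arange(n) < n // 2
    rho, delta = -0.664, 0.954
    cov = np.array([[1.0, rho], [rho, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n) + delta * y[:, None]
    records = [
        _record(i, mt.Group.HNF1A if y[i] else mt.Group.GCK,
                ag15=float(10 + xy[i, 0]), hscrp=float(10 + xy[i, 1]))
        for i in range(n)
    ]
    cohort = mt.Cohort(records)
    markers, fit, auc = mt.forward_select_markers(
        cohort, mt.Group.HNF1A, ["ag15", "hscrp"], alpha=0.05
    )
    assert set(markers) == {"ag15", "hscrp"}
    singles = {
        m: max(a := mt.auc_from_labels([getattr(r, m) for r in cohort], y).auc, 1 - a)
        for m in ("ag15", "hscrp")
    }
    assert markers[0] == max(singles, key=singles.get)
    assert auc.auc > max(singles.values())


def test_build_tree_recovers_published_structure(default_cohort):
    tree = mt.build_tree(default_cohort)
    assert len(tree.steps) == 3
    assert tree.steps[0].target_group == mt.Group.T1D
    assert tree.steps[0].index.markers == ("c_peptide",)
    assert tree.steps[0].direction == "lower_is_positive"
    assert tree.steps[1].target_group == mt.Group.T2D
    assert {"c_peptide", "bmi"} <= set(tree.steps[1].index.markers)
    assert set(tree.terminal_pair) == {mt.Group.HNF1A, mt.Group.GCK}
    # AUCs decrease down the cascade, as the remaining groups get harder
    aucs = [s.auc.auc for s in tree.steps]
    assert aucs[0] > aucs[1] > aucs[2] > 0.5
    # every group is reachable as a leaf and the step AUC counts the target
    assert set(tree.groups()) == set(mt.Group)
    sizes = default_cohort.group_sizes()
    assert tree.steps[0].auc.n_pos == sizes[mt.Group.T1D]


def test_three_group_cohort_with_separable_group():
    rng = np.random.default_rng(5)
    cohort = _noise_cohort(
        rng,
        [mt.Group.T1D, mt.Group.HNF1A, mt.Group.GCK],
        30,
        shifts={mt.Group.T1D: {"c_peptide": 40.0}, mt.Group.HNF1A: {"ag15": -0.8}},
    )
    tree = mt.build_tree(cohort)
    assert tree.steps[0].target_group == mt.Group.T1D
    assert tree.steps[0].auc.auc == 1.0


def test_group_peeling_matches_manual_deletion(default_cohort):
    """Records of a peeled group never influence later steps: building on
    the cohort with the first target removed reproduces steps 2+ exactly."""
    full = mt.build_tree(default_cohort)
    first = full.steps[0].target_group
    reduced = mt.build_tree(default_cohort.subset(lambda r: r.group != first))
    assert tree_to_dict(reduced)["steps"] == tree_to_dict(full)["steps"][1:]


def test_record_permutation_and_pool_order_invariance(default_cohort):
    tree = mt.build_tree(default_cohort)
    shuffled_records = list(default_cohort.records)
    random.Random(3).shuffle(shuffled_records)
    tree_shuffled = mt.build_tree(mt.Cohort(shuffled_records))
    assert tree_to_dict(tree_shuffled) == tree_to_dict(tree)
    tree_pool = mt.build_tree(default_cohort, pool=list(reversed(mt.BIOMARKER_FIELDS)))
    assert tree_to_dict(tree_pool) == tree_to_dict(tree)


def test_retained_additions_strictly_increase_auc(default_cohort):
    """Monotone gate: within every multi-marker step, the selected set's AUC
    strictly exceeds the lead marker's single AUC."""
    tree = mt.build_tree(default_cohort)
    records = sorted(default_cohort.records, key=lambda r: r.id)
    peeled = []
    for step in tree.steps:
        current = [r for r in records if r.group not in peeled]
        y = np.array([r.group == step.target_group for r in current])
        if len(step.index.markers) > 1:
            lead = np.array([getattr(r, step.index.markers[0]) for r in current])
            a = mt.auc_from_labels(lead, y).auc
            assert step.auc.auc > max(a, 1 - a)
        peeled.append(step.target_group)


def test_small_group_aborts():
    rng = np.random.default_rng(1)
    cohort = _noise_cohort(rng, [mt.Group.T1D, mt.Group.T2D], 30)
    merged = mt.Cohort(cohort.records + [
        mt.PatientRecord(id=f"g{i}", group=mt.Group.GCK, c_peptide=1.0, bmi=25.0,
                         ag15=5.0, hscrp=1.0, fasting_glucose=6.0)
        for i in range(5)
    ])
    with pytest.raises(mt.SmallSampleError, match="GCK"):
        mt.build_tree(merged)


def test_constant_markers_are_degenerate():
    records = [
        _record(i, g)
        for i, g in enumerate(
            [mt.Group.T1D] * 15 + [mt.Group.T2D] * 15 + [mt.Group.GCK] * 15
        )
    ]
    with pytest.raises((mt.DegenerateDiscriminationError, mt.SingularDesignError)):
        mt.build_tree(mt.Cohort(records))


def test_fewer_than_three_groups_rejected():
    rng = np.random.default_rng(9)
    cohort = _noise_cohort(rng, [mt.Group.T1D, mt.Group.T2D], 20)
    with pytest.raises(ValueError, match="3 groups"):
        mt.build_tree(cohort)


def test_json_round_trip(default_cohort, tmp_path):
    tree = mt.build_tree(default_cohort)
    path = tmp_path / "tree.json"
    mt.tree_to_json(tree, path)
    back = mt.tree_from_json(path)
    assert tree_to_dict(back) == tree_to_dict(tree)


def test_published_tree_fixture(published):
    assert [s.target_group for s in published.steps] == [
        mt.Group.T1D,
        mt.Group.T2D,
        mt.Group.HNF1A,
    ]
    assert [s.threshold for s in published.steps] == [0.6, 6.29, 10.16]
    assert published.steps[1].index.weights == (1.0, 0.16)
    assert published.steps[2].index.weights == (1.0, 1.56)
    assert published.terminal_pair == (mt.Group.HNF1A, mt.Group.GCK)
    assert published.boundary == "strict"
    # step C-statistics with their confidence intervals
    assert [s.auc.auc for s in published.steps] == [0.976, 0.917, 0.863]
    assert published.steps[0].auc.ci_low == 0.962
    assert published.steps[0].auc.ci_high == 0.989


def test_no_group_targeted_twice(published):
    with pytest.raises(ValueError):
        mt.DecisionTree(
            steps=published.steps + (published.steps[0],),
            terminal_pair=(mt.Group.T1D, mt.Group.GCK),
            candidate_markers=published.candidate_markers,
        )
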