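import numpy as np
import pandas as pd
import pytest

from crcpod.diff_abundance import BiomarkerPanel, case_control_labels
from crcpod.evaluation import roc_auc
from crcpod.pod_model import (
    DecisionTree,
    PODModel,
    mda_importance,
    pod_scores,
    select_biomarkers,
    train_forest,
)
from crcpod.synthetic_data import SyntheticConfig, simulate_cohort, simulate_multi_cohort

from conftest import make_table


def _separable_data(n=30, seed=0):
    """One perfectly separating taxon plus noise taxa (no closure, so the
    separation survives in the stored values)."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) < n // 2
    signal = np.where(y, 10.0, 1.0)
    noise = rng.lognormal(0, 1, size=(4, n))
    table = make_table(np.vstack([signal, noise]))
    return table, y


def test_separable_signal_gives_extreme_training_pod():
    # restrict the panel to the separating taxon: every tree must split on it
    table, y = _separable_data()
    panel = BiomarkerPanel(["s__T0"])
    model = train_forest(table, y, panel, n_trees=50, seed=1)
    pod = model.pod(table)
    np.testing.assert_array_equal(pod[y], 1.0)
    np.testing.assert_array_equal(pod[~y], 0.0)
    assert model.oob_error == pytest.approx(0.0)


def test_same_seed_same_data_bit_identical():
    table, y = _separable_data(seed=3)
    panel = BiomarkerPanel(list(table.taxon_ids))
    m1 = train_forest(table, y, panel, n_trees=25, seed=7)
    m2 = train_forest(table, y, panel, n_trees=25, seed=7)
    assert m1.to_dict() == m2.to_dict()
    np.testing.assert_array_equal(m1.pod(table), m2.pod(table))


def test_permuted_labels_oob_error_near_half():
    rng = np.random.default_rng(0)
    errs = []
    for seed in range(5):
        cfg = SyntheticConfig(n_taxa=30, n_diff=5, effect_fold=4.0,
                              n_case=50, n_control=50, seed=seed)
        table, meta, _ = simulate_cohort(cfg)
        y = rng.permutation(case_control_labels(meta).to_numpy())
        panel = BiomarkerPanel(list(table.taxon_ids))
        model = train_forest(table, y, panel, n_trees=100, seed=seed)
        errs.append(model.oob_error)
    assert abs(np.mean(errs) - 0.5) <= 0.1


def test_single_class_labels_rejected():
    table, y = _separable_data()
    panel = BiomarkerPanel(list(table.taxon_ids))
    with pytest.raises(ValueError, match="both classes"):
        train_forest(table, np.ones_like(y, dtype=bool), panel, n_trees=5)


def test_hand_built_three_tree_vote():
    """Two of three stump trees vote disease for the toy profile: POD 2/3."""

    def stump(feat, thr):
        # left leaf (x <= thr) votes control, right leaf votes case
        return DecisionTree(
            feature=np.array([feat, -1, -1]),
            threshold=np.array([thr, 0.0, 0.0]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            counts=np.array([[10, 10], [8, 0], [0, 8]]),
            oob_idx=np.array([], dtype=np.int64),
        )

    # profile: taxon0 = 0.7, taxon1 = 0.3 (proportions after /100)
    trees = [
        stump(0, 0.5),  # 0.7 > 0.5 -> right -> case
        stump(1, 0.5),  # 0.3 <= 0.5 -> left -> control
        stump(0, 0.1),  # 0.7 > 0.1 -> right -> case
    ]
    panel = BiomarkerPanel(["s__A", "s__B"])
    model = PODModel(trees, panel, "toy", 0.0, 0)
    table = make_table([[70.0], [30.0]], taxa=["s__A", "s__B"])
    assert model.pod(table)[0] == pytest.approx(2.0 / 3.0)


def test_leaf_tie_votes_control():
    tree = DecisionTree(
        feature=np.array([-1]),
        threshold=np.array([0.0]),
        left=np.array([-1]),
        right=np.array([-1]),
        counts=np.array([[5, 5]]),
        oob_idx=np.array([], dtype=np.int64),
    )
    assert tree.predict(np.zeros((3, 1)))[0] == 0


def test_unused_taxon_importance_exactly_zero():
    table, y = _separable_data(n=40, seed=2)
    # add a constant taxon that can never be chosen for a split
    frame = table.data.copy()
    frame.loc["s__unused"] = 0.0
    table2 = make_table(frame.to_numpy(), taxa=list(frame.index),
                        samples=list(frame.columns))
    panel = BiomarkerPanel(list(table2.taxon_ids))
    model = train_forest(table2, y, panel, n_trees=30, seed=4)
    imp = mda_importance(model, table2, y, seed=4)
    assert imp["s__unused"] == 0.0


def test_noise_taxon_importance_near_zero_dominant_taxon_largest():
    """The separating taxon must dominate the MDA ranking; pure-noise taxa
    average to ~0 importance over seeds."""
    noise_means = []
    for seed in range(10):
        table, y = _separable_data(n=60, seed=seed)
        panel = BiomarkerPanel(list(table.taxon_ids))
        model = train_forest(table, y, panel, n_trees=60, seed=seed)
        imp = mda_importance(model, table, y, seed=seed)
        assert imp.idxmax() == "s__T0"
        assert imp["s__T0"] == imp.max()
        noise_means.append(imp.drop("s__T0").mean())
    assert abs(np.mean(noise_means)) <= 0.01


def test_select_biomarkers_rules():
    imp = pd.Series({"b": 0.3, "a": 0.3, "c": 0.1, "d": 0.0})
    full = select_biomarkers(imp, k=4)
    assert len(full) == 4
    top1 = select_biomarkers(imp, k=1)
    assert top1.taxon_ids == ["a"]  # tie with b broken lexicographically
    thresh = select_biomarkers(imp, min_importance=0.05)
    assert thresh.taxon_ids == ["a", "b", "c"]
    with pytest.warns(UserWarning, match="clamping"):
        clamped = select_biomarkers(imp, k=10)
    assert len(clamped) == 4


def test_serialization_round_trip(tmp_path):
    table, y = _separable_data(seed=5)
    panel = BiomarkerPanel(list(table.taxon_ids))
    model = train_forest(table, y, panel, n_trees=20, seed=9)
    path = tmp_path / "model.json"
    model.save(path)
    back = PODModel.load(path)
    assert back.to_dict() == model.to_dict()
    np.testing.assert_array_equal(back.pod(table), model.pod(table))


def test_pod_invariant_under_monotone_transform():
    """Splits are placed at observed values, so applying the same strictly
    monotone per-taxon transform at train and score time leaves every vote
    unchanged — including on unseen samples."""
    cfg = SyntheticConfig(n_taxa=40, n_diff=8, effect_fold=4.0,
                          n_case=40, n_control=40, seed=13)
    table, meta, _ = simulate_cohort(cfg)
    y = case_control_labels(meta)
    test_table, test_meta, _ = simulate_cohort(cfg.model_copy(update={"seed": 14}))
    panel = BiomarkerPanel(list(table.taxon_ids))

    def transform(t):
        frame = np.log10(t.data / 100.0 + 1e-5)  # strictly monotone
        return make_table(frame.to_numpy(), taxa=list(frame.index),
                          samples=list(frame.columns), scale="log10")

    m_raw = train_forest(table, y, panel, n_trees=40, seed=2)
    m_log = train_forest(transform(table), y, panel, n_trees=40, seed=2)
    np.testing.assert_array_equal(m_raw.pod(test_table), m_log.pod(transform(test_table)))


def test_missing_panel_taxon_scored_as_zero():
    table, y = _separable_data()
    panel = BiomarkerPanel(list(table.taxon_ids))
    model = train_forest(table, y, panel, n_trees=20, seed=1)
    reduced = make_table(table.values[1:], taxa=table.taxon_ids[1:],
                         samples=table.sample_ids)
    scores = pod_scores(model, reduced)
    assert scores["pod"].between(0, 1).all()
    assert list(scores.index) == table.sample_ids


def test_forest_matches_sklearn_oracle_on_auc():
    """Independent cross-check: on shared-planted synthetic cohorts my
    forest and scikit-learn's RandomForestClassifier should reach similar
    cross-cohort discrimination."""
    from sklearn.ensemble import RandomForestClassifier

    cfgs = [SyntheticConfig(cohort=c, n_taxa=100, n_diff=10, effect_fold=3.0,
                            n_case=60, n_control=60) for c in ("a", "b")]
    coll, _ = simulate_multi_cohort(cfgs, seed=21)
    ta, ma = coll.cohorts["a"]
    tb, mb = coll.cohorts["b"]
    ya = case_control_labels(ma).to_numpy()
    yb = case_control_labels(mb).to_numpy()
    panel = BiomarkerPanel(list(ta.taxon_ids))
    mine = train_forest(ta, ya, panel, n_trees=200, seed=5)
    auc_mine = roc_auc(mine.pod(tb), yb).auc

    sk = RandomForestClassifier(n_estimators=200, random_state=5)
    sk.fit(ta.sample_matrix(), ya)
    auc_sk = roc_auc(sk.predict_proba(tb.sample_matrix())[:, 1], yb).auc
    assert abs(auc_mine - auc_sk) < 0.05
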