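import numpy as np
import pytest
from sklearn.base import clone
from sklearn.svm import SVC

from flowps import (
    AUCTopogram,
    FloWPSClassifier,
    TrimGrid,
    accountable_set,
    auc_topogram,
    flowps_predict_one,
    loo_evaluate,
    roc_auc,
    svm_cell_predict,
    trim,
)

from conftest import make_ds, random_ds


def corner_grid(ds):
    return TrimGrid((0,), (ds.n_samples - 1,))


# ---------------------------------------------------------------------------
# accountable set


def _topogram(aucs, m_vals, k_vals, valid=None):
    aucs = np.asarray(aucs, dtype=float)
    valid = np.ones_like(aucs, dtype=bool) if valid is None else np.asarray(valid)
    return AUCTopogram(grid=TrimGrid(m_vals, k_vals), auc=aucs, valid=valid)


def test_accountable_set_threshold_arithmetic():
    topo = _topogram([[0.80, 0.73], [0.71, 0.60]], (0, 1), (3, 4))
    s = accountable_set(topo, p=0.90)
    assert s.threshold_theta == pytest.approx(0.72)
    assert set(s.cells) == {(0, 3), (0, 4)}


def test_accountable_set_p1_keeps_argmax_only():
    topo = _topogram([[0.80, 0.95], [0.70, 0.60]], (0, 1), (3, 4))
    assert set(accountable_set(topo, p=1.0).cells) == {(0, 4)}


def test_accountable_set_flat_topogram_keeps_all_valid():
    topo = _topogram([[0.7, 0.7], [0.7, 0.7]], (0, 1), (3, 4),
                     valid=[[True, True], [True, False]])
    assert set(accountable_set(topo, p=0.95).cells) == {(0, 3), (0, 4), (1, 3)}


def test_accountable_set_grows_as_p_drops():
    rng = np.random.default_rng(0)
    topo = _topogram(rng.uniform(0.4, 0.9, size=(4, 5)), tuple(range(4)), tuple(range(3, 8)))
    for p_hi, p_lo in [(1.0, 0.95), (0.95, 0.9), (0.9, 0.5)]:
        assert set(accountable_set(topo, p_hi).cells) <= set(accountable_set(topo, p_lo).cells)


# ---------------------------------------------------------------------------
# cell prediction


def test_single_class_neighbors_short_circuit(separable_ds, default_config):
    t = trim(separable_ds, 0, m=0, k=3)  # nearest neighbors share class 0's side
    # force single-class by selecting neighbors of one class
    labels = np.delete(separable_ds.labels, 0)
    assert len(set(labels[t.neighbor_indices])) == 1
    pred = svm_cell_predict(t, separable_ds, 0, default_config)
    assert pred == float(labels[t.neighbor_indices][0])


def test_cell_predict_separable_toy(default_config):
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-4, 1, (6, 2)), rng.normal(4, 1, (6, 2))])
    X = np.vstack([X, [[3.0, 0.0]]])
    y = [0] * 6 + [100] * 6 + [100]
    ds = make_ds(X, y)
    t = trim(ds, 12, m=0, k=12)
    assert svm_cell_predict(t, ds, 12, default_config) == 100.0


def test_cell_predict_rejects_invalid_trim(default_config):
    ds = random_ds(3, n=8, s=2)
    t = trim(ds, 0, m=99, k=3)
    with pytest.raises(ValueError):
        svm_cell_predict(t, ds, 0, default_config)


# ---------------------------------------------------------------------------
# topogram


def test_corner_topogram_equals_plain_svm_inner_loo(default_config):
    ds = random_ds(11, n=12, s=3)
    topo = auc_topogram(ds, corner_grid(ds), default_config)
    # independent route: SVC leave-one-out by hand
    preds = np.empty(ds.n_samples)
    for j in range(ds.n_samples):
        keep = np.arange(ds.n_samples) != j
        model = SVC(kernel="linear", C=1.0).fit(ds.values[keep], ds.labels[keep])
        preds[j] = model.predict(ds.values[j][None, :])[0]
    assert topo.auc[0, 0] == pytest.approx(roc_auc(preds, ds.labels))


def test_topogram_separable_corner_is_perfect(separable_ds, default_config):
    topo = auc_topogram(separable_ds, corner_grid(separable_ds), default_config)
    assert topo.valid[0, 0]
    assert topo.auc[0, 0] == 1.0


def test_topogram_null_labels_near_half(default_config):
    rng = np.random.default_rng(42)
    ds = random_ds(42, n=40, s=5)  # labels independent of values
    topo = auc_topogram(ds, TrimGrid((0, 1, 2), (20, 30, 39)), default_config)
    assert topo.valid.all()
    assert np.all(np.abs(topo.auc - 0.5) < 0.25)


def test_topogram_marks_unreachable_m_rows_invalid(default_config):
    ds = random_ds(7, n=10, s=2)
    topo = auc_topogram(ds, TrimGrid((0, 8), (5, 9)), default_config)
    assert topo.valid[0].all()
    assert not topo.valid[1].any()
    assert np.isnan(topo.auc[1]).all()


# ---------------------------------------------------------------------------
# per-sample prediction and the LOO harness


def test_forced_corner_reduces_to_classical(default_config):
    ds = random_ds(9, n=12, s=3)
    grid = corner_grid(ds)
    for i in (0, 3, 7):
        rec = flowps_predict_one(ds, i, default_config, grid=grid)
        keep = np.arange(ds.n_samples) != i
        svc = SVC(kernel="linear", C=1.0).fit(ds.values[keep], ds.labels[keep])
        assert rec.p_f == svc.predict(ds.values[i][None, :])[0]
        assert rec.n_cells == 1


def test_p_f_is_vote_mean_in_unit_range(default_config):
    ds = random_ds(13, n=14, s=4)
    grid = TrimGrid((0, 1), (6, 9, 13))
    for i in range(0, 14, 3):
        rec = flowps_predict_one(ds, i, default_config, grid=grid)
        assert 0.0 <= rec.p_f <= 100.0
        if rec.n_cells:
            votes = rec.p_f * rec.n_cells / 100
            assert votes == pytest.approx(round(votes))


def test_loo_separable_dataset_is_perfect(default_config):
    rng = np.random.default_rng(17)
    n = 40
    X = rng.normal(size=(n, 5))
    y = np.array([0] * (n // 2) + [100] * (n // 2))
    X[y == 100, :3] += 6.0
    ds = make_ds(X, y)
    records, report = loo_evaluate(ds, default_config)
    assert report.auc == 1.0
    assert report.fdr == 0.0


def test_loo_null_labels_within_chance_band(default_config):
    ds = random_ds(101, n=40, s=5)
    _, report = loo_evaluate(ds, default_config)
    assert 0.25 <= report.auc <= 0.75


def test_loo_deterministic(default_config):
    ds = random_ds(23, n=12, s=3)
    r1, _ = loo_evaluate(ds, default_config)
    r2, _ = loo_evaluate(ds, default_config)
    assert [r.p_f for r in r1] == [r.p_f for r in r2]


def test_loo_rejects_degenerate_inputs(default_config):
    ds = make_ds(np.random.default_rng(0).normal(size=(6, 2)), [0, 100, 100, 100, 100, 100])
    with pytest.raises(ValueError, match="at least 2"):
        loo_evaluate(ds, default_config)


# ---------------------------------------------------------------------------
# estimator API


def test_estimator_fit_predict_shapes():
    ds = random_ds(31, n=14, s=3)
    est = FloWPSClassifier(kernel="linear", C=1.0, p=0.9)
    est.fit(ds.values, ds.labels)
    assert est.topogram_.valid.any()
    assert est.accountable_set_.cells
    scores = est.decision_function(ds.values[:3])
    assert scores.shape == (3,)
    assert set(est.predict(ds.values[:3])) <= {0, 100}
    assert list(est.classes_) == [0, 100]


def test_estimator_clone_and_params_round_trip():
    est = FloWPSClassifier(kernel="poly", C=10.0, p=0.95, k_min=5)
    params = est.get_params()
    assert params["C"] == 10.0 and params["kernel"] == "poly"
    cl = clone(est)
    assert cl.get_params() == params


def test_estimator_accepts_01_labels():
    ds = random_ds(37, n=12, s=3)
    est = FloWPSClassifier(grid=TrimGrid((0,), (11,)))
    est.fit(ds.values, (ds.labels // 100).astype(int))
    assert set(est.predict(ds.values)) <= {0, 100}
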