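import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from flowps import (
    ClassifierConfig,
    GeneratorSpec,
    classical_svm_loo,
    core_genes,
    equalize_classes,
    make_checkerboard,
    make_dataset,
    make_expression_like,
    make_global_linear,
    quantile_normalize,
    top_n_genes,
)
from flowps.synthetic import informative_genes


@pytest.mark.parametrize("structure", ["global_linear", "checkerboard", "expression_like"])
def test_generators_deterministic_and_balanced(structure):
    spec = GeneratorSpec(
        n_samples=20,
        n_features=6 if structure != "expression_like" else 50,
        n_informative=2,
        structure=structure,
        seed=9,
    )
    a, b = make_dataset(spec), make_dataset(spec)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.sample_ids == b.sample_ids
    assert a.class_counts() == (10, 10)


def test_generator_spec_validation():
    with pytest.raises(ValueError, match="even"):
        GeneratorSpec(n_samples=7)
    with pytest.raises(ValueError, match="structure"):
        GeneratorSpec(structure="spiral")
    with pytest.raises(ValueError, match="informative"):
        make_checkerboard(GeneratorSpec(n_samples=10, n_features=4, n_informative=3,
                                        structure="checkerboard"))


def test_global_linear_strong_effect_is_separable():
    ds = make_global_linear(GeneratorSpec(n_samples=24, n_features=5, n_informative=2,
                                          effect_size=6.0, seed=0))
    _, report = classical_svm_loo(ds, ClassifierConfig(kernel="linear", C=1.0))
    assert report.auc == 1.0


def test_global_linear_zero_effect_is_chance():
    ds = make_global_linear(GeneratorSpec(n_samples=40, n_features=5, n_informative=2,
                                          effect_size=0.0, seed=1))
    _, report = classical_svm_loo(ds, ClassifierConfig(kernel="linear", C=1.0))
    assert 0.2 <= report.auc <= 0.8


def test_checkerboard_local_order_without_global_order():
    """Adjacent-cell alternation defeats a global linear SVM but not a local
    kNN vote — the geometric premise behind per-sample trimming."""
    ds = make_checkerboard(GeneratorSpec(n_samples=64, n_features=4, n_informative=2,
                                         structure="checkerboard", seed=2))
    _, svm_report = classical_svm_loo(ds, ClassifierConfig(kernel="linear", C=1.0))
    knn_scores = np.empty(ds.n_samples)
    for i in range(ds.n_samples):
        keep = np.arange(ds.n_samples) != i
        model = KNeighborsClassifier(n_neighbors=5).fit(ds.values[keep], ds.labels[keep])
        knn_scores[i] = model.predict(ds.values[i][None])[0]
    knn_auc = (
        (knn_scores[ds.labels == 100] == 100).mean()
        + (knn_scores[ds.labels == 0] == 0).mean()
    ) / 2
    assert svm_report.auc <= 0.65
    assert knn_auc >= 0.85


def test_checkerboard_single_cell_per_class_is_separable():
    ds = make_checkerboard(GeneratorSpec(n_samples=16, n_features=2, n_informative=2,
                                         structure="checkerboard", seed=3, grid_size=1))
    model = SVC(kernel="linear").fit(ds.values, ds.labels)
    assert (model.predict(ds.values) == ds.labels).all()


def test_expression_like_markers_recoverable():
    recovered = []
    for seed in range(10):
        spec = GeneratorSpec(n_samples=50, n_features=2000, n_informative=20,
                             effect_size=1.5, structure="expression_like", seed=seed)
        ds = make_expression_like(spec)
        top = set(top_n_genes(ds, 30).gene_ids)
        recovered.append(len(top & set(informative_genes(spec))))
    assert np.median(recovered) >= 15


def test_core_set_separates_signal_from_null():
    """The leave-one-out core filter keeps real markers and sheds noise:
    with signal present the core set is dominated by informative genes;
    without signal it holds none of the designated (inert) genes and only
    the stochastically stable tail of the null ranking.  (Because the N
    leave-one-out subdatasets share N-1 samples each, null rankings are
    strongly correlated and the null core is smaller than n but far from
    empty.)"""
    signal_cores, null_cores, signal_hits, null_hits = [], [], [], []
    for seed in range(5):
        for effect, cores, hits in ((1.5, signal_cores, signal_hits),
                                    (0.0, null_cores, null_hits)):
            spec = GeneratorSpec(n_samples=50, n_features=2000, n_informative=20,
                                 effect_size=effect, structure="expression_like",
                                 seed=seed)
            core = core_genes(make_expression_like(spec), 30)
            cores.append(len(core))
            hits.append(len(core & set(informative_genes(spec))))
    assert np.median(signal_hits) >= 15      # markers survive the filter
    assert np.median(null_hits) <= 2         # inert genes do not
    assert np.median(null_cores) < np.median(signal_cores) < 30


def test_expression_like_balanced_equalize_noop():
    ds = make_expression_like(GeneratorSpec(n_samples=60, n_features=100,
                                            n_informative=5, structure="expression_like",
                                            seed=4))
    assert equalize_classes(ds, seed=0) is ds


def test_expression_like_sample_baselines_give_qn_work():
    ds = make_expression_like(GeneratorSpec(n_samples=20, n_features=500,
                                            n_informative=5, structure="expression_like",
                                            seed=5))
    row_means = ds.values.mean(axis=1)
    assert row_means.std() > 0.05  # distinct per-sample baselines before QN
    qn = quantile_normalize(ds.values)
    assert np.allclose(qn.mean(axis=1), qn.mean(axis=1)[0])
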