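"""Metrics, cross-validation mechanics, algorithm ranking and persistence."""

import numpy as np
import pytest

from chirtransfer import (
    ConstantInputError,
    RegressorSpec,
    SyntheticSPRConfig,
    encode_dataset,
    fit_base,
    kfold_cv,
    load_model,
    mae,
    pearson_r,
    predict_base,
    rank_algorithms,
    save_model,
)
from chirtransfer.reaction_data import EncodedDataset
from chirtransfer.synthetic import (
    generate_descriptor_library,
    generate_source_domain,
    make_latent,
)

STRICT_LSVR = RegressorSpec("linear_svr", {"C": 1e5, "epsilon": 1e-5})


@pytest.fixture(scope="module")
def noiseless_dataset():
    """Exactly-linear SPR, no noise, n = 120 so folds cover the entity pool."""
    cfg = SyntheticSPRConfig(
        noise_sd=0.0, perturbation_mode="none", n_source_records=120, seed=1
    )
    lib = generate_descriptor_library(cfg)
    latent = make_latent(cfg, lib)
    records = generate_source_domain(cfg, lib, latent)
    return encode_dataset(records, lib.tables)


class TestMetrics:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # hand-evaluated covariance formula
        ],
    )
    def test_pearson_values(self, a, b, expected):
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_input_flags(self):
        with pytest.raises(ConstantInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_mae_values(self):
        assert mae([1, 2], [1, 2]) == 0.0
        assert mae([0, 0], [1, -1]) == 1.0  # (|-1| + |1|) / 2

    def test_mae_shift_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mae(a, b) == pytest.approx(mae(a + 3.7, b + 3.7), abs=1e-12)


class TestKFoldCV:
    def test_fold_partition_properties(self, source_dataset):
        report = kfold_cv(source_dataset, RegressorSpec("ridge"), k=10, seed=0)
        folds = np.array(list(report.fold_assignment.values()))
        assert len(folds) == source_dataset.n  # exhaustive, one fold each
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        assert set(report.per_sample_prediction) == set(source_dataset.reaction_ids)

    def test_deterministic_given_seed(self, source_dataset):
        spec = RegressorSpec("linear_svr")
        a = kfold_cv(source_dataset, spec, k=10, seed=3)
        b = kfold_cv(source_dataset, spec, k=10, seed=3)
        assert a.per_sample_prediction == b.per_sample_prediction
        assert a.fold_assignment == b.fold_assignment
        c = kfold_cv(source_dataset, spec, k=10, seed=4)
        assert c.fold_assignment != a.fold_assignment

    def test_k_equal_n_is_loo(self, noiseless_dataset):
        small = EncodedDataset(
            X=noiseless_dataset.X[:12],
            y=noiseless_dataset.y[:12],
            reaction_ids=noiseless_dataset.reaction_ids[:12],
            column_names=noiseless_dataset.column_names,
        )
        report = kfold_cv(small, RegressorSpec("ridge"), k=12, seed=0)
        sizes = np.bincount(list(report.fold_assignment.values()))
        assert (sizes == 1).all()

    def test_k_larger_than_n_rejected(self, source_dataset):
        with pytest.raises(ValueError):
            kfold_cv(source_dataset, RegressorSpec("ridge"), k=source_dataset.n + 1)

    def test_no_target_leakage(self, source_dataset):
        """Held-out prediction must not depend on the held-out target value."""
        spec = RegressorSpec("ridge")
        ref = kfold_cv(source_dataset, spec, k=5, seed=0)
        rid = source_dataset.reaction_ids[0]
        y2 = source_dataset.y.copy()
        y2[0] += 5.0  # corrupt one target
        tampered = EncodedDataset(
            X=source_dataset.X,
            y=y2,
            reaction_ids=source_dataset.reaction_ids,
            column_names=source_dataset.column_names,
        )
        alt = kfold_cv(tampered, spec, k=5, seed=0)
        assert alt.per_sample_prediction[rid] == pytest.approx(
            ref.per_sample_prediction[rid], abs=1e-9
        )

    def test_noiseless_linear_recovery(self, noiseless_dataset):
        report = kfold_cv(noiseless_dataset, STRICT_LSVR, k=10, seed=0)
        assert report.pearson_r > 0.99
        assert report.mae < 1e-3

    def test_constant_target_flags_pearson(self, source_dataset):
        const = EncodedDataset(
            X=source_dataset.X[:10],
            y=np.full(10, 1.5),
            reaction_ids=source_dataset.reaction_ids[:10],
            column_names=source_dataset.column_names,
        )
        report = kfold_cv(const, RegressorSpec("ridge"), k=5, seed=0)
        assert not report.pearson_defined
        assert report.mae >= 0


class TestRankAlgorithms:
    def test_true_model_class_wins(self, noiseless_dataset):
        specs = [RegressorSpec("k_neighbors"), STRICT_LSVR]
        ranked = rank_algorithms(noiseless_dataset, specs, k=5, seed=0)
        assert ranked[0].spec.algorithm == "linear_svr"

    def test_output_is_permutation(self, source_dataset):
        specs = [RegressorSpec("ridge"), RegressorSpec("lasso"), RegressorSpec("k_neighbors")]
        ranked = rank_algorithms(source_dataset, specs, k=5, seed=0)
        assert sorted(r.spec.algorithm for r in ranked) == sorted(
            s.algorithm for s in specs
        )
        rs = [r.pearson_r for r in ranked]
        assert rs == sorted(rs, reverse=True)

    def test_duplicate_specs_keep_stable_order(self, source_dataset):
        spec = RegressorSpec("ridge")
        ranked = rank_algorithms(source_dataset, [spec, spec], k=5, seed=0)
        assert len(ranked) == 2
        assert ranked[0].spec == ranked[1].spec

    def test_single_spec_singleton(self, source_dataset):
        ranked = rank_algorithms(source_dataset, [RegressorSpec("ridge")], k=5, seed=0)
        assert len(ranked) == 1

    def test_empty_spec_list_rejected(self, source_dataset):
        with pytest.raises(ValueError):
            rank_algorithms(source_dataset, [], k=5, seed=0)


class TestFitPredictPersist:
    def test_training_point_recovered_noiseless(self, noiseless_dataset):
        model = fit_base(noiseless_dataset, STRICT_LSVR)
        preds = model.predict_matrix(noiseless_dataset.X)
        assert mae(preds, noiseless_dataset.y) < 1e-3

    def test_serialise_round_trip_identical(self, noiseless_dataset, tmp_path):
        model = fit_base(noiseless_dataset, RegressorSpec("linear_svr"))
        path = tmp_path / "model.json"
        save_model(model, path)
        reloaded = load_model(path)
        a = model.predict_matrix(noiseless_dataset.X)
        b = reloaded.predict_matrix(noiseless_dataset.X)
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_tree_model_not_json_persistable(self, source_dataset, tmp_path):
        model = fit_base(source_dataset, RegressorSpec("random_forest"), seed=0)
        with pytest.raises(ValueError, match="linear"):
            save_model(model, tmp_path / "rf.json")

    def test_constant_feature_column_tolerated(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 1.0  # zero variance
        ds = EncodedDataset(
            X=X,
            y=X[:, 0] * 2.0,
            reaction_ids=tuple(f"r{i}" for i in range(20)),
            column_names=tuple(f"c{i}" for i in range(5)),
        )
        model = fit_base(ds, RegressorSpec("linear_svr"))
        assert np.isfinite(model.predict_matrix(X)).all()

    def test_dimension_mismatch_rejected(self, base_model):
        with pytest.raises(ValueError, match="schema"):
            predict_base(base_model, np.zeros(7))

    def test_identical_inputs_identical_outputs(self, base_model, source_dataset):
        x = source_dataset.X[0]
        assert predict_base(base_model, x) == predict_base(base_model, x)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            RegressorSpec("deep_net")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="hyperparameter"):
            RegressorSpec("ridge", {"C": 1.0})
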