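"""Residuals, delta fitting, LOO evaluation, additivity and the pooled baseline."""

import numpy as np
import pytest

from chirtransfer import (
    DeltaRecord,
    RegressorSpec,
    SyntheticSPRConfig,
    compute_residuals,
    encode_dataset,
    fit_base,
    fit_delta,
    fit_naive_pooled,
    fit_transfer,
    loo_evaluate,
    predict_base,
    predict_transfer,
)
from chirtransfer.base_model import BaseModel, _LinearPredictor
from chirtransfer.delta_transfer import TransferModel, load_transfer, save_transfer
from chirtransfer.reaction_data import EncodedReaction
from chirtransfer.synthetic import (
    generate_descriptor_library,
    generate_source_domain,
    generate_target_domain,
    make_latent,
    make_perturbation,
)


def oracle_base(latent, n_features=108):
    """A BaseModel whose predictions equal the generator's latent SPR exactly."""
    return BaseModel(
        spec=RegressorSpec("linear_svr"),
        scaler_mean=np.zeros(n_features),
        scaler_scale=np.ones(n_features),
        estimator=_LinearPredictor(latent.weights, latent.intercept),
        column_names=tuple(f"c{i}" for i in range(n_features)),
        training_fingerprint="oracle",
    )


@pytest.fixture(scope="module")
def perturbed_campaign():
    cfg = SyntheticSPRConfig(seed=2)
    lib = generate_descriptor_library(cfg)
    latent = make_latent(cfg, lib)
    pert = make_perturbation(cfg, lib)
    target = generate_target_domain(cfg, lib, latent, pert)
    return cfg, lib, latent, pert, target


class TestResiduals:
    def test_residual_is_pred_minus_exp(self):
        rec = DeltaRecord(
            cca_id="c",
            encoded=EncodedReaction(vector=np.zeros(3), column_names=("a", "b", "c")),
            ddg_pred_base=1.5,
            ddg_exp_target=1.2,
        )
        assert rec.D == pytest.approx(0.3)

    def test_exact_base_gives_zero_D(self, perturbed_campaign):
        cfg, lib, latent, _, _ = perturbed_campaign
        cfg0 = SyntheticSPRConfig(seed=2, perturbation_mode="none", noise_sd=0.0)
        target0 = generate_target_domain(cfg0, lib, latent, None)
        res = compute_residuals(oracle_base(latent), target0, lib.tables)
        assert max(abs(r.D) for r in res) < 1e-9

    def test_D_equals_minus_g_pointwise(self, perturbed_campaign):
        """With an exact base model and no noise, D = −g(x_CCA) exactly."""
        cfg, lib, latent, pert, _ = perturbed_campaign
        cfg0 = SyntheticSPRConfig(seed=2, noise_sd=0.0)
        target0 = generate_target_domain(cfg0, lib, latent, pert)
        res = compute_residuals(oracle_base(latent), target0, lib.tables)
        for r in res:
            g = pert.g(r.encoded.vector[41:107][None, :])[0]
            assert r.D == pytest.approx(-g, abs=1e-9)

    def test_empty_target_rejected(self, base_model, campaign):
        with pytest.raises(ValueError):
            compute_residuals(base_model, [], campaign["lib"].tables)


class TestFitDelta:
    def test_zero_residuals_predict_zero(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        zero = [
            DeltaRecord(r.cca_id, r.encoded, r.ddg_exp_target, r.ddg_exp_target)
            for r in res
        ]
        model = fit_delta(zero)
        X = np.vstack([r.encoded.vector for r in zero])
        assert np.abs(model.predict_D(X)).max() < 1e-6

    def test_constant_residual_captured_by_intercept(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        const = [
            DeltaRecord(r.cca_id, r.encoded, r.ddg_exp_target + 0.4, r.ddg_exp_target)
            for r in res
        ]
        model = fit_delta(const)
        X = np.vstack([r.encoded.vector for r in const])
        np.testing.assert_allclose(model.predict_D(X), 0.4, atol=1e-6)

    def test_constant_context_columns_dropped(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        model = fit_delta(res)
        # substrate context and temperature are fixed across the target set
        assert any("temperature" in c for c in model.dropped_columns)
        assert len(model.dropped_columns) >= 35 + 6

    def test_too_few_records_rejected(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        with pytest.raises(ValueError):
            fit_delta(res[:1])


class TestLOO:
    def test_identical_D_gives_near_zero_corrected(self, perturbed_campaign):
        """A constant SPR offset is fully learnable regardless of base error."""
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        shifted = [
            DeltaRecord(r.cca_id, r.encoded, r.ddg_exp_target + 0.5, r.ddg_exp_target)
            for r in res
        ]
        report = loo_evaluate(shifted)
        assert report.mae_uncorrected == pytest.approx(0.5, abs=1e-9)
        assert report.mae_corrected < 0.02

    def test_order_invariance_and_determinism(self, perturbed_campaign, base_model):
        cfg, lib, latent, _, target = perturbed_campaign
        base = fit_base(encode_dataset(
            generate_source_domain(cfg, lib, latent), lib.tables
        ), RegressorSpec("linear_svr"))
        res = compute_residuals(base, target, lib.tables)
        a = loo_evaluate(res)
        b = loo_evaluate(list(reversed(res)))
        assert a == b

    def test_unstructured_residuals_gain_nothing(self, perturbed_campaign):
        """Random-sign D uncorrelated with descriptors: no free lunch."""
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            signs = rng.choice([-0.3, 0.3], size=len(res))
            noisy = [
                DeltaRecord(r.cca_id, r.encoded, r.ddg_exp_target + s, r.ddg_exp_target)
                for r, s in zip(res, signs)
            ]
            rep = loo_evaluate(noisy)
            ratios.append(rep.mae_corrected / rep.mae_uncorrected)
        assert np.mean(ratios) > 0.8

    def test_minimum_size(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        res = compute_residuals(oracle_base(latent), target, lib.tables)
        with pytest.raises(ValueError):
            loo_evaluate(res[:2])


class TestTransferModel:
    def test_exact_additivity(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        base = oracle_base(latent)
        model = fit_transfer(base, target, lib.tables)
        for rec in target[:5]:
            from chirtransfer import encode_reaction

            enc = encode_reaction(rec, lib.tables)
            expected = predict_base(base, enc) - float(
                model.delta.predict_D(enc.vector[None, :])[0]
            )
            assert predict_transfer(model, enc) == expected  # bitwise additivity

    def test_sign_conventions_agree(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        base = oracle_base(latent)
        sub = fit_transfer(base, target, lib.tables, convention="subtract_D")
        add = fit_transfer(base, target, lib.tables, convention="add_negD")
        from chirtransfer import encode_reaction

        for rec in target[:5]:
            enc = encode_reaction(rec, lib.tables)
            assert predict_transfer(sub, enc) == pytest.approx(
                predict_transfer(add, enc), abs=1e-8
            )

    def test_zero_delta_equals_base(self, perturbed_campaign):
        cfg, lib, latent, _, target = perturbed_campaign
        base = oracle_base(latent)
        res = compute_residuals(base, target, lib.tables)
        zero = [
            DeltaRecord(r.cca_id, r.encoded, r.ddg_exp_target, r.ddg_exp_target)
            for r in res
        ]
        model = TransferModel(base=base, delta=fit_delta(zero))
        from chirtransfer import encode_reaction

        enc = encode_reaction(target[0], lib.tables)
        assert predict_transfer(model, enc) == pytest.approx(
            predict_base(base, enc), abs=1e-6
        )

    def test_persistence_round_trip(self, perturbed_campaign, tmp_path):
        cfg, lib, latent, _, target = perturbed_campaign
        model = fit_transfer(oracle_base(latent), target, lib.tables)
        path = tmp_path / "transfer.json"
        save_transfer(model, path)
        reloaded = load_transfer(path)
        from chirtransfer import encode_reaction

        enc = encode_reaction(target[0], lib.tables)
        assert predict_transfer(reloaded, enc) == pytest.approx(
            predict_transfer(model, enc), abs=1e-12
        )


class TestNaivePooled:
    def test_empty_target_equals_base_fit(self, source_dataset):
        spec = RegressorSpec("linear_svr")
        pooled = fit_naive_pooled(source_dataset, None, spec)
        base = fit_base(source_dataset, spec)
        np.testing.assert_allclose(
            pooled.predict_matrix(source_dataset.X),
            base.predict_matrix(source_dataset.X),
            atol=1e-12,
        )

    def test_zero_perturbation_pooled_close_to_source_fit(self):
        cfg = SyntheticSPRConfig(seed=4, perturbation_mode="none", noise_sd=0.0)
        lib = generate_descriptor_library(cfg)
        latent = make_latent(cfg, lib)
        source = generate_source_domain(cfg, lib, latent)
        target = generate_target_domain(cfg, lib, latent, make_perturbation(cfg, lib))
        spec = RegressorSpec("linear_svr", {"C": 100.0, "epsilon": 1e-3})
        src_ds = encode_dataset(source, lib.tables)
        tgt_ds = encode_dataset(target, lib.tables)
        pooled = fit_naive_pooled(src_ds, tgt_ds, spec)
        src_only = fit_base(src_ds, spec)
        diff = np.abs(
            pooled.predict_matrix(tgt_ds.X) - src_only.predict_matrix(tgt_ds.X)
        )
        assert diff.mean() < 0.05  # same SPR in both domains: pooling changes little
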