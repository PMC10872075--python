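import numpy as np
import pytest

from mmdrp._autodiff import Tensor
from mmdrp.core_data import OmicType, ResponseRecord
from mmdrp.model import (DRPModel, ModelConfig, elastic_net_baseline,
                         load_model, random_search, save_model, train_fold,
                         weighted_rmse_loss)
from mmdrp.splitters import split
from mmdrp.synthetic_data import SyntheticConfig, generate_cohort

FAST = dict(epochs=30, patience=10, batch_size=0)


@pytest.fixture(scope="module")
def tiny_problem():
    cfg = SyntheticConfig(n_cell_lines=25, n_drugs=20, seed=17,
                          features_per_omic={OmicType.EXP: 15, OmicType.CNV: 10})
    matrices, catalog, records, truth = generate_cohort(cfg)
    fold = split(records, "cell_line", 5, seed=0)[0]
    return matrices, catalog, records, fold, truth


class TestWeightedRMSE:
    def test_perfect_predictions_zero(self):
        assert weighted_rmse_loss([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_hand_computation(self):
        # errors 0.3 and 0.4 with unit weights
        assert weighted_rmse_loss([0.3, 0.4], [0.0, 0.0]) == pytest.approx(
            0.35355339, abs=1e-6)

    def test_weight_scale_invariance(self, rng):
        preds, targets = rng.random(10), rng.random(10)
        w = rng.random(10) + 0.1
        a = weighted_rmse_loss(preds, targets, w)
        b = weighted_rmse_loss(preds, targets, 2.0 * w)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unit_weights_match_unweighted(self, rng):
        """The base preset's unweighted objective is exactly the weighted
        loss with all weights forced to one."""
        preds, targets = rng.random(20), rng.random(20)
        assert weighted_rmse_loss(preds, targets) == pytest.approx(
            weighted_rmse_loss(preds, targets, np.ones(20)), abs=1e-15)

    def test_tensor_path_matches_numpy_path(self, rng):
        preds, targets = rng.random(8), rng.random(8)
        w = rng.random(8) + 0.5
        t = weighted_rmse_loss(Tensor(preds.reshape(-1, 1)), targets, w)
        assert t.item() == pytest.approx(weighted_rmse_loss(preds, targets, w))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_rmse_loss([], [])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_rmse_loss([0.1], [0.2], [0.0])


class TestModelConfig:
    def test_presets(self):
        base = ModelConfig.mmdrp_base()
        assert (base.drug_encoder, base.fusion, base.use_lds) == ("ecfp", "concat", False)
        refined = ModelConfig.mmdrp_refined()
        assert (refined.drug_encoder, refined.fusion, refined.use_lds) == ("gnn", "lmf", True)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(omic_types=[])
        with pytest.raises(ValueError):
            ModelConfig(drug_encoder="cnn")
        with pytest.raises(ValueError):
            ModelConfig(fusion="attention")


class TestTrainFold:
    def test_one_prediction_per_validation_record(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        mc = ModelConfig.mmdrp_base(omic_types=["EXP"], seed=1, **FAST)
        _, preds = train_fold(records, fold, matrices, catalog, mc)
        assert len(preds) == len(fold.validation_indices)
        assert all(0.0 <= p.pred_aac <= 1.0 for p in preds)

    def test_deterministic_given_seed(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        mc = ModelConfig.mmdrp_base(omic_types=["EXP"], seed=2, **FAST)
        _, a = train_fold(records, fold, matrices, catalog, mc)
        _, b = train_fold(records, fold, matrices, catalog, mc)
        assert [(p.cell_line, p.drug, p.pred_aac) for p in a] == \
               [(p.cell_line, p.drug, p.pred_aac) for p in b]

    def test_freeze_encoders_keeps_encoder_outputs(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        mc = ModelConfig.mmdrp_base(omic_types=["EXP"], seed=3,
                                    freeze_encoders=True, **FAST)
        model, _ = train_fold(records, fold, matrices, catalog, mc)
        fresh = DRPModel(mc, {OmicType.EXP: matrices[0].n_features})
        assert model.encoder_hashes() == fresh.encoder_hashes()

    def test_validation_labels_cannot_shape_lds_or_standardizer(self, tiny_problem):
        """Perturbing validation AACs leaves the trained model's parameters
        untouched (validation only steers early stopping via predictions)."""
        matrices, catalog, records, fold, _ = tiny_problem
        mc = ModelConfig.mmdrp_refined(omic_types=["EXP"], seed=4, epochs=1,
                                       patience=10, batch_size=0)
        val = set(fold.validation_indices)
        bumped = [ResponseRecord(r.cell_line, r.drug,
                                 min(1.0, r.aac + 0.31) if i in val else r.aac,
                                 r.lineage)
                  for i, r in enumerate(records)]
        m1, _ = train_fold(records, fold, matrices, catalog, mc)
        m2, _ = train_fold(bumped, fold, matrices, catalog, mc)
        # one epoch: snapshot selection cannot vary, so any difference would
        # have to come from gradients, LDS weights or standardizers
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.array_equal(p1.data, p2.data)

    def test_checkpoint_round_trip(self, tiny_problem, tmp_path):
        matrices, catalog, records, fold, _ = tiny_problem
        mc = ModelConfig.mmdrp_base(omic_types=["EXP"], seed=5, **FAST)
        model, preds = train_fold(records, fold, matrices, catalog, mc)
        path = tmp_path / "ckpt.npz"
        save_model(model, {OmicType.EXP: matrices[0].n_features}, str(path))
        loaded = load_model(str(path))
        for p1, p2 in zip(model.params(), loaded.params()):
            assert np.array_equal(p1.data, p2.data)
        assert loaded.config.config_id() == mc.config_id()


class TestElasticNet:
    def test_recovers_pure_linear_signal(self):
        """An AAC that is a noiseless linear function of one omic feature is
        recovered with high validation R^2."""
        cfg = SyntheticConfig(n_cell_lines=40, n_drugs=10, seed=23,
                              features_per_omic={OmicType.EXP: 10})
        matrices, catalog, records, _ = generate_cohort(cfg)
        x = matrices[0].values[:, 0]
        u = (x - x.min()) / (x.max() - x.min())
        idx = matrices[0].row_index()
        linear = [ResponseRecord(r.cell_line, r.drug,
                                 float(0.1 + 0.6 * u[idx[r.cell_line]]),
                                 r.lineage) for r in records]
        fold = split(linear, "cell_line", 4, seed=0)[0]
        preds = elastic_net_baseline(linear, fold, matrices, catalog,
                                     alpha=1e-4)
        y = np.array([p.true_aac for p in preds])
        yh = np.array([p.pred_aac for p in preds])
        r2 = 1 - np.sum((y - yh) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.8

    def test_constant_target_predicted_exactly(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        const = [ResponseRecord(r.cell_line, r.drug, 0.4, r.lineage)
                 for r in records]
        preds = elastic_net_baseline(const, fold, matrices, catalog)
        errs = [abs(p.pred_aac - p.true_aac) for p in preds]
        assert max(errs) < 1e-6

    def test_same_fold_protocol_as_neural_model(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        preds = elastic_net_baseline(records, fold, matrices, catalog)
        expected = [(records[i].cell_line, records[i].drug)
                    for i in fold.validation_indices]
        assert [(p.cell_line, p.drug) for p in preds] == expected


class TestRandomSearch:
    def test_single_trial_returns_that_config(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        base = ModelConfig.mmdrp_base(omic_types=["EXP"], epochs=3,
                                      patience=5, batch_size=0)
        best, log = random_search({"head_hidden": [8]}, 1, records, [fold],
                                  matrices, catalog, base_config=base, seed=0)
        assert best.head_hidden == 8
        assert len(log) == 1

    def test_trial_log_bookkeeping_and_determinism(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        base = ModelConfig.mmdrp_base(omic_types=["EXP"], epochs=3,
                                      patience=5, batch_size=0)
        space = {"head_hidden": [4, 8, 16]}
        best1, log1 = random_search(space, 3, records, [fold], matrices,
                                    catalog, base_config=base, seed=9)
        best2, log2 = random_search(space, 3, records, [fold], matrices,
                                    catalog, base_config=base, seed=9)
        assert len(log1) == 3
        assert [t["overrides"] for t in log1] == [t["overrides"] for t in log2]
        assert best1.head_hidden == best2.head_hidden
        assert all(np.isfinite(t["mean_val_rmse"]) for t in log1)

    def test_obviously_better_knob_selected(self, tiny_problem):
        """A 30-epoch budget beats a 1-epoch budget on held-out loss, so the
        search must pick it."""
        matrices, catalog, records, fold, _ = tiny_problem
        base = ModelConfig.mmdrp_base(omic_types=["EXP"], patience=50,
                                      batch_size=0)
        hits = 0
        for seed in range(5):
            best, _ = random_search({"epochs": [1, 30]}, 4, records, [fold],
                                    matrices, catalog, base_config=base,
                                    seed=seed)
            hits += best.epochs == 30
        assert hits >= 4

    def test_zero_trials_rejected(self, tiny_problem):
        matrices, catalog, records, fold, _ = tiny_problem
        with pytest.raises(ValueError):
            random_search({}, 0, records, [fold], matrices, catalog)
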