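import numpy as np
import pytest

from mmdrp._autodiff import Tensor
from mmdrp.attribution import (AttributionConfig, AttributionMap,
                               integrated_gradients, top_features)
from mmdrp.core_data import OmicType
from mmdrp.drug_graphs import featurize_smiles
from mmdrp.model import DRPModel, ModelConfig


class LinearDuck:
    """F(x, fp) = w.x + v.fp — closed-form attributions w_j x_j, v_j fp_j."""

    def __init__(self, w, v):
        self.config = ModelConfig(omic_types=["EXP"], drug_encoder="ecfp",
                                  fusion="concat", use_lds=False)
        self.w, self.v = np.asarray(w, float), np.asarray(v, float)

    def predict_pair(self, omic_vectors, drug_input):
        return (omic_vectors[OmicType.EXP] @ Tensor(self.w.reshape(-1, 1))
                + drug_input @ Tensor(self.v.reshape(-1, 1)))


class TwoLayerDuck:
    """Smooth nonlinear toy model for quadrature-convergence checks."""

    def __init__(self, rng, d=6, h=8):
        self.config = ModelConfig(omic_types=["EXP"], drug_encoder="ecfp",
                                  fusion="concat", use_lds=False)
        self.W1 = Tensor(rng.normal(size=(d, h)))
        self.W2 = Tensor(rng.normal(size=(h, 1)))

    def predict_pair(self, omic_vectors, drug_input):
        return (omic_vectors[OmicType.EXP] @ self.W1).tanh() @ self.W2 \
            + drug_input * 0.0


class TestClosedForm:
    def test_linear_model_exact_any_step_count(self, rng):
        w, v = rng.normal(size=4), rng.normal(size=3)
        x, fp = rng.normal(size=4), rng.normal(size=3)
        model = LinearDuck(w, v)
        for steps, rule in [(1, "trapezoid"), (1, "riemann_right"),
                            (7, "trapezoid"), (64, "riemann_right")]:
            attr = integrated_gradients(
                model, {OmicType.EXP: x}, fp,
                config=AttributionConfig(steps=steps, rule=rule))
            got = np.array([attr.omic_scores[("EXP", f"f{j:04d}")]
                            for j in range(4)])
            assert np.allclose(got, w * x, atol=1e-10)
            assert np.allclose(attr.atom_scores[0], v * fp, atol=1e-10)
            assert attr.completeness_residual < 1e-10

    def test_input_equal_to_baseline_gives_zero(self, rng):
        model = LinearDuck(rng.normal(size=3), rng.normal(size=2))
        attr = integrated_gradients(model, {OmicType.EXP: np.zeros(3)},
                                    np.zeros(2))
        assert all(s == 0.0 for s in attr.flat().values())

    def test_ignored_feature_gets_zero_attribution(self, rng):
        w = np.array([1.0, 0.0, -2.0])
        model = LinearDuck(w, rng.normal(size=2))
        attr = integrated_gradients(model, {OmicType.EXP: rng.normal(size=3)},
                                    rng.normal(size=2))
        assert abs(attr.omic_scores[("EXP", "f0001")]) < 1e-9


class TestCompleteness:
    def test_residual_converges_on_smooth_model(self, rng):
        model = TwoLayerDuck(rng)
        x = rng.normal(size=6)
        fp = np.zeros(1)
        attr = integrated_gradients(model, {OmicType.EXP: x}, fp,
                                    target="omics",
                                    config=AttributionConfig(steps=512))
        delta = abs(attr.prediction - attr.baseline_prediction)
        assert attr.completeness_residual < 1e-3 * delta

    def test_residual_tightens_with_steps(self, rng):
        model = TwoLayerDuck(rng, d=5)
        x = 2.0 * rng.normal(size=5)
        residuals = []
        for steps in (4, 32, 256):
            attr = integrated_gradients(model, {OmicType.EXP: x}, np.zeros(1),
                                        target="omics",
                                        config=AttributionConfig(steps=steps))
            residuals.append(attr.completeness_residual)
        assert residuals[2] <= residuals[1] <= residuals[0] + 1e-12


@pytest.fixture(scope="module")
def gnn_model():
    cfg = ModelConfig.mmdrp_refined(
        omic_types=["EXP"], omic_latent_dim=4, encoder_hidden=8,
        drug_latent_dim=4, gnn_hidden=8, lmf_rank=2, fused_dim=6,
        head_hidden=6, seed=11)
    return DRPModel(cfg, {OmicType.EXP: 5})


class TestRealModel:

    def test_drug_graph_attribution_atom_permutation_invariant(self, gnn_model, rng):
        from rdkit import Chem
        smiles = "CC(=O)Nc1ccc(O)cc1"
        mol = Chem.MolFromSmiles(smiles)
        order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        x = rng.normal(size=5)
        scores = []
        for s in (smiles, alt):
            attr = integrated_gradients(gnn_model, {OmicType.EXP: x},
                                        featurize_smiles(s), target="drug",
                                        config=AttributionConfig(steps=16))
            scores.append(np.sort(attr.per_atom()))
        assert np.allclose(scores[0], scores[1], atol=1e-5)

    def test_completeness_reported_for_full_pipeline(self, gnn_model, rng):
        x = rng.normal(size=5)
        attr = integrated_gradients(gnn_model, {OmicType.EXP: x},
                                    featurize_smiles("c1ccccc1O"),
                                    config=AttributionConfig(steps=256))
        delta = abs(attr.prediction - attr.baseline_prediction)
        assert np.isfinite(attr.completeness_residual)
        # relu kinks limit quadrature accuracy; residual must still be small
        assert attr.completeness_residual < 0.02 * max(delta, 0.1)


class TestTopFeatures:
    def make_map(self, scores):
        return AttributionMap(omic_scores={("EXP", k): v
                                           for k, v in scores.items()})

    def test_absolute_value_ranking(self):
        attr = self.make_map({"a": 0.5, "b": -0.9, "c": 0.1})
        top = top_features(attr, 2)
        assert [k[1] for k, _ in top] == ["b", "a"]

    def test_all_zero_map_deterministic(self):
        attr = self.make_map({"b": 0.0, "a": 0.0, "c": 0.0})
        top1 = top_features(attr, 3)
        top2 = top_features(attr, 3)
        assert top1 == top2
        assert [k[1] for k, _ in top1] == ["a", "b", "c"]  # name tie-break

    def test_k_beyond_count_returns_all(self):
        attr = self.make_map({"a": 1.0})
        assert len(top_features(attr, 10)) == 1

    def test_modality_filter(self):
        attr = AttributionMap(omic_scores={("EXP", "g"): 1.0,
                                           ("CNV", "g"): 2.0})
        top = top_features(attr, 5, modality="EXP")
        assert [k[0] for k, _ in top] == ["EXP"]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            top_features(self.make_map({"a": 1.0}), 0)
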