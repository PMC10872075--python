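"""Integrated Gradients attribution for single (cell line, drug) predictions.

The attribution of feature j is (x_j - x'_j) times the path integral of
dF/dx_j along the straight line from a baseline x' to the input x,
approximated with an m-step quadrature (trapezoid by default). Attributions
satisfy *completeness*: they sum to F(x) - F(x') up to a quadrature residual,
which is always computed and reported rather than hidden.

For standardized omic inputs the zeros baseline is the training-mean profile
— "zero" is only meaningful after fold-local standardization. Drug-graph
attributions target the atom feature matrix (a continuous relaxation of the
discrete chemistry) and can be summed per atom for substructure-level
interpretation; bond features are not attributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .core_data import OmicType
from .drug_graphs import ATOM_FEATURE_NAMES, MolecularGraph
from .model import DRPModel

__all__ = ["AttributionConfig", "AttributionMap", "integrated_gradients",
           "top_features"]


@dataclass
class AttributionConfig:
    steps: int = 64
    rule: str = "trapezoid"            # trapezoid | riemann_right
    baselines: dict | None = None      # modality key -> baseline array; default zeros

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.rule not in ("trapezoid", "riemann_right"):
            raise ValueError(f"unknown integration rule {self.rule!r}")


@dataclass
class AttributionMap:
    """Per-feature attribution scores for one prediction.

    ``omic_scores`` is keyed ``(omic type value, feature name)``;
    ``atom_scores`` has one row per atom and one column per atom feature.
    """

    omic_scores: dict = field(default_factory=dict)
    atom_scores: np.ndarray | None = None
    atom_feature_names: list[str] = field(default_factory=list)
    prediction: float = 0.0
    baseline_prediction: float = 0.0
    completeness_residual: float = 0.0

    def per_atom(self) -> np.ndarray | None:
        """Atom-level totals for molecular highlighting."""
        return None if self.atom_scores is None else self.atom_scores.sum(axis=1)

    def flat(self) -> dict:
        out = dict(self.omic_scores)
        if self.atom_scores is not None:
            for a in range(self.atom_scores.shape[0]):
                for j, name in enumerate(self.atom_feature_names):
                    out[("drug", f"atom{a}:{name}")] = self.atom_scores[a, j]
        return out


def _quadrature(steps: int, rule: str) -> tuple[np.ndarray, np.ndarray]:
    if rule == "riemann_right":
        alphas = np.arange(1, steps + 1) / steps
        weights = np.full(steps, 1.0 / steps)
    else:
        alphas = np.arange(0, steps + 1) / steps
        weights = np.full(steps + 1, 1.0 / steps)
        weights[0] = weights[-1] = 0.5 / steps
    return alphas, weights


def integrated_gradients(model: DRPModel,
                         omic_vectors: dict[OmicType, np.ndarray],
                         drug_graph_or_fp,
                         target: str = "all",
                         config: AttributionConfig | None = None,
                         feature_names: dict[OmicType, list[str]] | None = None
                         ) -> AttributionMap:
    """Attribute one prediction to its input features.

    ``target`` selects which inputs are path-integrated: ``"omics"``,
    ``"drug"`` or ``"all"``. Non-target inputs stay fixed at their actual
    values, so completeness holds over the selected set.
    """
    config = config or AttributionConfig()
    if target not in ("omics", "drug", "all"):
        raise ValueError(f"unknown attribution target {target!r}")
    do_omics = target in ("omics", "all")
    do_drug = target in ("drug", "all")
    baselines = config.baselines or {}

    omic_x = {t: np.atleast_2d(np.asarray(omic_vectors[t], dtype=float))
              for t in model.config.omic_types}
    omic_x0 = {t: np.atleast_2d(np.asarray(
        baselines.get(t.value, np.zeros_like(omic_x[t])), dtype=float))
        for t in omic_x}

    is_gnn = model.config.drug_encoder == "gnn"
    if is_gnn:
        if not isinstance(drug_graph_or_fp, MolecularGraph):
            raise TypeError("gnn model needs a MolecularGraph input")
        drug_x = drug_graph_or_fp.atom_features.astype(float)
    else:
        drug_x = np.atleast_2d(np.asarray(drug_graph_or_fp, dtype=float))
    drug_x0 = np.asarray(baselines.get("drug", np.zeros_like(drug_x)), dtype=float)

    def evaluate(alpha: float | None, want_grads: bool):
        """Forward at the path point; alpha=None means the raw input."""
        a = 1.0 if alpha is None else alpha
        leaves_omic = {}
        for t in omic_x:
            arr = omic_x0[t] + a * (omic_x[t] - omic_x0[t]) if do_omics else omic_x[t]
            leaves_omic[t] = Tensor(arr, requires_grad=want_grads and do_omics)
        arr = drug_x0 + a * (drug_x - drug_x0) if do_drug else drug_x
        drug_leaf = Tensor(arr, requires_grad=want_grads and do_drug)
        drug_input = (drug_graph_or_fp, drug_leaf) if is_gnn else drug_leaf
        out = model.predict_pair(leaves_omic, drug_input)
        if want_grads:
            out.backward()
            grads_omic = {t: leaves_omic[t].grad for t in leaves_omic} \
                if do_omics else {}
            if do_omics and any(g is None or not np.isfinite(g).all()
                                for g in grads_omic.values()):
                raise FloatingPointError(
                    f"non-finite omic gradient at path position alpha={a}")
            grad_drug = drug_leaf.grad if do_drug else None
            if do_drug and (grad_drug is None or not np.isfinite(grad_drug).all()):
                raise FloatingPointError(
                    f"non-finite drug gradient at path position alpha={a}")
            return out.item(), grads_omic, grad_drug
        return out.item(), None, None

    alphas, weights = _quadrature(config.steps, config.rule)
    avg_omic = {t: np.zeros_like(omic_x[t]) for t in omic_x} if do_omics else {}
    avg_drug = np.zeros_like(drug_x) if do_drug else None
    for alpha, w in zip(alphas, weights):
        _, g_omic, g_drug = evaluate(alpha, want_grads=True)
        if do_omics:
            for t in avg_omic:
                avg_omic[t] += w * g_omic[t]
        if do_drug:
            avg_drug += w * g_drug

    f_x, _, _ = evaluate(None, want_grads=False)
    f_x0, _, _ = evaluate(0.0, want_grads=False)

    omic_scores: dict = {}
    total = 0.0
    if do_omics:
        for t in model.config.omic_types:
            attr = (omic_x[t] - omic_x0[t]) * avg_omic[t]
            total += attr.sum()
            names = (feature_names or {}).get(
                t, [f"f{j:04d}" for j in range(attr.shape[1])])
            for j in range(attr.shape[1]):
                omic_scores[(t.value, names[j])] = float(attr[0, j])
    atom_scores = None
    if do_drug:
        # for the ecfp encoder this is a single "atom" row of bit attributions
        atom_scores = (drug_x - drug_x0) * avg_drug
        total += atom_scores.sum()

    return AttributionMap(
        omic_scores=omic_scores,
        atom_scores=atom_scores,
        atom_feature_names=list(ATOM_FEATURE_NAMES) if is_gnn else
        [f"bit{j}" for j in range(drug_x.shape[1])],
        prediction=f_x,
        baseline_prediction=f_x0,
        completeness_residual=float(abs(total - (f_x - f_x0))),
    )


def top_features(attr: AttributionMap, k: int, modality: str | None = None
                 ) -> list[tuple]:
    """Top-k (key, score) by |attribution|, stable tie-break on the key.

    ``modality`` restricts to one omic type's features (e.g. ``"EXP"``) or
    ``"drug"``. k beyond the feature count returns the full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = attr.flat()
    items = [(key, s) for key, s in scores.items()
             if modality is None or key[0] == modality]
    items.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    return items[:k]
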