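"""The assembled drug-response predictor and its training protocol.

A model is: per-omic encoders (MLPs, optionally warm-started from pretrained
autoencoders), a drug encoder (graph-attention network or a linear map over
ECFP bits), a fusion stage (LMF / concatenation / summation) and a small
head that outputs the predicted AAC. Training minimises weighted RMSE, where
the weights come from label-distribution smoothing when enabled.

Two named presets bracket the ablation space:

* ``mmdrp-base``    — ECFP drug features, concatenation fusion, no LDS;
* ``mmdrp-refined`` — graph encoder, LMF fusion, LDS weighting.

All fold-local statistics (standardizers, LDS weights) are computed from the
fold's training split only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Adam, Tensor, no_grad
from .autoencoders import MLP, Autoencoder
from .core_data import DrugRecord, OmicMatrix, OmicType, ResponseRecord, \
    apply_standardizer, fit_standardizer
from .drug_graphs import AttentiveFPEncoder, MolecularGraph, ecfp, featurize_smiles
from .fusion import LMFFusion, concat_fuse, sum_fuse
from .lds import LDSConfig, compute_lds_weights

__all__ = [
    "ModelConfig", "PredictionRecord", "DRPModel", "weighted_rmse_loss",
    "train_fold", "elastic_net_baseline", "random_search",
    "save_model", "load_model",
]


@dataclass
class ModelConfig:
    omic_types: list = field(default_factory=lambda: [OmicType.EXP])
    drug_encoder: str = "gnn"          # gnn | ecfp
    fusion: str = "lmf"                # lmf | concat | sum
    use_lds: bool = True
    omic_latent_dim: int = 16
    encoder_hidden: int = 64
    drug_latent_dim: int = 16
    gnn_hidden: int = 48
    gnn_atom_rounds: int = 2
    gnn_mol_rounds: int = 2
    gnn_dropout: float = 0.0
    fp_radius: int = 2
    fp_bits: int = 1024
    lmf_rank: int = 4
    fused_dim: int = 32
    head_hidden: int = 32
    learning_rate: float = 2e-3
    weight_decay: float = 1e-2
    epochs: int = 400
    batch_size: int = 512
    patience: int = 80                 # early stopping on validation loss
    freeze_encoders: bool = False
    lds: LDSConfig = field(default_factory=LDSConfig)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        self.omic_types = [OmicType(t) for t in self.omic_types]
        if not self.omic_types:
            raise ValueError("need at least one omic type")
        if self.drug_encoder not in ("gnn", "ecfp"):
            raise ValueError(f"unknown drug encoder {self.drug_encoder!r}")
        if self.fusion not in ("lmf", "concat", "sum"):
            raise ValueError(f"unknown fusion {self.fusion!r}")

    @classmethod
    def mmdrp_base(cls, **overrides) -> "ModelConfig":
        """Baseline ablation: ECFP drug features, concat fusion, no LDS."""
        kw = dict(drug_encoder="ecfp", fusion="concat", use_lds=False,
                  name="mmdrp-base")
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def mmdrp_refined(cls, **overrides) -> "ModelConfig":
        """Refined model: graph drug encoder, LMF fusion, LDS weighting."""
        kw = dict(drug_encoder="gnn", fusion="lmf", use_lds=True,
                  name="mmdrp-refined")
        kw.update(overrides)
        return cls(**kw)

    def config_id(self) -> str:
        import hashlib, json

        def default(o):
            if isinstance(o, OmicType):
                return o.value
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PredictionRecord:
    cell_line: str
    drug: str
    true_aac: float
    pred_aac: float
    fold: int
    scheme: str
    config_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.pred_aac):
            raise ValueError(
                f"non-finite prediction for ({self.cell_line}, {self.drug})")


def weighted_rmse_loss(preds, targets, weights=None):
    """sqrt( sum w_i (y_i - yhat_i)^2 / sum w_i ).

    Accepts an autodiff ``Tensor`` for ``preds`` (returns a Tensor for
    training) or plain arrays (returns a float). Invariant to rescaling all
    weights by a common factor.
    """
    targets = np.asarray(targets, dtype=float).reshape(-1)
    if targets.size == 0:
        raise ValueError("empty batch")
    if weights is None:
        weights = np.ones_like(targets)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if isinstance(preds, Tensor):
        err = preds.reshape(1, -1) - Tensor(targets.reshape(1, -1))
        w = Tensor(weights.reshape(1, -1) / weights.sum())
        return ((w * err ** 2.0).sum()) ** 0.5
    preds = np.asarray(preds, dtype=float).reshape(-1)
    if preds.shape != targets.shape or weights.shape != targets.shape:
        raise ValueError("preds, targets and weights must have equal length")
    return float(np.sqrt(np.sum(weights * (preds - targets) ** 2) / weights.sum()))


class DRPModel:
    """Encoders + fusion + head wired into one differentiable predictor."""

    def __init__(self, config: ModelConfig, omic_dims: dict[OmicType, int],
                 pretrained: dict[OmicType, Autoencoder] | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.omic_encoders: dict[OmicType, MLP] = {}
        for omic in config.omic_types:
            if pretrained and omic in pretrained:
                self.omic_encoders[omic] = copy.deepcopy(pretrained[omic].encoder)
            else:
                self.omic_encoders[omic] = MLP(
                    [omic_dims[omic], config.encoder_hidden, config.omic_latent_dim],
                    "relu", rng)
        if config.drug_encoder == "gnn":
            self.drug_encoder = AttentiveFPEncoder(
                hidden_dim=config.gnn_hidden, latent_dim=config.drug_latent_dim,
                k_atom_rounds=config.gnn_atom_rounds,
                t_mol_rounds=config.gnn_mol_rounds,
                dropout=config.gnn_dropout,
                seed=int(rng.integers(2 ** 31)))
        else:
            self.drug_encoder = MLP([config.fp_bits, config.drug_latent_dim],
                                    "linear", rng)
        dims = [config.omic_latent_dim] * len(config.omic_types) \
            + [config.drug_latent_dim]
        if config.fusion == "lmf":
            self.fuser = LMFFusion(dims, config.lmf_rank, config.fused_dim,
                                   seed=int(rng.integers(2 ** 31)))
            fused_dim = config.fused_dim
        elif config.fusion == "concat":
            self.fuser = None
            fused_dim = sum(dims)
        else:  # sum
            if len(set(dims)) != 1:
                raise ValueError("sum fusion requires equal latent dims")
            self.fuser = None
            fused_dim = dims[0]
        self.head = MLP([fused_dim, config.head_hidden, 1], "relu", rng,
                        final_scale=0.01)

    # -- parameters -----------------------------------------------------------
    def params(self, include_encoders: bool = True) -> list[Tensor]:
        ps: list[Tensor] = []
        if include_encoders:
            for enc in self.omic_encoders.values():
                ps += enc.params()
        ps += self.drug_encoder.params()
        if self.fuser is not None:
            ps += self.fuser.params()
        ps += self.head.params()
        return ps

    def encoder_hashes(self) -> dict[str, int]:
        return {omic.value: enc.state_hash()
                for omic, enc in self.omic_encoders.items()}

    # -- forward --------------------------------------------------------------
    def drug_latents(self, drug_inputs: list, train: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Encode the unique drug panel into one (n_drugs, d) tensor.

        ``drug_inputs`` holds one :class:`MolecularGraph` (gnn) or one
        fingerprint vector (ecfp) per drug.
        """
        if self.config.drug_encoder == "gnn":
            return self.drug_encoder.forward_batch(drug_inputs, train=train,
                                                   rng=rng)
        fp = Tensor(np.vstack(drug_inputs))
        return self.drug_encoder(fp)

    def fuse(self, latents: list[Tensor]) -> Tensor:
        if self.config.fusion == "lmf":
            # bound latents before the multiplicative interaction so the
            # multi-way products cannot explode during optimisation
            return self.fuser([z.tanh() for z in latents])
        if self.config.fusion == "concat":
            return concat_fuse(latents)
        return sum_fuse(latents)

    def forward(self, omic_rows: dict[OmicType, Tensor],
                cell_index: np.ndarray, drug_latents: Tensor,
                drug_index: np.ndarray) -> Tensor:
        """Predict AAC for records given as (cell row index, drug index)."""
        latents = []
        for omic in self.config.omic_types:
            z = self.omic_encoders[omic](omic_rows[omic])
            latents.append(z.take(cell_index))
        latents.append(drug_latents.take(drug_index))
        return self.head(self.fuse(latents))

    def predict_pair(self, omic_vectors: dict[OmicType, Tensor],
                     drug_input) -> Tensor:
        """Scalar prediction for one (cell line, drug) pair.

        ``omic_vectors`` maps each configured omic type to a (1, d) tensor of
        standardized features; ``drug_input`` is a MolecularGraph (gnn), a
        fingerprint tensor/array (ecfp), or a 2-tuple ``(graph, atom_tensor)``
        to substitute a differentiable atom-feature leaf. Used for single
        predictions and integrated-gradients attribution.
        """
        latents = []
        for omic in self.config.omic_types:
            x = omic_vectors[omic]
            if not isinstance(x, Tensor):
                x = Tensor(np.atleast_2d(x))
            latents.append(self.omic_encoders[omic](x))
        if self.config.drug_encoder == "gnn":
            if isinstance(drug_input, tuple):
                graph, atom_leaf = drug_input
                latents.append(self.drug_encoder.forward(graph, atom_input=atom_leaf))
            else:
                latents.append(self.drug_encoder.forward(drug_input))
        else:
            fp = drug_input if isinstance(drug_input, Tensor) \
                else Tensor(np.atleast_2d(drug_input))
            latents.append(self.drug_encoder(fp))
        return self.head(self.fuse(latents))

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, data in zip(self.params(), snap):
            p.data = data.copy()


def save_model(model: DRPModel, omic_dims: dict[OmicType, int], path: str) -> None:
    """Checkpoint parameters + config (npz with an embedded config hash)."""
    import json

    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.params())}
    cfg = asdict(model.config)  # recurses into the LDS dataclass
    cfg["omic_types"] = [t.value for t in model.config.omic_types]
    meta = {
        "config": cfg,
        "config_id": model.config.config_id(),
        "omic_dims": {t.value: d for t, d in omic_dims.items()},
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> DRPModel:
    """Rebuild a checkpointed model (architecture from embedded config)."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["lds"] = LDSConfig(**cfg_dict["lds"])
        config = ModelConfig(**cfg_dict)
        omic_dims = {OmicType(t): d for t, d in meta["omic_dims"].items()}
        model = DRPModel(config, omic_dims)
        for i, p in enumerate(model.params()):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p.data = stored.copy()
    return model


def _prepare_fold_inputs(records, fold, matrices, catalog, config):
    """Fold-local standardization + drug featurization shared by trainers."""
    omic_by_type = {m.omic_type: m for m in matrices}
    missing = [t.value for t in config.omic_types if t not in omic_by_type]
    if missing:
        raise ValueError(f"no omic matrix supplied for {missing}")
    train_records = [records[i] for i in fold.train_indices]
    val_records = [records[i] for i in fold.validation_indices]

    std_matrices: dict[OmicType, OmicMatrix] = {}
    for omic in config.omic_types:
        m = omic_by_type[omic]
        ridx = m.row_index()
        for r in train_records + val_records:
            if r.cell_line not in ridx:
                raise ValueError(
                    f"cell line {r.cell_line!r} missing from {omic.value} matrix")
        train_rows = sorted({ridx[r.cell_line] for r in train_records})
        stats = fit_standardizer(m, train_rows)
        std_matrices[omic] = apply_standardizer(m, stats)

    drug_names = [d.name for d in catalog]
    drug_pos = {n: i for i, n in enumerate(drug_names)}
    for r in train_records + val_records:
        if r.drug not in drug_pos:
            raise ValueError(f"drug {r.drug!r} missing from catalog")
    if config.drug_encoder == "gnn":
        drug_inputs = [featurize_smiles(d.smiles) for d in catalog]
    else:
        drug_inputs = [ecfp(d.smiles, config.fp_radius, config.fp_bits)
                       for d in catalog]
    return train_records, val_records, std_matrices, drug_pos, drug_inputs


def train_fold(records: list[ResponseRecord], fold, matrices: list[OmicMatrix],
               catalog: list[DrugRecord], config: ModelConfig,
               pretrained: dict[OmicType, Autoencoder] | None = None
               ) -> tuple[DRPModel, list[PredictionRecord]]:
    """Train on one fold's training split; return the model and its
    validation predictions (one per validation record, clipped to [0, 1]).

    Deterministic given ``config.seed``. Standardizers and LDS weights are
    fit on the training split only.
    """
    train_records, val_records, std_matrices, drug_pos, drug_inputs = \
        _prepare_fold_inputs(records, fold, matrices, catalog, config)
    if not train_records or not val_records:
        raise ValueError("fold must have non-empty train and validation splits")

    train_y = np.array([r.aac for r in train_records])
    val_y = np.array([r.aac for r in val_records])
    if config.use_lds:
        weights = compute_lds_weights(train_y, config.lds)
        # early stopping tracks the *training objective* on validation data:
        # the train-fitted smoothed density scores the validation labels
        # (leakage-free; no validation label shapes the density)
        from .lds import smoothed_density
        density, _ = smoothed_density(train_y, config.lds)
        vbins = np.minimum((val_y * config.lds.n_bins).astype(int),
                           config.lds.n_bins - 1)
        val_weights = 1.0 / np.maximum(density[vbins], config.lds.density_floor)
        val_weights = val_weights / val_weights.mean()
    else:
        weights = np.ones_like(train_y)
        val_weights = np.ones_like(val_y)

    model = DRPModel(config, {t: m.n_features for t, m in std_matrices.items()},
                     pretrained)
    rng = np.random.default_rng(config.seed + 1)
    omic_rows = {t: Tensor(m.values) for t, m in std_matrices.items()}
    cell_pos = {cl: i for i, cl in
                enumerate(next(iter(std_matrices.values())).cell_lines)}
    # all standardized matrices share the generated panel ordering
    for t, m in std_matrices.items():
        if {cl: i for i, cl in enumerate(m.cell_lines)} != cell_pos:
            raise ValueError(f"{t.value}: cell-line panels differ across matrices")

    tr_cell = np.array([cell_pos[r.cell_line] for r in train_records])
    tr_drug = np.array([drug_pos[r.drug] for r in train_records])
    va_cell = np.array([cell_pos[r.cell_line] for r in val_records])
    va_drug = np.array([drug_pos[r.drug] for r in val_records])

    optimiser = Adam(model.params(include_encoders=not config.freeze_encoders),
                     lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    n = len(train_records)
    batch = n if config.batch_size in (0, None) else min(config.batch_size, n)
    best_val, best_snap, since_best = np.inf, model.snapshot(), 0

    def validate() -> float:
        with no_grad():
            dl = model.drug_latents(drug_inputs)
            preds = model.forward(omic_rows, va_cell, dl, va_drug)
        return weighted_rmse_loss(preds.data.reshape(-1), val_y, val_weights)

    for epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            dl = model.drug_latents(drug_inputs, train=True, rng=rng)
            preds = model.forward(omic_rows, tr_cell[idx], dl, tr_drug[idx])
            loss = weighted_rmse_loss(preds, train_y[idx], weights[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"training loss diverged at epoch {epoch}; "
                    f"config={config.name} id={config.config_id()}")
            optimiser.zero_grad()
            loss.backward()
            optimiser.step()
        val_rmse = validate()
        if val_rmse < best_val - 1e-6:
            best_val, best_snap, since_best = val_rmse, model.snapshot(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.restore(best_snap)

    with no_grad():
        dl = model.drug_latents(drug_inputs)
        preds = model.forward(omic_rows, va_cell, dl, va_drug).data.reshape(-1)
    cid = config.config_id()
    out = [PredictionRecord(r.cell_line, r.drug, r.aac,
                            float(np.clip(p, 0.0, 1.0)),
                            fold.fold, fold.scheme, cid)
           for r, p in zip(val_records, preds)]
    return model, out


def elastic_net_baseline(records, fold, matrices, catalog,
                         config: ModelConfig | None = None,
                         alpha: float = 1e-3, l1_ratio: float = 0.5
                         ) -> list[PredictionRecord]:
    """Elastic-net linear regression on concatenated standardized omics plus
    ECFP bits, under exactly the same fold protocol as the neural models."""
    from sklearn.linear_model import ElasticNet

    config = config or ModelConfig(drug_encoder="ecfp", fusion="concat",
                                   use_lds=False, name="elastic-net")
    if config.drug_encoder != "ecfp":
        config = copy.deepcopy(config)
        config.drug_encoder = "ecfp"
    train_records, val_records, std_matrices, drug_pos, drug_inputs = \
        _prepare_fold_inputs(records, fold, matrices, catalog, config)
    cell_pos = {cl: i for i, cl in
                enumerate(next(iter(std_matrices.values())).cell_lines)}
    fp = np.vstack(drug_inputs)

    def design(recs):
        cells = np.array([cell_pos[r.cell_line] for r in recs])
        drugs = np.array([drug_pos[r.drug] for r in recs])
        blocks = [std_matrices[t].values[cells] for t in config.omic_types]
        blocks.append(fp[drugs])
        return np.hstack(blocks)

    X_train, y_train = design(train_records), np.array([r.aac for r in train_records])
    X_val = design(val_records)
    net = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
    net.fit(X_train, y_train)
    preds = np.clip(net.predict(X_val), 0.0, 1.0)
    return [PredictionRecord(r.cell_line, r.drug, r.aac, float(p),
                             fold.fold, fold.scheme, "elastic-net")
            for r, p in zip(val_records, preds)]


def random_search(space: dict[str, list], n_trials: int,
                  records, folds, matrices, catalog,
                  base_config: ModelConfig | None = None, seed: int = 0
                  ) -> tuple[ModelConfig, list[dict]]:
    """Seed-deterministic random search over ``space`` (knob -> candidate
    values). Each trial trains on the supplied folds and is scored by mean
    validation RMSE; returns (best config, full trial log)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    base_config = base_config or ModelConfig()
    log: list[dict] = []
    best_cfg, best_score = None, np.inf
    n_failed = 0
    for trial in range(n_trials):
        overrides = {k: v[int(rng.integers(len(v)))] for k, v in space.items()}
        cfg = copy.deepcopy(base_config)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        cfg.seed = int(rng.integers(2 ** 31))
        try:
            scores = []
            for fold in folds:
                _, preds = train_fold(records, fold, matrices, catalog, cfg)
                scores.append(weighted_rmse_loss(
                    [p.pred_aac for p in preds], [p.true_aac for p in preds]))
            score = float(np.mean(scores))
        except FloatingPointError:
            score, n_failed = np.nan, n_failed + 1
        log.append({"trial": trial, "overrides": overrides, "seed": cfg.seed,
                    "mean_val_rmse": score})
        if np.isfinite(score) and score < best_score:
            best_cfg, best_score = cfg, score
    if best_cfg is None:
        raise RuntimeError(f"all {n_trials} trials diverged")
    return best_cfg, log
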