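"""Per-omic autoencoders supplying compressed cell-line latents.

Each omic data type gets its own encoder/decoder pair, pretrained by
mean-squared reconstruction on standardized profiles. Pretraining needs no
response labels, so it may use every available cell line without leaking
dose-response information into a cross-validation fold. Downstream, the
encoder is either fine-tuned jointly with the prediction head (default) or
frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, no_grad
from .core_data import OmicMatrix, OmicType

__all__ = ["MLP", "AutoencoderSpec", "Autoencoder", "pretrain_autoencoder", "encode"]

_ACTIVATIONS = ("relu", "tanh", "linear")


class MLP:
    """Dense feed-forward stack on the autodiff engine.

    ``widths`` includes input and output dims; the activation applies to all
    layers except the last (linear output).
    """

    def __init__(self, widths: list[int], activation: str = "relu",
                 rng: np.random.Generator | None = None,
                 final_scale: float = 1.0):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if len(widths) < 2 or any(w < 1 for w in widths):
            raise ValueError(f"invalid layer widths {widths}")
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.widths = list(widths)
        self.weights = [
            Tensor.param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
            for n_in, n_out in zip(widths[:-1], widths[1:])
        ]
        self.biases = [Tensor.param(np.zeros(n_out)) for n_out in widths[1:]]
        if final_scale != 1.0:
            # near-zero output layer: the net starts close to the zero
            # function, so unseen-input predictions stay tame early on and
            # early stopping can catch the generalising phase
            self.weights[-1].data *= final_scale

    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = h.relu() if self.activation == "relu" else (
                    h.tanh() if self.activation == "tanh" else h)
        return h

    def forward_array(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            return self(Tensor(np.atleast_2d(x))).data

    def state_hash(self) -> int:
        """Hash of all parameter bytes (frozen-encoder verification)."""
        import hashlib
        digest = hashlib.sha256()
        for p in self.params():
            digest.update(p.data.tobytes())
        return int.from_bytes(digest.digest()[:8], "big")


@dataclass
class AutoencoderSpec:
    """Architecture and optimisation settings for one omic type."""

    omic_type: OmicType
    latent_dim: int = 16
    hidden_widths: list[int] | None = None   # default: [max(64, 2 * latent_dim)]
    activation: str = "relu"
    learning_rate: float = 1e-2
    epochs: int = 200
    batch_size: int = 0                      # 0 = full batch
    seed: int = 0

    def __post_init__(self):
        self.omic_type = OmicType(self.omic_type)
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.hidden_widths is None:
            self.hidden_widths = [max(64, 2 * self.latent_dim)]
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")


@dataclass
class Autoencoder:
    """Trained encoder/decoder pair plus the feature layout it expects."""

    spec: AutoencoderSpec
    encoder: MLP
    decoder: MLP
    feature_names: list[str] = field(default_factory=list)

    def encode_array(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.encoder.widths[0]:
            raise ValueError(
                f"feature-count mismatch: encoder expects "
                f"{self.encoder.widths[0]}, got {rows.shape[1]}")
        return self.encoder.forward_array(rows)

    def reconstruct_array(self, rows: np.ndarray) -> np.ndarray:
        return self.decoder.forward_array(self.encode_array(rows))


def pretrain_autoencoder(matrix: OmicMatrix, spec: AutoencoderSpec
                         ) -> tuple[Autoencoder, list[float]]:
    """Train an autoencoder by reconstruction MSE; returns it with the
    per-epoch loss history. Deterministic given ``spec.seed``."""
    if spec.latent_dim > matrix.n_features:
        raise ValueError(
            f"{spec.omic_type.value}: latent dim {spec.latent_dim} exceeds "
            f"input dim {matrix.n_features}")
    rng = np.random.default_rng(spec.seed)
    widths = [matrix.n_features, *spec.hidden_widths, spec.latent_dim]
    encoder = MLP(widths, spec.activation, rng)
    decoder = MLP(widths[::-1], spec.activation, rng)
    optimiser = Adam(encoder.params() + decoder.params(), lr=spec.learning_rate)

    X = matrix.values
    n = X.shape[0]
    batch = n if spec.batch_size in (0, None) else min(spec.batch_size, n)
    history: list[float] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb = Tensor(X[idx])
            recon = decoder(encoder(xb))
            loss = ((recon - xb) ** 2.0).mean()
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"{spec.omic_type.value}: reconstruction loss diverged to "
                    f"{loss.item()} at epoch {epoch}")
            optimiser.zero_grad()
            loss.backward()
            optimiser.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return Autoencoder(spec, encoder, decoder, list(matrix.feature_names)), history


def encode(rows: np.ndarray, autoencoder: Autoencoder) -> np.ndarray:
    """Encode matrix rows into per-cell-line omic latents (batch-size free)."""
    return autoencoder.encode_array(rows)
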