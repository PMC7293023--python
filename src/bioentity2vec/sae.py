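"""Stacked autoencoder for attribute compression.

High-dimensional raw attribute vectors (similarity-matrix rows, 1024-bit
fingerprints) are mapped to a 64-dimensional code by a small stacked
autoencoder: encoder input -> 256 -> 64 with sigmoid hidden activations,
mirrored linear-output decoder, trained to minimize mean squared
reconstruction error with the Adam optimizer (epochs=10, batch_size=128 by
default).  Implemented directly in numpy so training is deterministic and
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HIDDEN_DIM = 256
CODE_DIM = 64


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class EncoderModel:
    """Trained encoder: weights/biases per layer plus training metadata.

    Layers 0..1 are the encoder (sigmoid), layers 2..3 the decoder (sigmoid
    then linear).  ``encode`` is a pure function; ``code_dim`` outputs are
    always 64-wide regardless of ``input_dim``.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_dim: int
    code_dim: int = CODE_DIM
    seed: int | None = None
    epochs: int = 10
    loss_history: list[float] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] == 0:
            return np.zeros((0, self.code_dim))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"input width {X.shape[1]} != model input_dim {self.input_dim}")
        h = _sigmoid(X @ self.weights[0] + self.biases[0])
        return _sigmoid(h @ self.weights[1] + self.biases[1])

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        code = self.encode(X)
        h = _sigmoid(code @ self.weights[2] + self.biases[2])
        return h @ self.weights[3] + self.biases[3]

    def save(self, prefix: str | Path) -> None:
        """Persist weights (npz text-unsafe, so .npz) with a JSON sidecar."""
        prefix = Path(prefix)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(prefix.with_suffix(".npz"), **arrays)
        meta = {
            "input_dim": self.input_dim,
            "code_dim": self.code_dim,
            "seed": self.seed,
            "epochs": self.epochs,
            "loss_history": self.loss_history,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "EncoderModel":
        prefix = Path(prefix)
        data = np.load(prefix.with_suffix(".npz"))
        n_layers = len([k for k in data.files if k.startswith("W")])
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            weights,
            biases,
            input_dim=meta["input_dim"],
            code_dim=meta["code_dim"],
            seed=meta["seed"],
            epochs=meta["epochs"],
            loss_history=meta["loss_history"],
        )


def train_sae(
    X: np.ndarray,
    code_dim: int = CODE_DIM,
    epochs: int = 10,
    batch_size: int = 128,
    seed: int = 0,
    hidden_dim: int = HIDDEN_DIM,
    lr: float = 1e-3,
) -> EncoderModel:
    """Train the autoencoder on raw attribute vectors.

    Minimizes mean squared reconstruction error by minibatch Adam
    (beta1=0.9, beta2=0.999, eps=1e-8).  Raises on empty or non-finite
    input, or when the input width is below ``code_dim`` (no compression
    target exists).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, width = X.shape
    if n == 0:
        raise ValueError("empty training matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training matrix")
    if width < code_dim:
        raise ValueError(f"input width {width} < code_dim {code_dim}")

    rng = np.random.default_rng(seed)
    dims = [width, hidden_dim, code_dim, hidden_dim, width]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    def forward(batch: np.ndarray):
        acts = [batch]
        a = batch
        for li in range(4):
            z = a @ weights[li] + biases[li]
            a = z if li == 3 else _sigmoid(z)
            acts.append(a)
        return acts

    loss_history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = X[idx]
            acts = forward(batch)
            err = acts[-1] - batch
            epoch_loss += float(np.sum(err**2))
            # backprop of mean-over-batch-and-dims squared error
            delta = 2.0 * err / (batch.shape[0] * width)
            t += 1
            for li in range(3, -1, -1):
                gw = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ weights[li].T) * acts[li] * (1.0 - acts[li])
                m_w[li] = beta1 * m_w[li] + (1 - beta1) * gw
                v_w[li] = beta2 * v_w[li] + (1 - beta2) * gw**2
                m_b[li] = beta1 * m_b[li] + (1 - beta1) * gb
                v_b[li] = beta2 * v_b[li] + (1 - beta2) * gb**2
                corr1, corr2 = 1 - beta1**t, 1 - beta2**t
                weights[li] -= lr * (m_w[li] / corr1) / (np.sqrt(v_w[li] / corr2) + eps)
                biases[li] -= lr * (m_b[li] / corr1) / (np.sqrt(v_b[li] / corr2) + eps)
        loss_history.append(epoch_loss / (n * width))

    return EncoderModel(
        weights, biases, input_dim=width, code_dim=code_dim, seed=seed,
        epochs=epochs, loss_history=loss_history,
    )
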