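"""MLP autoencoder mapping log-normalized expression to a low-dimensional
latent space and back.

The encoder is two MLP layers (Linear-ReLU-Linear with a linear latent
head) and the decoder three (Linear-ReLU-Linear-ReLU-Linear with a linear
output head); the layer counts are fixed, the widths are free.  Training
minimizes the squared Frobenius reconstruction error with Adam.  Both maps
act cell-wise, so encode/decode are exactly permutation-equivariant over
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Linear, relu
from .io_preprocess import NormalizedMatrix


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class AEConfig:
    """Autoencoder hyperparameters.

    ``encoder_hidden`` has exactly one width (encoder = 2 layers total) and
    ``decoder_hidden`` exactly two (decoder = 3 layers total).  The default
    128-dimensional latent suits real-size gene panels; toy presets shrink
    every width.
    """

    latent_dim: int = 128
    encoder_hidden: list[int] = field(default_factory=lambda: [512])
    decoder_hidden: list[int] = field(default_factory=lambda: [256, 512])
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_hidden) != 1:
            raise ValueError("encoder has exactly 2 layers: one hidden width")
        if len(self.decoder_hidden) != 2:
            raise ValueError("decoder has exactly 3 layers: two hidden widths")
        if self.latent_dim < 1 or min(self.encoder_hidden + self.decoder_hidden) < 1:
            raise ValueError("all widths must be positive")


@dataclass
class LatentBatch:
    """Cells x latent_dim embeddings with labels carried through."""

    values: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("latent values must be finite")

    def combined_labels(self, sep: str = "_") -> np.ndarray:
        if not self.labels:
            return np.array([""] * len(self.values))
        cols = [np.asarray(v).astype(str) for v in self.labels.values()]
        out = cols[0]
        for c in cols[1:]:
            out = np.char.add(np.char.add(out, sep), c)
        return out


class AEParams:
    """Weight collection for one autoencoder (encoder + decoder layers)."""

    def __init__(self, cfg: AEConfig, n_genes: int):
        self.cfg = cfg
        self.input_dim = n_genes
        self.latent_dim = cfg.latent_dim
        rng = np.random.default_rng(cfg.seed)
        h = cfg.encoder_hidden[0]
        d1, d2 = cfg.decoder_hidden
        self.enc = [Linear(n_genes, h, rng), Linear(h, cfg.latent_dim, rng)]
        self.dec = [Linear(cfg.latent_dim, d1, rng), Linear(d1, d2, rng),
                    Linear(d2, n_genes, rng)]
        self._pre: list[np.ndarray] = []

    def modules(self):
        return self.enc + self.dec

    def encode_values(self, x: np.ndarray) -> np.ndarray:
        self._pre_enc = self.enc[0].forward(x)
        return self.enc[1].forward(relu(self._pre_enc))

    def decode_values(self, z: np.ndarray) -> np.ndarray:
        self._pre_dec1 = self.dec[0].forward(z)
        self._pre_dec2 = self.dec[1].forward(relu(self._pre_dec1))
        return self.dec[2].forward(relu(self._pre_dec2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Gradient of the last encode->decode pass; returns d(input)."""
        g = self.dec[2].backward(g)
        g = g * (self._pre_dec2 > 0)
        g = self.dec[1].backward(g)
        g = g * (self._pre_dec1 > 0)
        g = self.dec[0].backward(g)
        g = self.enc[1].backward(g)
        g = g * (self._pre_enc > 0)
        return self.enc[0].backward(g)


def init_autoencoder(cfg: AEConfig, n_genes: int) -> AEParams:
    """Seeded deterministic initialization."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return AEParams(cfg, n_genes)


def encode(p: AEParams, s: NormalizedMatrix) -> LatentBatch:
    if s.n_genes != p.input_dim:
        raise ValueError(f"matrix has {s.n_genes} genes, model expects {p.input_dim}")
    z = p.encode_values(s.values)
    return LatentBatch(z, {k: v.copy() for k, v in s.labels.items()},
                       list(s.cell_ids))


def decode(p: AEParams, z: LatentBatch,
           gene_ids: list[str] | None = None) -> NormalizedMatrix:
    vals = np.asarray(z.values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != p.latent_dim:
        raise ValueError(f"latent shape {vals.shape} incompatible with "
                         f"latent_dim {p.latent_dim}")
    rec = p.decode_values(vals)
    n = rec.shape[0]
    cell_ids = z.cell_ids if z.cell_ids is not None else [f"gen_{i}" for i in range(n)]
    if gene_ids is None:
        gene_ids = [f"gene_{j}" for j in range(p.input_dim)]
    return NormalizedMatrix(rec, list(cell_ids), list(gene_ids),
                            {k: np.asarray(v).copy() for k, v in z.labels.items()})


def reconstruction_loss(s: NormalizedMatrix | np.ndarray,
                        r: NormalizedMatrix | np.ndarray) -> float:
    """Squared Frobenius norm of the reconstruction residual."""
    a = s.values if isinstance(s, NormalizedMatrix) else np.asarray(s, dtype=float)
    b = r.values if isinstance(r, NormalizedMatrix) else np.asarray(r, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sum((a - b) ** 2))


def train_autoencoder(cfg: AEConfig, data: NormalizedMatrix
                      ) -> tuple[AEParams, list[float]]:
    """Fit the autoencoder by minibatch Adam on the reconstruction error.

    Gradients use the element-mean MSE for learning-rate stability; the
    returned per-epoch trace records the full-data squared Frobenius loss.
    Deterministic for a fixed seed (single-threaded numpy).
    """
    if data.n_cells < 2:
        raise ValueError("need at least 2 cells to train")
    p = init_autoencoder(cfg, data.n_genes)
    opt = Adam(p.modules(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    X = data.values
    n = X.shape[0]
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start:start + cfg.batch_size]]
            rec = p.decode_values(p.encode_values(xb))
            resid = rec - xb
            opt.zero_grad()
            p.backward(2.0 * resid / resid.size)
            opt.step()
        epoch_loss = reconstruction_loss(X, p.decode_values(p.encode_values(X)))
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(f"epoch {_epoch}: loss={epoch_loss}")
        trace.append(epoch_loss)
    return p, trace


def relative_reconstruction_error(p: AEParams, data: NormalizedMatrix) -> float:
    """||S_rec - S_ori||_F / ||S_ori||_F on the given data."""
    rec = p.decode_values(p.encode_values(data.values))
    denom = float(np.linalg.norm(data.values))
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(rec - data.values)) / denom
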