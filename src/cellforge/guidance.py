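"""Classifier-free guidance: training with random label nulling and guided
sampling with optional cached-feature acceleration.

One network is trained on labelled latents where each label is replaced by
the reserved null index with probability ``null_prob``; at sampling time
the conditional and unconditional noise predictions are combined as

    eps_hat = eps_u + w * (eps_c - eps_u)

so w = 1 is the pure conditional model and w = 0 the unconditional one.
The guidance hyperparameter k (useful range 1-2) maps to w through
``weight_form``: ``"k"`` (default, w = k) or ``"1+k"`` (w = 1 + k, the
expansion eps_c - k (eps_u - eps_c) = (1+k) eps_c - k eps_u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import LatentBatch
from .backbone import BackboneParams, HighLevelFeature
from .cache import CacheSchedule, should_update
from .diffusion import DiffusionState, NoiseSchedule, reverse_step


class GuidanceError(ValueError):
    """Invalid guidance usage (e.g. sampling with the null label)."""


@dataclass
class GuidanceConfig:
    """Guidance strength and training-time label-nulling probability."""

    k: float = 1.0
    null_prob: float = 0.1
    weight_form: str = "k"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise GuidanceError("k must be >= 0")
        if not (0.0 <= self.null_prob < 1.0):
            raise GuidanceError("null_prob must be in [0, 1)")
        if self.weight_form not in ("k", "1+k"):
            raise GuidanceError("weight_form must be 'k' or '1+k'")

    @property
    def w(self) -> float:
        """Interpolation weight between unconditional and conditional."""
        return self.k if self.weight_form == "k" else 1.0 + self.k


def null_labels(labels: np.ndarray, null_prob: float, null_index: int,
                rng: np.random.Generator) -> np.ndarray:
    """Independently replace each label with the null index w.p. null_prob."""
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    if null_prob > 0:
        out[rng.random(labels.shape) < null_prob] = null_index
    return out


def combine_guidance(eps_c: np.ndarray, eps_u: np.ndarray, w: float) -> np.ndarray:
    """eps_u + w (eps_c - eps_u); linear in both predictions.

    The endpoints return the corresponding branch exactly (no float
    round-trip), so w=1 is the pure conditional model and w=0 the pure
    unconditional one.
    """
    if w == 1.0:
        return eps_c
    if w == 0.0:
        return eps_u
    return eps_u + w * (eps_c - eps_u)


def guided_epsilon(p: BackboneParams, x_t: np.ndarray, t, y,
                   g: GuidanceConfig) -> np.ndarray:
    """Guided noise prediction from exactly two backbone evaluations."""
    null = p.cfg.n_classes - 1
    y_arr = np.full(x_t.shape[0], y, dtype=int) if np.isscalar(y) else \
        np.asarray(y, dtype=int)
    if (y_arr == null).any():
        raise GuidanceError("guided_epsilon requires a real class label")
    eps_c, _ = p.forward_full(x_t, t, y_arr)
    eps_u, _ = p.forward_full(x_t, t, np.full_like(y_arr, null))
    return combine_guidance(eps_c, eps_u, g.w)


def train_diffusion(p: BackboneParams, latents: LatentBatch | np.ndarray,
                    label_indices: np.ndarray, schedule: NoiseSchedule,
                    guidance: GuidanceConfig, n_steps: int = 2000,
                    batch_size: int = 128, lr: float = 1e-3,
                    seed: int = 0) -> list[float]:
    """Train the noise predictor by minibatch Adam on the epsilon MSE.

    Per step: sample a batch, null labels with probability ``null_prob``,
    draw per-cell t ~ U[1, T-1] and eps ~ N(0, I), corrupt with the closed
    form and minimize mean((eps_hat - eps)^2).  Mutates ``p`` in place and
    returns the per-step loss trace; deterministic for a fixed seed.
    """
    z0 = latents.values if isinstance(latents, LatentBatch) else \
        np.asarray(latents, dtype=float)
    label_indices = np.asarray(label_indices, dtype=int)
    if label_indices.shape[0] != z0.shape[0]:
        raise ValueError("one label per latent row required")
    null = p.cfg.n_classes - 1
    rng = np.random.default_rng(seed)
    opt = p.make_optimizer(lr=lr)
    n = z0.shape[0]
    trace: list[float] = []
    for _step in range(n_steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        zb = z0[idx]
        yb = null_labels(label_indices[idx], guidance.null_prob, null, rng)
        t = rng.integers(1, schedule.T, size=len(idx))
        eps = rng.standard_normal(zb.shape)
        ab = schedule.alpha_bar[t][:, None]
        x_t = np.sqrt(ab) * zb + np.sqrt(1.0 - ab) * eps

        eps_hat, _ = p.forward_full(x_t, t, yb)
        resid = eps_hat - eps
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {_step}")
        trace.append(loss)
        opt.zero_grad()
        p.backward_full(2.0 * resid / resid.size)
        opt.step()
    return trace


def sample(p: BackboneParams, schedule: NoiseSchedule, label: int,
           n_cells: int, guidance: GuidanceConfig,
           cache_schedule: CacheSchedule | None = None,
           rng: np.random.Generator | int = 0,
           labels_out: dict[str, np.ndarray] | None = None) -> LatentBatch:
    """Generate a latent batch for one class by ancestral reverse diffusion.

    Starts from x_T ~ N(0, I) and iterates t = T-1 .. 0.  At steps in the
    cache schedule's xi (or at every step when no schedule is given) both
    guidance branches take the full backbone and refresh their own cached
    feature; elsewhere both take the truncated cached pass.  With interval
    c = 1 the output is bit-identical to uncached sampling under the same
    rng, since the cache is refreshed before every use.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    null = p.cfg.n_classes - 1
    if label == null:
        raise GuidanceError("cannot sample the null label")
    if cache_schedule is not None and cache_schedule.T != schedule.T:
        raise ValueError("cache schedule T differs from noise schedule T")
    T = schedule.T
    depth = min(cache_schedule.depth, p.cfg.depth) if cache_schedule else p.cfg.depth
    x = rng.standard_normal((n_cells, p.cfg.latent_dim))
    y_c = np.full(n_cells, label, dtype=int)
    y_u = np.full(n_cells, null, dtype=int)
    feat_c: HighLevelFeature | None = None
    feat_u: HighLevelFeature | None = None

    for t in range(T - 1, -1, -1):
        if cache_schedule is None or should_update(cache_schedule, t):
            eps_c, feat_c = p.forward_full(x, t, y_c, cache_depth=depth)
            eps_u, feat_u = p.forward_full(x, t, y_u, cache_depth=depth)
        else:
            eps_c = p.forward_cached(x, t, y_c, feat_c)
            eps_u = p.forward_cached(x, t, y_u, feat_u)
        eps_hat = combine_guidance(eps_c, eps_u, guidance.w)
        if t >= 1:
            x = reverse_step(DiffusionState(x, t), eps_hat, schedule, rng).x
        else:
            # final refinement at t = 0: posterior mean only, no noise
            a, ab = schedule.alpha[0], schedule.alpha_bar[0]
            x = (x - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
    return LatentBatch(x, labels_out or {}, None)
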