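"""Noise-prediction backbone: a symmetric stack of MLP chunks with
per-chunk label/time conditioning, stack-based additive skip connections,
and a two-layer fully-connected head.

For depth ``d`` the conditioned chunks are D_1..D_d, mid, U_1..U_d — an odd
count n = 2d + 1 — followed by the FC head.  Each chunk first injects
conditioning as ``x <- x * proj_y(E[y]) + proj_t(temb(t))`` (elementwise
product with a chunk-projected label embedding plus a chunk-projected
sinusoidal time embedding), then applies a 2-layer MLP.  Down-chunk outputs
are pushed on a stack; each up-chunk adds the popped top to its output, so
U_i receives the skip of D_{d+1-i} (LIFO discipline).

The cacheable high-level feature at depth ``b`` is the input to up-chunk
U_b (the post-skip output of the stage before it).  The cached forward pass
recomputes only the shallow down chunks D_1..D_{d+1-b} (whose outputs feed
the remaining skips), applies U_b..U_d to the cached feature with
conditioning at the *current* step, and finishes with the FC head — the
deep chunks D_{d+2-b}..D_d, mid and U_1..U_{b-1} are never evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Embedding, Linear, MLP2, relu, sinusoidal_embedding


class VocabularyError(KeyError):
    """Label outside the trained vocabulary."""


class LabelVocabulary:
    """Joint vocabulary over attribute combinations, plus one null index.

    Multi-attribute labels are joined into a single combined string (e.g.
    ``fibroblast_Bladder``), so single- and paired-attribute conditioning
    share one mechanism.  The null (unconditional) index is the last row of
    the embedding table.
    """

    def __init__(self, classes: list[str]):
        if len(set(classes)) != len(classes):
            raise ValueError("duplicate class names")
        self.classes = list(classes)
        self._index = {c: i for i, c in enumerate(self.classes)}

    @classmethod
    def from_labels(cls, combined: np.ndarray) -> "LabelVocabulary":
        return cls(sorted(set(np.asarray(combined).astype(str).tolist())))

    @property
    def n_classes(self) -> int:
        """Vocabulary size including the reserved null index."""
        return len(self.classes) + 1

    @property
    def null_index(self) -> int:
        return len(self.classes)

    def encode(self, labels) -> np.ndarray:
        labels = np.atleast_1d(np.asarray(labels).astype(str))
        try:
            return np.array([self._index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise VocabularyError(f"unknown label {exc.args[0]!r}; "
                                  f"known: {self.classes}") from None

    def decode(self, idx: np.ndarray) -> np.ndarray:
        return np.array([self.classes[i] if i != self.null_index else "<null>"
                         for i in np.atleast_1d(idx)])


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    ``chunk_widths`` holds d + 1 widths: the output widths of the down
    chunks D_1..D_d followed by the mid chunk.  ``n_classes`` counts the
    label vocabulary *including* the reserved null index.
    """

    latent_dim: int
    n_classes: int
    depth: int = 2
    chunk_widths: list[int] = field(default_factory=lambda: [256, 128, 128])
    embed_dim: int = 64
    time_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.chunk_widths) != self.depth + 1:
            raise ValueError(f"need depth+1={self.depth + 1} chunk widths")
        if min(self.chunk_widths) < 1 or self.latent_dim < 1:
            raise ValueError("widths must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes counts real classes plus the null index")

    @property
    def n_chunks(self) -> int:
        """Conditioned chunk count n = 2d + 1 (always odd)."""
        return 2 * self.depth + 1


@dataclass
class HighLevelFeature:
    """Cached deep feature: the input to up-chunk U_b at some step."""

    values: np.ndarray
    produced_at_t: int
    depth_b: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("cached feature must be finite")


class _Conditioner:
    """Per-chunk injection x * proj_y(E[y]) + proj_t(temb)."""

    def __init__(self, embed_dim: int, time_dim: int, width: int,
                 rng: np.random.Generator):
        # bias 1 on the label projection keeps the product near-identity at
        # init so early training signal is not multiplicatively destroyed
        self.label_proj = Linear(embed_dim, width, rng, w_scale=0.05, b_init=1.0)
        self.time_proj = Linear(time_dim, width, rng, w_scale=0.05)

    def forward(self, x: np.ndarray, yemb: np.ndarray,
                temb: np.ndarray) -> np.ndarray:
        self._x = x
        self._yp = self.label_proj.forward(yemb)
        return x * self._yp + self.time_proj.forward(temb)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (d_x, d_yemb); the time embedding is fixed (no grad)."""
        dyemb = self.label_proj.backward(g * self._x)
        self.time_proj.backward(g)
        return g * self._yp, dyemb

    def params_and_grads(self):
        yield from self.label_proj.params_and_grads()
        yield from self.time_proj.params_and_grads()


class BackboneParams:
    """Weights of the backbone plus full/cached evaluation counters."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.depth
        widths = cfg.chunk_widths
        self.embed = Embedding(cfg.n_classes, cfg.embed_dim, rng)

        in_w = [cfg.latent_dim] + widths[:d - 1]        # inputs of D_1..D_d
        self.downs = [MLP2(in_w[i], widths[i], widths[i], rng) for i in range(d)]
        self.mid = MLP2(widths[d - 1], widths[d], widths[d], rng)
        # up-chunk U_i maps its input to the width of the skip it pops
        # (output of D_{d+1-i}); U_1's input is the mid output
        up_in = [widths[d]] + [widths[d - i] for i in range(1, d)]
        up_out = [widths[d - i] for i in range(1, d + 1)]
        self.ups = [MLP2(up_in[i], up_out[i], up_out[i], rng) for i in range(d)]
        head_w = up_out[-1]
        self.fc1 = Linear(head_w, head_w, rng)
        self.fc2 = Linear(head_w, cfg.latent_dim, rng)

        # conditioners indexed by chunk id: 0..d-1 downs, d mid, d+1..2d ups
        cond_w = in_w + [widths[d - 1]] + up_in
        self.conds = [_Conditioner(cfg.embed_dim, cfg.time_dim, w, rng)
                      for w in cond_w]

        self.n_full = 0
        self.n_cached = 0

    # ------------------------------------------------------------------
    def modules(self):
        return [self.embed, *self.downs, self.mid, *self.ups,
                self.fc1, self.fc2, *self.conds]

    def reset_counters(self) -> None:
        self.n_full = 0
        self.n_cached = 0

    def _embed_inputs(self, t, y, n: int) -> tuple[np.ndarray, np.ndarray]:
        t_arr = np.full(n, t, dtype=float) if np.isscalar(t) else \
            np.asarray(t, dtype=float)
        y_arr = np.full(n, y, dtype=int) if np.isscalar(y) else \
            np.asarray(y, dtype=int)
        return self.embed.forward(y_arr), sinusoidal_embedding(t_arr, self.cfg.time_dim)

    def _head(self, h: np.ndarray) -> np.ndarray:
        self._fc_pre = self.fc1.forward(h)
        return self.fc2.forward(relu(self._fc_pre))

    # ------------------------------------------------------------------
    def forward_full(self, x: np.ndarray, t, y, cache_depth: int | None = None
                     ) -> tuple[np.ndarray, HighLevelFeature | None]:
        """Full pass through all chunks; optionally export the feature at
        ``cache_depth`` b (the input to U_b)."""
        cfg = self.cfg
        d = cfg.depth
        if cache_depth is not None and not (1 <= cache_depth <= d):
            raise ValueError(f"cache depth must be in [1, {d}]")
        x = np.asarray(x, dtype=float)
        if x.shape[1] != cfg.latent_dim:
            raise ValueError(f"input width {x.shape[1]} != latent {cfg.latent_dim}")
        yemb, temb = self._embed_inputs(t, y, x.shape[0])

        skips: list[np.ndarray] = []
        h = x
        for i in range(d):
            h = self.downs[i].forward(self.conds[i].forward(h, yemb, temb))
            skips.append(h)
        h = self.mid.forward(self.conds[d].forward(h, yemb, temb))
        feat_val = h if cache_depth == 1 else None
        for i in range(d):                      # up stage i+1
            h = self.ups[i].forward(self.conds[d + 1 + i].forward(h, yemb, temb))
            h = h + skips.pop()
            if cache_depth is not None and cache_depth == i + 2:
                feat_val = h
        eps = self._head(h)
        self.n_full += 1
        feat = None
        if cache_depth is not None:
            t_tag = int(t) if np.isscalar(t) else -1
            feat = HighLevelFeature(feat_val.copy(), t_tag, cache_depth)
        return eps, feat

    def forward_cached(self, x: np.ndarray, t, y,
                       feat: HighLevelFeature) -> np.ndarray:
        """Truncated pass reusing a cached deep feature.

        Runs D_1..D_{d+1-b} for the remaining skips, then U_b..U_d on the
        cached feature with conditioning at the current t, then the head.
        """
        cfg = self.cfg
        d = cfg.depth
        b = feat.depth_b
        if not (1 <= b <= d):
            raise ValueError(f"feature depth {b} outside [1, {d}]")
        x = np.asarray(x, dtype=float)
        yemb, temb = self._embed_inputs(t, y, x.shape[0])

        skips: list[np.ndarray] = []
        h = x
        for j in range(d + 1 - b):
            h = self.downs[j].forward(self.conds[j].forward(h, yemb, temb))
            skips.append(h)
        h = feat.values
        if h.shape[0] != x.shape[0]:
            raise ValueError("cached feature batch size mismatch")
        for i in range(b - 1, d):               # up stage i+1 = b..d
            h = self.ups[i].forward(self.conds[d + 1 + i].forward(h, yemb, temb))
            h = h + skips.pop()
        eps = self._head(h)
        self.n_cached += 1
        return eps

    # ------------------------------------------------------------------
    def backward_full(self, g: np.ndarray) -> np.ndarray:
        """Backprop through the most recent :meth:`forward_full`.

        Accumulates parameter gradients (including the label-embedding
        table) and returns the gradient w.r.t. the input batch.
        """
        d = self.cfg.depth
        g = self.fc2.backward(g)
        g = g * (self._fc_pre > 0)
        g = self.fc1.backward(g)

        dyemb = 0.0
        skip_grad: list[np.ndarray | None] = [None] * d
        for i in range(d - 1, -1, -1):          # up stages d..1
            skip_grad[d - 1 - i] = g            # grad to popped D_{d-i} output
            g = self.ups[i].backward(g)
            g, dy = self.conds[d + 1 + i].backward(g)
            dyemb = dyemb + dy
        g = self.mid.backward(g)
        g, dy = self.conds[d].backward(g)
        dyemb = dyemb + dy
        for j in range(d - 1, -1, -1):          # down stages d..1
            g = g + skip_grad[j]
            g = self.downs[j].backward(g)
            g, dy = self.conds[j].backward(g)
            dyemb = dyemb + dy
        self.embed.backward(dyemb)
        return g

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.modules(), lr=lr)


def init_backbone(cfg: BackboneConfig) -> BackboneParams:
    """Seeded deterministic initialization."""
    return BackboneParams(cfg)


def condition_inject(x: np.ndarray, y, t, p: BackboneParams,
                     chunk_id: int) -> np.ndarray:
    """Apply chunk ``chunk_id``'s conditioning to a feature block."""
    if not (0 <= chunk_id < p.cfg.n_chunks):
        raise ValueError(f"chunk_id outside [0, {p.cfg.n_chunks})")
    x = np.asarray(x, dtype=float)
    yemb, temb = p._embed_inputs(t, y, x.shape[0])
    return p.conds[chunk_id].forward(x, yemb, temb)
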