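"""End-to-end orchestration: simulate -> preprocess -> train-ae ->
train-diffusion -> generate -> evaluate.

The programmatic surface is :func:`fit` (train autoencoder + conditional
diffusion on a labelled count matrix) and :func:`generate` /
:func:`generate_matched` (sample latents per class, decode, and invert the
normalization back to integer counts with per-cell library sizes resampled
from the real cells of the same class).  :func:`run_pipeline` drives the
same stages from a validated config dict and writes artifacts to disk.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import autoencoder as ae_mod
from . import guidance as guid_mod
from .autoencoder import AEConfig, AEParams, LatentBatch
from .backbone import BackboneConfig, BackboneParams, LabelVocabulary, init_backbone
from .cache import CacheSchedule, make_cache_schedule
from .diffusion import NoiseSchedule, make_schedule
from .guidance import GuidanceConfig
from .io_preprocess import (ExpressionMatrix, NormalizedMatrix,
                            denormalize_counts, normalize, read_counts,
                            write_counts)
from .metrics import MetricsReport, evaluate
from .synthetic_data import SyntheticConfig, make_dataset

log = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A pipeline stage is missing an upstream artifact."""


class ConfigKeyError(ValueError):
    """Unknown configuration key."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "io": {"format": "h5ad"},
    "synthetic": {
        "n_genes": 200, "cells_per_group": 300,
        "attributes": [["cell_type", ["type_0", "type_1", "type_2"]]],
        "nb_mean_range": [2.0, 8.0], "baseline_mean": 0.1,
        "dispersion": 0.3, "marker_fraction": 0.1, "n_timepoints": 0,
    },
    "ae": {"latent_dim": 32, "encoder_hidden": [256],
           "decoder_hidden": [256, 256], "learning_rate": 1e-3,
           "epochs": 800, "batch_size": 128},
    "diffusion": {"T": 200, "schedule": "linear",
                  "beta_start": 1e-4, "beta_end": 0.02},
    "backbone": {"depth": 2, "chunk_widths": [128, 64, 64],
                 "embed_dim": 64, "time_dim": 64},
    "guidance": {"k": 1.0, "null_prob": 0.1, "weight_form": "k"},
    "train": {"steps": 16000, "batch_size": 128, "lr": 1e-3},
    "cache": {"interval": 5, "depth": 2},
    "generate": {"n_per_label": 0},          # 0 = match real class sizes
    "metrics": {"n_pcs": 50, "k_neighbors": 30, "knn_k": 5, "n_folds": 5},
}


def make_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Defaults merged with overrides; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _merge(cfg, overrides, path="")
    return cfg


def _merge(base: dict, over: dict, path: str) -> None:
    for key, val in over.items():
        if key not in base:
            raise ConfigKeyError(f"unknown config key '{path}{key}'")
        if isinstance(base[key], dict) and key != "attributes":
            if not isinstance(val, dict):
                raise ConfigKeyError(f"'{path}{key}' must be a section")
            _merge(base[key], val, path=f"{path}{key}.")
        else:
            base[key] = val


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# programmatic pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Everything needed to generate and evaluate after training."""

    ae: AEParams
    ae_trace: list[float]
    backbone: BackboneParams
    diff_trace: list[float]
    vocab: LabelVocabulary
    schedule: NoiseSchedule
    guidance: GuidanceConfig
    gene_ids: list[str]
    label_attrs: dict[str, dict[str, str]]    # class -> attr -> value
    library_sizes: dict[str, np.ndarray]      # class -> real totals
    latent_mu: np.ndarray | None = None       # per-dim latent standardization
    latent_sd: np.ndarray | None = None
    real_norm: NormalizedMatrix | None = None


def fit(real: ExpressionMatrix, cfg: dict[str, Any] | None = None,
        seed: int | None = None) -> TrainedModel:
    """Normalize, train the autoencoder, then the guided diffusion model."""
    cfg = make_config(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg["seed"])

    norm = normalize(real)
    ae_cfg = AEConfig(**cfg["ae"], seed=master)
    ae_params, ae_trace = ae_mod.train_autoencoder(ae_cfg, norm)

    latents = ae_mod.encode(ae_params, norm)
    # diffusion operates on standardized latents (the forward process mixes
    # signal with unit-variance noise, so the data must live on that scale)
    mu = latents.values.mean(axis=0)
    sd = latents.values.std(axis=0) + 1e-8
    z_std = (latents.values - mu) / sd
    combined = real.combined_labels()
    vocab = LabelVocabulary.from_labels(combined)
    y_idx = vocab.encode(combined)

    bb_cfg = BackboneConfig(latent_dim=ae_cfg.latent_dim,
                            n_classes=vocab.n_classes,
                            seed=master + 1, **cfg["backbone"])
    bb = init_backbone(bb_cfg)
    d = cfg["diffusion"]
    schedule = make_schedule(T=d["T"], kind=d["schedule"],
                             beta_start=d["beta_start"], beta_end=d["beta_end"])
    g_cfg = GuidanceConfig(**cfg["guidance"])
    tr = cfg["train"]
    diff_trace = guid_mod.train_diffusion(
        bb, z_std, y_idx, schedule, g_cfg, n_steps=tr["steps"],
        batch_size=tr["batch_size"], lr=tr["lr"], seed=master + 2)

    totals = real.dense().sum(axis=1)
    lib, attrs = {}, {}
    names = list(real.labels.keys())
    for cls in vocab.classes:
        mask = combined == cls
        lib[cls] = totals[mask]
        row = int(np.flatnonzero(mask)[0])
        attrs[cls] = {a: str(real.labels[a][row]) for a in names}
    return TrainedModel(ae_params, ae_trace, bb, diff_trace, vocab, schedule,
                        g_cfg, list(real.gene_ids), attrs, lib,
                        latent_mu=mu, latent_sd=sd, real_norm=norm)


def generate(model: TrainedModel, label: str, n_cells: int,
             cache_interval: int | None = 5, seed: int = 0,
             guidance: GuidanceConfig | None = None,
             cache_depth: int | None = None) -> ExpressionMatrix:
    """Generate ``n_cells`` cells of one class as an integer count matrix.

    Latents are sampled by guided reverse diffusion (cached passes between
    cache-schedule updates when an interval is given), decoded to
    log-normalized expression, and inverted to counts using library sizes
    resampled from the real cells of the same class.
    """
    g_cfg = guidance or model.guidance
    idx = int(model.vocab.encode([label])[0])
    sched: CacheSchedule | None = None
    if cache_interval is not None:
        depth = cache_depth if cache_depth is not None else model.backbone.cfg.depth
        sched = make_cache_schedule(model.schedule.T, cache_interval, depth)
    rng = np.random.default_rng(seed)
    z = guid_mod.sample(model.backbone, model.schedule, idx, n_cells,
                        g_cfg, sched, rng)
    if model.latent_mu is not None:
        z.values = z.values * model.latent_sd + model.latent_mu
    z.labels = {a: np.full(n_cells, v)
                for a, v in model.label_attrs[label].items()}
    rec = ae_mod.decode(model.ae, z, gene_ids=model.gene_ids)
    libs = rng.choice(model.library_sizes[label], size=n_cells, replace=True)
    counts = denormalize_counts(rec.values, libs, rng)
    return ExpressionMatrix(counts,
                            [f"gen_{label}_{i}" for i in range(n_cells)],
                            list(model.gene_ids), z.labels)


def generate_matched(model: TrainedModel, n_per_label: int | None = None,
                     cache_interval: int | None = 5, seed: int = 0,
                     guidance: GuidanceConfig | None = None
                     ) -> ExpressionMatrix:
    """Generate every class (real class size by default) and concatenate."""
    parts = []
    for j, cls in enumerate(model.vocab.classes):
        n = n_per_label or len(model.library_sizes[cls])
        parts.append(generate(model, cls, n, cache_interval,
                              seed=seed + 1000 + j, guidance=guidance))
    counts = np.vstack([p.dense() for p in parts])
    cell_ids = [c for p in parts for c in p.cell_ids]
    labels = {a: np.concatenate([p.labels[a] for p in parts])
              for a in parts[0].labels}
    return ExpressionMatrix(counts, cell_ids, model.gene_ids, labels)


# ---------------------------------------------------------------------------
# disk-level pipeline
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "preprocess", "train-ae", "train-diffusion",
           "generate", "evaluate")


def run_pipeline(cfg: dict[str, Any], outdir: str | Path,
                 stages: tuple[str, ...] = _STAGES,
                 real_path: str | Path | None = None) -> dict[str, Any]:
    """Execute the requested stages in order, writing artifacts to outdir.

    Every artifact carries the config hash; the returned summary records
    per-stage wall time and the backbone's full/cached evaluation counters.
    """
    cfg = make_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    fmt = cfg["io"]["format"]
    summary: dict[str, Any] = {"config_hash": chash, "stages": {},
                               "seed": cfg["seed"]}

    real: ExpressionMatrix | None = None
    model: TrainedModel | None = None
    gen: ExpressionMatrix | None = None

    def _tick(stage, fn):
        t0 = time.perf_counter()
        out = fn()
        summary["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %-15s %6.2fs", stage, time.perf_counter() - t0)
        return out

    if "simulate" in stages:
        def _sim():
            s = dict(cfg["synthetic"])
            s["attributes"] = [(n, list(lv)) for n, lv in s["attributes"]]
            m = make_dataset(SyntheticConfig(**s, seed=cfg["seed"]))
            write_counts(m, outdir / f"real.{fmt}", fmt)
            return m
        real = _tick("simulate", _sim)
    elif real_path is not None:
        real = read_counts(real_path, fmt)

    if "train-ae" in stages or "train-diffusion" in stages:
        if real is None:
            raise DependencyError("training stages need 'simulate' or a real_path")
        model = _tick("train", lambda: fit(real, cfg))
        summary["ae_final_loss"] = model.ae_trace[-1]
        summary["diffusion_final_loss"] = model.diff_trace[-1]

    if "generate" in stages:
        if model is None:
            raise DependencyError("'generate' needs the training stages")
        model.backbone.reset_counters()
        n = cfg["generate"]["n_per_label"] or None
        gen = _tick("generate", lambda: generate_matched(
            model, n, cfg["cache"]["interval"], seed=cfg["seed"]))
        write_counts(gen, outdir / f"generated.{fmt}", fmt)
        summary["backbone_passes"] = {"full": model.backbone.n_full,
                                      "cached": model.backbone.n_cached}

    if "evaluate" in stages:
        if real is None or gen is None:
            raise DependencyError("'evaluate' needs 'simulate' and 'generate'")
        mc = cfg["metrics"]
        report = _tick("evaluate", lambda: evaluate(
            normalize(real), normalize(gen), n_pcs=mc["n_pcs"],
            k_neighbors=mc["k_neighbors"], knn_k=mc["knn_k"],
            n_folds=mc["n_folds"], seed=cfg["seed"]))
        payload = report.to_dict()
        payload["config_hash"] = chash
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
        summary["metrics"] = payload

    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    return summary
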