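"""Single-archive checkpoints for trained models.

One ``.npz`` file holds every weight array (in deterministic module order)
plus a JSON header with the configs, label vocabulary, noise schedule and
per-class library sizes — enough to reload and generate without the
training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .autoencoder import AEConfig, AEParams
from .backbone import BackboneConfig, BackboneParams, LabelVocabulary
from .diffusion import NoiseSchedule
from .guidance import GuidanceConfig
from .pipeline import TrainedModel

FORMAT_VERSION = 1


def _weight_arrays(modules) -> list[np.ndarray]:
    return [p for m in modules for p, _ in m.params_and_grads()]


def _ae_modules(p: AEParams):
    return p.modules()


def save_model(model: TrainedModel, path: str | Path) -> None:
    header = {
        "version": FORMAT_VERSION,
        "ae_cfg": asdict(model.ae.cfg),
        "n_genes": model.ae.input_dim,
        "backbone_cfg": asdict(model.backbone.cfg),
        "classes": model.vocab.classes,
        "beta": model.schedule.beta.tolist(),
        "guidance": asdict(model.guidance),
        "gene_ids": model.gene_ids,
        "label_attrs": model.label_attrs,
        "ae_trace": model.ae_trace,
        "diff_trace_tail": model.diff_trace[-50:],
    }
    arrays = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, a in enumerate(_weight_arrays(_ae_modules(model.ae))):
        arrays[f"ae_{i}"] = a
    for i, a in enumerate(_weight_arrays(model.backbone.modules())):
        arrays[f"bb_{i}"] = a
    for cls, libs in model.library_sizes.items():
        arrays[f"lib_{cls}"] = np.asarray(libs)
    if model.latent_mu is not None:
        arrays["latent_mu"] = model.latent_mu
        arrays["latent_sd"] = model.latent_sd
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header["version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        ae = AEParams(AEConfig(**header["ae_cfg"]), header["n_genes"])
        for i, (p, _) in enumerate(pg for m in _ae_modules(ae)
                                   for pg in m.params_and_grads()):
            p[...] = data[f"ae_{i}"]
        bb = BackboneParams(BackboneConfig(**header["backbone_cfg"]))
        for i, (p, _) in enumerate(pg for m in bb.modules()
                                   for pg in m.params_and_grads()):
            p[...] = data[f"bb_{i}"]
        beta = np.asarray(header["beta"])
        schedule = NoiseSchedule(beta=beta, alpha=1 - beta,
                                 alpha_bar=np.cumprod(1 - beta))
        vocab = LabelVocabulary(header["classes"])
        libs = {cls: np.asarray(data[f"lib_{cls}"]) for cls in vocab.classes}
        mu = np.asarray(data["latent_mu"]) if "latent_mu" in data else None
        sd = np.asarray(data["latent_sd"]) if "latent_sd" in data else None
    return TrainedModel(
        ae=ae, ae_trace=list(header["ae_trace"]), backbone=bb,
        diff_trace=list(header["diff_trace_tail"]), vocab=vocab,
        schedule=schedule, guidance=GuidanceConfig(**header["guidance"]),
        gene_ids=list(header["gene_ids"]), label_attrs=header["label_attrs"],
        library_sizes=libs, latent_mu=mu, latent_sd=sd, real_norm=None)
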