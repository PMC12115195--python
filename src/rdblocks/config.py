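"""YAML run configuration.

One file describes a full run: model switches and block hyper-parameters
under ``model``, training recipe under ``train``.  Every key is optional;
omitted keys fall back to the reference defaults (300 epochs, batch 32,
SGD lr 0.01 with cosine decay to 1e-4, momentum 0.937, weight decay
0.005, 640 px input).

Example::

    model:
      scale: calibrated
      num_classes: 3
      sdl: true
      sppflkc: true
      cfcglu: true
      cscbam: true
      lskac: {k: 23, d: 3}
      sppflkc_cfg: {pool_kernel: 5}
      cfcglu_cfg: {t: 0.5, alpha: 0.5, beta: 0.25, groups: 2}
      cscbam_cfg: {reduction: 16, interact_hidden_ratio: 0.125, spatial_tokens: 20}
    train:
      epochs: 300
      batch_size: 32
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .model import ModelSpec
from .train import TrainConfig


def _take(dc_cls, d: dict):
    names = {f.name for f in fields(dc_cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {dc_cls.__name__} keys: {sorted(unknown)}")
    return dc_cls(**d)


def model_spec_from_dict(d: dict) -> ModelSpec:
    d = dict(d or {})
    flat: dict = {}
    lskac = d.pop("lskac", {})
    flat["lskac_k"] = lskac.get("k", 23)
    flat["lskac_d"] = lskac.get("d", 3)
    spp = d.pop("sppflkc_cfg", {})
    flat["pool_kernel"] = spp.get("pool_kernel", 5)
    cf = d.pop("cfcglu_cfg", {})
    flat["gate_t"] = cf.get("t", 0.5)
    flat["cglu_alpha"] = cf.get("alpha", 0.5)
    flat["cglu_beta"] = cf.get("beta", 0.25)
    flat["cglu_groups"] = cf.get("groups", 2)
    cs = d.pop("cscbam_cfg", {})
    flat["cscbam_reduction"] = cs.get("reduction", 16)
    flat["cscbam_tokens"] = cs.get("spatial_tokens", 20)
    flat["cscbam_hidden_ratio"] = cs.get("interact_hidden_ratio", 0.125)
    flat.update(d)
    return _take(ModelSpec, flat)


def load_config(path) -> tuple[ModelSpec, TrainConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    spec = model_spec_from_dict(raw.get("model", {}))
    tcfg = _take(TrainConfig, raw.get("train", {}) or {})
    return spec, tcfg
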