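"""Declarative run configuration, global seeding and the ablation harness.

A :class:`RunConfig` gathers every tunable of the pipeline with its default
value.  Configs load from flat TOML-style key/value files; command-line
overrides win over the file, the file over defaults; unknown keys are
rejected by name.  One seed drives every random consumer.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("plisage")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    device: str = "cpu"
    # surface generation
    level_radius: float = 1.0
    n_init: int = 8
    voxel: float = 0.25
    # patching
    num_group: int = 512
    group_size: int = 32
    mask_ratio: float = 0.6
    # surface encoder
    token_dim: int = 128
    enc_depth: int = 10
    enc_heads: int = 2
    dec_depth: int = 4
    dec_heads: int = 6
    # structure encoder
    gvp_layers: int = 3
    node_scalar: int = 128
    node_vector: int = 32
    edge_scalar: int = 32
    edge_vector: int = 1
    gvp_dropout: float = 0.3
    knn_k: int = 30
    # ligand encoder
    mpnn_layers: int = 3
    mpnn_hidden: int = 64
    mpnn_dropout: float = 0.3
    # fusion
    d_model: int = 128
    nhead: int = 8
    fusion_enc_layers: int = 1
    fusion_dec_layers: int = 1
    fusion_dropout: float = 0.3
    fusion_mode: str = "enc_dec"
    # pretraining
    lr_pretrain: float = 1e-4
    wd_pretrain: float = 1e-4
    scheduler_patience: int = 5
    scheduler_factor: float = 0.5
    epochs_pretrain: int = 100
    batch_pretrain: int = 64
    lambda_cont: float = 1.0
    lambda_recon: float = 1.0
    tau: float = 0.05
    # fine-tuning
    lr_finetune: float = 1e-4
    wd_finetune: float = 5e-4
    epochs_finetune: int = 100
    batch_finetune: int = 16
    # ablation switches
    use_surface: bool = True
    use_structure: bool = True
    use_pretrain: bool = True

    def __post_init__(self):
        if not (self.use_surface or self.use_structure):
            raise ConfigError("at least one of use_surface/use_structure must be on")
        if self.fusion_mode not in ("concat", "cross_attn", "enc_dec"):
            raise ConfigError(f"invalid fusion_mode {self.fusion_mode!r}")


_FIELDS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _coerce(key: str, value):
    target = _FIELDS[key]
    if isinstance(value, str):
        if target == "bool":
            return value.lower() in ("1", "true", "yes", "on")
        if target == "int":
            return int(value)
        if target == "float":
            return float(value)
    return value


def load_config(path: str | None = None, overrides: dict | list[str] | None = None
                ) -> RunConfig:
    """Resolve a RunConfig from defaults < TOML file < overrides.

    Overrides may be a dict or a list of "key=value" strings.  Unknown keys
    raise a :class:`ConfigError` naming the offenders.
    """
    values: dict = {}
    if path:
        with open(path, "rb") as f:
            values.update(tomllib.load(f))
    if overrides:
        if isinstance(overrides, dict):
            values.update(overrides)
        else:
            for item in overrides:
                key, _, val = item.partition("=")
                values[key.strip()] = val.strip()
    unknown = sorted(set(values) - set(_FIELDS))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    values = {k: _coerce(k, v) for k, v in values.items()}
    cfg = RunConfig(**values)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    """Write the resolved config as a flat TOML file beside run outputs."""
    with open(path, "w") as f:
        for k, v in dataclasses.asdict(cfg).items():
            if isinstance(v, bool):
                f.write(f"{k} = {str(v).lower()}\n")
            elif isinstance(v, str):
                f.write(f'{k} = "{v}"\n')
            else:
                f.write(f"{k} = {v}\n")


def model_from_config(cfg: RunConfig, rng: np.random.Generator):
    """Instantiate a PredictionModel from a RunConfig."""
    from .encoders import GvpConfig, SurfaceEncoderConfig
    from .fusion_predict import FusionConfig, PredictionModel

    return PredictionModel(
        rng,
        gvp_cfg=GvpConfig(cfg.gvp_layers, cfg.node_scalar, cfg.node_vector,
                          cfg.edge_scalar, cfg.edge_vector, cfg.gvp_dropout),
        surf_cfg=SurfaceEncoderConfig(cfg.token_dim, cfg.enc_depth, cfg.enc_heads,
                                      cfg.dec_depth, cfg.dec_heads, cfg.mask_ratio,
                                      cfg.group_size),
        fusion_cfg=FusionConfig(cfg.d_model, cfg.nhead, cfg.fusion_enc_layers,
                                cfg.fusion_dec_layers, cfg.fusion_dropout,
                                cfg.fusion_mode),
        ligand_hidden=cfg.mpnn_hidden,
        use_surface=cfg.use_surface,
        use_structure=cfg.use_structure,
    )


#: the six component-ablation variants (modalities x pretraining)
ABLATION_VARIANTS = (
    ("Stru", dict(use_surface=False, use_structure=True, use_pretrain=False)),
    ("Stru+Pretrain", dict(use_surface=False, use_structure=True, use_pretrain=True)),
    ("Surf", dict(use_surface=True, use_structure=False, use_pretrain=False)),
    ("Surf+Pretrain", dict(use_surface=True, use_structure=False, use_pretrain=True)),
    ("Surf+Stru", dict(use_surface=True, use_structure=True, use_pretrain=False)),
    ("Surf+Stru+Pretrain", dict(use_surface=True, use_structure=True, use_pretrain=True)),
)

FUSION_GRID = ("concat", "cross_attn", "enc_dec")


def run_ablation(
    train_records,
    val_records,
    task: str,
    seed: int = 0,
    checkpoint: str | None = None,
    grid: str = "components",
    model_kwargs: dict | None = None,
    train_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Train/evaluate every ablation variant on the same data and seed.

    ``grid='components'`` runs the six modality/pretraining variants;
    ``grid='fusion'`` runs the three fusion modes of the full model.
    Variants that request pretrained initialization need `checkpoint`.
    """
    from .fusion_predict import evaluate, predict_dataset, train_downstream, build_token_cache

    model_kwargs = dict(model_kwargs or {})
    train_kwargs = dict(train_kwargs or {})
    if grid == "components":
        variants = [(name, dict(flags)) for name, flags in ABLATION_VARIANTS]
    elif grid == "fusion":
        variants = [(mode, {"fusion_mode": mode}) for mode in FUSION_GRID]
    else:
        raise ConfigError(f"unknown ablation grid {grid!r}")

    rows = []
    for name, flags in variants:
        kw = dict(model_kwargs)
        use_pretrain = flags.pop("use_pretrain", checkpoint is not None)
        if use_pretrain and checkpoint is None:
            raise ConfigError(f"variant {name!r} needs a pretraining checkpoint")
        if "fusion_mode" in flags:
            fusion_cfg = dataclasses.replace(kw["fusion_cfg"], mode=flags.pop("fusion_mode"))
            kw["fusion_cfg"] = fusion_cfg
        if not (flags.get("use_surface", True) or flags.get("use_structure", True)):
            raise ConfigError("variant with both modalities off is rejected")
        kw.update(flags)
        res = train_downstream(
            train_records, task, seed=seed, val_records=None,
            checkpoint=checkpoint if use_pretrain else None,
            model_kwargs=kw, **train_kwargs)
        cache = build_token_cache(res.model, val_records)
        preds = predict_dataset(res.model, val_records, cache)
        metrics = evaluate(preds, [r.label for r in val_records], task)
        rows.append({"variant": name, **{k: round(v, 6) for k, v in metrics.items()}})
    return pd.DataFrame(rows)
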