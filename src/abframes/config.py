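"""Model / training / refinement configuration.

``ModelConfig`` defaults are the published architecture hyperparameters
(node/edge dims, graph-transformer and IPA head geometry).  ``toy()``
returns the reduced 2-layer-scale preset used for desk-scale training runs
and tests.  All configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["ModelConfig", "TrainingConfig", "RefinementConfig",
           "load_config", "save_config"]


@dataclass
class ModelConfig:
    # language-model interface
    lm_hidden_dim: int = 512
    lm_attn_layers: int = 8
    lm_attn_heads: int = 8
    # feature dims
    d_node: int = 64
    d_edge: int = 64
    # graph transformer
    n_gt_layers: int = 4
    d_gt_head: int = 32
    n_gt_head: int = 8
    gt_ff_dim: int = 256
    # template IPA
    n_temp_layers: int = 2
    d_temp_head_scalar: int = 16
    d_temp_head_point: int = 4
    n_temp_head: int = 8
    temp_ff_dim: int = 64
    temp_ff_layers: int = 3
    # structure IPA
    n_str_layers: int = 3
    d_str_head_scalar: int = 16
    d_str_head_point: int = 4
    n_str_head: int = 8
    str_ff_dim: int = 64
    str_ff_layers: int = 3
    # error-prediction IPA
    n_err_layers: int = 2
    d_err_head_scalar: int = 16
    d_err_head_point: int = 4
    n_err_head: int = 4
    err_ff_dim: int = 64
    err_ff_layers: int = 3
    # value points per head: the cited attention algorithm pairs 4 query
    # points with 8 value points; the head-point dims above set the query side
    n_value_points: int = 8
    # embedder
    embedder_kind: str = "synthetic"   # synthetic | external
    embedder_seed: int = 0

    @property
    def lm_attn_stack_dim(self) -> int:
        return self.lm_attn_layers * self.lm_attn_heads

    @staticmethod
    def toy() -> "ModelConfig":
        """Reduced 2-layer-scale preset for desk-scale training and tests."""
        return ModelConfig(
            d_node=32, d_edge=8,
            n_gt_layers=2, d_gt_head=16, n_gt_head=2, gt_ff_dim=64,
            n_temp_layers=1, d_temp_head_scalar=8, d_temp_head_point=2,
            n_temp_head=2, temp_ff_dim=32,
            n_str_layers=2, d_str_head_scalar=8, d_str_head_point=2,
            n_str_head=2, str_ff_dim=32,
            n_err_layers=1, d_err_head_scalar=8, d_err_head_point=2,
            n_err_head=2, err_ff_dim=32,
            n_value_points=2,
        )


@dataclass
class TrainingConfig:
    optimizer: str = "radam"
    learning_rate: float = 5e-4
    steps: int = 2_000_000        # published full-scale setting
    batch_size: int = 1
    ensemble_size: int = 4
    seed: int = 0
    template_prob: float = 0.5    # fraction of examples receiving a template
    grad_clip: float = 1.0        # global gradient-norm cap (None disables)
    segment_count_min: int = 1
    segment_count_max: int = 6
    segment_length: int = 20
    log_every: int = 100

    def __post_init__(self):
        if not 0.0 <= self.template_prob <= 1.0:
            raise ValueError("template_prob must be in [0, 1]")
        if self.segment_length <= 0 or self.segment_count_min <= 0:
            raise ValueError("segment parameters must be positive")

    @staticmethod
    def toy(steps: int = 2000, seed: int = 0) -> "TrainingConfig":
        return TrainingConfig(steps=steps, seed=seed)


@dataclass
class RefinementConfig:
    learning_rate: float = 0.02
    steps: int = 80
    # relative weights of the idealization terms and the coordinate restraint;
    # parity (all 1) mirrors the unweighted sum of the objective
    w_bond: float = 1.0
    w_angle: float = 1.0
    w_omega: float = 1.0
    w_coords: float = 1.0

    def __post_init__(self):
        if self.steps <= 0 or self.learning_rate <= 0:
            raise ValueError("steps and learning_rate must be positive")


_SECTIONS = {"model": ModelConfig, "training": TrainingConfig,
             "refinement": RefinementConfig}


def save_config(path, model: ModelConfig | None = None,
                training: TrainingConfig | None = None,
                refinement: RefinementConfig | None = None) -> None:
    doc = {}
    for key, obj in (("model", model), ("training", training),
                     ("refinement", refinement)):
        if obj is not None:
            doc[key] = asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for key, cls in _SECTIONS.items():
        if key in doc:
            valid = {f.name for f in fields(cls)}
            unknown = set(doc[key]) - valid
            if unknown:
                raise KeyError(f"unknown {key} config keys: {sorted(unknown)}")
            out[key] = cls(**doc[key])
    return out
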