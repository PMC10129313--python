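"""Full structure-prediction network: embedding projection, encoder,
template incorporation, structure module, and error head.

With default hyperparameters the assembled network has ~1.6M trainable
parameters.  Checkpoints are ``.npz`` archives holding every parameter
plus the JSON-encoded configuration and a content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .config import ModelConfig
from .embeddings import (EmbeddingBundle, EmbeddingProjector,
                         LanguageModelOutput, SyntheticEmbedder, pair_chains)
from .geometry import IdealGeometry
from .graph_net import Encoder
from .ipa import ErrorHead, StructureModule, TemplateEncoder
from .nn import Module
from .structure import BackboneStructure

__all__ = ["StructurePredictor", "ForwardResult"]


@dataclass
class ForwardResult:
    """Everything one forward pass produces.

    `coords` / `pred_error_all` stay in the autodiff graph for training;
    `structure` is the detached result with the Cα error attached.
    """

    coords: Tensor               # (L, 4, 3), in-graph
    rotations: Tensor
    translations: Tensor
    pred_error_all: Tensor       # (L, 4), in-graph (error-head params only)
    structure: BackboneStructure


class StructurePredictor(Module):
    def __init__(self, config: ModelConfig | None = None,
                 seed: int = 0, geom: IdealGeometry | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.projector = EmbeddingProjector(self.config, rng)
        self.encoder = Encoder(self.config, rng)
        self.template_encoder = TemplateEncoder(self.config, rng)
        self.structure_module = StructureModule(self.config, rng, geom)
        self.error_head = ErrorHead(self.config, rng)
        self.seed = seed

    # -- embedding front end --------------------------------------------------
    def embed(self, lm_outs: list[LanguageModelOutput]) -> EmbeddingBundle:
        bundles = [self.projector(lm) for lm in lm_outs]
        combined = bundles[0]
        for extra in bundles[1:]:
            combined = pair_chains(combined, extra)
        return combined

    # -- forward --------------------------------------------------------------
    def forward(self, lm_outs: list[LanguageModelOutput],
                template: BackboneStructure | None = None,
                template_mask: np.ndarray | None = None) -> ForwardResult:
        bundle = self.embed(lm_outs)
        nodes, edges = self.encoder(bundle.nodes, bundle.edges)
        nodes = self.template_encoder(nodes, edges, template, template_mask)
        coords, R, t = self.structure_module(nodes, edges)
        structure = self._to_structure(lm_outs, coords.numpy())
        pred_err = self.error_head(lm_outs, structure)
        structure.predicted_error = pred_err.numpy()[:, ErrorHead.CA_CHANNEL].copy()
        return ForwardResult(coords, R, t, pred_err, structure)

    def predict(self, lm_outs: list[LanguageModelOutput],
                template: BackboneStructure | None = None,
                template_mask: np.ndarray | None = None) -> BackboneStructure:
        return self.forward(lm_outs, template, template_mask).structure

    @staticmethod
    def _to_structure(lm_outs: list[LanguageModelOutput],
                      coords: np.ndarray) -> BackboneStructure:
        seq = "".join(lm.sequence for lm in lm_outs)
        labels = ["H", "L"]
        chain_ids = np.concatenate([
            np.full(len(lm.sequence), labels[i] if len(lm_outs) > 1 else "H")
            for i, lm in enumerate(lm_outs)])
        return BackboneStructure(seq, chain_ids, coords.copy())

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> str:
        state = self.state_dict()
        cfg = json.dumps(asdict(self.config), sort_keys=True)
        h = hashlib.sha256()
        for key in sorted(state):
            h.update(key.encode())
            h.update(state[key].tobytes())
        h.update(cfg.encode())
        checksum = h.hexdigest()[:16]
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 __checksum__=np.frombuffer(checksum.encode(), dtype=np.uint8),
                 **state)
        return checksum

    @staticmethod
    def load(path) -> "StructurePredictor":
        with np.load(path) as data:
            cfg_json = bytes(data["__config__"]).decode()
            stored_sum = bytes(data["__checksum__"]).decode()
            state = {k: data[k] for k in data.files
                     if not k.startswith("__")}
        config = ModelConfig(**json.loads(cfg_json))
        model = StructurePredictor(config)
        try:
            model.load_state_dict(state)
        except (KeyError, ValueError) as err:
            raise ValueError(
                f"checkpoint/config mismatch (checksum {stored_sum}): {err}"
            ) from err
        return model

    def checksum(self) -> str:
        state = self.state_dict()
        cfg = json.dumps(asdict(self.config), sort_keys=True)
        h = hashlib.sha256()
        for key in sorted(state):
            h.update(key.encode())
            h.update(state[key].tobytes())
        h.update(cfg.encode())
        return h.hexdigest()[:16]


def default_embedder(config: ModelConfig | None = None,
                     seed: int | None = None) -> SyntheticEmbedder:
    return SyntheticEmbedder(config, seed)
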