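"""Training losses and procedure.

The total objective is the sum of three terms: a coordinate loss (mean
squared frame-atom deviation after Kabsch alignment), a bond-geometry
loss (L1 deviation of near-neighbour backbone inter-atomic distances from
their ideal values, scaled ×10 and clamped at 1), and an error-prediction
loss (L1 between the predicted and realized per-residue Cα deviations,
the latter measured after aligning on the beta-annotated strand residues).

Training corrupts the native structure into a partial template for half
of the examples, samples sources inversely to their dataset sizes, and
runs single-structure steps with RAdam under a cosine-annealed schedule.
Ensembles are resolved by the 90th-percentile per-residue error rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .config import TrainingConfig
from .embeddings import LanguageModelOutput
from .geometry import IdealGeometry, kabsch_superpose
from .nn import RAdam, Adam, cosine_lr
from .structure import BackboneStructure

__all__ = ["LossBreakdown", "DatasetSource", "TrainingExample",
           "coordinate_loss", "bond_geometry_loss", "error_label",
           "total_loss", "corrupt_template", "sample_source", "train_loop",
           "ensemble_select"]


@dataclass
class LossBreakdown:
    coords: float        # Å², mean squared frame-atom deviation
    bonds: float         # dimensionless, after x10 scale and clamp at 1
    error: float         # Å, L1
    total: float

    def finite(self) -> bool:
        return all(math.isfinite(v) for v in
                   (self.coords, self.bonds, self.error, self.total))


@dataclass
class DatasetSource:
    """A training-set partition; sampling weight is inverse to size."""

    name: str
    size: int

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("source size must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.size


@dataclass
class TrainingExample:
    lm_outs: list[LanguageModelOutput]
    native: BackboneStructure


def _coords_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, BackboneStructure):
        return Tensor(x.coords)
    return Tensor(np.asarray(x, dtype=np.float64))


# -- Loss terms ---------------------------------------------------------------

def coordinate_loss(pred, label: BackboneStructure) -> Tensor:
    """Mean squared frame-atom deviation (Å²) after Kabsch alignment.

    The optimal rigid transform is computed from the current numeric
    coordinates and held constant in the graph; by the envelope theorem
    the resulting gradient is exact.
    """
    pred_t = _coords_tensor(pred)
    L = pred_t.shape[0]
    if len(label) != L:
        raise ValueError("residue-count mismatch between prediction and label")
    pred_flat = pred_t.reshape(L * 4, 3)
    label_flat = label.coords.reshape(L * 4, 3)
    R, t, _ = kabsch_superpose(label_flat, pred_flat.numpy())
    label_aligned = label_flat @ R.T + t
    diff = pred_flat - Tensor(label_aligned)
    return (diff * diff).sum(axis=-1).mean()


def _bond_terms(chain_ids: np.ndarray, geom: IdealGeometry
                ) -> tuple[list[tuple[int, int, int, int]], np.ndarray]:
    """Backbone near-neighbour distance terms and their ideal values.

    Terms pair backbone atoms one and two positions apart along the
    N→Cα→C mainchain (within a chain), plus each residue's Cβ to its
    bonded Cα and the two flanking atoms.  Every reference distance is
    fixed by ideal covalent geometry alone (no torsion dependence), so an
    ideally built structure scores exactly zero.
    """
    def law_of_cosines(r1, r2, ang_deg):
        return math.sqrt(r1 * r1 + r2 * r2
                         - 2 * r1 * r2 * math.cos(math.radians(ang_deg)))

    d_n_c = law_of_cosines(geom.bond_n_ca, geom.bond_ca_c, geom.angle_n_ca_c)
    d_ca_n = law_of_cosines(geom.bond_ca_c, geom.bond_c_n, geom.angle_ca_c_n)
    d_c_ca = law_of_cosines(geom.bond_c_n, geom.bond_n_ca, geom.angle_c_n_ca)
    d_n_cb = law_of_cosines(geom.bond_n_ca, geom.bond_ca_cb, geom.angle_n_ca_cb)
    d_c_cb = law_of_cosines(geom.bond_ca_c, geom.bond_ca_cb, geom.angle_c_ca_cb)
    # atom codes: 0 N, 1 CA, 2 C, 3 CB; term = (res_i, atom_i, res_j, atom_j)
    terms: list[tuple[int, int, int, int]] = []
    ideals: list[float] = []
    L = len(chain_ids)
    for i in range(L):
        terms += [(i, 0, i, 1), (i, 1, i, 2), (i, 1, i, 3)]
        ideals += [geom.bond_n_ca, geom.bond_ca_c, geom.bond_ca_cb]
        terms += [(i, 0, i, 2), (i, 0, i, 3), (i, 2, i, 3)]
        ideals += [d_n_c, d_n_cb, d_c_cb]
        if i + 1 < L and chain_ids[i] == chain_ids[i + 1]:
            terms += [(i, 2, i + 1, 0), (i, 1, i + 1, 0), (i, 2, i + 1, 1)]
            ideals += [geom.bond_c_n, d_ca_n, d_c_ca]
    return terms, np.array(ideals)


def bond_geometry_loss(pred, geom: IdealGeometry | None = None,
                       chain_ids: np.ndarray | None = None,
                       clamped: bool = True) -> Tensor:
    """×10-scaled, clamped-at-1 mean L1 deviation of backbone distances."""
    geom = geom or IdealGeometry()
    if isinstance(pred, BackboneStructure):
        chain_ids = pred.chain_ids
    elif chain_ids is None:
        chain_ids = np.zeros(_coords_tensor(pred).shape[0])
    pred_t = _coords_tensor(pred)
    terms, ideals = _bond_terms(np.asarray(chain_ids), geom)
    ri = np.array([t[0] for t in terms])
    ai = np.array([t[1] for t in terms])
    rj = np.array([t[2] for t in terms])
    aj = np.array([t[3] for t in terms])
    diff = pred_t[ri, ai] - pred_t[rj, aj]
    dist = ((diff * diff).sum(axis=-1) + 1e-12).sqrt()
    raw = (dist - Tensor(ideals)).abs().mean()
    scaled = raw * 10.0
    return scaled.clamp(hi=1.0) if clamped else scaled


def error_label(pred: BackboneStructure | np.ndarray,
                label: BackboneStructure,
                align_set: np.ndarray | None = None) -> np.ndarray:
    """Per-residue Cα deviation (Å) after Kabsch alignment on `align_set`.

    `align_set` holds the residue indices of the alignment reference (the
    beta-annotated strand residues by default).
    """
    pred_coords = pred.coords if isinstance(pred, BackboneStructure) else np.asarray(pred)
    if align_set is None:
        if label.beta is None:
            raise ValueError("no align_set and label carries no beta flags")
        align_set = np.flatnonzero(label.beta)
    align_set = np.asarray(align_set)
    if align_set.size == 0:
        raise ValueError("empty alignment set")
    L = len(label)
    atom_idx = (align_set[:, None] * 4 + np.arange(4)[None, :]).ravel()
    pred_flat = pred_coords.reshape(L * 4, 3)
    label_flat = label.coords.reshape(L * 4, 3)
    R, t, _ = kabsch_superpose(pred_flat[atom_idx], label_flat[atom_idx])
    pred_aligned = pred_flat @ R.T + t
    ca_pred = pred_aligned.reshape(L, 4, 3)[:, 1]
    ca_label = label.coords[:, 1]
    return np.linalg.norm(ca_pred - ca_label, axis=-1)


def total_loss(pred, pred_err: Tensor, label: BackboneStructure,
               align_set: np.ndarray | None = None,
               geom: IdealGeometry | None = None
               ) -> tuple[Tensor, LossBreakdown]:
    """Sum of coordinate, bond-geometry, and error-prediction losses."""
    l_coords = coordinate_loss(pred, label)
    l_bonds = bond_geometry_loss(pred, geom, label.chain_ids)
    labels = error_label(
        pred.numpy() if isinstance(pred, Tensor) else pred, label, align_set)
    err = pred_err if pred_err.ndim == 1 else pred_err[:, 1]
    l_error = (err - Tensor(labels)).abs().mean()
    total = l_coords + l_bonds + l_error
    breakdown = LossBreakdown(l_coords.item(), l_bonds.item(),
                              l_error.item(), total.item())
    return total, breakdown


# -- Template corruption and sampling ----------------------------------------

def corrupt_template(native: BackboneStructure, rng: np.random.Generator,
                     config: TrainingConfig | None = None
                     ) -> np.ndarray | None:
    """Produce a partial-template mask from the native structure, or None.

    With probability ``1 - template_prob`` no template is given.  Otherwise
    1–6 segments of 20 consecutive residues are hidden (their coordinates
    treated as meaningless) and the rest serve as template; the returned
    boolean mask is True where the template is valid.
    """
    config = config or TrainingConfig()
    L = len(native)
    seg = config.segment_length
    if L < seg:
        raise ValueError(f"structure shorter than segment length {seg}")
    if rng.random() >= config.template_prob:
        return None
    k = int(rng.integers(config.segment_count_min, config.segment_count_max + 1))
    mask = np.ones(L, dtype=bool)
    for _ in range(k):
        start = int(rng.integers(0, L - seg + 1))
        mask[start:start + seg] = False
    if not mask.any():
        return None
    return mask


def sample_source(sources: list[DatasetSource], rng: np.random.Generator) -> int:
    """Draw a source index under inverse-size example weighting.

    Every example carries weight 1/|its dataset|, so a dataset's total
    draw probability is |dataset| x (1/|dataset|) — equal across sources:
    with the three structure sources this lands each at roughly one third
    of draws regardless of their very different sizes.
    """
    if not sources:
        raise ValueError("empty source list")
    p = np.array([s.size * s.weight for s in sources])
    return int(rng.choice(len(sources), p=p / p.sum()))


# -- Training loop ------------------------------------------------------------

def train_loop(model, datasets: list[list[TrainingExample]],
               config: TrainingConfig | None = None,
               sources: list[DatasetSource] | None = None,
               geom: IdealGeometry | None = None,
               callback=None) -> list[LossBreakdown]:
    """Single-structure training steps; returns the loss trace.

    `datasets` is one example list per source.  Deterministic for a fixed
    seed; aborts with the step index if the loss turns non-finite.
    """
    config = config or TrainingConfig()
    if sources is None:
        sources = [DatasetSource(f"source{i}", len(d))
                   for i, d in enumerate(datasets)]
    if len(sources) != len(datasets):
        raise ValueError("sources/datasets length mismatch")
    rng = np.random.default_rng(config.seed)
    opt_cls = {"radam": RAdam, "adam": Adam}[config.optimizer]
    opt = opt_cls(model.parameters(), lr=config.learning_rate)
    trace: list[LossBreakdown] = []
    for step in range(config.steps):
        opt.lr = cosine_lr(config.learning_rate, step, config.steps)
        src = sample_source(sources, rng)
        example = datasets[src][int(rng.integers(len(datasets[src])))]
        mask = corrupt_template(example.native, rng, config)
        template = example.native if mask is not None else None
        result = model.forward(example.lm_outs, template, mask)
        err_ca = result.pred_error_all[:, 1]
        loss, breakdown = total_loss(result.coords, err_ca, example.native,
                                     geom=geom)
        if not breakdown.finite():
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        if config.grad_clip is not None:
            clip_gradients(model.parameters(), config.grad_clip)
        opt.step()
        trace.append(breakdown)
        if callback is not None:
            callback(step, breakdown)
    return trace


def clip_gradients(params: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    norm = math.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


# -- Ensemble selection -------------------------------------------------------

def ensemble_select(candidates: list) -> int:
    """Pick the candidate minimizing the 90th-percentile residue error.

    `candidates` holds (structure, per-residue error) pairs or bare error
    vectors.  Linear interpolation between order statistics; ties resolve
    to the lowest index.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    scores = []
    for cand in candidates:
        err = cand[1] if isinstance(cand, tuple) else (
            cand.predicted_error if isinstance(cand, BackboneStructure) else cand)
        if err is None:
            raise ValueError("candidate lacks a per-residue error vector")
        scores.append(float(np.percentile(np.asarray(err, dtype=float), 90.0)))
    return int(np.argmin(scores))
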