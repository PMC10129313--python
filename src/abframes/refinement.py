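"""Stage-1 backbone refinement: gradient-based idealization.

The predicted backbone is optimized under a four-term objective: squared
deviations of bond lengths from their ideal targets, squared deviations
of the backbone planar angles (radians), squared angle-wrapped deviation
of the peptide ω dihedral from trans, and the Kabsch-then-MSE coordinate
restraint used in training, holding the refined structure near the
original prediction.  The idealization terms are summed over violations
(an unweighted sum, so a single distorted bond is not diluted by the
chain length); the restraint is the training-form mean.

Optimization runs Adam on the raw coordinates (default 80 steps at
learning rate 0.02) with a monotone acceptance safeguard: a step that
would increase the objective is rejected, the adaptive state reset, and
the step size backed off — so the reported loss trace is non-increasing
by construction and an already-ideal structure does not move.  Full-atom
energy refinement and side-chain packing are an external post-process
outside this package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, atan2, stack
from .config import RefinementConfig
from .geometry import IdealGeometry, place_oxygens
from .nn import Adam
from .structure import BackboneStructure
from .training import coordinate_loss

__all__ = ["idealization_loss", "refine_backbone", "RefinementTrace"]


@dataclass
class RefinementTrace:
    total: list
    bond: list
    angle: list
    omega: list
    coords: list
    omega_values: list  # per-step ω arrays (deg), for diagnostics


def _chain_pairs(chain_ids: np.ndarray) -> np.ndarray:
    idx = np.arange(len(chain_ids) - 1)
    return idx[np.asarray(chain_ids)[:-1] == np.asarray(chain_ids)[1:]]


def _dist(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return ((d * d).sum(axis=-1) + 1e-12).sqrt()


def _angle(a: Tensor, b: Tensor, c: Tensor) -> Tensor:
    u = a - b
    v = c - b
    num = (u * v).sum(axis=-1)
    den = (((u * u).sum(axis=-1)) * ((v * v).sum(axis=-1)) + 1e-12).sqrt()
    return (num / den).clamp(-1.0 + 1e-9, 1.0 - 1e-9).acos()


def _dihedral_t(p0: Tensor, p1: Tensor, p2: Tensor, p3: Tensor) -> Tensor:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / (((b1 * b1).sum(axis=-1, keepdims=True) + 1e-12).sqrt())
    v = b0 - (b0 * b1n).sum(axis=-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(axis=-1, keepdims=True) * b1n
    x = (v * w).sum(axis=-1)
    cross = stack([b1n[:, 1] * v[:, 2] - b1n[:, 2] * v[:, 1],
                   b1n[:, 2] * v[:, 0] - b1n[:, 0] * v[:, 2],
                   b1n[:, 0] * v[:, 1] - b1n[:, 1] * v[:, 0]], axis=-1)
    y = (cross * w).sum(axis=-1)
    return atan2(y, x)


def idealization_loss(x_ref, x_pred: BackboneStructure,
                      geom: IdealGeometry | None = None,
                      config: RefinementConfig | None = None
                      ) -> tuple[Tensor, dict]:
    """Idealization terms plus coordinate restraint.

    `x_ref` is the structure being refined (Tensor coords (L,4,3) or a
    BackboneStructure); `x_pred` is the fixed original prediction.  Bond
    terms are squared deviations in Å, angle and ω terms squared
    deviations in radians (wrapped), each summed over all occurrences;
    the restraint is the training coordinate loss (mean squared Å² after
    Kabsch).
    """
    geom = geom or IdealGeometry()
    config = config or RefinementConfig()
    if isinstance(x_ref, BackboneStructure):
        if len(x_ref) != len(x_pred):
            raise ValueError("topology mismatch between x_ref and x_pred")
        coords = Tensor(x_ref.coords)
    else:
        coords = x_ref
        if coords.shape[0] != len(x_pred):
            raise ValueError("topology mismatch between x_ref and x_pred")
    chain_ids = x_pred.chain_ids
    n, ca, c, cb = coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3]
    pairs = _chain_pairs(chain_ids)
    nxt = pairs + 1

    bond_devs = [
        _dist(n, ca) - geom.bond_n_ca,
        _dist(ca, c) - geom.bond_ca_c,
        _dist(ca, cb) - geom.bond_ca_cb,
        _dist(c[pairs], n[nxt]) - geom.bond_c_n,
    ]
    l_bond = sum((d * d).sum() for d in bond_devs)

    angle_devs = [
        _angle(n, ca, c) - math.radians(geom.angle_n_ca_c),
        _angle(n, ca, cb) - math.radians(geom.angle_n_ca_cb),
        _angle(c, ca, cb) - math.radians(geom.angle_c_ca_cb),
        _angle(ca[pairs], c[pairs], n[nxt]) - math.radians(geom.angle_ca_c_n),
        _angle(c[pairs], n[nxt], ca[nxt]) - math.radians(geom.angle_c_n_ca),
    ]
    l_angle = sum((d * d).sum() for d in angle_devs)

    if len(pairs):
        omega = _dihedral_t(ca[pairs], c[pairs], n[nxt], ca[nxt])
        dev = omega - math.radians(geom.omega)
        wrapped = atan2(dev.sin(), dev.cos())   # into (-pi, pi]
        l_omega = (wrapped * wrapped).sum()
        omega_deg = np.degrees(omega.numpy())
    else:
        l_omega = Tensor(0.0)
        omega_deg = np.zeros(0)

    l_coords = coordinate_loss(coords, x_pred)
    total = (config.w_bond * l_bond + config.w_angle * l_angle
             + config.w_omega * l_omega + config.w_coords * l_coords)
    terms = {"bond": l_bond.item(), "angle": l_angle.item(),
             "omega": l_omega.item(), "coords": l_coords.item(),
             "total": total.item(), "_omega_deg": omega_deg}
    return total, terms


def _canonical_transform(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic canonical pose: centroid at origin, principal axes as
    the coordinate axes, signs fixed by coordinate skewness, right-handed.

    Because Adam's per-coordinate normalization is not rotation
    equivariant, optimizing in this pose makes refinement commute exactly
    with rigid motions of the input.  Returns (rotation, translation)
    such that canonical = (x - t) @ R.
    """
    flat = coords.reshape(-1, 3)
    centroid = flat.mean(axis=0)
    centered = flat - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt.T  # columns
    proj = centered @ axes
    skew = (proj ** 3).sum(axis=0)
    for k in range(3):
        if skew[k] < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes, centroid


def refine_backbone(pred: BackboneStructure,
                    config: RefinementConfig | None = None,
                    geom: IdealGeometry | None = None
                    ) -> tuple[BackboneStructure, RefinementTrace]:
    """Idealize a predicted backbone; deterministic given inputs.

    Returns the refined structure (with oxygens placed geometrically) and
    the per-accepted-step loss trace.  If the objective turns non-finite
    the last finite iterate is returned with a warning.
    """
    config = config or RefinementConfig()
    geom = geom or IdealGeometry()
    axes, centroid = _canonical_transform(pred.coords)
    pred_canon = pred.copy()
    pred_canon.coords = (pred.coords - centroid) @ axes
    pred = pred_canon
    coords = Tensor(pred.coords.copy(), requires_grad=True)
    opt = Adam({"coords": coords}, lr=config.learning_rate)
    trace = RefinementTrace([], [], [], [], [], [])
    _, last_terms = idealization_loss(coords, pred, geom, config)
    cur_lr = config.learning_rate

    def record(terms):
        trace.total.append(terms["total"])
        trace.bond.append(terms["bond"])
        trace.angle.append(terms["angle"])
        trace.omega.append(terms["omega"])
        trace.coords.append(terms["coords"])
        trace.omega_values.append(terms["_omega_deg"])

    record(last_terms)
    for _ in range(config.steps):
        loss, terms = idealization_loss(coords, pred, geom, config)
        if not math.isfinite(terms["total"]):
            warnings.warn("non-finite refinement loss; returning last iterate")
            break
        opt.zero_grad()
        loss.backward()
        previous = coords.numpy().copy()
        opt.lr = cur_lr
        opt.step()
        _, new_terms = idealization_loss(coords, pred, geom, config)
        if (not math.isfinite(new_terms["total"])
                or new_terms["total"] > last_terms["total"] + 1e-12):
            # reject the uphill step: restore, reset moments, back off
            coords.data = previous
            opt.m = {k: np.zeros_like(v) for k, v in opt.m.items()}
            opt.v = {k: np.zeros_like(v) for k, v in opt.v.items()}
            cur_lr = max(cur_lr * 0.5, config.learning_rate / 256.0)
            record(last_terms)
        else:
            last_terms = new_terms
            cur_lr = min(cur_lr * 1.1, config.learning_rate)
            record(new_terms)
    refined = pred.copy()
    refined.coords = coords.numpy() @ axes.T + centroid  # back to input pose
    refined.oxygens = place_oxygens(refined, geom)
    refined.predicted_error = pred.predicted_error
    return refined, trace
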