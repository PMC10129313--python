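"""Rigid-body math for the residue-gas representation.

Each residue carries an independent rigid frame (rotation + translation).
The frame convention follows the AlphaFold construction the attention
layers inherit: Cα is the origin, the x-axis points along Cα→C, and N lies
in the xy-plane with positive y — fitted from backbone atoms by
Gram–Schmidt.  The four frame atoms (N, Cα, C, Cβ) sit at ideal positions
in the local frame, so a frame fully determines its residue's backbone.

Angles are handled in radians internally and degrees at the interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, einsum
from .structure import BackboneStructure

__all__ = ["IdealGeometry", "ResidueFrame", "FrameSet", "kabsch_superpose",
           "frame_atoms", "frames_from_backbone", "internal_coords",
           "place_oxygens", "local_frame_template", "random_rotation"]


@dataclass
class IdealGeometry:
    """Ideal backbone covalent geometry (Engh–Huber-style restraint targets).

    The literature standard values ship as editable defaults; every length
    is in Å and every angle in degrees.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329       # peptide bond
    bond_ca_cb: float = 1.521
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_n_ca_cb: float = 110.4
    angle_c_ca_cb: float = 110.1
    angle_ca_c_o: float = 120.8
    omega: float = 180.0          # trans peptide dihedral

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_ca_cb",
                     "bond_c_o"):
            v = getattr(self, name)
            if not 1.0 < v < 2.0:
                raise ValueError(f"{name}={v} outside (1.0, 2.0) Å")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca",
                     "angle_n_ca_cb", "angle_c_ca_cb", "angle_ca_c_o"):
            v = getattr(self, name)
            if not 90.0 < v < 140.0:
                raise ValueError(f"{name}={v} outside (90, 140) degrees")


def local_frame_template(geom: IdealGeometry | None = None) -> np.ndarray:
    """Ideal positions of (N, Cα, C, Cβ) in the local residue frame.

    Cα at the origin, C on +x, N in the xy-plane; Cβ below the plane
    (negative z) giving the L-amino-acid handedness.
    """
    geom = geom or IdealGeometry()
    ca = np.zeros(3)
    c = np.array([geom.bond_ca_c, 0.0, 0.0])
    ang_nc = math.radians(geom.angle_n_ca_c)
    n = geom.bond_n_ca * np.array([math.cos(ang_nc), math.sin(ang_nc), 0.0])
    # Cβ: unit direction u with u·(C dir) = cos(C-Cα-Cβ), u·(N dir) = cos(N-Cα-Cβ)
    cos_c = math.cos(math.radians(geom.angle_c_ca_cb))
    cos_n = math.cos(math.radians(geom.angle_n_ca_cb))
    ux = cos_c
    uy = (cos_n - ux * math.cos(ang_nc)) / math.sin(ang_nc)
    uz = -math.sqrt(max(1.0 - ux * ux - uy * uy, 0.0))
    cb = geom.bond_ca_cb * np.array([ux, uy, uz])
    return np.stack([n, ca, c, cb])


@dataclass
class ResidueFrame:
    rotation: np.ndarray    # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        _check_rotation(self.rotation)
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("non-finite translation")

    def compose(self, other: "ResidueFrame") -> "ResidueFrame":
        """self ∘ other: apply `other` in this frame's coordinates."""
        return ResidueFrame(self.rotation @ other.rotation,
                            self.rotation @ other.translation + self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "ResidueFrame":
        return ResidueFrame(np.eye(3), np.zeros(3))


@dataclass
class FrameSet:
    """One frame per residue plus a validity mask (masked frames are never
    read by attention)."""

    rotations: np.ndarray     # (L, 3, 3)
    translations: np.ndarray  # (L, 3)
    mask: np.ndarray = field(default=None)  # (L,) bool

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=np.float64)
        self.translations = np.asarray(self.translations, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.rotations), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.rotations)

    @staticmethod
    def identity(L: int) -> "FrameSet":
        return FrameSet(np.tile(np.eye(3), (L, 1, 1)), np.zeros((L, 3)))


def _check_rotation(R: np.ndarray, tol: float = 1e-5) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if np.linalg.norm(R.T @ R - np.eye(3)) >= tol:
        raise ValueError("rotation not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det < 0)")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     subset: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of `mobile` onto `target`.

    The transform is fitted on `subset` (indices into both point sets;
    default all) and the returned RMSD is over the subset after applying
    it.  Returns (rotation, translation, rmsd) with
    ``mobile @ rotation.T + translation ≈ target``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape:
        raise ValueError("point-set cardinality mismatch")
    if subset is None:
        subset = np.arange(len(mobile))
    subset = np.asarray(subset)
    if len(subset) < 3:
        raise ValueError("fewer than 3 subset points: rigid fit under-determined")
    P = mobile[subset]
    Q = target[subset]
    # collinearity guard: rank of the centred subset must be >= 2
    Pc = P - P.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) subset")
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def frame_atoms(frame: ResidueFrame, geom: IdealGeometry | None = None
                ) -> np.ndarray:
    """Place the four ideal frame atoms (N, Cα, C, Cβ) for one frame."""
    local = local_frame_template(geom)
    return frame.apply(local)


def frame_atoms_batch(rotations, translations, geom: IdealGeometry | None = None):
    """Tensor version used by the structure module: (L,3,3),(L,3) → (L,4,3).

    Differentiable when the inputs are autodiff tensors.
    """
    local = local_frame_template(geom)
    if isinstance(rotations, Tensor) or isinstance(translations, Tensor):
        placed = einsum("lij,aj->lai", rotations, Tensor(local))
        return placed + translations.reshape(-1, 1, 3)
    return np.einsum("lij,aj->lai", rotations, local) + translations[:, None, :]


def frames_from_backbone(structure: BackboneStructure) -> FrameSet:
    """Fit a frame per residue by Gram–Schmidt on N, Cα, C.

    Origin at Cα, x-axis along Cα→C, N in the xy-plane.  Inverse of
    :func:`frame_atoms` for ideal backbones.
    """
    n = structure.coords[:, 0]
    ca = structure.coords[:, 1]
    c = structure.coords[:, 2]
    return frames_from_three_points(n, ca, c)


def frames_from_three_points(n: np.ndarray, ca: np.ndarray, c: np.ndarray
                             ) -> FrameSet:
    e1 = c - ca
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    v2 = n - ca
    e2 = v2 - np.sum(v2 * e1, axis=-1, keepdims=True) * e1
    e2 = e2 / np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=-1)  # columns are the local axes
    return FrameSet(R, ca.copy())


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def internal_coords(structure: BackboneStructure) -> dict[str, list[float]]:
    """Bond lengths (Å), planar angles (deg), and ω dihedrals (deg).

    Inter-residue terms (C–N bond, C–N–Cα / Cα–C–N angles, ω) are computed
    only within chains; chain breaks contribute nothing.
    """
    out: dict[str, list[float]] = {
        "bond_n_ca": [], "bond_ca_c": [], "bond_c_n": [], "bond_ca_cb": [],
        "angle_n_ca_c": [], "angle_ca_c_n": [], "angle_c_n_ca": [],
        "omega": [],
    }
    X = structure.coords
    L = len(structure)
    for i in range(L):
        n_i, ca_i, c_i, cb_i = X[i]
        out["bond_n_ca"].append(float(np.linalg.norm(n_i - ca_i)))
        out["bond_ca_c"].append(float(np.linalg.norm(ca_i - c_i)))
        out["bond_ca_cb"].append(float(np.linalg.norm(ca_i - cb_i)))
        out["angle_n_ca_c"].append(_angle(n_i, ca_i, c_i))
        if i + 1 < L and structure.chain_ids[i] == structure.chain_ids[i + 1]:
            n_j, ca_j = X[i + 1, 0], X[i + 1, 1]
            out["bond_c_n"].append(float(np.linalg.norm(c_i - n_j)))
            out["angle_ca_c_n"].append(_angle(ca_i, c_i, n_j))
            out["angle_c_n_ca"].append(_angle(c_i, n_j, ca_j))
            out["omega"].append(_dihedral(ca_i, c_i, n_j, ca_j))
    return out


def place_oxygens(structure: BackboneStructure,
                  geom: IdealGeometry | None = None) -> np.ndarray:
    """Place carbonyl O atoms geometrically in the peptide plane.

    For residues with an intra-chain successor, O lies opposite the
    bisector of the Cα–C and N(next)–C directions (the standard planar
    construction).  Chain-terminal O is placed in the N/Cα/C plane at the
    ideal Cα–C–O angle on the side away from N.
    """
    geom = geom or IdealGeometry()
    X = structure.coords
    L = len(structure)
    O = np.zeros((L, 3))
    for i in range(L):
        ca, c = X[i, 1], X[i, 2]
        if i + 1 < L and structure.chain_ids[i] == structure.chain_ids[i + 1]:
            n_next = X[i + 1, 0]
            u = (ca - c) / np.linalg.norm(ca - c)
            v = (n_next - c) / np.linalg.norm(n_next - c)
            d = -(u + v)
            d /= np.linalg.norm(d)
            O[i] = c + geom.bond_c_o * d
        else:
            n = X[i, 0]
            e1 = (ca - c) / np.linalg.norm(ca - c)
            w = n - c
            e2 = w - np.dot(w, e1) * e1
            e2 /= np.linalg.norm(e2)
            ang = math.radians(geom.angle_ca_c_o)
            d = math.cos(ang) * e1 - math.sin(ang) * e2
            O[i] = c + geom.bond_c_o * d
    return O
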