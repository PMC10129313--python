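"""Synthetic toy antibody structures.

Backbones are grown residue-by-residue at exactly ideal covalent geometry
(trans peptide, ideal bond lengths/angles) from per-residue φ/ψ plans:
strand residues use extended sheet-like angles, loop (CDR) residues sample
a permissive turn basin.  Two chains are placed with a rigid offset to
form a pseudo-interface.  Region labels, strand (beta) flags, and a
deterministic sequence are stamped at generation, so the toys satisfy
every invariant the rest of the package demands of real inputs.

These fixtures emulate the *shape contracts* of antibody data — paired
chains, contiguous CDR loops, beta-annotated frameworks, ideal local
geometry — not the physics of real immunoglobulins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (IdealGeometry, frames_from_three_points,
                       frame_atoms_batch)
from .structure import BackboneStructure

__all__ = ["ToySpec", "make_toy_fv", "perturb_structure"]

_STRAND_PHI_PSI = (-120.0, 120.0)
# permissive turn basin for loop residues (φ, ψ ranges, degrees)
_LOOP_PHI = (-90.0, -50.0)
_LOOP_PSI = (-60.0, -10.0)

_FRAMEWORK_PATTERN = "EVQLVESGGGLVQPGGSLRLSCAAS"  # cycled over framework positions
_CDR_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ToySpec:
    """Recipe for one toy Fv (or nanobody when light_length == 0)."""

    heavy_length: int = 32
    light_length: int = 28
    heavy_cdrs: tuple = ((8, 4), (16, 3), (24, 5))   # (start, length) per CDR
    light_cdrs: tuple = ((7, 3), (14, 3), (21, 4))
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for length, cdrs in ((self.heavy_length, self.heavy_cdrs),
                             (self.light_length, self.light_cdrs)):
            if length == 0:
                continue
            if length < 20:
                raise ValueError("chain length must be >= 20")
            for start, n in cdrs:
                if start < 0 or start + n > length:
                    raise ValueError("CDR segment outside chain bounds")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from A-B-C internal coordinates (natural extension)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(chi),
                        bond * math.sin(theta) * math.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(length: int, cdrs: tuple, rng: np.random.Generator,
                 geom: IdealGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (mainchain (L,3,3) N/CA/C coords, plan chars, region labels)."""
    plan = np.full(length, "E", dtype="<U1")
    regions = np.full(length, "FR", dtype="<U4")
    for idx, (start, n) in enumerate(cdrs, start=1):
        plan[start:start + n] = "L"
        regions[start:start + n] = f"CDR{idx}"
    phi = np.empty(length)
    psi = np.empty(length)
    for i in range(length):
        if plan[i] == "E":
            phi[i], psi[i] = _STRAND_PHI_PSI
        else:
            phi[i] = rng.uniform(*_LOOP_PHI)
            psi[i] = rng.uniform(*_LOOP_PSI)
    X = np.zeros((length, 3, 3))  # N, CA, C
    ang = math.radians(geom.angle_n_ca_c)
    X[0, 0] = [0.0, 0.0, 0.0]
    X[0, 1] = [geom.bond_n_ca, 0.0, 0.0]
    X[0, 2] = X[0, 1] + geom.bond_ca_c * np.array(
        [math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    for i in range(length - 1):
        n_next = _nerf(X[i, 0], X[i, 1], X[i, 2], geom.bond_c_n,
                       geom.angle_ca_c_n, psi[i])
        ca_next = _nerf(X[i, 1], X[i, 2], n_next, geom.bond_n_ca,
                        geom.angle_c_n_ca, geom.omega)
        c_next = _nerf(X[i, 2], n_next, ca_next, geom.bond_ca_c,
                       geom.angle_n_ca_c, phi[i + 1])
        X[i + 1] = [n_next, ca_next, c_next]
    return X, plan, regions


def _with_cb(mainchain: np.ndarray, geom: IdealGeometry) -> np.ndarray:
    """(L,3,3) N/CA/C -> (L,4,3) with ideal virtual Cβ from fitted frames."""
    frames = frames_from_three_points(mainchain[:, 0], mainchain[:, 1],
                                      mainchain[:, 2])
    ideal = frame_atoms_batch(frames.rotations, frames.translations, geom)
    coords = np.empty((len(mainchain), 4, 3))
    coords[:, :3] = mainchain
    coords[:, 3] = ideal[:, 3]
    return coords


def _min_separation(coords: np.ndarray) -> float:
    """Min distance between atoms of residues more than 2 apart."""
    L = len(coords)
    flat = coords.reshape(-1, 3)
    res_of = np.repeat(np.arange(L), coords.shape[1])
    d = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
    far = np.abs(res_of[:, None] - res_of[None, :]) > 2
    return float(d[far].min()) if far.any() else np.inf


def _sequence(length: int, regions: np.ndarray,
              rng: np.random.Generator) -> str:
    letters = []
    for i in range(length):
        if regions[i] == "FR":
            letters.append(_FRAMEWORK_PATTERN[i % len(_FRAMEWORK_PATTERN)])
        else:
            letters.append(_CDR_ALPHABET[rng.integers(len(_CDR_ALPHABET))])
    return "".join(letters)


def make_toy_fv(spec: ToySpec | None = None,
                geom: IdealGeometry | None = None,
                max_attempts: int = 20) -> BackboneStructure:
    """Build a toy Fv backbone (deterministic per spec + seed)."""
    spec = spec or ToySpec()
    geom = geom or IdealGeometry()
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_attempts):
        chains = []
        for label, length, cdrs in (("H", spec.heavy_length, spec.heavy_cdrs),
                                    ("L", spec.light_length, spec.light_cdrs)):
            if length == 0:
                continue
            mainchain, plan, regions = _build_chain(length, cdrs, rng, geom)
            coords = _with_cb(mainchain, geom)
            chains.append((label, coords, plan, regions))
        if len(chains) == 2:
            # rigid offset of the light chain: flip and shift to form a
            # pseudo-interface next to the heavy chain
            flip = np.array([[-1.0, 0.0, 0.0],
                             [0.0, 1.0, 0.0],
                             [0.0, 0.0, -1.0]])
            label, coords, plan, regions = chains[1]
            heavy_coords = chains[0][1]
            shifted = coords @ flip.T
            offset = (heavy_coords[:, 1].mean(axis=0)
                      - shifted.reshape(-1, 3).mean(axis=0)
                      + np.array([0.0, 0.0, 14.0]))
            chains[1] = (label, shifted + offset, plan, regions)
        all_coords = np.concatenate([c[1] for c in chains])
        if _min_separation(all_coords) > 2.0:
            break
        rng = np.random.default_rng(spec.seed + 7919 * (attempt + 1))
    else:
        raise RuntimeError(f"could not build clash-free toy in {max_attempts} attempts")

    chain_ids = np.concatenate([np.full(len(c[1]), c[0]) for c in chains])
    regions = np.concatenate([c[3] for c in chains])
    beta = np.concatenate([c[2] == "E" for c in chains])
    seq = "".join(_sequence(len(c[1]), c[3], rng) for c in chains)
    structure = BackboneStructure(seq, chain_ids, all_coords,
                                  regions=regions, beta=beta)
    if spec.noise > 0:
        structure = perturb_structure(structure, spec.noise, spec.seed + 1)
    return structure


def perturb_structure(structure: BackboneStructure, noise: float,
                      seed: int = 0) -> BackboneStructure:
    """Add seeded isotropic Gaussian displacement (σ = `noise` Å per axis)."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    out = structure.copy()
    if noise == 0:
        return out
    rng = np.random.default_rng(seed)
    out.coords = out.coords + rng.normal(0.0, noise, size=out.coords.shape)
    if out.oxygens is not None:
        out.oxygens = out.oxygens + rng.normal(0.0, noise, size=out.oxygens.shape)
    return out
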