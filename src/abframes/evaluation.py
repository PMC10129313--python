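"""Antibody-specific accuracy metrics.

* Region assignment by Chothia CDR definitions (from fixture metadata or
  an externally computed numbering table).
* Per-region backbone heavy-atom (N, Cα, C, O) RMSD after a single
  framework alignment per chain — CDR RMSDs are *not* re-aligned, so loop
  errors include their displacement relative to the framework.
* OCD, the inter-chain orientational coordinate distance: absolute
  deviations of packing angle, inter-domain distance, and the two opening
  angles, each rescaled by its population standard deviation and summed.
* Spearman calibration of predicted vs. realized RMSD.
* The benchmark metadata filter (date window, resolution, sequence
  identity clustering, CDR H3 length cap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import kabsch_superpose, place_oxygens, _dihedral
from .structure import BackboneStructure

__all__ = ["RegionMap", "CHOTHIA_CDRS", "assign_regions", "region_rmsd",
           "OCDDefinition", "interchain_coordinates", "ocd_from_coords",
           "ocd", "error_calibration", "BenchmarkFilterConfig",
           "benchmark_filter", "sequence_identity"]


# Chothia CDR boundaries (inclusive), by chain type
CHOTHIA_CDRS = {
    "H": {"CDR1": (26, 32), "CDR2": (52, 56), "CDR3": (95, 102)},
    "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
}

_REGIONS = ("FR", "CDR1", "CDR2", "CDR3")


@dataclass
class RegionMap:
    """Per-chain index sets (indices into the full structure)."""

    chains: dict  # chain label -> {region -> np.ndarray of indices}
    scheme: str = "chothia"

    def __post_init__(self):
        for label, regions in self.chains.items():
            all_idx = np.concatenate([np.asarray(v) for v in regions.values()])
            if len(np.unique(all_idx)) != len(all_idx):
                raise ValueError(f"chain {label}: region sets overlap")

    def framework(self, chain: str) -> np.ndarray:
        return np.asarray(self.chains[chain]["FR"])


def assign_regions(structure: BackboneStructure | None = None,
                   numbering: dict | None = None,
                   scheme: str = "chothia") -> RegionMap:
    """Build a RegionMap from structure metadata or a numbering table.

    `numbering` maps chain label to a list of Chothia position numbers
    (insertion codes stripped; e.g. "100A" -> 100), one per residue of
    that chain.  Fixture-style structures carry region labels directly.
    """
    if numbering is not None:
        if structure is None:
            raise ValueError("numbering requires the structure for chain layout")
        chains = {}
        for label in structure.chain_labels:
            idx = structure.chain_indices(label)
            nums = numbering[label]
            if len(nums) != len(idx):
                raise ValueError(f"numbering length mismatch for chain {label}")
            cdrs = CHOTHIA_CDRS[label]
            regions = {r: [] for r in _REGIONS}
            for local_i, raw in enumerate(nums):
                num = int("".join(ch for ch in str(raw) if ch.isdigit()))
                region = "FR"
                for name, (lo, hi) in cdrs.items():
                    if lo <= num <= hi:
                        region = name
                        break
                regions[region].append(idx[local_i])
            chains[label] = {r: np.array(v, dtype=int)
                             for r, v in regions.items()}
        return RegionMap(chains, scheme)
    if structure is not None and structure.regions is not None:
        chains = {}
        for label in structure.chain_labels:
            idx = structure.chain_indices(label)
            labels = structure.regions[idx]
            chains[label] = {r: idx[labels == r] for r in _REGIONS}
        return RegionMap(chains, scheme)
    raise ValueError(
        "cannot assign regions: supply an externally computed numbering "
        "table (e.g. from an antibody numbering tool) or region metadata")


def _backbone_heavy(structure: BackboneStructure) -> np.ndarray:
    """(L, 4, 3) N/Cα/C/O coordinates, placing O when absent."""
    oxy = structure.oxygens
    if oxy is None:
        oxy = place_oxygens(structure)
    return np.concatenate([structure.coords[:, :3, :], oxy[:, None, :]], axis=1)


def region_rmsd(pred: BackboneStructure, native: BackboneStructure,
                regions: RegionMap) -> dict[str, float]:
    """Backbone heavy-atom RMSD per region, framework-aligned per chain.

    Keys like "H_FR", "H_CDR3".  One Kabsch fit on the chain's framework
    backbone atoms; all that chain's region RMSDs reuse the fitted
    transform.  Regions with no residues are omitted.
    """
    if len(pred) != len(native):
        raise ValueError("structure length mismatch")
    P = _backbone_heavy(pred)
    N = _backbone_heavy(native)
    out: dict[str, float] = {}
    for label, chain_regions in regions.chains.items():
        fr = regions.framework(label)
        R, t, _ = kabsch_superpose(P[fr].reshape(-1, 3), N[fr].reshape(-1, 3))
        P_fit = P @ R.T + t
        for region, idx in chain_regions.items():
            if len(idx) == 0:
                continue
            diff = P_fit[idx].reshape(-1, 3) - N[idx].reshape(-1, 3)
            out[f"{label}_{region}"] = float(
                np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return out


@dataclass
class OCDDefinition:
    """Residue sets, axis construction, and rescaling σ for the four
    inter-chain coordinates.

    The coordinate set follows the inter-chain orientation convention:
    packing angle (torsion between the two domain principal axes about
    the centroid connection), inter-domain distance, and the opening
    angle of each domain axis against the connection.  Residue sets
    default to the chain's framework Cα atoms; σ values are configurable
    population standard deviations.
    """

    heavy_set: np.ndarray | None = None   # indices into the structure
    light_set: np.ndarray | None = None
    sigma_packing: float = 2.6    # degrees
    sigma_distance: float = 0.4   # Å
    sigma_heavy_open: float = 1.9  # degrees
    sigma_light_open: float = 1.6  # degrees

    def __post_init__(self):
        for s in (self.sigma_packing, self.sigma_distance,
                  self.sigma_heavy_open, self.sigma_light_open):
            if s <= 0:
                raise ValueError("σ must be positive")

    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_packing, self.sigma_distance,
                         self.sigma_heavy_open, self.sigma_light_open])


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # deterministic sign: point along the chain direction
    if np.dot(axis, points[-1] - points[0]) < 0:
        axis = -axis
    return axis


def interchain_coordinates(structure: BackboneStructure,
                           defs: OCDDefinition | None = None,
                           regions: RegionMap | None = None) -> np.ndarray:
    """The four inter-chain coordinates: (packing angle deg,
    inter-domain distance Å, heavy-opening deg, light-opening deg)."""
    defs = defs or OCDDefinition()
    if structure.n_chains < 2:
        raise ValueError("inter-chain coordinates undefined for single chains")
    sets = {}
    for label, chosen in (("H", defs.heavy_set), ("L", defs.light_set)):
        if chosen is not None:
            sets[label] = np.asarray(chosen)
        elif regions is not None:
            sets[label] = regions.framework(label)
        else:
            sets[label] = structure.chain_indices(label)
    ca = structure.coords[:, 1]
    cen_h = ca[sets["H"]].mean(axis=0)
    cen_l = ca[sets["L"]].mean(axis=0)
    axis_h = _principal_axis(ca[sets["H"]])
    axis_l = _principal_axis(ca[sets["L"]])
    conn = cen_l - cen_h
    dist = float(np.linalg.norm(conn))
    packing = _dihedral(cen_h + axis_h, cen_h, cen_l, cen_l + axis_l)
    conn_u = conn / dist
    open_h = math.degrees(math.acos(np.clip(np.dot(axis_h, conn_u), -1, 1)))
    open_l = math.degrees(math.acos(np.clip(np.dot(axis_l, -conn_u), -1, 1)))
    return np.array([packing, dist, open_h, open_l])


def ocd_from_coords(coords_a: np.ndarray, coords_b: np.ndarray,
                    sigmas: np.ndarray) -> float:
    """OCD = Σ |Δcoordinate| / σ; angle deviations wrapped to ≤180°."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    dev = np.abs(coords_a - coords_b)
    for k in (0, 2, 3):  # angular components
        dev[k] = min(dev[k], 360.0 - dev[k])
    return float(np.sum(dev / np.asarray(sigmas, dtype=float)))


def ocd(pred: BackboneStructure, native: BackboneStructure,
        defs: OCDDefinition | None = None,
        regions: RegionMap | None = None) -> float:
    """Orientational coordinate distance between two paired structures."""
    defs = defs or OCDDefinition()
    ca = interchain_coordinates(pred, defs, regions)
    cb = interchain_coordinates(native, defs, regions)
    return ocd_from_coords(ca, cb, defs.sigmas())


def error_calibration(pred_errors: np.ndarray, true_rmsds: np.ndarray
                      ) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with the
    two-sided t-approximation p-value."""
    x = np.asarray(pred_errors, dtype=float)
    y = np.asarray(true_rmsds, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity fraction (matches / alignment columns)."""
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / len(sa)


@dataclass
class BenchmarkFilterConfig:
    date_start: str = "2021-07-01"
    date_end: str = "2022-09-01"
    resolution_cutoff: float = 3.0
    # "below" keeps resolution <= cutoff (conventional quality filter);
    # "above" keeps resolution > cutoff (the printed alternative)
    resolution_rule: str = "below"
    identity_threshold: float = 0.99
    h3_max_length: int = 20


def benchmark_filter(table: pd.DataFrame,
                     config: BenchmarkFilterConfig | None = None
                     ) -> pd.DataFrame:
    """Apply the benchmark-selection rules to a metadata table.

    Requires columns: date, resolution, sequence, h3_length.  Rules, in
    order: deposition-date window, resolution cutoff, CDR H3 length cap,
    then greedy single-linkage identity clustering keeping the first
    representative of each cluster.
    """
    config = config or BenchmarkFilterConfig()
    required = {"date", "resolution", "sequence", "h3_length"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"missing column(s): {sorted(missing)}")
    if len(table) == 0:
        return table.copy()
    df = table.copy()
    dates = pd.to_datetime(df["date"])
    keep = (dates >= pd.Timestamp(config.date_start)) & \
           (dates <= pd.Timestamp(config.date_end))
    if config.resolution_rule == "below":
        keep &= df["resolution"] <= config.resolution_cutoff
    elif config.resolution_rule == "above":
        keep &= df["resolution"] > config.resolution_cutoff
    else:
        raise ValueError("resolution_rule must be 'below' or 'above'")
    keep &= df["h3_length"] <= config.h3_max_length
    df = df[keep]
    kept_rows = []
    kept_seqs: list[str] = []
    for _, row in df.iterrows():
        seq = str(row["sequence"])
        if any(sequence_identity(seq, other) >= config.identity_threshold
               for other in kept_seqs):
            continue
        kept_rows.append(row)
        kept_seqs.append(seq)
    return pd.DataFrame(kept_rows).reset_index(drop=True)
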