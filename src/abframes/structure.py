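"""Backbone structure container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ATOM_ORDER = ("N", "CA", "C", "CB")  # the four frame atoms, in storage order


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates for one or two chains.

    ``coords`` holds the four frame atoms (N, Cα, C, Cβ) as an (L, 4, 3)
    array in Å.  Carbonyl oxygens are optional (placed geometrically when a
    metric needs them).  Glycines carry a virtual Cβ placed by ideal
    geometry so that all losses and labels see four atoms per residue.
    """

    sequence: str
    chain_ids: np.ndarray          # (L,) of 'H' / 'L'
    coords: np.ndarray             # (L, 4, 3) Å
    oxygens: np.ndarray | None = None      # (L, 3) Å
    regions: np.ndarray | None = None      # (L,) labels: 'FR', 'CDR1', 'CDR2', 'CDR3'
    beta: np.ndarray | None = None         # (L,) bool, immunoglobulin strand flags
    predicted_error: np.ndarray | None = None  # (L,) Å

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        L = len(self.sequence)
        if self.coords.shape != (L, 4, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({L}, 4, 3)")
        if self.chain_ids.shape != (L,):
            raise ValueError("chain_ids length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_chains(self) -> int:
        return len(self.chain_labels)

    @property
    def chain_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(str(c))
        return seen

    def chain_indices(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.chain_ids == chain)

    def copy(self) -> "BackboneStructure":
        return replace(
            self,
            chain_ids=self.chain_ids.copy(),
            coords=self.coords.copy(),
            oxygens=None if self.oxygens is None else self.oxygens.copy(),
            regions=None if self.regions is None else self.regions.copy(),
            beta=None if self.beta is None else self.beta.copy(),
            predicted_error=(None if self.predicted_error is None
                             else self.predicted_error.copy()),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneStructure":
        """Apply a global rigid transform; returns a new structure."""
        out = self.copy()
        out.coords = self.coords @ rotation.T + translation
        if self.oxygens is not None:
            out.oxygens = self.oxygens @ rotation.T + translation
        return out

    def atom_array(self, atoms=("N", "CA", "C", "CB")) -> np.ndarray:
        """Flat (L*len(atoms), 3) array in residue-major order."""
        idx = [ATOM_ORDER.index(a) for a in atoms]
        return self.coords[:, idx, :].reshape(-1, 3)
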