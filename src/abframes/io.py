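"""FASTA and PDB input/output.

PDB writing stores the per-residue predicted deviation (Å) in the
B-factor column, mirroring the common practice of shipping model
confidence there.  The four frame atoms are always written, including the
virtual Cβ of glycine (a documented modelling artifact that keeps
round-trips exact).
"""

from __future__ import annotations

import warnings

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

from .embeddings import AMINO_ACIDS
from .geometry import frames_from_three_points, frame_atoms_batch, IdealGeometry
from .structure import BackboneStructure

__all__ = ["read_fasta", "write_pdb", "read_pdb"]


def read_fasta(path) -> dict[str, str]:
    """Read 1 (nanobody) or 2 (paired) chain sequences.

    Returns {"H": seq} or {"H": seq, "L": seq}.  A ":H"/":L" tag in the
    record id assigns the role regardless of order; otherwise the first
    record is heavy.  Lowercase letters are uppercased with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError("empty FASTA file")
    if len(records) > 2:
        raise ValueError(f"expected 1 or 2 records, found {len(records)}")
    out: dict[str, str] = {}
    order_roles = ["H", "L"]
    for i, rec in enumerate(records):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id}: lowercase letters uppercased")
            seq = seq.upper()
        bad = [j for j, a in enumerate(seq) if a not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"record {rec.id}: invalid characters at {bad}")
        header = rec.id + " " + (rec.description or "")
        role = None
        for tag, r in ((":H", "H"), (":L", "L")):
            if tag in header:
                role = r
        if role is None:
            role = order_roles[i]
        if role in out:
            raise ValueError(f"duplicate chain role {role}")
        out[role] = seq
    if "H" not in out:
        raise ValueError("no heavy chain found")
    return out


def write_pdb(structure: BackboneStructure, path,
              b_factor_source: np.ndarray | None = None) -> None:
    """Write ATOM records (N, CA, C, CB, and O when present)."""
    b = b_factor_source
    if b is None:
        b = structure.predicted_error
    if b is None:
        b = np.zeros(len(structure))
    b = np.round(np.asarray(b, dtype=float), 2)
    atom_names = ["N", "CA", "C", "CB"]
    n_per_res = 4 + (structure.oxygens is not None)
    n_atoms = len(structure) * n_per_res
    arr = struc.AtomArray(n_atoms)
    pos = 0
    res_counters: dict[str, int] = {}
    for i, aa in enumerate(structure.sequence):
        chain = str(structure.chain_ids[i])
        res_counters[chain] = res_counters.get(chain, 0) + 1
        res_name = protein_letters_1to3[aa].upper()
        names = atom_names + (["O"] if structure.oxygens is not None else [])
        for name in names:
            arr.chain_id[pos] = chain
            arr.res_id[pos] = res_counters[chain]
            arr.res_name[pos] = res_name
            arr.atom_name[pos] = name
            arr.element[pos] = name[0]
            if name == "O":
                arr.coord[pos] = structure.oxygens[i]
            else:
                arr.coord[pos] = structure.coords[i, atom_names.index(name)]
            pos += 1
    arr.set_annotation("b_factor", np.repeat(b, n_per_res))
    arr.hetero[:] = False
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def read_pdb(path, geom: IdealGeometry | None = None) -> BackboneStructure:
    """Read a backbone structure; missing Cβ (e.g. glycine) is placed by
    ideal geometry.  CA B-factors populate predicted_error."""
    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, extra_fields=["b_factor"])
    arr = arr[np.isin(arr.atom_name, ["N", "CA", "C", "CB", "O"])
              & ~arr.hetero]
    seq = []
    chain_ids = []
    coords = []
    oxygens = []
    b_factors = []
    have_o = True
    for chain in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == chain]
        for res_id in np.unique(sub.res_id):
            res = sub[sub.res_id == res_id]
            by_name = {a: res.coord[res.atom_name == a] for a in
                       ("N", "CA", "C", "CB", "O")}
            if any(len(by_name[a]) == 0 for a in ("N", "CA", "C")):
                raise ValueError(
                    f"chain {chain} residue {res_id}: missing mainchain atom")
            n, ca, c = (by_name[a][0] for a in ("N", "CA", "C"))
            if len(by_name["CB"]):
                cb = by_name["CB"][0]
            else:
                frames = frames_from_three_points(n[None], ca[None], c[None])
                cb = frame_atoms_batch(frames.rotations, frames.translations,
                                       geom)[0, 3]
            coords.append(np.stack([n, ca, c, cb]))
            if len(by_name["O"]):
                oxygens.append(by_name["O"][0])
            else:
                have_o = False
            three = str(res.res_name[0]).capitalize()
            seq.append(protein_letters_3to1.get(three, "A"))
            chain_ids.append(str(chain))
            b_factors.append(float(res.b_factor[res.atom_name == "CA"][0]))
    structure = BackboneStructure(
        "".join(seq), np.array(chain_ids), np.stack(coords),
        oxygens=np.stack(oxygens) if have_o and oxygens else None,
        predicted_error=np.array(b_factors))
    return structure
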