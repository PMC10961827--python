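"""PDB / XYZ input and output.

Reading goes through gemmi (tolerant, multi-model aware); writing is done
with explicit wwPDB v3.3 fixed-width formatting so that write->read round
trips preserve coordinates to the format's 3-decimal precision.
"""

from __future__ import annotations

import os
import warnings

import gemmi
import numpy as np

from .core import AtomRecord, Model, Structure, NUCLEIC_RESNAMES

__all__ = ["read_pdb", "write_pdb", "write_xyz", "read_xyz"]


def read_pdb(path: str) -> Structure:
    """Read a (possibly multi-model) PDB file into a Structure.

    All models must share one atom roster; non-nucleic residues are kept
    but flagged with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models = []
    non_nucleic: set[str] = set()
    for gm in st:
        atoms = []
        serial = 0
        for chain in gm:
            for res in chain:
                if res.name not in NUCLEIC_RESNAMES and res.is_water() is False:
                    non_nucleic.add(res.name)
                for at in res:
                    serial += 1
                    atoms.append(AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        chain_id=chain.name or "A",
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    ))
        models.append(Model(atoms))
    if not models:
        raise ValueError(f"{path}: no models found")
    if non_nucleic:
        warnings.warn(f"{path}: non-nucleic residues retained: {sorted(non_nucleic)}")
    return Structure(models)


def _pdb_atom_line(a: AtomRecord, serial: int) -> str:
    name = a.name
    # column 13 is blank for names of <4 chars unless the name starts
    # with a digit or the element symbol is two characters
    if len(name) < 4 and len(a.element) < 2 and not name[:1].isdigit():
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = a.xyz
    return (f"ATOM  {serial:5d} {name_field} {a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}")


def write_pdb(structure: Structure, path: str) -> None:
    """Write a Structure as a fixed-width multi-model PDB file."""
    if structure.n_models == 0 or len(structure.models[0]) == 0:
        raise ValueError("cannot write an empty Structure")
    multi = structure.n_models > 1
    lines = []
    for imod, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {imod:4d}")
        serial = 0
        prev_chain = None
        for a in model.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = a.chain_id
            serial += 1
            lines.append(_pdb_atom_line(a, serial))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz(model: Model, path: str, comment: str = "") -> None:
    """Write one Model in standard XYZ format (element symbols, 6 decimals)."""
    if len(model) == 0:
        raise ValueError("cannot write an empty Model")
    comment = comment.replace("\n", " ")
    with open(path, "w") as fh:
        fh.write(f"{len(model)}\n{comment}\n")
        for a in model.atoms:
            x, y, z = a.xyz
            fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path: str) -> tuple[list[str], np.ndarray, str]:
    """Read an XYZ file -> (elements, coords, comment)."""
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().rstrip("\n")
        elements, coords = [], []
        for _ in range(n):
            parts = fh.readline().split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
    return elements, np.asarray(coords), comment
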