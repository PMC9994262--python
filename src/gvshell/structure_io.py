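"""Reading and writing atomic structures (PDB / mmCIF) via biotite.

Also bundles small per-element constant tables: atomic masses (Da) and the
Bondi van der Waals radii (A) used by the pore module.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure, set_structure

__all__ = [
    "ATOMIC_MASS",
    "VDW_RADIUS",
    "read_structure_file",
    "write_structure_file",
    "atom_array_from_arrays",
]

# monoisotopic-ish average masses, Da
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

# Bondi (1964) van der Waals radii, Angstrom
VDW_RADIUS = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}

_PDB_MAX_ATOMS = 99_999


def read_structure_file(path: str | PathLike) -> struc.AtomArray:
    """Read a PDB or mmCIF file into a biotite AtomArray (first model)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        cif = CIFFile.read(str(path))
        atoms = get_structure(cif, model=1)
    elif suffix in (".pdb", ".ent"):
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    else:
        raise ValueError(f"unsupported structure format: {path.suffix!r} "
                         "(expected .pdb or .cif)")
    return atoms


def write_structure_file(atoms: struc.AtomArray, path: str | PathLike,
                         fmt: str | None = None) -> None:
    """Write an AtomArray as PDB or mmCIF, chosen by ``fmt`` or file suffix.

    PDB output is refused above the 99,999-atom serial limit or for
    multi-character chain identifiers; use mmCIF for complete vesicles.
    """
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif", ".pdbx") else "pdb"
    if atoms.array_length() == 0:
        raise ValueError("refusing to write an empty structure")
    if fmt == "pdb":
        if atoms.array_length() > _PDB_MAX_ATOMS:
            raise ValueError(
                f"model has {atoms.array_length()} atoms, beyond the PDB "
                f"format limit of {_PDB_MAX_ATOMS}; write mmCIF instead")
        if max(len(str(c)) for c in np.unique(atoms.chain_id)) > 1:
            raise ValueError("multi-character chain identifiers need mmCIF output")
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))
    elif fmt == "cif":
        cif = CIFFile()
        set_structure(cif, atoms)
        cif.write(str(path))
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def atom_array_from_arrays(
    coords: np.ndarray,
    atom_names: np.ndarray,
    res_ids: np.ndarray,
    elements: np.ndarray,
    chain_id: str = "A",
    res_name: str = "GVA",
    occupancy: np.ndarray | None = None,
) -> struc.AtomArray:
    """Assemble a biotite AtomArray from plain numpy arrays."""
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.atom_name = np.asarray(atom_names)
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.res_name = np.full(n, res_name)
    atoms.chain_id = np.full(n, chain_id)
    atoms.element = np.asarray(elements)
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("occupancy",
                         np.ones(n, dtype=np.float32) if occupancy is None
                         else np.asarray(occupancy, dtype=np.float32))
    return atoms
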