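"""Atomic model container and PDB/mmCIF I/O (via gemmi)."""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable

import gemmi
import numpy as np

from .cell import SymmetryOps, UnitCell

__all__ = ["Atom", "AtomicModel", "read_model", "write_model"]


@dataclasses.dataclass
class Atom:
    """One atom: element, fractional position, occupancy, isotropic B.

    Fractional coordinates are stored wrapped into [0, 1); the cell that
    defines the wrapping lives on the enclosing :class:`AtomicModel`.
    """

    element: str
    frac: np.ndarray
    occ: float = 1.0
    b_iso: float = 20.0
    chain: str = "A"
    resnum: int = 1
    resname: str = "ALA"
    name: str = ""

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float) % 1.0
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"negative B factor {self.b_iso}")
        if not self.name:
            self.name = self.element

    def copy(self) -> "Atom":
        return dataclasses.replace(self, frac=self.frac.copy())


class AtomicModel:
    """An ordered list of atoms in a unit cell with symmetry.

    Atom order is stable across read -> write -> read cycles, so refined
    quantities can always be compared positionally against the input model.
    """

    def __init__(self, cell: UnitCell, atoms: Iterable[Atom], sym: SymmetryOps | None = None):
        self.cell = cell
        self.sym = sym if sym is not None else SymmetryOps.p1()
        self.atoms = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.cell, [a.copy() for a in self.atoms], self.sym)

    def frac_coords(self) -> np.ndarray:
        """(n, 3) array of fractional coordinates in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.frac for a in self.atoms])

    def set_frac_coords(self, frac: np.ndarray) -> None:
        frac = np.asarray(frac, dtype=float)
        if frac.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, x in zip(self.atoms, frac):
            atom.frac = x % 1.0

    def orth_coords(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac_coords())

    def b_values(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms])

    def set_b_values(self, b: np.ndarray) -> None:
        for atom, bi in zip(self.atoms, np.asarray(b, dtype=float)):
            atom.b_iso = float(bi)

    def expand_to_p1(self) -> "AtomicModel":
        """Replicate atoms over all symmetry operators; result carries P1 symmetry."""
        if self.sym.is_p1:
            return self
        images = self.sym.apply(self.frac_coords())
        atoms: list[Atom] = []
        for img in images:
            for atom, x in zip(self.atoms, img):
                a = atom.copy()
                a.frac = x
                atoms.append(a)
        return AtomicModel(self.cell, atoms, SymmetryOps.p1())


def _from_gemmi(st: gemmi.Structure, path: str) -> AtomicModel:
    if st.cell.volume == 0 or not st.cell.is_crystal():
        raise ValueError(f"no unit cell record in {path}")
    cell = UnitCell.from_gemmi(st.cell)
    try:
        sym = SymmetryOps.from_spacegroup(st.spacegroup_hm or "P 1")
    except Exception:
        sym = SymmetryOps.p1()
    atoms: list[Atom] = []
    frac_mat = cell.frac_matrix
    for g_model in st:
        for chain in g_model:
            for res in chain:
                for at in res:
                    if at.element.name in ("", "X"):
                        raise ValueError(
                            f"unknown element for atom {chain.name}/{res.seqid.num}/{at.name}"
                        )
                    pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                    atoms.append(
                        Atom(
                            element=at.element.name,
                            frac=frac_mat @ pos,
                            occ=at.occ,
                            b_iso=at.b_iso,
                            chain=chain.name,
                            resnum=res.seqid.num,
                            resname=res.name,
                            name=at.name,
                        )
                    )
        break  # first model only
    return AtomicModel(cell, atoms, sym)


def read_model(path: str | os.PathLike) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Coordinates are converted to fractional and wrapped; atoms keep file order.
    Raises ``ValueError`` if the file carries no unit-cell record.
    """
    st = gemmi.read_structure(os.fspath(path))
    return _from_gemmi(st, os.fspath(path))


def _to_gemmi(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = model.sym.name
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    orth = model.orth_coords()
    for atom, pos in zip(model.atoms, orth):
        if atom.chain not in chains:
            chains[atom.chain] = gemmi.Chain(atom.chain)
        key = (atom.chain, atom.resnum)
        if key not in residues:
            res = gemmi.Residue()
            res.name = atom.resname
            res.seqid = gemmi.SeqId(atom.resnum, " ")
            chains[atom.chain].add_residue(res)
            residues[key] = chains[atom.chain][-1]
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*pos)
        ga.occ = atom.occ
        ga.b_iso = atom.b_iso
        residues[key].add_atom(ga)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path: str | os.PathLike) -> None:
    """Write a model as PDB (default) or mmCIF (``.cif``/``.mmcif`` extension)."""
    path = os.fspath(path)
    st = _to_gemmi(model)
    if path.lower().endswith((".cif", ".mmcif")):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
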