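"""Reading and writing atomic structures (PDB / mmCIF).

Exposes a small hierarchical model (StructureModel -> Chain -> Residue ->
Atom) that every downstream module consumes. Parsing and serialization are
delegated to :mod:`gemmi`; this module enforces the package conventions on
top of it:

* only standard amino-acid residues are kept (waters, ligands and nucleic
  acids are skipped);
* alternate locations are resolved to the highest-occupancy atom, ties
  broken by first appearance in the file;
* hydrogens present in input files are discarded — amide hydrogens are
  rebuilt geometrically by the scoring module, which is the single source
  of truth for them;
* only the first model of multi-model (NMR) files is read.

Coordinates are Angstrom throughout the package.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import StructureError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "read_structure",
    "write_structure",
    "STANDARD_AA3",
    "AA3_TO_1",
    "AA1_TO_3",
]

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Single-character chain ids accepted by the PDB dialect, in the order we
#: assign them to generated structures.
PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Atom:
    """One heavy atom with Angstrom coordinates."""

    name: str
    element: str
    pos: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.pos)):
            raise StructureError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise StructureError("atom name must be non-empty")


@dataclass
class Residue:
    """An amino-acid residue (3-letter code, author numbering, atoms)."""

    name: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_backbone_complete(self) -> bool:
        present = {a.name for a in self.atoms}
        return {"N", "CA", "C", "O"} <= present

    def backbone_coords(self) -> np.ndarray:
        """(4, 3) array of N, CA, C, O coordinates."""
        if not self.is_backbone_complete:
            raise StructureError(
                f"residue {self.name} {self.seq_id}{self.icode} lacks a full backbone"
            )
        return np.stack([self.atom(n).pos for n in ("N", "CA", "C", "O")])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.residues)

    def backbone_coords(self) -> np.ndarray:
        """(n_res, 4, 3) backbone coordinates for backbone-complete chains."""
        return np.stack([r.backbone_coords() for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            a = r.atom("CA")
            if a is None:
                raise StructureError(f"residue {r.seq_id} has no CA atom")
            out.append(a.pos)
        return np.asarray(out)

    def all_coords(self) -> np.ndarray:
        return np.asarray([a.pos for r in self.residues for a in r.atoms])

    def transformed(self, transform) -> "Chain":
        """Copy of this chain with every atom moved by a RigidTransform."""
        new = Chain(self.chain_id)
        for r in self.residues:
            nr = Residue(r.name, r.seq_id, r.icode)
            for a in r.atoms:
                nr.atoms.append(Atom(a.name, a.element, transform.apply(a.pos), a.serial))
            new.residues.append(nr)
        return new


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError("duplicate chain ids in model")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def heavy_coords_and_elements(self) -> tuple[np.ndarray, list[str]]:
        coords, elements = [], []
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    coords.append(a.pos)
                    elements.append(a.element)
        return np.asarray(coords), elements


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise StructureError(f"cannot detect format from extension {suffix!r}; pass format=")


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        File to read. With ``format='auto'`` the dialect is taken from the
        extension (``.pdb``/``.ent`` vs ``.cif``/``.mmcif``).
    format
        One of ``{'pdb', 'mmcif', 'auto'}``.

    Returns
    -------
    StructureModel
        Chains and residues in file order; only standard amino acids with
        at least one heavy atom survive. Altlocs resolved to highest
        occupancy (first seen wins ties); hydrogens and waters dropped.

    Raises
    ------
    StructureError
        If the file cannot be parsed or contains no protein atoms.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no model")
    model = st[0]  # first model only

    out = StructureModel(source=str(path))
    seen_ids: set[str] = set()
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            if gres.name not in STANDARD_AA3:
                continue
            res = Residue(gres.name, gres.seqid.num, (gres.seqid.icode or " ").strip())
            best: dict[str, Atom] = {}
            best_occ: dict[str, float] = {}
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                name = gatom.name
                occ = gatom.occ
                if name in best and occ <= best_occ[name]:
                    continue  # keep highest occupancy, first-seen wins ties
                best[name] = Atom(
                    name,
                    gatom.element.name,
                    np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    gatom.serial,
                )
                best_occ[name] = occ
            res.atoms = list(best.values())
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            if chain.chain_id in seen_ids:
                chain.chain_id = chain.chain_id + "_2"
            seen_ids.add(chain.chain_id)
            out.chains.append(chain)
    if not out.chains:
        raise StructureError(f"{path} contains no standard protein atoms")
    return out


def write_structure(model: StructureModel, path, format: str = "auto") -> None:
    """Write a :class:`StructureModel` as PDB or mmCIF.

    Chain ids and author residue numbering are preserved. The PDB dialect
    supports at most ``len(PDB_CHAIN_IDS)`` (62) single-character chain
    ids; larger assemblies must be written as mmCIF.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if not model.chains or model.n_atoms == 0:
        raise StructureError("refusing to write an empty model")
    if fmt == "pdb":
        if len(model.chains) > len(PDB_CHAIN_IDS):
            raise StructureError(
                f"{len(model.chains)} chains exceed the PDB dialect limit of "
                f"{len(PDB_CHAIN_IDS)}; write mmCIF instead"
            )
        for c in model.chains:
            if len(c.chain_id) > 1:
                raise StructureError(
                    f"chain id {c.chain_id!r} is not a single character; write mmCIF instead"
                )

    st = gemmi.Structure()
    st.name = "fibrilcap"
    gmodel = gemmi.Model("1")
    serial = 1
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.serial = serial
                ga.occ = 1.0
                serial += 1
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
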