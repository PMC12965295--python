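"""Coordinate-file I/O and pigment extraction.

Thin domain layer over gemmi: reads and writes mmCIF/PDB, flattens the
hierarchy into plain atom records (coordinates in Å throughout), and groups
registry-mapped heteroatom residues into :class:`PigmentInstance` objects.
Alternate locations are collapsed deterministically to a single atom per name
(highest occupancy, then lowest altloc label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import DegeneratePigmentError, FormatError, ParseError
from .registry import (
    AMINO_ACID_RESIDUE_MASSES,
    CHLORIN_CLASSES,
    MACROCYCLE_N,
    PigmentRegistry,
)


@dataclass
class AtomRecord:
    """One atom: name, element symbol, Cartesian position in Å."""

    atom_name: str
    element: str
    xyz: np.ndarray
    residue_name: str
    residue_number: int
    chain_id: str
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")


@dataclass
class StructureModel:
    """Ordered atom list plus free-form metadata."""

    atoms: list[AtomRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self):
        """Yield (chain_id, residue_number, residue_name, [atoms]) groups in file order."""
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            groups.setdefault(
                (a.chain_id, a.residue_number, a.residue_name), []).append(a)
        yield from groups.items()


@dataclass
class PigmentInstance:
    """One cofactor: typed class, identity, and its atoms.

    ``degenerate`` marks instances missing the atoms required for geometric
    descriptors (e.g. a chlorin with neither Mg nor four macrocycle N); they
    are retained in censuses but excluded from dipole/network computations.
    """

    pigment_class: str
    chain_id: str
    residue_number: int
    residue_name: str
    atoms: list[AtomRecord]
    label: str = ""
    degenerate: bool = False

    @property
    def node_id(self) -> str:
        return f"{self.chain_id}:{self.residue_number}"

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise DegeneratePigmentError(
            f"{self.node_id}/{self.residue_name}: atom {name!r} not present")

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.xyz for a in self.atoms])
        return np.array([a.xyz for a in self.atoms if a.atom_name in set(names)])


def _coor_format(path: str | Path, format: str) -> gemmi.CoorFormat:
    fmt = format.lower()
    if fmt == "auto":
        suffix = Path(path).suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            return gemmi.CoorFormat.Mmcif
        if suffix in {".pdb", ".ent"}:
            return gemmi.CoorFormat.Pdb
        return gemmi.CoorFormat.Detect
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    raise FormatError(f"unknown coordinate format {format!r}")


def parse_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB file into a flat :class:`StructureModel`.

    All ATOM/HETATM records are retained; when a residue carries alternate
    locations, exactly one atom per atom name is kept (highest occupancy,
    ties broken by altloc label order).
    """
    fmt = _coor_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    model = StructureModel(metadata={"source": str(path), "name": st.name})
    if len(st) == 0:
        return model
    for chain in st[0]:
        for residue in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for atom in residue:
                if atom.name not in by_name:
                    order.append(atom.name)
                by_name.setdefault(atom.name, []).append(atom)
            for name in order:
                variants = by_name[name]
                chosen = min(
                    variants,
                    key=lambda a: (-a.occ, a.altloc if a.altloc != "\0" else ""))
                alt = chosen.altloc if chosen.altloc not in ("\0", "") else ""
                model.atoms.append(AtomRecord(
                    atom_name=name,
                    element=chosen.element.name,
                    xyz=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                    alt_loc=alt,
                ))
    return model


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> None:
    """Write a :class:`StructureModel` as PDB or mmCIF.

    Round-trips identity on (atom name, residue, chain) and coordinates to
    3 decimals via the PDB dialect, exactly via mmCIF.
    """
    fmt = _coor_format(path, format)
    if fmt == gemmi.CoorFormat.Detect:
        raise FormatError(f"cannot infer output format from {path!r}")
    st = gemmi.Structure()
    st.name = str(model.metadata.get("name", "model"))
    gmodel = gemmi.Model("1")
    # gemmi's add_residue/add_chain copy their argument, so assemble each
    # level completely before inserting it into its parent.
    chain_order: list[str] = []
    per_chain: dict[str, dict[tuple[int, str], gemmi.Residue]] = {}
    for rec in model.atoms:
        if rec.chain_id not in per_chain:
            per_chain[rec.chain_id] = {}
            chain_order.append(rec.chain_id)
        residues = per_chain[rec.chain_id]
        key = (rec.residue_number, rec.residue_name)
        if key not in residues:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_number, " ")
            res.het_flag = (
                "A" if rec.residue_name in AMINO_ACID_RESIDUE_MASSES else "H")
            residues[key] = res
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element or "X")
        atom.pos = gemmi.Position(*rec.xyz)
        atom.occ = 1.0
        if rec.alt_loc:
            atom.altloc = rec.alt_loc
        residues[key].add_atom(atom)
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        for res in per_chain[chain_id].values():
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        if fmt == gemmi.CoorFormat.Pdb:
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _site_label(pigment_class: str, chain_id: str, residue_number: int) -> str:
    # Green-lineage antenna site nomenclature: Chl sites 601-624 etc.
    if pigment_class in CHLORIN_CLASSES and 600 <= residue_number <= 699:
        return f"a{residue_number}"
    return f"{chain_id}:{residue_number}"


def extract_pigments(model: StructureModel,
                     registry: PigmentRegistry | None = None
                     ) -> list[PigmentInstance]:
    """Group registry-mapped heteroatom residues into pigment instances.

    One instance per (chain, residue); residues whose code is not in the
    registry are ignored.  Instances missing required atoms are flagged
    degenerate but kept.
    """
    registry = registry or PigmentRegistry()
    out: list[PigmentInstance] = []
    for (chain_id, resnum, resname), atoms in model.residues():
        pclass = registry.pigment_class(resname)
        if pclass is None:
            continue
        degenerate = False
        if pclass in CHLORIN_CLASSES:
            names = {a.atom_name for a in atoms}
            n_count = sum(1 for n in MACROCYCLE_N if n in names)
            degenerate = "MG" not in names and n_count < 4
        elif not atoms:
            degenerate = True
        out.append(PigmentInstance(
            pigment_class=pclass,
            chain_id=chain_id,
            residue_number=resnum,
            residue_name=resname,
            atoms=list(atoms),
            label=_site_label(pclass, chain_id, resnum),
            degenerate=degenerate,
        ))
    return out
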