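"""Per-pigment geometric descriptors.

Chlorin anchors (Mg or macrocycle-N centroid), Qy transition dipoles, ring
planes and inter-plane angles, minimum interatomic distances, polyene
dihedral scans with cis/trans classification, and the Förster orientation
factor κ².

Conventions
-----------
* The Qy dipole is the unit vector along the NB→ND axis of the chlorin
  macrocycle (configurable to NA→NC through the registry's ``dipole_atoms``).
  κ² is invariant to the sign of either dipole, so the axis ordering is a
  bookkeeping choice.
* The point dipole is anchored at the Mg, the same point used for
  donor–acceptor distances, so one anchor serves both R and κ.
* A bond is classified cis when |dihedral| ≤ 90°, all-trans otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegeneratePigmentError, GeometryError
from .registry import CHLORIN_CLASSES, MACROCYCLE_N, RING_PLANE_ATOMS
from .structure import PigmentInstance


@dataclass
class TransitionDipole:
    """Unit Qy direction anchored at a point (Å)."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise GeometryError("zero-length dipole direction")
            self.direction = self.direction / norm


@dataclass
class RingPlane:
    """Least-squares macrocycle plane: centroid, unit normal, fit RMSD (Å)."""

    centroid: np.ndarray
    normal: np.ndarray
    rmsd_from_plane: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)


@dataclass
class IsomerLabel:
    """Polyene configuration: all-trans, or cis with the twisted bond indices."""

    configuration: str
    cis_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.configuration == "cis") != bool(self.cis_positions):
            raise ValueError("configuration=cis iff cis_positions non-empty")


def _require_chlorin(p: PigmentInstance) -> None:
    if p.pigment_class not in CHLORIN_CLASSES:
        raise DegeneratePigmentError(
            f"{p.node_id}: not a chlorin ({p.pigment_class})")


def magnesium_center(p: PigmentInstance) -> np.ndarray:
    """Chlorin anchor: the Mg position, or the NA/NB/NC/ND centroid if Mg is absent."""
    _require_chlorin(p)
    if p.has_atom("MG"):
        return p.atom("MG").xyz.copy()
    n_coords = p.coords(list(MACROCYCLE_N))
    if len(n_coords) < 4:
        raise DegeneratePigmentError(
            f"{p.node_id}: no MG and only {len(n_coords)} macrocycle N atoms")
    return n_coords.mean(axis=0)


def qy_dipole(p: PigmentInstance,
              dipole_atoms: tuple[str, str] = ("NB", "ND")) -> TransitionDipole:
    """Qy transition dipole: unit vector between the registry's dipole atom pair."""
    _require_chlorin(p)
    tail, head = dipole_atoms
    for name in (tail, head):
        if not p.has_atom(name):
            raise DegeneratePigmentError(
                f"{p.node_id}: dipole atom {name!r} missing")
    v = p.atom(head).xyz - p.atom(tail).xyz
    norm = np.linalg.norm(v)
    if norm == 0:
        raise GeometryError(f"{p.node_id}: coincident dipole atoms")
    return TransitionDipole(anchor=magnesium_center(p), direction=v / norm)


def _fix_normal_sign(n: np.ndarray) -> np.ndarray:
    # Deterministic sign: positive z, then y, then x, whichever is nonzero first.
    for i in (2, 1, 0):
        if abs(n[i]) > 1e-12:
            return n if n[i] > 0 else -n
    return n


def ring_plane(p: PigmentInstance,
               atom_names: tuple[str, ...] = RING_PLANE_ATOMS) -> RingPlane:
    """Least-squares plane through the macrocycle N and ring C atoms.

    The normal is the singular vector of the smallest singular value of the
    centered coordinates; its sign is fixed deterministically.
    """
    _require_chlorin(p)
    coords = p.coords(list(atom_names))
    if len(coords) < 3:
        raise GeometryError(
            f"{p.node_id}: only {len(coords)} ring atoms, need >= 3")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:  # atoms collinear: plane undefined
        raise GeometryError(f"{p.node_id}: ring atoms are collinear")
    normal = _fix_normal_sign(vt[-1])
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(centroid=centroid, normal=normal, rmsd_from_plane=rmsd)


def interplane_angle(a: RingPlane, b: RingPlane) -> float:
    """Acute angle between two ring planes, degrees in [0, 90]."""
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def min_interatomic_distance(a: PigmentInstance, b: PigmentInstance
                             ) -> tuple[float, tuple[str, str]]:
    """Closest approach between two residues in Å, with the arg-min atom pair."""
    xa, xb = a.coords(), b.coords()
    if len(xa) == 0 or len(xb) == 0:
        raise GeometryError("residue with no atoms in distance query")
    d = cdist(xa, xb)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (a.atoms[i].atom_name, b.atoms[j].atom_name)


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Torsion of p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def polyene_dihedrals(p: PigmentInstance, chain_atom_names: list[str] | tuple[str, ...]
                      ) -> tuple[list[tuple[int, float]], list[str]]:
    """Backbone dihedral scan of a carotenoid polyene chain.

    For backbone atoms a_1..a_N (1-based along ``chain_atom_names``), bond i
    joins a_i and a_(i+1); its dihedral is the torsion a_(i-1)-a_i-a_(i+1)-a_(i+2),
    defined for 2 <= i <= N-2.  Missing backbone atoms are reported as gaps and
    the dihedrals spanning them are skipped.

    Returns (list of (bond_index, dihedral_degrees), list of missing atom names).
    """
    present = {a.atom_name: a.xyz for a in p.atoms}
    missing = [n for n in chain_atom_names if n not in present]
    names = list(chain_atom_names)
    if len(names) < 4:
        raise GeometryError("polyene backbone needs >= 4 atoms")
    out: list[tuple[int, float]] = []
    for i in range(2, len(names) - 1):  # bond index, 1-based
        quad = names[i - 2:i + 2]
        if any(n not in present for n in quad):
            continue
        out.append((i, dihedral_angle(*(present[n] for n in quad))))
    return out, missing


def classify_cis_trans(dihedrals: list[tuple[int, float]]) -> IsomerLabel:
    """Label a polyene all-trans or cis from its bond dihedrals.

    Bond i is cis iff |dihedral_i| <= 90° (the boundary maps to cis).
    """
    if not dihedrals:
        raise GeometryError("empty dihedral list")
    cis = [i for i, d in dihedrals if abs(d) <= 90.0]
    if cis:
        return IsomerLabel(configuration="cis", cis_positions=sorted(cis))
    return IsomerLabel(configuration="all-trans")


def kappa_squared(d: TransitionDipole, a: TransitionDipole) -> float:
    """Förster orientation factor κ² in [0, 4].

    κ = μ̂_D·μ̂_A − 3 (μ̂_D·R̂)(μ̂_A·R̂) with R̂ the unit donor→acceptor
    anchor separation.  Symmetric under donor/acceptor swap and under
    negation of either dipole.
    """
    r = a.anchor - d.anchor
    dist = np.linalg.norm(r)
    if dist < 1e-9:
        raise GeometryError("coincident dipole anchors")
    rhat = r / dist
    # multiply the two projections first so the result is exactly symmetric
    # under donor/acceptor swap (product commutes; 3*x*y would not)
    proj = float(np.dot(d.direction, rhat)) * float(np.dot(a.direction, rhat))
    kappa = float(np.dot(d.direction, a.direction)) - 3.0 * proj
    return kappa * kappa
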