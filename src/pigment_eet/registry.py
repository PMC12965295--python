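"""Chemical-component registry: residue codes -> pigment classes.

Maps heteroatom residue codes found in deposited photosystem models to the
pigment classes the pipeline understands, and records per-class metadata:
which atoms are required (and which define the Qy transition dipole of a
chlorin), the ordered carotenoid backbone, and average molecular masses used
by the inventory module.  Everything here is data, overridable from a YAML
mapping, because deposited models name pigments by chemical-component code
while the science names them chemically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Pigment classes
CHL_A = "CHL_A"
CHL_B = "CHL_B"
BCAR = "BCAR"
DDX = "DDX"
PQN = "PQN"
FE4S4 = "FE4S4"
LIPID = "LIPID"
OTHER = "OTHER"

CHLORIN_CLASSES = frozenset({CHL_A, CHL_B})
CAROTENOID_CLASSES = frozenset({BCAR, DDX})
#: classes counted as chromophores ("pigment molecules")
CHROMOPHORE_CLASSES = (CHL_A, CHL_B, BCAR, DDX)
#: classes counted as cofactors
COFACTOR_CLASSES = (CHL_A, CHL_B, BCAR, DDX, PQN, FE4S4, LIPID)

#: chlorin macrocycle nitrogens; Qy convention is the NB->ND axis
MACROCYCLE_N = ("NA", "NB", "NC", "ND")

#: atoms used for the ring-plane fit: the four N plus the inner ring carbons
RING_PLANE_ATOMS = (
    "NA", "NB", "NC", "ND",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C",
    "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

DEFAULT_CODE_MAP: dict[str, str] = {
    "CLA": CHL_A,
    "CHL": CHL_B,
    "BCR": BCAR,
    "DD6": DDX,
    "DDX": DDX,
    "PQN": PQN,
    "PHQ": PQN,
    "SF4": FE4S4,
    "SQD": LIPID,
    "LHG": LIPID,
    "LMG": LIPID,
    "DGD": LIPID,
}

# Average molecular masses (Da) of the cofactors, overridable.
DEFAULT_COFACTOR_MASSES: dict[str, float] = {
    "CLA": 893.49,   # chlorophyll a
    "CHL": 907.47,   # chlorophyll b
    "BCR": 536.87,   # beta-carotene
    "DD6": 582.85,   # diadinoxanthin
    "DDX": 582.85,
    "PQN": 450.70,   # phylloquinone
    "PHQ": 450.70,
    "SF4": 351.64,   # Fe4S4 cluster
    "SQD": 794.12,   # sulfoquinovosyl diacylglycerol
    "LHG": 722.96,   # phosphatidylglycerol
    "LMG": 768.17,   # monogalactosyl diacylglycerol
    "DGD": 930.37,   # digalactosyl diacylglycerol
}

# Average residue masses (Da, water already condensed out) of amino acids.
AMINO_ACID_RESIDUE_MASSES: dict[str, float] = {
    "GLY": 57.0519, "ALA": 71.0788, "SER": 87.0782, "PRO": 97.1167,
    "VAL": 99.1326, "THR": 101.1051, "CYS": 103.1388, "LEU": 113.1594,
    "ILE": 113.1594, "ASN": 114.1038, "ASP": 115.0886, "GLN": 128.1307,
    "LYS": 128.1741, "GLU": 129.1155, "MET": 131.1926, "HIS": 137.1411,
    "PHE": 147.1766, "ARG": 156.1875, "TYR": 163.1760, "TRP": 186.2132,
}
WATER_MASS = 18.0153

#: default carotenoid backbone atom order (conjugated chain)
DEFAULT_CAROTENOID_BACKBONE = tuple(f"C{i}" for i in range(1, 31))


@dataclass
class PigmentRegistry:
    """Residue-code to pigment-class mapping plus per-class atom conventions.

    Parameters
    ----------
    code_map
        residue_name -> pigment class.  Injective per residue name by
        construction (a dict).
    dipole_atoms
        Ordered atom pair defining the chlorin Qy axis (tail, head).
    cofactor_masses
        residue_name -> average mass in Da, used by the inventory module.
    carotenoid_backbone
        Ordered backbone atom names for polyene dihedral scans.
    """

    code_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CODE_MAP))
    dipole_atoms: tuple[str, str] = ("NB", "ND")
    cofactor_masses: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COFACTOR_MASSES))
    carotenoid_backbone: tuple[str, ...] = DEFAULT_CAROTENOID_BACKBONE

    def pigment_class(self, residue_name: str) -> str | None:
        return self.code_map.get(residue_name.strip().upper())

    def is_chlorin(self, residue_name: str) -> bool:
        return self.pigment_class(residue_name) in CHLORIN_CLASSES

    def required_atoms(self, pigment_class: str) -> tuple[str, ...]:
        """Atoms a pigment must carry to be geometrically usable.

        Chlorins need the Mg or the four macrocycle nitrogens; other classes
        only need at least one atom (checked elsewhere).
        """
        if pigment_class in CHLORIN_CLASSES:
            return ("MG",) + MACROCYCLE_N
        return ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PigmentRegistry":
        """Load overrides from a YAML mapping.

        Recognized keys: ``code_map``, ``dipole_atoms``, ``cofactor_masses``,
        ``carotenoid_backbone``.  Unspecified keys keep their defaults.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        reg = cls()
        if "code_map" in cfg:
            reg.code_map.update(
                {str(k).upper(): str(v).upper() for k, v in cfg["code_map"].items()})
        if "dipole_atoms" in cfg:
            pair = tuple(cfg["dipole_atoms"])
            if len(pair) != 2:
                raise ValueError("dipole_atoms must be a pair of atom names")
            reg.dipole_atoms = (str(pair[0]), str(pair[1]))
        if "cofactor_masses" in cfg:
            reg.cofactor_masses.update(
                {str(k).upper(): float(v) for k, v in cfg["cofactor_masses"].items()})
        if "carotenoid_backbone" in cfg:
            reg.carotenoid_backbone = tuple(
                str(a) for a in cfg["carotenoid_backbone"])
        return reg
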