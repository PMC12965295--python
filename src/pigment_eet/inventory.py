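"""Cofactor censuses, Chl a/b ratios, mass estimates and distance reports.

The census counts every registry-mapped heteroatom residue by pigment class
and chain.  Two headline totals are emitted, because the conventions differ:

* chromophores = Chl a + Chl b + β-Car + Ddx
* cofactors    = chromophores + phylloquinones + Fe4S4 clusters + lipids

and both definitions are printed in the output header so reported totals are
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geometry import min_interatomic_distance
from .registry import (
    AMINO_ACID_RESIDUE_MASSES,
    CHL_A,
    CHL_B,
    CHROMOPHORE_CLASSES,
    COFACTOR_CLASSES,
    WATER_MASS,
    PigmentRegistry,
)
from .structure import PigmentInstance, StructureModel, extract_pigments


@dataclass
class CofactorCensus:
    """Per-chain and total cofactor counts by pigment class."""

    per_chain: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    n_protein_chains: int = 0

    @property
    def n_chromophores(self) -> int:
        return sum(self.totals.get(c, 0) for c in CHROMOPHORE_CLASSES)

    @property
    def n_cofactors(self) -> int:
        return sum(self.totals.get(c, 0) for c in COFACTOR_CLASSES)

    def to_dataframe(self) -> pd.DataFrame:
        classes = list(COFACTOR_CLASSES)
        rows = [
            [chain] + [counts.get(c, 0) for c in classes]
            for chain, counts in sorted(self.per_chain.items())
        ]
        rows.append(["TOTAL"] + [self.totals.get(c, 0) for c in classes])
        return pd.DataFrame(rows, columns=["chain"] + classes)


def cofactor_census(model: StructureModel,
                    registry: PigmentRegistry | None = None) -> CofactorCensus:
    """Count registry-mapped residues by class and chain.

    Protein chains are chains containing at least one standard amino-acid
    residue.
    """
    registry = registry or PigmentRegistry()
    census = CofactorCensus()
    protein_chains: set[str] = set()
    for (chain_id, _resnum, resname), _atoms in model.residues():
        if resname in AMINO_ACID_RESIDUE_MASSES:
            protein_chains.add(chain_id)
        pclass = registry.pigment_class(resname)
        if pclass is None:
            continue
        census.per_chain.setdefault(chain_id, {})
        census.per_chain[chain_id][pclass] = \
            census.per_chain[chain_id].get(pclass, 0) + 1
        census.totals[pclass] = census.totals.get(pclass, 0) + 1
    census.n_protein_chains = len(protein_chains)
    return census


def chl_ab_ratio(census: CofactorCensus, chain: str) -> float | None:
    """Chl a / Chl b count ratio for one chain.

    Returns None (the "a-only" flag) when the chain binds no Chl b, as the
    Lhca-type antennae do.
    """
    if chain not in census.per_chain:
        raise KeyError(f"chain {chain!r} not in census")
    counts = census.per_chain[chain]
    n_a = counts.get(CHL_A, 0)
    n_b = counts.get(CHL_B, 0)
    if n_b == 0:
        return None
    return n_a / n_b


def mass_estimate(model: StructureModel,
                  registry: PigmentRegistry | None = None
                  ) -> tuple[float, list[str]]:
    """Total mass in kDa: polymer residues (average masses) + cofactors.

    Each protein chain contributes one condensation water.  Residues without
    a mass entry are listed in the gap report and excluded from the sum.
    """
    registry = registry or PigmentRegistry()
    total_da = 0.0
    gaps: list[str] = []
    chains_with_protein: set[str] = set()
    for (chain_id, resnum, resname), _atoms in model.residues():
        if resname in AMINO_ACID_RESIDUE_MASSES:
            total_da += AMINO_ACID_RESIDUE_MASSES[resname]
            chains_with_protein.add(chain_id)
        elif resname.upper() in registry.cofactor_masses:
            total_da += registry.cofactor_masses[resname.upper()]
        else:
            gaps.append(f"{chain_id}:{resnum}/{resname}")
    total_da += WATER_MASS * len(chains_with_protein)
    return total_da / 1000.0, gaps


def distance_report(model: StructureModel,
                    queries: list[tuple[str, str]],
                    registry: PigmentRegistry | None = None) -> pd.DataFrame:
    """Minimum interatomic distances for residue pair queries.

    Queries are ("chain:resnum", "chain:resnum") pairs; any residue in the
    model may be queried, not only registry-mapped ones.  Missing residues
    flag their row; a self query reports 0 with the self flag.
    """
    residues: dict[str, PigmentInstance] = {}
    for (chain_id, resnum, resname), atoms in model.residues():
        residues[f"{chain_id}:{resnum}"] = PigmentInstance(
            pigment_class="OTHER", chain_id=chain_id, residue_number=resnum,
            residue_name=resname, atoms=list(atoms))
    rows = []
    for qa, qb in queries:
        if qa not in residues or qb not in residues:
            rows.append((qa, qb, float("nan"), "", "", "missing-residue"))
            continue
        if qa == qb:
            rows.append((qa, qb, 0.0, "", "", "self"))
            continue
        d, (atom_a, atom_b) = min_interatomic_distance(
            residues[qa], residues[qb])
        rows.append((qa, qb, d, atom_a, atom_b, ""))
    return pd.DataFrame(
        rows, columns=["residue_a", "residue_b", "min_distance_A",
                       "atom_a", "atom_b", "flag"])


def census_report(census: CofactorCensus) -> str:
    """Human-readable census block, definitions stated in the header."""
    lines = [
        "# cofactor census",
        "# chromophores = CHL_A + CHL_B + BCAR + DDX",
        "# cofactors    = chromophores + PQN + FE4S4 + LIPID",
        f"protein_chains\t{census.n_protein_chains}",
        f"chromophores\t{census.n_chromophores}",
        f"cofactors\t{census.n_cofactors}",
    ]
    for cls in COFACTOR_CLASSES:
        lines.append(f"{cls}\t{census.totals.get(cls, 0)}")
    return "\n".join(lines)
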