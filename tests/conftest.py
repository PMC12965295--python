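"""Shared fixtures: small seeded synthetic structures and surfaces."""

import numpy as np
import pytest

from pigment_eet import (
    FretParams,
    StructureModel,
    make_chlorin,
    make_toy_complex,
)
from pigment_eet.structure import AtomRecord


@pytest.fixture
def toy_complex():
    """Small 2x3 chlorin complex with its brute-force edge table."""
    params = FretParams()
    model, truth = make_toy_complex(
        n_chains=2, chlorins_per_chain=3, seed=11, params=params)
    return model, truth, params


def _residue(chain, resnum, resname, atom_specs):
    return [AtomRecord(atom_name=n, element=e, xyz=xyz, residue_name=resname,
                       residue_number=resnum, chain_id=chain)
            for n, e, xyz in atom_specs]


def make_synthetic_supercomplex():
    """Synthetic stand-in for a deposited photosystem model (no accession is
    available), with a planted supercomplex-scale composition:

    - core chain Z: 88 Chl a, 13 beta-Car, 4 Ddx, 3 Fe4S4, 4 PQN
    - 16 antenna chains: 13 Chl-a-only chains (11-12 Chl a each), two mixed
      chains (14 a + 1 b; 13 a + 1 b), and one chain with 10 a + 4 b
      (the lowest-ratio antenna, a/b = 2.5)
    - 37 Ddx on the antenna chains, 24 lipids, and a short glycine peptide
      per chain so chains count as protein chains

    Totals: 276 Chl a, 6 Chl b, 13 beta-Car, 41 Ddx, 3 Fe4S4, 4 PQN,
    24 lipids = 336 chromophores, 367 cofactors.  Two marker residues are
    planted at closest approaches of 12.84 and 3.16 angstroms.
    """
    rng = np.random.default_rng(2026)
    model = StructureModel(metadata={"name": "synthetic_supercomplex"})
    ddx_left = 41 - 4 - 1  # 4 on the core, 1 planted Ddx624 marker

    def add_peptide(chain, n_res=3, origin=(0.0, 0.0, -50.0)):
        for i in range(n_res):
            base = np.asarray(origin, float) + [3.8 * i, 0, 0]
            model.atoms.extend(_residue(chain, i + 1, "GLY", [
                ("N", "N", base), ("CA", "C", base + [1.4, 0, 0]),
                ("C", "C", base + [2.4, 1.0, 0]), ("O", "O", base + [2.4, 2.2, 0]),
            ]))

    def add_point_residue(chain, resnum, resname, element, xyz):
        model.atoms.extend(_residue(chain, resnum, resname,
                                    [("C1", element, np.asarray(xyz, float))]))

    def add_chlorins(chain, n_a, n_b, origin):
        k = 0
        for kind_count, kind, resname in ((n_a, "CHL_A", "CLA"),
                                          (n_b, "CHL_B", "CHL")):
            for _ in range(kind_count):
                center = np.asarray(origin, float) + [9.0 * k, 0.0, 0.0]
                normal = rng.normal(size=3)
                qy = rng.normal(size=3)
                pig = make_chlorin(center, normal, qy, kind=kind,
                                   chain_id=chain, residue_number=601 + k)
                model.atoms.extend(pig.atoms)
                k += 1

    # core chain Z
    add_peptide("Z", origin=(0, 0, -60))
    core_origin = np.array([0.0, 0.0, 0.0])
    kk = 0
    for _ in range(88):
        center = core_origin + [9.0 * (kk % 12), 9.0 * (kk // 12), 0.0]
        pig = make_chlorin(center, rng.normal(size=3), rng.normal(size=3),
                           kind="CHL_A", chain_id="Z", residue_number=1101 + kk)
        model.atoms.extend(pig.atoms)
        kk += 1
    for i in range(12):  # 13th beta-Car is the planted BCR790 marker below
        add_point_residue("Z", 1301 + i, "BCR", "C", [9.0 * i, -12.0, 0.0])
    for i in range(4):
        add_point_residue("Z", 1401 + i, "DD6", "C", [9.0 * i, -18.0, 0.0])
    for i in range(3):
        add_point_residue("Z", 1501 + i, "SF4", "Fe", [9.0 * i, -24.0, 0.0])
    for i in range(4):
        add_point_residue("Z", 1601 + i, "PQN", "C", [9.0 * i, -30.0, 0.0])

    # antenna chains
    antenna = (
        [("A", 10, 4)]                       # a/b = 2.5 (LHCE 4-like)
        + [("B", 14, 1), ("C", 13, 1)]       # 14:1 and 13:1
        + [(c, 12, 0) for c in "DEFGHIJK"]   # Chl-a-only antennae
        + [(c, 11, 0) for c in "LMNOP"]
    )
    for idx, (chain, n_a, n_b) in enumerate(antenna):
        origin = (0.0, 20.0 + 12.0 * idx, 30.0)
        add_peptide(chain, origin=(0, 20.0 + 12.0 * idx, -60.0))
        add_chlorins(chain, n_a, n_b, origin)
    total_a = 88 + sum(n_a for _, n_a, _ in antenna)
    assert total_a == 276 and sum(n_b for *_, n_b in antenna) == 6

    # 36 antenna Ddx spread over the 16 antenna chains
    for i in range(ddx_left):
        chain = antenna[i % len(antenna)][0]
        add_point_residue(chain, 901 + i // len(antenna), "DD6", "C",
                          [150.0 + 9.0 * i, 0.0, 30.0])
    # 24 lipids on the core chain
    for i in range(24):
        code = ["SQD", "LHG", "LMG", "DGD"][i % 4]
        add_point_residue("Z", 1701 + i, code, "C", [9.0 * i, -36.0, 0.0])

    # planted distance markers: BCR790-like at 12.84 A from a Chl marker,
    # and a Ddx624-like head at 3.16 A from another Chl marker
    add_point_residue("Z", 790, "BCR", "C", [500.0, 0.0, 0.0])
    model.atoms.extend(_residue("Z", 791, "UNL",
                                [("M1", "C", np.array([500.0, 12.84, 0.0]))]))
    add_point_residue("A", 624, "DD6", "C", [520.0, 0.0, 0.0])
    model.atoms.extend(_residue("A", 793, "UNL",
                                [("M1", "C", np.array([520.0, 3.16, 0.0]))]))
    return model


@pytest.fixture(scope="session")
def synthetic_supercomplex():
    return make_synthetic_supercomplex()
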