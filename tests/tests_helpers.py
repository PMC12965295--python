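"""Small construction helpers shared across test modules."""

import numpy as np

from pigment_eet.structure import AtomRecord, PigmentInstance


def single_atom_residue(chain, resnum, xyz, resname="UNL", name="C1"):
    atom = AtomRecord(atom_name=name, element="C", xyz=np.asarray(xyz, float),
                      residue_name=resname, residue_number=resnum,
                      chain_id=chain)
    return PigmentInstance(pigment_class="OTHER", chain_id=chain,
                           residue_number=resnum, residue_name=resname,
                           atoms=[atom])


def isotropic_kappa_draws(rng, n):
    """Vectorized isotropic kappa^2 draws: random unit dipoles and separation."""
    mu_d = rng.normal(size=(n, 3))
    mu_d /= np.linalg.norm(mu_d, axis=1, keepdims=True)
    mu_a = rng.normal(size=(n, 3))
    mu_a /= np.linalg.norm(mu_a, axis=1, keepdims=True)
    rhat = rng.normal(size=(n, 3))
    rhat /= np.linalg.norm(rhat, axis=1, keepdims=True)
    kappa = (np.sum(mu_d * mu_a, axis=1)
             - 3 * np.sum(mu_d * rhat, axis=1) * np.sum(mu_a * rhat, axis=1))
    return kappa**2, mu_d, mu_a, rhat
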