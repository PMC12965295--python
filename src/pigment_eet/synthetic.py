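"""Seeded synthetic generators with serialized ground truth.

Every generator emulates just enough of the real data for the pipeline stage
it targets: chlorin macrocycles with prescribed centers/normals/Qy axes (so
dipole extraction can be inverted exactly), zig-zag polyenes with prescribed
cis bonds, multi-chain toy complexes with a brute-force Förster edge table as
ground truth, and TA surfaces that are sums of IRF-convolved exponentials
with Gaussian band shapes plus homoscedastic Gaussian noise.

All randomness flows from an integer seed; the same seed reproduces the same
object bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PackingError, ParameterError
from .fret import FretParams
from .geometry import TransitionDipole, kappa_squared
from .registry import CHL_A, CHL_B
from .structure import AtomRecord, PigmentInstance, StructureModel
from .tafit import TASurface, irf_decay

MG_N_DISTANCE = 2.05  # Å, typical chlorin Mg-N coordination


@dataclass
class GroundTruth:
    """True values planted by a generator, for oracle comparisons."""

    pigments: pd.DataFrame | None = None   # center / normal / qy per pigment
    edges: pd.DataFrame | None = None      # brute-force Förster edge table
    lifetimes: np.ndarray | None = None    # ps
    dads: np.ndarray | None = None         # (component, wavelength)
    extras: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.pigments is not None:
            self.pigments.to_csv(d / "truth_pigments.tsv", sep="\t", index=False)
        if self.edges is not None:
            self.edges.to_csv(d / "truth_edges.tsv", sep="\t", index=False)
        if self.lifetimes is not None:
            np.savetxt(d / "truth_lifetimes_ps.tsv", self.lifetimes)
        if self.dads is not None:
            np.savetxt(d / "truth_dads.tsv", self.dads, delimiter="\t")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("zero vector")
    return v / n


def _orthonormalize(normal: np.ndarray, qy: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    n = _unit(np.asarray(normal, dtype=float))
    q = np.asarray(qy, dtype=float)
    q = q - np.dot(q, n) * n  # project Qy into the ring plane
    return n, _unit(q)


def make_chlorin(center, normal, qy_direction, kind: str = CHL_A,
                 chain_id: str = "A", residue_number: int = 601
                 ) -> PigmentInstance:
    """Minimal chlorin: Mg at ``center``, four N at 2.05 Å in the ring plane
    with the NB→ND axis along ``qy_direction``, plus ring carbons for the
    plane fit.

    ``qy_direction`` is projected into the plane of ``normal`` so that the
    generator's Qy is exactly recoverable by the extraction ops.
    """
    if kind not in (CHL_A, CHL_B):
        raise ParameterError(f"kind must be CHL_A or CHL_B, got {kind!r}")
    center = np.asarray(center, dtype=float)
    n, q = _orthonormalize(normal, qy_direction)
    p = np.cross(n, q)  # in-plane axis perpendicular to Qy
    resname = "CLA" if kind == CHL_A else "CHL"

    def rec(name: str, element: str, xyz: np.ndarray) -> AtomRecord:
        return AtomRecord(atom_name=name, element=element, xyz=xyz,
                          residue_name=resname, residue_number=residue_number,
                          chain_id=chain_id)

    atoms = [
        rec("MG", "Mg", center),
        rec("NB", "N", center - MG_N_DISTANCE * q),
        rec("ND", "N", center + MG_N_DISTANCE * q),
        rec("NA", "N", center + MG_N_DISTANCE * p),
        rec("NC", "N", center - MG_N_DISTANCE * p),
    ]
    # inner-ring carbons: in-plane ring at 3.2 Å for a stable plane fit
    ring_names = ["CHA", "CHB", "CHC", "CHD",
                  "C1A", "C1B", "C1C", "C1D"]
    for k, name in enumerate(ring_names):
        ang = 2.0 * np.pi * (k + 0.5) / len(ring_names)
        atoms.append(rec(name, "C",
                         center + 3.2 * (np.cos(ang) * q + np.sin(ang) * p)))
    label = (f"a{residue_number}"
             if 600 <= residue_number <= 699 else
             f"{chain_id}:{residue_number}")
    return PigmentInstance(pigment_class=kind, chain_id=chain_id,
                           residue_number=residue_number,
                           residue_name=resname, atoms=atoms, label=label)


def make_polyene(n_bonds: int, cis_positions: list[int] | tuple[int, ...] = (),
                 chain_id: str = "X", residue_number: int = 701,
                 residue_name: str = "BCR") -> PigmentInstance:
    """Zig-zag polyene backbone: 180° dihedrals except 0° at ``cis_positions``.

    Bond i (1-based) joins backbone atoms C{i} and C{i+1}; a dihedral is
    defined for bonds 2..n_bonds-1, so those are the valid cis positions.
    """
    if n_bonds < 3:
        raise ParameterError("need at least 3 bonds")
    valid = range(2, n_bonds)
    for pos in cis_positions:
        if pos not in valid:
            raise ParameterError(
                f"cis position {pos} out of range [2, {n_bonds - 1}]")
    cis = set(cis_positions)
    bond, angle = 1.45, np.radians(120.0)
    coords = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    coords.append(coords[1] + bond * np.array(
        [-np.cos(angle), np.sin(angle), 0.0]))
    for k in range(3, n_bonds + 1):
        # placing atom k+1 sets the torsion about bond (k-1, k): index k-1
        torsion = 0.0 if (k - 1) in cis else np.pi
        a, b_, c = coords[k - 3], coords[k - 2], coords[k - 1]
        bc = _unit(c - b_)
        nvec = _unit(np.cross(b_ - a, bc))
        m = np.cross(nvec, bc)
        d2 = np.array([-bond * np.cos(angle),
                       bond * np.sin(angle) * np.cos(torsion),
                       bond * np.sin(angle) * np.sin(torsion)])
        coords.append(c + d2[0] * bc + d2[1] * m + d2[2] * nvec)
    atoms = [AtomRecord(atom_name=f"C{i + 1}", element="C", xyz=xyz,
                        residue_name=residue_name,
                        residue_number=residue_number, chain_id=chain_id)
             for i, xyz in enumerate(coords)]
    return PigmentInstance(pigment_class="BCAR" if residue_name == "BCR" else "DDX",
                           chain_id=chain_id, residue_number=residue_number,
                           residue_name=residue_name, atoms=atoms,
                           label=f"{chain_id}:{residue_number}")


def _random_frame(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random unit normal and in-plane Qy direction (uniform on the sphere)."""
    n = _unit(rng.normal(size=3))
    v = rng.normal(size=3)
    v -= np.dot(v, n) * n
    return n, _unit(v)


def oracle_edge_table(pigments_df: pd.DataFrame, params: FretParams
                      ) -> pd.DataFrame:
    """Brute-force all-pairs Förster edge table from planted centers/dipoles.

    Independent of the structure pipeline: works directly on the generator's
    planted vectors with an explicit double loop over ordered pairs.
    """
    rows = []
    ids = pigments_df["node_id"].tolist()
    centers = pigments_df[["cx", "cy", "cz"]].to_numpy(float)
    dipoles = pigments_df[["qx", "qy", "qz"]].to_numpy(float)
    classes = pigments_df["pigment_class"].tolist()
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i == j:
                continue
            rvec = centers[j] - centers[i]
            R = float(np.linalg.norm(rvec))
            if R > params.r_max:
                continue
            k2 = kappa_squared(
                TransitionDipole(anchor=centers[i], direction=dipoles[i]),
                TransitionDipole(anchor=centers[j], direction=dipoles[j]))
            k = params.C(classes[i], classes[j]) * k2 / (params.n ** 4 * R ** 6)
            if k <= 0:
                continue
            rows.append((ids[i], ids[j], R, k2, k, 1.0 / k))
    return pd.DataFrame(rows, columns=["donor", "acceptor", "R_A", "kappa2",
                                       "k_per_ps", "tau_ps"])


def make_toy_complex(n_chains: int = 2, chlorins_per_chain: int | tuple[int, int] = 3,
                     box: float = 60.0, min_sep: float = 8.0,
                     seed: int = 0, chl_b_fraction: float = 0.0,
                     params: FretParams | None = None,
                     max_attempts: int = 200_000
                     ) -> tuple[StructureModel, GroundTruth]:
    """Random multi-chain chlorin complex with a known Förster edge table.

    Chlorins are placed uniformly in a cubic box of edge ``box`` Å by
    rejection sampling with Mg–Mg separation ≥ ``min_sep``; orientations are
    isotropic.  Ground truth carries the planted centers/normals/Qy axes and
    the brute-force edge table under ``params`` (default :class:`FretParams`).
    """
    rng = np.random.default_rng(seed)
    params = params or FretParams()
    if isinstance(chlorins_per_chain, tuple):
        counts = [int(rng.integers(chlorins_per_chain[0],
                                   chlorins_per_chain[1] + 1))
                  for _ in range(n_chains)]
    else:
        counts = [int(chlorins_per_chain)] * n_chains
    chain_ids = [_chain_name(i) for i in range(n_chains)]
    centers: list[np.ndarray] = []
    rows = []
    model = StructureModel(metadata={"name": f"toy_complex_seed{seed}"})
    attempts = 0
    for chain_id, count in zip(chain_ids, counts):
        for k in range(count):
            while True:
                attempts += 1
                if attempts > max_attempts:
                    raise PackingError(
                        f"cannot place {sum(counts)} chlorins at "
                        f"min_sep={min_sep} in box={box}")
                c = rng.uniform(0.0, box, size=3)
                if all(np.linalg.norm(c - o) >= min_sep for o in centers):
                    break
            centers.append(c)
            normal, qy = _random_frame(rng)
            kind = CHL_B if rng.uniform() < chl_b_fraction else CHL_A
            resnum = 601 + k
            pig = make_chlorin(c, normal, qy, kind=kind, chain_id=chain_id,
                               residue_number=resnum)
            model.atoms.extend(pig.atoms)
            rows.append((f"{chain_id}:{resnum}", chain_id, resnum, kind,
                         *c, *qy, *normal))
    pigments_df = pd.DataFrame(rows, columns=[
        "node_id", "chain", "resnum", "pigment_class",
        "cx", "cy", "cz", "qx", "qy", "qz", "nx", "ny", "nz"])
    truth = GroundTruth(pigments=pigments_df,
                        edges=oracle_edge_table(pigments_df, params),
                        extras={"seed": seed, "params": params})
    return model, truth


def make_psi_like_complex(seed: int = 0, params: FretParams | None = None
                          ) -> tuple[StructureModel, GroundTruth]:
    """Toy complex echoing the supercomplex architecture: 16 antenna chains of
    8–16 chlorins around one 88-chlorin core chain."""
    rng = np.random.default_rng(seed)
    params = params or FretParams()
    model_a, truth_a = make_toy_complex(
        n_chains=16, chlorins_per_chain=(8, 16), box=110.0, min_sep=8.0,
        seed=int(rng.integers(2**31)), params=params)
    model_c, truth_c = make_toy_complex(
        n_chains=1, chlorins_per_chain=88, box=60.0, min_sep=8.0,
        seed=int(rng.integers(2**31)), params=params)
    # relabel the core chain and offset it so the two boxes do not collide
    offset = np.array([130.0, 25.0, 25.0])
    for a in model_c.atoms:
        a.chain_id = "Z"
        a.xyz = a.xyz + offset
    core_df = truth_c.pigments.copy()
    core_df["chain"] = "Z"
    core_df["node_id"] = "Z:" + core_df["resnum"].astype(str)
    core_df[["cx", "cy", "cz"]] += offset
    pigments_df = pd.concat([truth_a.pigments, core_df], ignore_index=True)
    model = StructureModel(atoms=model_a.atoms + model_c.atoms,
                           metadata={"name": f"psi_like_seed{seed}"})
    truth = GroundTruth(pigments=pigments_df,
                        edges=oracle_edge_table(pigments_df, params),
                        extras={"seed": seed, "params": params})
    return model, truth


def _chain_name(i: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXY"  # Z reserved for the core
    if i < len(alphabet):
        return alphabet[i]
    return alphabet[i % len(alphabet)] + str(i // len(alphabet))


def gaussian_band(wavelengths: np.ndarray, center: float, width: float,
                  amplitude: float) -> np.ndarray:
    """Gaussian spectral band; sign of ``amplitude`` distinguishes
    excited-state absorption (+) from ground-state bleach (−)."""
    wl = np.asarray(wavelengths, dtype=float)
    return amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)


#: five-component convention used for reproduction runs: lifetimes (ps) and
#: DADS bands (center nm, width nm, amplitude ΔOD).  The dominant ~72 ps
#: trapping component carries the largest amplitude.
EGRACILIS_LIFETIMES_PS = (0.36, 3.0, 15.0, 72.0, 2500.0)
EGRACILIS_DADS_BANDS = (
    (676.0, 9.0, 6.0e-3),
    (705.0, 10.0, 3.0e-3),
    (690.0, 12.0, -2.5e-3),
    (682.0, 10.0, 1.0e-2),
    (672.0, 8.0, 1.5e-3),
)


def simulate_ta(lifetimes, dads_spec, delays, wavelengths,
                irf_sigma: float = 0.1, noise_sd: float = 0.0,
                seed: int = 0, t0: float = 0.0,
                chirp_coefficients=None) -> tuple[TASurface, GroundTruth]:
    """Synthetic TA surface: Σ_i DADS_i(λ) · irf_decay(t, τ_i) + noise.

    ``dads_spec`` is either a list of (center nm, width nm, amplitude) band
    triples (one per component) or a ready (n_components, n_wavelengths)
    array.  ``chirp_coefficients`` optionally add a polynomial per-wavelength
    t0 shift, for dispersion-correction tests.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if np.any(lifetimes <= 0):
        raise ParameterError("lifetimes must be positive")
    if np.unique(lifetimes).size != lifetimes.size:
        raise ParameterError("lifetimes must be distinct")
    delays = np.asarray(delays, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(dads_spec, dtype=object)
    if spec.ndim == 2 and spec.shape == (lifetimes.size, wavelengths.size):
        dads = np.asarray(dads_spec, dtype=float)
    else:
        if len(dads_spec) != lifetimes.size:
            raise ParameterError("one DADS band per lifetime required")
        dads = np.array([gaussian_band(wavelengths, c, w, a)
                         for c, w, a in dads_spec])
    rng = np.random.default_rng(seed)
    shifts = (np.polyval(np.asarray(chirp_coefficients, dtype=float)[::-1],
                         wavelengths)
              if chirp_coefficients is not None else np.zeros_like(wavelengths))
    dA = np.zeros((delays.size, wavelengths.size))
    for j in range(wavelengths.size):
        for i, tau in enumerate(lifetimes):
            dA[:, j] += dads[i, j] * irf_decay(delays, float(tau),
                                               t0 + shifts[j], irf_sigma)
    if noise_sd > 0:
        dA = dA + rng.normal(0.0, noise_sd, size=dA.shape)
    surface = TASurface(delays=delays, wavelengths=wavelengths, dA=dA,
                        irf_sigma=irf_sigma, t0=t0)
    truth = GroundTruth(lifetimes=lifetimes, dads=dads,
                        extras={"seed": seed, "noise_sd": noise_sd,
                                "t0": t0, "irf_sigma": irf_sigma})
    return surface, truth


def default_ta_axes() -> tuple[np.ndarray, np.ndarray]:
    """Reproduction-run axes: 150 log-spaced delays 0.05 ps – 7 ns,
    60 wavelengths 640–760 nm."""
    return (np.geomspace(0.05, 7000.0, 150), np.linspace(640.0, 760.0, 60))
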