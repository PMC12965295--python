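"""Pairwise Förster rates and the excitation-energy-transfer network.

The rate between two chlorins in the point-dipole approximation is

    k_FRET = C κ² / (n⁴ R⁶)

with R the Mg–Mg distance in Å, κ² the orientation factor, n the refractive
index and C an overlap-integral factor per (donor class, acceptor class) pair
in units of rate·Å⁶ so that k comes out in ps⁻¹.  C and n are inputs: only
relative rate structure is meaningful under the default C = 1.

The network is a directed graph over non-degenerate chlorins; κ² = 0 pairs
are excluded so that path search terminates cleanly.  Path cost between
subunits is the summed per-hop transfer time Σ τ = Σ 1/k (mean first-passage
along a chain under irreversible hopping); an alternative −log branching-
probability cost is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GeometryError, GroupingError
from .geometry import (
    TransitionDipole,
    interplane_angle,
    kappa_squared,
    magnesium_center,
    qy_dipole,
    ring_plane,
)
from .registry import CHL_A, CHLORIN_CLASSES
from .structure import PigmentInstance

EDGE_COLUMNS = ["donor", "acceptor", "R_A", "kappa2", "k_per_ps", "tau_ps"]


@dataclass
class FretParams:
    """Förster-rate parameters.

    ``coupling`` maps (donor_class, acceptor_class) -> C in ps⁻¹·Å⁶; a plain
    float applies one C to every chlorin pair.  ``n`` is the refractive
    index, ``r_max`` the Mg–Mg cutoff (Å) for edge inclusion.
    """

    coupling: float | dict[tuple[str, str], float] = 1.0
    n: float = 1.55
    r_max: float = 30.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.r_max <= 0:
            raise ValueError("n and r_max must be positive")
        if isinstance(self.coupling, (int, float)):
            if self.coupling <= 0:
                raise ValueError("C must be positive")
        elif any(v <= 0 for v in self.coupling.values()):
            raise ValueError("all C values must be positive")

    def C(self, donor_class: str, acceptor_class: str) -> float:
        if isinstance(self.coupling, dict):
            try:
                return self.coupling[(donor_class, acceptor_class)]
            except KeyError:
                raise KeyError(
                    f"no coupling factor for ({donor_class}, {acceptor_class})")
        return float(self.coupling)


@dataclass
class EETEdge:
    """One directed donor→acceptor transfer: distance, κ², rate, transfer time."""

    donor: str
    acceptor: str
    R: float
    kappa2: float
    k_fret: float
    tau_transfer: float


@dataclass
class EETNetwork:
    """Directed weighted pigment graph with rate-constant edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[EETEdge]:
        return [
            EETEdge(u, v, d["R"], d["kappa2"], d["k_fret"], d["tau"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(e.donor, e.acceptor, e.R, e.kappa2, e.k_fret, e.tau_transfer)
                for e in self.edges]
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def pair_rate(d: TransitionDipole, a: TransitionDipole, params: FretParams,
              classes: tuple[str, str] = (CHL_A, CHL_A),
              ids: tuple[str, str] = ("donor", "acceptor")) -> EETEdge:
    """Förster rate for one donor→acceptor pair: k = C κ² / (n⁴ R⁶)."""
    r_vec = a.anchor - d.anchor
    R = float(np.linalg.norm(r_vec))
    if R < 1e-9:
        raise GeometryError("coincident anchors in pair_rate")
    k2 = kappa_squared(d, a)
    C = params.C(*classes)
    k = C * k2 / (params.n ** 4 * R ** 6)
    tau = math.inf if k == 0 else 1.0 / k
    return EETEdge(donor=ids[0], acceptor=ids[1], R=R, kappa2=k2,
                   k_fret=k, tau_transfer=tau)


def _chlorin_dipoles(pigments: list[PigmentInstance],
                     dipole_atoms: tuple[str, str]
                     ) -> list[tuple[PigmentInstance, TransitionDipole]]:
    out = []
    for p in pigments:
        if p.pigment_class in CHLORIN_CLASSES and not p.degenerate:
            out.append((p, qy_dipole(p, dipole_atoms)))
    return out


def build_network(pigments: list[PigmentInstance], params: FretParams,
                  dipole_atoms: tuple[str, str] = ("NB", "ND")) -> EETNetwork:
    """All-pairs EET network over the non-degenerate chlorins.

    Ordered pairs with Mg–Mg distance ≤ r_max and κ² > 0 become directed
    edges; node order is deterministic (chain, residue number).
    """
    entries = _chlorin_dipoles(pigments, dipole_atoms)
    entries.sort(key=lambda pd_: (pd_[0].chain_id, pd_[0].residue_number))
    net = EETNetwork()
    for p, _ in entries:
        net.graph.add_node(p.node_id, chain=p.chain_id,
                           resnum=p.residue_number, label=p.label,
                           pigment_class=p.pigment_class)
    for i, (pi, di) in enumerate(entries):
        for j, (pj, dj) in enumerate(entries):
            if i == j:
                continue
            R = float(np.linalg.norm(dj.anchor - di.anchor))
            if R > params.r_max:
                continue
            edge = pair_rate(di, dj, params,
                             classes=(pi.pigment_class, pj.pigment_class),
                             ids=(pi.node_id, pj.node_id))
            if edge.k_fret <= 0.0:
                continue  # non-transferring (kappa2 == 0)
            net.graph.add_edge(pi.node_id, pj.node_id, R=edge.R,
                               kappa2=edge.kappa2, k_fret=edge.k_fret,
                               tau=edge.tau_transfer)
    return net


def intersubunit_matrix(net: EETNetwork, grouping: dict[str, str]) -> pd.DataFrame:
    """Summed donor→acceptor rates between subunits; diagonal zero.

    ``grouping`` maps every node id to a subunit name; an ungrouped node is
    an error.
    """
    for node in net.graph.nodes:
        if node not in grouping:
            raise GroupingError(f"node {node} has no subunit assignment")
    subunits = sorted(set(grouping.values()))
    mat = pd.DataFrame(0.0, index=subunits, columns=subunits)
    for u, v, d in net.graph.edges(data=True):
        su, sv = grouping[u], grouping[v]
        if su != sv:
            mat.loc[su, sv] += d["k_fret"]
    return mat


def fastest_paths(net: EETNetwork, source_subunit: str, sink_subunit: str,
                  k_paths: int, grouping: dict[str, str] | None = None,
                  cost: str = "time") -> list[tuple[list[str], float]]:
    """Up to ``k_paths`` fastest inter-subunit transfer routes.

    Cost along a path is Σ τ = Σ 1/k per hop (``cost="time"``), or
    Σ −log(branching probability) with ``cost="neglog_prob"``.  Ties are
    broken by fewer hops, then lexicographic node order.  Returns
    (node path, cost) pairs; empty list when no route exists.
    """
    if grouping is None:
        grouping = {n: d["chain"] for n, d in net.graph.nodes(data=True)}
    sources = [n for n in net.graph.nodes if grouping.get(n) == source_subunit]
    sinks = [n for n in net.graph.nodes if grouping.get(n) == sink_subunit]
    if not sources or not sinks:
        raise GroupingError(
            f"empty subunit: {source_subunit!r} or {sink_subunit!r}")
    G = nx.DiGraph()
    for u, v, d in net.graph.edges(data=True):
        if cost == "time":
            w = d["tau"]
        elif cost == "neglog_prob":
            out_k = sum(dd["k_fret"] for _, _, dd in
                        net.graph.out_edges(u, data=True))
            w = -math.log(d["k_fret"] / out_k)
        else:
            raise ValueError(f"unknown cost {cost!r}")
        G.add_edge(u, v, w=w)
    SRC, SNK = "\x00src", "\x00snk"
    for s in sources:
        if s in G:
            G.add_edge(SRC, s, w=0.0)
    for t in sinks:
        if t in G:
            G.add_edge(t, SNK, w=0.0)
    if SRC not in G or SNK not in G or not nx.has_path(G, SRC, SNK):
        return []

    # Yen's algorithm via networkx, over-collect to resolve cost ties
    # deterministically, then re-rank by (cost, hops, lexicographic path).
    candidates: list[tuple[float, int, list[str]]] = []
    kth_cost = math.inf
    for path in nx.shortest_simple_paths(G, SRC, SNK, weight="w"):
        inner = path[1:-1]
        c = sum(G[u][v]["w"] for u, v in zip(path[:-1], path[1:]))
        if len(candidates) >= k_paths and c > kth_cost + 1e-12:
            break
        candidates.append((c, len(inner), inner))
        if len(candidates) >= k_paths:
            kth_cost = sorted(candidates)[k_paths - 1][0]
        if len(candidates) > 50 * max(k_paths, 1):
            break
    ranked = sorted(candidates)[:k_paths]
    return [(p, c) for c, _, p in ranked]


def detect_red_pairs(pigments: list[PigmentInstance], d_max: float = 10.0,
                     angle_max: float = 35.0) -> pd.DataFrame:
    """Candidate red-Chl pairs: tightly coupled, near-coplanar Chl a dimers.

    Reports each unordered Chl a pair whose Mg–Mg distance is ≤ ``d_max`` Å
    and whose ring planes are within ``angle_max`` degrees — the geometry of
    the a603–a609-type dimers responsible for far-red absorption.
    """
    chl_a = [p for p in pigments
             if p.pigment_class == CHL_A and not p.degenerate]
    chl_a.sort(key=lambda p: (p.chain_id, p.residue_number))
    anchors = [magnesium_center(p) for p in chl_a]
    planes = [ring_plane(p) for p in chl_a]
    rows = []
    for i in range(len(chl_a)):
        for j in range(i + 1, len(chl_a)):
            R = float(np.linalg.norm(anchors[j] - anchors[i]))
            if R > d_max:
                continue
            ang = interplane_angle(planes[i], planes[j])
            if ang > angle_max:
                continue
            rows.append((chl_a[i].node_id, chl_a[j].node_id,
                         chl_a[i].label, chl_a[j].label, R, ang))
    return pd.DataFrame(
        rows, columns=["a", "b", "label_a", "label_b",
                       "mg_mg_A", "interplane_deg"])
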