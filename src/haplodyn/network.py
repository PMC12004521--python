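"""Occurrence-weighted protein structure networks and protein-DNA interfaces.

A protein structure network (PSN) has residues as nodes and noncovalent
interactions as edges.  Edges are detected frame by frame with geometric
criteria for three interaction types (hydrogen bond, salt bridge,
hydrophobic), weighted by *occurrence* — the fraction of sampled frames in
which the interaction is present — combined across types by taking the
maximum occurrence per edge, and binarised at an occurrence cutoff (strict
``>``, default 20%).  Unweighted networks are compared with the Jaccard
similarity of their edge sets.

Protein-DNA interfaces are summarised as residue x nucleotide contact maps:
atom-pair contacts are scored 1 below an inner cutoff (4 A), 0 beyond an
outer cutoff (5 A), and ramped smoothly in between (cosine switch by
default, pluggable), then summed per residue-nucleotide pair and rounded to
the nearest integer.

Geometric criteria (all configurable through :class:`ContactParams`):
salt bridge — any pair of oppositely charged side-chain group atoms within
4.5 A; hydrogen bond — donor-acceptor distance <= 3.5 A and donor-H-acceptor
angle >= 120 deg; hydrophobic — side-chain centres of mass of apolar
residues within 5 A.  Sequence-adjacent residue pairs are never edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from haplodyn.core import SelectionError, TopologyError, Trajectory, RegionSelection
from haplodyn.geometry import angle_between

__all__ = [
    "ContactParams",
    "contact_weight",
    "dna_contact_map",
    "detect_edges",
    "occurrence_network",
    "combine_max",
    "binarize",
    "jaccard",
    "occurrence_difference",
    "pair_distance_occurrence",
    "INTERACTION_TYPES",
]

INTERACTION_TYPES = ("hydrogen-bond", "salt-bridge", "hydrophobic")

BACKBONE_NAMES = {"N", "H", "CA", "C", "O", "OXT", "HA", "H1", "H2", "H3"}

# charged side-chain group atoms (positively / negatively charged residues)
POSITIVE_GROUP = {"ARG": ("NH1", "NH2", "NE", "CZ"), "LYS": ("NZ",),
                  "HIS": ("ND1", "NE2"), "HSP": ("ND1", "NE2")}
NEGATIVE_GROUP = {"ASP": ("OD1", "OD2", "CG"), "GLU": ("OE1", "OE2", "CD")}

# apolar residues whose side-chain centres of mass define hydrophobic contacts
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP"}


def cosine_switch(d: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """Smooth switch: 1 at d<=inner, 0 at d>=outer, half-cosine ramp between."""
    t = np.clip((np.asarray(d, dtype=float) - inner) / (outer - inner), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


@dataclass(frozen=True)
class ContactParams:
    """Geometric criteria and sampling settings for interaction detection."""

    inner_cutoff: float = 4.0
    outer_cutoff: float = 5.0
    salt_bridge_cutoff: float = 4.5
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_cutoff: float = 5.0
    occurrence_cutoff: float = 0.2
    network_stride_ps: float = 100.0
    switch: Callable[[np.ndarray, float, float], np.ndarray] = field(
        default=cosine_switch, compare=False
    )

    def __post_init__(self) -> None:
        if self.inner_cutoff >= self.outer_cutoff:
            raise ValueError("inner cutoff must be below outer cutoff")
        for name in ("inner_cutoff", "outer_cutoff", "salt_bridge_cutoff",
                     "hbond_distance", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def contact_weight(d, params: ContactParams | None = None):
    """Smooth contact weight in [0, 1]: 1 below the inner cutoff, 0 beyond the
    outer cutoff, continuous and decreasing in between (pluggable switch)."""
    params = params or ContactParams()
    scalar = np.isscalar(d)
    w = params.switch(np.atleast_1d(np.asarray(d, dtype=float)), params.inner_cutoff,
                      params.outer_cutoff)
    return float(w[0]) if scalar else w


# --------------------------------------------------------- DNA contact map

def dna_contact_map(traj: Trajectory, frame: int,
                    protein_selection: RegionSelection,
                    dna_selection: RegionSelection,
                    params: ContactParams | None = None,
                    atom_whitelist: set[tuple[int, str]] | None = None) -> "pd.DataFrame":
    """Residue x nucleotide integer contact map for one frame.

    Atom-pair smooth weights are summed per residue-nucleotide pair and
    rounded to the nearest integer.  ``atom_whitelist`` (full_resid, atom
    name) restricts mutated residues to atoms common to all compared systems.
    """
    import pandas as pd

    params = params or ContactParams()
    pmask = traj.atom_mask(protein_selection)
    dmask = traj.atom_mask(dna_selection)
    if atom_whitelist is not None:
        keep = np.asarray([
            (r, a) in atom_whitelist
            for r, a in zip(traj.full_resids, traj.atom_names)
        ])
        pmask = pmask & keep
        if not pmask.any():
            raise SelectionError("atom whitelist removed every protein atom")
    coords = traj.coordinates[frame]
    d = cdist(coords[pmask], coords[dmask])
    w = params.switch(d, params.inner_cutoff, params.outer_cutoff)
    pres = traj.full_resids[pmask]
    dres = traj.full_resids[dmask]
    prows = np.unique(pres)
    dcols = np.unique(dres)
    out = np.zeros((len(prows), len(dcols)))
    for i, r in enumerate(prows):
        wi = w[pres == r]
        for j, c in enumerate(dcols):
            out[i, j] = wi[:, dres == c].sum()
    return pd.DataFrame(np.rint(out).astype(int), index=prows, columns=dcols)


# --------------------------------------------------------- edge detection

def _sidechain_mask(traj: Trajectory) -> np.ndarray:
    return ~np.isin(np.asarray(traj.atom_names, dtype=str), sorted(BACKBONE_NAMES))


def _group_atoms(traj: Trajectory, table: dict[str, tuple[str, ...]]) -> dict[int, np.ndarray]:
    """Map full resid -> atom indices of its charged-group atoms."""
    groups: dict[int, list[int]] = {}
    for idx, (resid, resname, aname) in enumerate(
            zip(traj.full_resids, traj.resnames, traj.atom_names)):
        wanted = table.get(str(resname))
        if wanted and str(aname) in wanted:
            groups.setdefault(int(resid), []).append(idx)
    return {r: np.asarray(ix) for r, ix in groups.items()}


def detect_edges(traj: Trajectory, frame: int, kind: str,
                 params: ContactParams | None = None) -> set[tuple[int, int]]:
    """Residue pairs interacting in one frame, as sorted (i, j) full resids.

    Sequence-adjacent pairs (|i - j| <= 1) are excluded for every type.
    """
    params = params or ContactParams()
    coords = traj.coordinates[frame]
    edges: set[tuple[int, int]] = set()

    if kind == "salt-bridge":
        pos = _group_atoms(traj, POSITIVE_GROUP)
        neg = _group_atoms(traj, NEGATIVE_GROUP)
        for rp, ip in pos.items():
            for rn, jn in neg.items():
                if abs(rp - rn) <= 1:
                    continue
                if cdist(coords[ip], coords[jn]).min() < params.salt_bridge_cutoff:
                    edges.add(tuple(sorted((rp, rn))))
    elif kind == "hydrogen-bond":
        names = np.asarray(traj.atom_names, dtype=str)
        elements = np.asarray(traj.elements, dtype=str)
        resids = traj.full_resids
        h_idx = np.flatnonzero(elements == "H")
        heavy_idx = np.flatnonzero(np.isin(elements, ["N", "O"]))
        if len(h_idx) and len(heavy_idx):
            dh = cdist(coords[h_idx], coords[heavy_idx])
            donors = []  # (donor heavy, hydrogen)
            for hi, row in zip(h_idx, dh):
                near = heavy_idx[row < 1.2]
                if len(near):
                    donors.append((int(near[np.argmin(row[row < 1.2])]), int(hi)))
            acceptors = [int(a) for a in heavy_idx]
            for d_atom, h_atom in donors:
                for a_atom in acceptors:
                    if a_atom == d_atom:
                        continue
                    ri, rj = int(resids[d_atom]), int(resids[a_atom])
                    if abs(ri - rj) <= 1:
                        continue
                    if np.linalg.norm(coords[d_atom] - coords[a_atom]) > params.hbond_distance:
                        continue
                    ang = angle_between(coords[d_atom], coords[h_atom], coords[a_atom])
                    if ang >= params.hbond_angle:
                        edges.add(tuple(sorted((ri, rj))))
    elif kind == "hydrophobic":
        side = _sidechain_mask(traj)
        centres: dict[int, np.ndarray] = {}
        for r in np.unique(traj.full_resids):
            rmask = (traj.full_resids == r) & side
            resname = str(traj.resnames[traj.full_resids == r][0])
            if resname in HYDROPHOBIC_RESIDUES and rmask.any():
                centres[int(r)] = coords[rmask].mean(axis=0)
        keys = sorted(centres)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ri, rj = keys[a], keys[b]
                if abs(ri - rj) <= 1:
                    continue
                if np.linalg.norm(centres[ri] - centres[rj]) < params.hydrophobic_cutoff:
                    edges.add((ri, rj))
    else:
        raise TypeError(f"unknown interaction type {kind!r}; expected one of {INTERACTION_TYPES}")
    return edges


# ------------------------------------------------------ occurrence network

def occurrence_network(traj: Trajectory, kind: str,
                       params: ContactParams | None = None) -> nx.Graph:
    """Occurrence-weighted network of one interaction type.

    Frames are sampled at ``params.network_stride_ps``; each edge's weight is
    the fraction of sampled frames where it is detected.  Apply any
    equilibration cut (``Trajectory.discard_initial_ns``) before calling.
    """
    params = params or ContactParams()
    sub = traj.stride_frames(params.network_stride_ps)
    if sub.n_frames == 0:
        raise ValueError("no frames to analyse")
    counts: dict[tuple[int, int], int] = {}
    for f in range(sub.n_frames):
        for e in detect_edges(sub, f, kind, params):
            counts[e] = counts.get(e, 0) + 1
    g = nx.Graph(interaction=kind, n_frames=sub.n_frames)
    g.add_nodes_from(int(r) for r in np.unique(sub.full_resids))
    for (i, j), c in counts.items():
        g.add_edge(i, j, occurrence=c / sub.n_frames, interaction=kind)
    return g


def combine_max(networks: Iterable[nx.Graph]) -> nx.Graph:
    """Merge per-type networks: per edge, keep the maximum occurrence across
    types and record the winning type."""
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one network")
    nodes = set(networks[0].nodes)
    for g in networks[1:]:
        if set(g.nodes) != nodes:
            raise ValueError("networks have different node sets")
    out = nx.Graph(interaction="combined")
    out.add_nodes_from(sorted(nodes))
    for g in networks:
        for i, j, data in g.edges(data=True):
            occ = data["occurrence"]
            if out.has_edge(i, j) and out[i][j]["occurrence"] >= occ:
                continue
            out.add_edge(i, j, occurrence=occ, interaction=data.get("interaction", "?"))
    return out


def binarize(net: nx.Graph, cutoff: float = 0.2) -> nx.Graph:
    """Unweighted network keeping edges with occurrence strictly above cutoff."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((i, j) for i, j, d in net.edges(data=True)
                     if d["occurrence"] > cutoff)
    return g


def jaccard(g1: nx.Graph, g2: nx.Graph) -> float:
    """|E1 n E2| / |E1 u E2| over undirected edge sets; 1.0 when both empty."""
    e1 = {frozenset(e) for e in g1.edges}
    e2 = {frozenset(e) for e in g2.edges}
    union = e1 | e2
    if not union:
        return 1.0
    return len(e1 & e2) / len(union)


def occurrence_difference(net_a: nx.Graph, net_b: nx.Graph,
                          focus_nodes: Iterable[int] | None = None
                          ) -> dict[tuple[int, int], float]:
    """Signed occurrence differences A - B on edges touching ``focus_nodes``
    (all edges when None); an edge missing from one network counts as 0."""
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share node labels")
    focus = set(focus_nodes) if focus_nodes is not None else None
    edges = {frozenset(e) for e in net_a.edges} | {frozenset(e) for e in net_b.edges}
    out = {}
    for e in edges:
        i, j = sorted(e)
        if focus is not None and not (i in focus or j in focus):
            continue
        a = net_a[i][j]["occurrence"] if net_a.has_edge(i, j) else 0.0
        b = net_b[i][j]["occurrence"] if net_b.has_edge(i, j) else 0.0
        if a != b or focus is None:
            out[(i, j)] = a - b
    return out


def pair_distance_occurrence(traj: Trajectory,
                             atom_pair: tuple[tuple[int, str], tuple[int, str]],
                             threshold: float,
                             stride_ps: float | None = None) -> float:
    """Fraction of (sampled) frames where the pair distance is below threshold."""
    sub = traj.stride_frames(stride_ps) if stride_ps else traj
    (r1, a1), (r2, a2) = atom_pair
    i = sub.atom_index(r1, a1)
    j = sub.atom_index(r2, a2)
    d = np.linalg.norm(sub.coordinates[:, i] - sub.coordinates[:, j], axis=1)
    return float(np.mean(d < threshold))


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a network as an edge-list CSV (i, j, occurrence, interaction)."""
    import pandas as pd

    rows = [{"i": i, "j": j, "occurrence": d.get("occurrence", 1.0),
             "interaction": d.get("interaction", "")}
            for i, j, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["i", "j", "occurrence", "interaction"]).to_csv(
        path, index=False)
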