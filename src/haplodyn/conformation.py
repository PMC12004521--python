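"""Essential-dynamics comparison and conformational clustering.

Essential dynamics: principal component analysis of aligned alpha-carbon
coordinates; two trajectories' essential subspaces (the first D = 30
components) are compared with the root mean square inner product

    RMSIP(U, V) = sqrt( (1/D) * sum_ij (u_i . v_j)^2 ),

which is 1 for identical subspaces and 0 for orthogonal ones.

Conformations are clustered with the density-peaks machinery of
``haplodyn.dpclustering`` on either backbone phi/psi dihedrals (periodic
angular metric) or integer protein-DNA interface maps (Manhattan metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from haplodyn.core import RegionSelection, TopologyError, Trajectory
from haplodyn.dpclustering import (ClusteringParams, ClusterResult, adp_cluster,
                                   pairwise_distances)
from haplodyn.metrics import superpose

__all__ = [
    "EssentialSubspace",
    "pca_essential",
    "rmsip",
    "dihedral_features",
    "interface_map_features",
    "cluster_composition",
    "ClusteringParams",
    "ClusterResult",
    "adp_cluster",
]


@dataclass
class EssentialSubspace:
    """Orthonormal basis of the top-D principal components of C-alpha motion.

    ``basis`` is (D, 3N); ``eigenvalues`` are the corresponding variances in
    non-increasing order; ``total_variance`` is the trace of the coordinate
    covariance (conserved across the full eigendecomposition).
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    mean: np.ndarray

    @property
    def D(self) -> int:
        return self.basis.shape[0]


def pca_essential(traj: Trajectory, align_reference: np.ndarray,
                  exclude: tuple[int, int] | None = (107, 131),
                  stride_ns: float = 0.5, D: int = 30) -> EssentialSubspace:
    """PCA of alpha-carbon coordinates after core alignment.

    Frames (sampled every ``stride_ns``) are aligned to ``align_reference``
    (a full coordinate frame) on the alpha-carbons *excluding* the
    ``exclude`` residue range (the mobile region is left out of the fit so
    it cannot dominate the rigid-body removal); the PCA itself runs over all
    alpha-carbons.
    """
    sub = traj.stride_frames(stride_ns * 1000.0)
    ca_mask = traj.atom_mask(RegionSelection(atom_names=("CA",)))
    if exclude is not None:
        lo, hi = exclude
        full = traj.full_resids
        align_mask = ca_mask & ~((full >= lo) & (full <= hi))
    else:
        align_mask = ca_mask
    if sub.n_frames < D:
        raise ValueError(f"{sub.n_frames} sampled frames < D = {D} components")
    X = np.empty((sub.n_frames, int(ca_mask.sum()) * 3))
    ref = np.asarray(align_reference, dtype=float)
    for f in range(sub.n_frames):
        fitted, _ = superpose(sub.coordinates[f], ref, align_mask)
        X[f] = fitted[ca_mask].ravel()
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred data matrix == eigendecomposition of the covariance
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (len(X) - 1)
    total = float(Xc.var(axis=0, ddof=1).sum())
    return EssentialSubspace(basis=vt[:D], eigenvalues=eigvals[:D],
                             total_variance=total, mean=mean)


def rmsip(U: EssentialSubspace | np.ndarray, V: EssentialSubspace | np.ndarray) -> float:
    """Root mean square inner product of two essential subspaces."""
    bu = U.basis if isinstance(U, EssentialSubspace) else np.asarray(U, dtype=float)
    bv = V.basis if isinstance(V, EssentialSubspace) else np.asarray(V, dtype=float)
    if bu.shape != bv.shape:
        raise ValueError(f"subspace shapes differ: {bu.shape} vs {bv.shape}")
    overlap = bu @ bv.T
    return float(np.sqrt((overlap ** 2).sum() / bu.shape[0]))


def dihedral_features(traj: Trajectory, region: tuple[int, int] | None = None,
                      stride_ps: float | None = None) -> tuple[np.ndarray, list[int]]:
    """Per-frame phi/psi backbone dihedrals (degrees) of region residues.

    Only residues with both dihedrals defined contribute (chain termini are
    skipped), giving 2 features per usable residue.  Returns (matrix of
    shape (n_frames, 2m), residue ids used); pair with the
    ``periodic-angular`` metric for clustering.
    """
    from MDAnalysis.lib.distances import calc_dihedrals

    sub = traj.stride_frames(stride_ps) if stride_ps else traj
    resid_list = [int(r) for r in np.unique(sub.full_resids)]
    interior = [r for r in resid_list[1:-1]
                if (region is None or region[0] <= r <= region[1])]
    if not interior:
        raise ValueError("no region residue has both dihedrals defined")

    def idx(resid, name):
        try:
            return sub.atom_index(resid, name)
        except TopologyError:
            raise TopologyError(f"residue {resid} lacks backbone atom {name}") from None

    cols = []
    for r in interior:
        c_prev = idx(r - 1, "C")
        n_i, ca_i, c_i = idx(r, "N"), idx(r, "CA"), idx(r, "C")
        n_next = idx(r + 1, "N")
        cols.append(("phi", c_prev, n_i, ca_i, c_i))
        cols.append(("psi", n_i, ca_i, c_i, n_next))

    X = np.empty((sub.n_frames, len(cols)))
    coords = sub.coordinates
    for j, (_, a, b, c, d) in enumerate(cols):
        ang = calc_dihedrals(coords[:, a], coords[:, b], coords[:, c], coords[:, d])
        X[:, j] = np.degrees(ang)
    # map to (-180, 180]
    X = (X + 180.0) % 360.0 - 180.0
    X[X == -180.0] = 180.0
    return X, interior


def interface_map_features(maps: list[pd.DataFrame]) -> np.ndarray:
    """Flatten a series of integer residue x nucleotide contact maps into an
    observation matrix; pair with the ``manhattan`` metric."""
    if not maps:
        raise ValueError("need at least one interface map")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError(f"interface maps must share shape; got {m.shape} vs {shape}")
    return np.vstack([np.asarray(m, dtype=float).ravel() for m in maps])


def cluster_composition(result: ClusterResult, min_total_fraction: float = 0.10
                        ) -> pd.DataFrame:
    """Per-cluster provenance fractions.

    Requires provenance (e.g. (variant, replica) tuples) on the result.
    Returns one row per (cluster, source): the fraction of the cluster's
    frames from that source, the cluster's share of all frames, and whether
    the cluster passes the ``min_total_fraction`` display threshold.
    """
    if result.provenance is None:
        raise ValueError("clustering was run without provenance")
    prov = np.empty(len(result.provenance), dtype=object)
    prov[:] = [str(p) for p in result.provenance]
    n = len(prov)
    rows = []
    for c in range(result.n_clusters):
        mask = result.labels == c
        size = int(mask.sum())
        sources, counts = np.unique(prov[mask], return_counts=True)
        for s, cnt in zip(sources, counts):
            rows.append({"cluster": c, "source": s, "fraction": cnt / size,
                         "cluster_size": size, "total_fraction": size / n,
                         "above_display_threshold": size / n >= min_total_fraction})
    return pd.DataFrame(rows)
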