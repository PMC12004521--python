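"""Per-trajectory structural and dynamic metrics.

Covers least-squares superposition and RMSD/RMSF, simplified secondary
structure ({helix, strand, loop}; beta-bulges count as loop), the ordered
fraction of a region, kink angles, residue-pair displacement maps, and
autocorrelation-aware uncertainties (autocorrelation time, moving block
bootstrap, between-replica SEM).

Uncertainty convention: a reported error on a trajectory average is the
standard error of the mean across replicas; the within-replica variance of
each replica's average is estimated with a moving block bootstrap whose block
length is the series' autocorrelation time, defined as the first lag at which
the normalised autocorrelation function drops to 1/e or below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from haplodyn.core import RegionSelection, SelectionError, TopologyError, Trajectory
from haplodyn.geometry import angle_between

__all__ = [
    "superpose",
    "rmsd_series",
    "rmsf",
    "rmsf_replicas",
    "assign_ss",
    "ordered_fraction",
    "ss_change_fraction",
    "kink_angle",
    "displacement_map",
    "autocorrelation",
    "autocorrelation_time",
    "moving_block_bootstrap_sem",
    "replica_mean_sem",
    "SeriesStats",
    "ReplicaStats",
    "ORDERED_LABELS",
]

ORDERED_LABELS = frozenset({"H", "E"})  # helix, strand; '-' is loop


# ----------------------------------------------------------- superposition

def superpose(mobile: np.ndarray, reference: np.ndarray,
              mask: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition of one frame onto another.

    ``mobile`` and ``reference`` are (n_atoms, 3); ``mask`` selects the atoms
    used to fit the transform (and over which the RMSD is reported).  The
    returned frame has the transform applied to *all* atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError(
            f"atom count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    if not np.any(mask):
        raise SelectionError("empty superposition selection")
    mob_sel = mobile[mask]
    ref_sel = reference[mask]
    mob_c = mob_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - ref_c, mob_sel - mob_c)
    transformed = rot.apply(mobile - mob_c) + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[mask] - ref_sel) ** 2, axis=1))))
    return transformed, rmsd


def _masked_rmsd(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a[mask] - b[mask]) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: RegionSelection,
                align_selection: RegionSelection | None = None,
                stride_ps: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD over ``selection`` after aligning each frame on
    ``align_selection`` (defaults to the report selection).

    ``reference`` is a full (n_atoms, 3) frame.  Returns (times_ns, values).
    """
    sub = traj.stride_frames(stride_ps)
    sel_mask = traj.atom_mask(selection)
    align_mask = traj.atom_mask(align_selection) if align_selection is not None else sel_mask
    values = np.empty(sub.n_frames)
    for f in range(sub.n_frames):
        fitted, _ = superpose(sub.coordinates[f], reference, align_mask)
        values[f] = _masked_rmsd(fitted, reference, sel_mask)
    times_ns = np.arange(sub.n_frames) * stride_ps / 1000.0
    return times_ns, values


def rmsf(traj: Trajectory, selection: RegionSelection,
         align_selection: RegionSelection | None = None,
         stride_ps: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF about the trajectory-average structure.

    Frames are first aligned (on ``align_selection``, default the report
    selection) to the first sampled frame, the average structure is taken as
    reference, and the RMSF of each selected atom is the root-mean-square
    distance from its average position.  Returns (full_resids, values)
    aggregated per residue over the selected atoms.
    """
    sub = traj.stride_frames(stride_ps)
    if sub.n_frames < 2:
        raise ValueError("RMSF undefined for fewer than 2 sampled frames")
    sel_mask = traj.atom_mask(selection)
    align_mask = traj.atom_mask(align_selection) if align_selection is not None else sel_mask
    fitted = np.empty_like(sub.coordinates)
    for f in range(sub.n_frames):
        fitted[f], _ = superpose(sub.coordinates[f], sub.coordinates[0], align_mask)
    mean_structure = fitted.mean(axis=0)
    sq = np.sum((fitted - mean_structure) ** 2, axis=2)  # frames x atoms
    atom_rmsf = np.sqrt(sq.mean(axis=0))
    resids = traj.full_resids[sel_mask]
    unique = np.unique(resids)
    values = np.array([atom_rmsf[sel_mask][resids == r].mean() for r in unique])
    return unique, values


def rmsf_replicas(replicas: list[Trajectory], selection: RegionSelection,
                  align_selection: RegionSelection | None = None,
                  stride_ps: float = 200.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RMSF per replica, then mean and between-replica SEM per residue."""
    profiles = []
    resids = None
    for traj in replicas:
        r, v = rmsf(traj, selection, align_selection, stride_ps)
        if resids is None:
            resids = r
        elif not np.array_equal(resids, r):
            raise SelectionError("replicas resolve to different residue sets")
        profiles.append(v)
    stack = np.vstack(profiles)
    mean = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
           if len(profiles) > 1 else np.full_like(mean, np.nan))
    return resids, mean, sem


# ------------------------------------------------------ secondary structure

def assign_ss(traj: Trajectory) -> np.ndarray:
    """Simplified per-residue secondary structure for every frame.

    Uses the PyDSSP scheme (as implemented in MDAnalysis): hydrogen bonds by
    the DSSP electrostatic criterion (E < -0.5 kcal/mol), helix from
    consecutive (i, i+4) bonds, strand from ladder patterns with beta-bulges
    demoted to loop.  Hydrogen positions are taken from the topology, never
    guessed — which is why the synthetic generator places amide hydrogens
    explicitly.  Returns an (n_frames, n_residues) array over {'H','E','-'}.
    """
    from MDAnalysis.analysis.dssp import DSSP

    for r in traj.residue_ids:
        present = set(traj.atom_names[traj.resids == r])
        missing = {"N", "CA", "C", "O"} - present
        if missing:
            raise TopologyError(f"residue {r} lacks backbone atoms {sorted(missing)}")
    u = traj.to_universe()
    result = DSSP(u, guess_hydrogens=False).run()
    return np.asarray(result.results.dssp, dtype=object)


def ordered_fraction(labels: np.ndarray, region_mask: np.ndarray | None = None
                     ) -> tuple[float, np.ndarray]:
    """Mean fraction of region residues labeled helix or strand.

    ``labels`` is (n_frames, n_residues); ``region_mask`` selects the residue
    columns (default all).  Returns (mean fraction, per-frame series); attach
    an uncertainty with :func:`moving_block_bootstrap_sem` /
    :func:`replica_mean_sem`.
    """
    labels = np.asarray(labels, dtype=object)
    if region_mask is None:
        region_mask = np.ones(labels.shape[1], dtype=bool)
    if not np.any(region_mask):
        raise SelectionError("empty region for ordered fraction")
    region = labels[:, region_mask]
    ordered = np.isin(region, list(ORDERED_LABELS))
    series = ordered.mean(axis=1)
    return float(series.mean()), series


def ss_change_fraction(labels: np.ndarray, reference_labels: np.ndarray) -> np.ndarray:
    """Per-frame fraction of residues whose label differs from a reference
    (e.g. the starting-structure assignment)."""
    labels = np.asarray(labels, dtype=object)
    reference_labels = np.asarray(reference_labels, dtype=object).ravel()
    if labels.shape[1] != reference_labels.shape[0]:
        raise SelectionError(
            f"residue sets differ: {labels.shape[1]} vs {reference_labels.shape[0]}"
        )
    return (labels != reference_labels[None, :]).mean(axis=1)


# ------------------------------------------------------------------ angles

def kink_angle(traj: Trajectory, residues: tuple[int, int, int],
               atom_name: str = "CA") -> np.ndarray:
    """Planar angle (degrees) at the middle residue's atom, per frame.

    ``residues`` are full-protein numbers; the angle is measured at
    ``residues[1]`` between the vectors to the flanking residues' atoms.
    """
    i, j, k = (traj.atom_index(r, atom_name) for r in residues)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        c = traj.coordinates[f]
        out[f] = angle_between(c[i], c[j], c[k])
    return out


# -------------------------------------------------------- displacement map

def displacement_map(traj: Trajectory, reference: np.ndarray,
                     selection: RegionSelection | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Average change in residue-pair distance relative to a reference frame.

    Entry (i, j) is the mean over frames of d_ij(frame) - d_ij(reference);
    positive entries mean the pair moved apart.  Computed on alpha-carbons by
    default.  Returns (full_resids, matrix); the matrix is symmetric with a
    zero diagonal.
    """
    if selection is None:
        selection = RegionSelection(atom_names=("CA",))
    mask = traj.atom_mask(selection)
    ref_d = pdist(np.asarray(reference, dtype=float)[mask])
    acc = np.zeros_like(ref_d)
    for f in range(traj.n_frames):
        acc += pdist(traj.coordinates[f][mask])
    mean_d = acc / traj.n_frames
    return traj.full_resids[mask], squareform(mean_d - ref_d)


# ------------------------------------------------- time-series uncertainty

def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Normalised empirical autocorrelation function (biased 1/n estimator)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = np.mean(x * x)
    if var == 0:
        raise ValueError("constant series has no autocorrelation")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx))[:n] / n
    return acov / var


def autocorrelation_time(series: np.ndarray) -> int:
    """Smallest lag at which the ACF reaches 1/e or below (>= 1 frame)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short for an autocorrelation time")
    acf = autocorrelation(x)
    below = np.flatnonzero(acf[1:] <= np.exp(-1.0))
    if len(below) == 0:
        return len(x) - 1
    return int(below[0]) + 1


@dataclass(frozen=True)
class SeriesStats:
    """Mean and block-bootstrap SEM of a correlated scalar series."""

    mean: float
    sem: float
    autocorrelation_time: int
    block_length: int
    n_boot: int
    seed: int


def moving_block_bootstrap_sem(series: np.ndarray, block_length: int | None = None,
                               n_boot: int = 200, seed: int = 0) -> SeriesStats:
    """Moving block bootstrap estimate of the SEM of a series mean.

    Resamples ceil(n / block) overlapping blocks with replacement ``n_boot``
    times; the SEM is the standard deviation of the resampled means.  The
    default block length is the series' autocorrelation time (ceil), which
    makes the estimate robust to serial correlation.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if block_length is None:
        tau = autocorrelation_time(x) if np.std(x) > 0 else 1
        block_length = int(np.ceil(tau))
    else:
        tau = block_length
    if block_length < 1 or block_length > n:
        raise ValueError(f"block length {block_length} invalid for series of length {n}")
    if np.std(x) == 0:
        return SeriesStats(float(x.mean()), 0.0, 1, block_length, n_boot, seed)
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n - block_length + 1, size=(n_boot, n_blocks))
    idx = starts[:, :, None] + np.arange(block_length)[None, None, :]
    resampled = x[idx.reshape(n_boot, -1)[:, :n]]
    means = resampled.mean(axis=1)
    return SeriesStats(mean=float(x.mean()), sem=float(means.std(ddof=1)),
                       autocorrelation_time=int(tau), block_length=int(block_length),
                       n_boot=n_boot, seed=seed)


@dataclass(frozen=True)
class ReplicaStats:
    """Mean of replica means with between-replica SEM (None for one replica)."""

    mean: float
    sem: float | None
    n_replicas: int


def replica_mean_sem(per_replica_means: list[float]) -> ReplicaStats:
    """Mean of replica means; SEM = sd / sqrt(R), flagged None for R = 1."""
    if not per_replica_means:
        raise ValueError("need at least one replica mean")
    values = np.asarray(per_replica_means, dtype=float)
    if len(values) == 1:
        return ReplicaStats(mean=float(values[0]), sem=None, n_replicas=1)
    return ReplicaStats(mean=float(values.mean()),
                        sem=float(values.std(ddof=1) / np.sqrt(len(values))),
                        n_replicas=len(values))
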