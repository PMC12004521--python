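"""Core containers: trajectories, region selections, and trajectory I/O.

A :class:`Trajectory` is a plain frames x atoms x 3 coordinate array plus a
flat topology (residue ids, residue names, atom names, elements).  This keeps
every metric in the package a pure array computation; conversion helpers bridge
to MDAnalysis when an external algorithm (secondary-structure assignment,
format writers) is needed.

Residue numbering follows the *construct* convention of the input topology.
Crystallographic constructs frequently omit disordered termini, so a
``numbering_offset`` records the shift between construct numbering and
full-protein numbering (offset = construct - full; the EXO5 construct used
throughout the examples has offset -68, i.e. construct residue 1 is
full-protein residue 69).  :class:`RegionSelection` ranges are always given in
full-protein numbering and resolved through the offset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Trajectory",
    "RegionSelection",
    "TopologyError",
    "SelectionError",
]


class TopologyError(ValueError):
    """An atom or residue required by an operation is absent from the topology."""


class SelectionError(ValueError):
    """A region selection resolves to nothing or to mismatched atom sets."""


@dataclass(frozen=True)
class RegionSelection:
    """Residue ranges (full-protein numbering, inclusive) plus an atom-name filter.

    ``ranges=None`` selects every residue.  ``atom_names=("CA",)`` restricts to
    alpha-carbons, the default for most distance-based metrics.
    """

    ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = ("CA",)

    @classmethod
    def residues(cls, start: int, stop: int, atom_names=("CA",)) -> "RegionSelection":
        return cls(ranges=((start, stop),), atom_names=tuple(atom_names) if atom_names else None)

    def contains_residue(self, full_resid: int) -> bool:
        if self.ranges is None:
            return True
        return any(lo <= full_resid <= hi for lo, hi in self.ranges)


@dataclass
class Trajectory:
    """Frames x atoms coordinates (angstrom) with a flat topology.

    Parameters
    ----------
    coordinates : (n_frames, n_atoms, 3) float array, angstrom.
    resids : per-atom residue index in construct numbering (1-based).
    resnames, atom_names, elements : per-atom string arrays.
    frame_interval_ps : simulated time between stored frames.
    replica : replica identifier (1-based).
    numbering_offset : construct numbering minus full-protein numbering.
    """

    coordinates: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    frame_interval_ps: float = 200.0
    replica: int = 1
    numbering_offset: int = 0
    chain_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        n = self.coordinates.shape[1]
        for arr, label in [
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.atom_names, "atom_names"),
            (self.elements, "elements"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} has {len(arr)} entries for {n} atoms")
        if self.chain_ids is None:
            self.chain_ids = np.asarray(["A"] * n, dtype=object)
        else:
            self.chain_ids = np.asarray(self.chain_ids, dtype=object)

    # ---------------------------------------------------------------- basics

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def full_resids(self) -> np.ndarray:
        """Per-atom residue index in full-protein numbering."""
        return self.resids - self.numbering_offset

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique construct residue ids."""
        return np.unique(self.resids)

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_interval_ps / 1000.0

    # ------------------------------------------------------------- selection

    def atom_mask(self, selection: RegionSelection) -> np.ndarray:
        """Boolean per-atom mask for a region selection."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if selection.atom_names is not None:
            names = set(selection.atom_names)
            mask &= np.asarray([a in names for a in self.atom_names])
        if selection.ranges is not None:
            full = self.full_resids
            in_range = np.zeros(self.n_atoms, dtype=bool)
            for lo, hi in selection.ranges:
                in_range |= (full >= lo) & (full <= hi)
            mask &= in_range
        if not mask.any():
            raise SelectionError(f"selection {selection} matches no atoms")
        return mask

    def atom_index(self, full_resid: int, atom_name: str) -> int:
        """Index of a single named atom, full-protein numbering."""
        hits = np.flatnonzero((self.full_resids == full_resid) & (self.atom_names == atom_name))
        if len(hits) != 1:
            raise TopologyError(
                f"expected exactly one atom {atom_name!r} in residue {full_resid}, found {len(hits)}"
            )
        return int(hits[0])

    def slice_frames(self, frame_indices) -> "Trajectory":
        return replace(self, coordinates=self.coordinates[frame_indices])

    def stride_frames(self, stride_ps: float) -> "Trajectory":
        """Subsample frames to one every ``stride_ps``; stride must be a multiple
        of the stored frame interval."""
        if stride_ps < self.frame_interval_ps:
            raise ValueError(
                f"stride {stride_ps} ps finer than stored frame interval {self.frame_interval_ps} ps"
            )
        step = stride_ps / self.frame_interval_ps
        if abs(step - round(step)) > 1e-9:
            raise ValueError(
                f"stride {stride_ps} ps is not a multiple of frame interval {self.frame_interval_ps} ps"
            )
        out = replace(self, coordinates=self.coordinates[:: int(round(step))])
        out.frame_interval_ps = stride_ps
        return out

    def discard_initial_ns(self, equilibration_ns: float) -> "Trajectory":
        """Drop the first ``equilibration_ns`` of simulated time (equilibration cut)."""
        n_cut = int(np.ceil(equilibration_ns * 1000.0 / self.frame_interval_ps))
        if n_cut >= self.n_frames:
            raise ValueError(
                f"equilibration cut of {equilibration_ns} ns removes all {self.n_frames} frames"
            )
        return self.slice_frames(slice(n_cut, None))

    # ------------------------------------------------------------ conversion

    def to_universe(self):
        """Build an in-memory MDAnalysis Universe mirroring this trajectory."""
        import MDAnalysis as mda

        n_res_per_atom, res_index = np.unique(self.resids, return_inverse=True)
        n_residues = len(n_res_per_atom)
        resnames = np.empty(n_residues, dtype=object)
        resnames[res_index] = self.resnames
        u = mda.Universe.empty(
            n_atoms=self.n_atoms,
            n_residues=n_residues,
            atom_resindex=res_index,
            residue_segindex=np.zeros(n_residues, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(a) for a in self.atom_names])
        u.add_TopologyAttr("elements", [str(e) for e in self.elements])
        u.add_TopologyAttr("resnames", [str(r) for r in resnames])
        u.add_TopologyAttr("resids", n_res_per_atom)
        u.load_new(self.coordinates.astype(np.float32), format="memory", dt=self.frame_interval_ps / 1000.0)
        return u

    # ------------------------------------------------------------------- I/O

    def write_pdb(self, path) -> None:
        """Write a multi-model PDB (one MODEL per frame)."""
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                serial = 1
                for a in range(self.n_atoms):
                    x, y, z = self.coordinates[f, a]
                    name = str(self.atom_names[a])
                    pdb_name = f" {name:<3s}" if len(name) < 4 else name
                    fh.write(
                        f"ATOM  {serial:5d} {pdb_name:<4s}{'':1s}{str(self.resnames[a]):<3s} "
                        f"{str(self.chain_ids[a]):1s}{int(self.resids[a]):4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {str(self.elements[a]):>2s}\n"
                    )
                    serial += 1
                fh.write("TER\nENDMDL\n")
            fh.write("END\n")

    def write_xtc(self, topology_pdb_path, xtc_path) -> None:
        """Write topology (single-frame PDB) plus an XTC trajectory."""
        import MDAnalysis as mda

        first = self.slice_frames(slice(0, 1))
        first.write_pdb(topology_pdb_path)
        u = self.to_universe()
        with mda.Writer(str(xtc_path), n_atoms=self.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)

    @classmethod
    def from_pdb(cls, path, frame_interval_ps: float = 200.0, replica: int = 1,
                 numbering_offset: int = 0) -> "Trajectory":
        """Read a (multi-model) PDB written by :meth:`write_pdb` or equivalent."""
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        atoms = u.atoms
        coords = np.array([atoms.positions.copy() for _ in u.trajectory], dtype=float)
        return cls(
            coordinates=coords,
            resids=atoms.resids,
            resnames=atoms.resnames,
            atom_names=atoms.names,
            elements=[str(e) for e in atoms.elements] if hasattr(atoms, "elements") else [a[0] for a in atoms.names],
            frame_interval_ps=frame_interval_ps,
            replica=replica,
            numbering_offset=numbering_offset,
        )
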