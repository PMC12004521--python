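"""Shared fixtures: small synthetic trajectories and hand-built structures."""

import numpy as np
import pytest

from haplodyn.core import Trajectory
from haplodyn.geometry import build_backbone
from haplodyn.synthetic import SyntheticSpec, gen_helix_coil_trajectory

BACKBONE = ("N", "H", "CA", "C", "O")


def backbone_trajectory(phi, psi, n_frames: int = 1, resname: str = "ALA") -> Trajectory:
    """Single-conformation trajectory built from explicit dihedrals."""
    bb = build_backbone(np.asarray(phi, float), np.asarray(psi, float))
    names, resids, resnames, elements, coords = [], [], [], [], []
    for i in range(len(phi)):
        for nm in BACKBONE:
            if nm == "H" and i == 0:
                continue
            names.append(nm)
            resids.append(i + 1)
            resnames.append(resname)
            elements.append(nm[0])
            coords.append(bb[nm][i])
    frame = np.asarray(coords)
    return Trajectory(np.repeat(frame[None], n_frames, axis=0), resids, resnames,
                      names, elements)


def hairpin_trajectory() -> Trajectory:
    """Two 6-residue antiparallel strands joined by a type II' turn."""
    strand_phi, strand_psi = -139.0, 135.0
    turn = [(60.0, -120.0), (-80.0, 0.0)]
    phi = [strand_phi] * 6 + [t[0] for t in turn] + [strand_phi] * 6
    psi = [strand_psi] * 6 + [t[1] for t in turn] + [strand_psi] * 6
    return backbone_trajectory(phi, psi)


@pytest.fixture(scope="session")
def ideal_helix() -> Trajectory:
    return gen_helix_coil_trajectory(
        SyntheticSpec(seed=0, n_frames=1, n_residues=12, helix_probability=1.0,
                      noise_sd=0.0))


@pytest.fixture(scope="session")
def hairpin() -> Trajectory:
    return hairpin_trajectory()


@pytest.fixture(scope="session")
def helix_coil_60():
    """2000-frame mixed trajectory with a planted 60% helix equilibrium."""
    spec = SyntheticSpec(seed=42, n_frames=2000, n_residues=12,
                         helix_probability=0.6)
    return spec, gen_helix_coil_trajectory(spec)
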