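"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here are statistical stand-ins, not physical simulations:

- :func:`gen_phased_panel` samples chromosomes i.i.d. from a prescribed
  haplotype distribution, recording which haplotype generated each one.
- :func:`gen_toy_scorer` builds a deterministic positionwise log-probability
  scorer with known rows, so every PLLR has a hand-computable value.
- :func:`gen_helix_coil_trajectory` rebuilds a backbone from internal
  coordinates frame by frame.  Each frame is drawn as an ideal alpha-helix
  (phi=-57, psi=-47) with probability ``helix_probability``, otherwise as a
  coil with dihedrals from the beta/PPII basin (phi in [-180,-60], psi in
  [60,180]) — coil frames can never satisfy helical hydrogen-bond patterns,
  so the planted helix probability is the exact expected ordered fraction of
  interior residues.  Pairwise contacts are planted by rigidly displacing the
  second atom of each designated pair to a below-threshold or above-threshold
  distance per frame, decoupling contact statistics from the dihedral draw.
- :func:`gen_ar1` produces a stationary AR(1) series with unit marginal
  variance, whose autocorrelation time has the closed form -1/ln(rho).

Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from haplodyn.core import Trajectory
from haplodyn.fitness import ToyScorer
from haplodyn.geometry import IDEAL_HELIX_PHI, IDEAL_HELIX_PSI, build_backbone
from haplodyn.haplotypes import PhasedPanel

__all__ = [
    "SyntheticSpec",
    "PlantedContact",
    "gen_phased_panel",
    "gen_toy_scorer",
    "gen_helix_coil_trajectory",
    "gen_ar1",
    "InvalidSpecError",
]

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")


class InvalidSpecError(ValueError):
    """A synthetic specification violates its invariants."""


@dataclass(frozen=True)
class PlantedContact:
    """A pair of atoms forced below/above two distances with a target rate.

    ``pair`` is ((resid, atom_name), (resid, atom_name)) in construct
    numbering; per frame the second atom is displaced along the pair axis to
    ``contact_distance`` with probability ``occurrence``, else to
    ``open_distance``.
    """

    pair: tuple[tuple[int, str], tuple[int, str]]
    occurrence: float
    contact_distance: float = 4.0
    open_distance: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence <= 1.0:
            raise InvalidSpecError("contact occurrence must be in [0, 1]")
        if self.contact_distance >= self.open_distance:
            raise InvalidSpecError("contact distance must be below open distance")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a helix/coil backbone trajectory fixture."""

    seed: int = 0
    n_frames: int = 100
    n_residues: int = 20
    helix_probability: float = 0.6
    noise_sd: float = 0.05
    planted_contacts: tuple[PlantedContact, ...] = field(default_factory=tuple)
    ar1_rho: float = 0.0
    frame_interval_ps: float = 200.0
    with_cb: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.helix_probability <= 1.0:
            raise InvalidSpecError("helix_probability must be in [0, 1]")
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise InvalidSpecError("ar1_rho must lie in (-1, 1)")


def gen_phased_panel(haplotype_defs: list[tuple[str, float]], n_individuals: int,
                     seed: int, populations: list[str] | None = None) -> PhasedPanel:
    """Sample ``2 * n_individuals`` chromosomes i.i.d. from a haplotype
    distribution given as (allele pattern, target frequency) pairs.

    Frequencies must sum to 1 (within 1e-9).  The generating haplotype index
    of each chromosome is stored as ground truth.  Optional ``populations``
    cycles labels over individuals (panel metadata only; sampling is i.i.d.).
    """
    if n_individuals < 1:
        raise InvalidSpecError("n_individuals must be >= 1")
    if not haplotype_defs:
        raise InvalidSpecError("need at least one haplotype")
    patterns = [p for p, _ in haplotype_defs]
    freqs = np.array([f for _, f in haplotype_defs], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise InvalidSpecError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
    n_var = len(patterns[0])
    if any(len(p) != n_var for p in patterns):
        raise InvalidSpecError("all patterns must cover the same variant set")

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(patterns), size=2 * n_individuals, p=freqs)
    hap_matrix = np.array([[int(a) for a in p] for p in patterns], dtype=int)
    chroms = hap_matrix[draws]
    individuals = [f"IND{i + 1:05d}" for i in range(n_individuals)]
    if populations is None:
        pops = ["ALL"] * n_individuals
    else:
        pops = [populations[i % len(populations)] for i in range(n_individuals)]
    return PhasedPanel(individuals=individuals, chromosomes=chroms, populations=pops,
                       true_haplotypes=draws)


def gen_toy_scorer(alphabet: str, length: int, table: np.ndarray | None = None,
                   seed: int = 0, identifier: str = "toy") -> ToyScorer:
    """Build a deterministic positionwise scorer.

    ``table`` may give explicit per-position log-probability rows (each row's
    probabilities summing to 1); if omitted, a random Dirichlet table is
    drawn from ``seed``.
    """
    if table is None:
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(len(alphabet)), size=length)
        table = np.log(probs)
    return ToyScorer(alphabet=alphabet, log_table=np.asarray(table, dtype=float),
                     identifier=identifier)


def _coil_dihedrals(rng: np.random.Generator, n_res: int) -> tuple[np.ndarray, np.ndarray]:
    phi = rng.uniform(-180.0, -60.0, size=n_res)
    psi = rng.uniform(60.0, 180.0, size=n_res)
    return phi, psi


def gen_helix_coil_trajectory(spec: SyntheticSpec,
                              sequence_name: str = "ALA") -> Trajectory:
    """Backbone trajectory with a tunable helix/coil equilibrium.

    Every residue carries N, H, CA, C, O (no amide H at the N-terminus).
    Each frame is all-helix with probability ``helix_probability`` or
    all-coil otherwise; the per-frame helix indicator times the interior
    residue count is the exact ground truth for the ordered fraction.
    Gaussian positional noise of sd ``noise_sd`` is added to every atom, and
    planted contacts are realised afterwards by rigid displacement of the
    second atom of each pair.
    """
    if spec.n_residues < 6:
        raise InvalidSpecError("need at least 6 residues for secondary structure")
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    layout = BACKBONE_ATOMS + ("CB",) if spec.with_cb else BACKBONE_ATOMS

    atom_names, resids, resnames, elements = [], [], [], []
    for i in range(n_res):
        for nm in layout:
            if nm == "H" and i == 0:
                continue
            atom_names.append(nm)
            resids.append(i + 1)
            resnames.append(sequence_name)
            elements.append(nm[0])
    n_atoms = len(atom_names)

    helix_frames = rng.random(spec.n_frames) < spec.helix_probability
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        if helix_frames[f]:
            phi = np.full(n_res, IDEAL_HELIX_PHI)
            psi = np.full(n_res, IDEAL_HELIX_PSI)
        else:
            phi, psi = _coil_dihedrals(rng, n_res)
        bb = build_backbone(phi, psi, with_cb=spec.with_cb)
        a = 0
        for i in range(n_res):
            for nm in layout:
                if nm == "H" and i == 0:
                    continue
                coords[f, a] = bb[nm][i]
                a += 1
    if spec.noise_sd > 0:
        coords += rng.normal(scale=spec.noise_sd, size=coords.shape)

    traj = Trajectory(coordinates=coords, resids=resids, resnames=resnames,
                      atom_names=atom_names, elements=elements,
                      frame_interval_ps=spec.frame_interval_ps)

    for contact in spec.planted_contacts:
        (r1, a1), (r2, a2) = contact.pair
        i1 = traj.atom_index(r1, a1)
        i2 = traj.atom_index(r2, a2)
        closed = rng.random(spec.n_frames) < contact.occurrence
        target = np.where(closed, contact.contact_distance, contact.open_distance)
        v = coords[:, i2] - coords[:, i1]
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        coords[:, i2] = coords[:, i1] + v / norm * target[:, None]

    return traj


def gen_ar1(n: int, rho: float, seed: int) -> np.ndarray:
    """Stationary AR(1) series of length ``n`` with unit marginal variance."""
    if not abs(rho) < 1:
        raise InvalidSpecError(f"|rho| must be < 1 for stationarity, got {rho}")
    if n < 10:
        raise InvalidSpecError("series length must be >= 10")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal()
    innovations = rng.normal(scale=np.sqrt(1.0 - rho * rho), size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innovations[t - 1]
    return x
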