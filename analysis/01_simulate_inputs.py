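#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emulates the EXO5 haplotype study in miniature: a phased diploid panel with
the observed common-haplotype frequency spectrum, and three protein
"variants" x three replicas of backbone trajectories whose conditionally
folded region has a planted helix/coil equilibrium (ordered fraction) chosen
per variant, plus a planted charged-pair contact with a per-variant target
occurrence.  Downstream scripts must recover all of these planted values.
"""

import json
from pathlib import Path

from haplodyn.haplotypes import VariantRecord, write_phased_vcf
from haplodyn.synthetic import (PlantedContact, SyntheticSpec,
                                gen_helix_coil_trajectory, gen_phased_panel)

OUT = Path("results/analysis")
TRAJ_OUT = Path("scratch/trajectories")   # bulky intermediates, regenerable
SEED = 2026

# global haplotype frequencies of the five common EXO5 haplotypes
# (wild type, rs11208299, rs11208299+rs1134586, rs35672330 SNP, rs35672330 del)
HAPLOTYPE_FREQS = [
    ("000", 0.404),  # haplotype 1, wild type
    ("100", 0.423),  # haplotype 2, G172V
    ("110", 0.106),  # haplotype 3, G172V + D115N
    ("001", 0.020),  # haplotype 4, L151P
    ("000", 0.028),  # haplotype 5 carries an indel; its SNP pattern is WT-like
]

VARIANTS = [
    VariantRecord("rs11208299", 515, "G", "T"),   # G172V (GGT->GTT)
    VariantRecord("rs1134586", 343, "G", "A"),    # D115N (GAC->AAC)
    VariantRecord("rs35672330", 452, "T", "C"),   # L151P (CTG->CCG)
]

# per-variant planted dynamics: ordered fraction of the mobile region, the
# occurrence of the shared charged-pair contact, and variant-specific extra
# contacts that should make the L151P network the most dissimilar one
TRAJECTORY_CONDITIONS = {
    "WT": {"helix_probability": 0.534, "contact_occurrence": 0.30,
           "extra_contacts": [(((6, "CB"), (15, "CB")), 0.5)]},
    "G172V": {"helix_probability": 0.524, "contact_occurrence": 0.35,
              "extra_contacts": []},
    "L151P": {"helix_probability": 0.422, "contact_occurrence": 0.705,
              "extra_contacts": [(((2, "CB"), (11, "CB")), 0.6),
                                 (((3, "CB"), (12, "CB")), 0.55)]},
}
N_REPLICAS = 3
N_FRAMES = 600
N_RESIDUES = 16
CONTACT_PAIR = ((4, "CA"), (13, "CA"))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    TRAJ_OUT.mkdir(parents=True, exist_ok=True)

    # merge haplotypes with identical SNP patterns (hap 5's indel is upstream
    # of this package's scope; its SNP pattern coincides with wild type)
    merged: dict[str, float] = {}
    for pattern, freq in HAPLOTYPE_FREQS:
        merged[pattern] = merged.get(pattern, 0.0) + freq
    total = sum(merged.values())
    defs = [(p, f / total) for p, f in merged.items()]

    panel = gen_phased_panel(defs, n_individuals=1000, seed=SEED,
                             populations=["EUR", "AFR", "EAS", "SAS", "AMR"])
    write_phased_vcf(panel, VARIANTS, OUT / "panel.vcf")
    print(f"wrote phased panel: {panel.n_chromosomes} chromosomes, "
          f"{len(defs)} generating haplotypes -> {OUT/'panel.vcf'}")

    manifest = {"seed": SEED, "haplotype_defs": defs, "systems": {}}
    for vi, (variant, cond) in enumerate(TRAJECTORY_CONDITIONS.items()):
        for rep in range(1, N_REPLICAS + 1):
            contacts = [PlantedContact(CONTACT_PAIR, cond["contact_occurrence"],
                                       4.0, 9.0)]
            contacts += [PlantedContact(pair, occ, 4.0, 9.0)
                         for pair, occ in cond["extra_contacts"]]
            spec = SyntheticSpec(
                seed=SEED + 100 * vi + rep,
                n_frames=N_FRAMES, n_residues=N_RESIDUES,
                helix_probability=cond["helix_probability"],
                planted_contacts=tuple(contacts),
                frame_interval_ps=200.0, with_cb=True,
            )
            traj = gen_helix_coil_trajectory(spec)
            traj.replica = rep
            path = TRAJ_OUT / f"traj_{variant}_r{rep}.pdb"
            traj.write_pdb(path)
            manifest["systems"][f"{variant}_r{rep}"] = {
                "path": str(path), "helix_probability": cond["helix_probability"],
                "contact_occurrence": cond["contact_occurrence"],
                "seed": spec.seed, "n_frames": N_FRAMES,
            }
            print(f"  {variant} replica {rep}: {N_FRAMES} frames, planted "
                  f"order {cond['helix_probability']}, contact {cond['contact_occurrence']}")
    (OUT / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"ground truth recorded in {OUT/'simulation_manifest.json'}")


if __name__ == "__main__":
    main()
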