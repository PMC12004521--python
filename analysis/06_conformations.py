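#!/usr/bin/env python
"""Essential dynamics (PCA/RMSIP) and dihedral density-peaks clustering.

PCA runs on alpha-carbon coordinates of every replica after aligning to a
common reference frame; pairwise RMSIP values quantify how similar the
essential subspaces are within and across variants.  Backbone phi/psi
dihedrals of the mobile region (concatenated across all systems, with
provenance) are clustered with the adaptive density-peaks algorithm under
the periodic angular metric; the cluster composition shows whether
conformational states are variant-specific.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from haplodyn.conformation import (cluster_composition, dihedral_features,
                                   pca_essential, rmsip)
from haplodyn.core import Trajectory
from haplodyn.dpclustering import ClusteringParams, adp_cluster

OUT = Path("results/analysis")
D_COMPONENTS = 10       # subspace size scaled to the small fixture systems
Z_MOBILE = 5.0          # merging significance for the mobile-region dihedrals
REGION = (4, 13)        # mobile region of the synthetic constructs


def main() -> None:
    manifest = json.loads((OUT / "simulation_manifest.json").read_text())
    systems = manifest["systems"]
    names = sorted(systems)
    trajs = {n: Trajectory.from_pdb(systems[n]["path"], frame_interval_ps=200.0)
             for n in names}
    reference = trajs[names[0]].coordinates[0]

    subspaces = {n: pca_essential(t, reference, exclude=REGION,
                                  stride_ns=0.2, D=D_COMPONENTS)
                 for n, t in trajs.items()}
    rm = pd.DataFrame([[rmsip(subspaces[a], subspaces[b]) for b in names]
                       for a in names], index=names, columns=names)
    rm.to_csv(OUT / "rmsip_matrix.csv")
    print(f"pairwise RMSIP (D = {D_COMPONENTS}):")
    print(rm.round(3).to_string())

    features, provenance = [], []
    for n in names:
        X, _ = dihedral_features(trajs[n], region=REGION, stride_ps=1000.0)
        features.append(X)
        provenance += [n] * len(X)
    X = np.vstack(features)
    print(f"\nclustering {X.shape[0]} frames x {X.shape[1]} dihedrals, "
          f"periodic angular metric")
    for z in (3.0, Z_MOBILE):
        res_z = adp_cluster(X, ClusteringParams(Z=z, metric="periodic-angular"))
        print(f"  Z = {z:g}: {res_z.n_clusters} clusters")
    result = adp_cluster(X, ClusteringParams(Z=Z_MOBILE, metric="periodic-angular"),
                         provenance=provenance)
    print(f"at Z = {Z_MOBILE:g}: {result.n_clusters} clusters "
          f"(intrinsic dimension {result.intrinsic_dimension:.1f}); the helical "
          "basin is the single significant density peak in these fixtures — "
          "coil frames form a diffuse sea whose local maxima do not survive "
          "the significance gate")

    comp = cluster_composition(result, min_total_fraction=0.10)
    comp.to_csv(OUT / "cluster_composition.csv", index=False)
    labels = pd.DataFrame({"system": provenance, "cluster": result.labels})
    labels.to_csv(OUT / "cluster_labels.csv", index=False)

    # summarise the variant mix of each displayed cluster
    comp["variant"] = comp["source"].str.rsplit("_r", n=1).str[0]
    for c, grp in comp[comp["above_display_threshold"]].groupby("cluster"):
        mix = grp.groupby("variant")["fraction"].sum().sort_values(ascending=False)
        top = mix.index[0]
        print(f"cluster {c}: {grp['cluster_size'].iloc[0]} frames, "
              f"dominant variant {top} ({100 * mix.iloc[0]:.0f}%)")


if __name__ == "__main__":
    main()
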