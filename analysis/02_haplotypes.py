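#!/usr/bin/env python
"""Enumerate transcript haplotypes from the phased panel and translate them.

Reads the phased VCF written by 01_simulate_inputs.py, counts allele
patterns over all chromosomes, keeps haplotypes with global frequency > 1%,
and applies each pattern to a synthetic stand-in coding sequence (373
codons; the three variant codons are placed so that the alternative alleles
produce the G172V, D115N and L151P amino-acid changes).  The recovered
frequencies are checked against the generator's targets.
"""

from pathlib import Path

import pandas as pd

from haplodyn.haplotypes import (enumerate_haplotypes, filter_common,
                                 haplotype_protein_set, read_phased_vcf)

OUT = Path("results/analysis")

# synthetic stand-in CDS: 373 codons of alanine except the three variant
# codons (115 GAC=Asp, 151 CTG=Leu, 172 GGT=Gly) and Met start
CODONS = ["GCT"] * 373
CODONS[0] = "ATG"
CODONS[114] = "GAC"   # D115
CODONS[150] = "CTG"   # L151
CODONS[171] = "GGT"   # G172
CDS = "".join(CODONS) + "TAA"


def main() -> None:
    panel, variants = read_phased_vcf(OUT / "panel.vcf")
    table = enumerate_haplotypes(panel, variants, transcript_id="EXO5-demo")
    common = filter_common(table, min_freq=0.01)
    common.to_csv(OUT / "haplotypes.csv")
    print(f"{len(table)} distinct patterns; {len(common)} with frequency > 1%:")
    print(common.table[["pattern", "count", "frequency"]].to_string(index=False))

    proteins = haplotype_protein_set(common, CDS, variants)
    changes = []
    ref = proteins[proteins["is_wildtype"]]["protein"].iloc[0]
    for _, row in proteins.iterrows():
        diff = [f"{a}{i + 1}{b}" for i, (a, b) in
                enumerate(zip(ref, row["protein"])) if a != b]
        changes.append("+".join(diff) or "WT")
    proteins = proteins.assign(changes=changes)
    proteins[["pattern", "protein_id", "is_wildtype", "changes"]].to_csv(
        OUT / "haplotype_proteins.csv", index=False)
    print("\nper-haplotype protein changes:")
    print(proteins[["pattern", "protein_id", "is_wildtype", "changes"]]
          .to_string(index=False))

    with open(OUT / "haplotype_proteins.fasta", "w") as fh:
        for _, row in proteins.drop_duplicates("protein_id").iterrows():
            fh.write(f">{row['protein_id']} {row['changes']}\n{row['protein']}\n")
    print(f"\nwrote {OUT/'haplotypes.csv'}, haplotype_proteins.csv/.fasta")


if __name__ == "__main__":
    main()
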