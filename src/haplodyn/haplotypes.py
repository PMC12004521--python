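"""Transcript-level haplotypes from phased genotypes.

A haplotype here is the ordered pattern of alleles carried on one chromosome
copy across a transcript's missense variant sites.  Given a phased diploid
panel (two chromosomes per individual), :func:`enumerate_haplotypes` counts
distinct patterns and their global and per-population frequencies;
:func:`filter_common` keeps patterns above a frequency threshold (strict
``>``, default 0.01); :func:`apply_variants_to_cds` substitutes alleles into
the coding sequence and translates it, so each haplotype maps to a protein
sequence.

Only substitutions are supported: insertions/deletions shift the reading
frame or delete codons and are rejected explicitly (``UnsupportedVariantError``)
rather than silently mistranslated.  Phasing is consumed, never inferred:
VCF records with unphased genotypes raise ``PhasingError``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "VariantRecord",
    "PhasedPanel",
    "HaplotypeTable",
    "enumerate_haplotypes",
    "filter_common",
    "apply_variants_to_cds",
    "haplotype_protein_set",
    "read_phased_vcf",
    "write_phased_vcf",
    "IncompletePanelError",
    "PhasingError",
    "ReferenceMismatchError",
    "UnsupportedVariantError",
]


class IncompletePanelError(ValueError):
    """A chromosome lacks an allele call for one of the variants."""


class PhasingError(ValueError):
    """A genotype is not phased (``/`` separator instead of ``|``)."""


class ReferenceMismatchError(ValueError):
    """A variant's reference allele disagrees with the reference CDS."""


class UnsupportedVariantError(ValueError):
    """Insertions/deletions are out of scope; only substitutions are applied."""


@dataclass(frozen=True)
class VariantRecord:
    """A coding variant.  ``cds_position`` is 1-based in the coding sequence."""

    id: str
    cds_position: int
    ref_base: str
    alt_base: str
    effect: str = "missense_variant"

    @property
    def is_substitution(self) -> bool:
        return len(self.ref_base) == len(self.alt_base)


@dataclass
class PhasedPanel:
    """Phased diploid panel: two ordered allele vectors per individual.

    ``chromosomes`` has shape (2 * n_individuals, n_variants), entries 0
    (reference) / 1 (alternative); chromosome ``2i`` and ``2i+1`` belong to
    individual ``i``.  ``true_haplotypes`` optionally records, for synthetic
    panels, the index of the generating haplotype of each chromosome.
    """

    individuals: list[str]
    chromosomes: np.ndarray
    populations: list[str]
    variant_ids: list[str] = field(default_factory=list)
    true_haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        if self.chromosomes.ndim != 2:
            raise ValueError("chromosomes must be 2-D (2*n_individuals, n_variants)")
        if self.chromosomes.shape[0] != 2 * len(self.individuals):
            raise ValueError("panel must carry exactly 2 chromosomes per individual")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        if not self.variant_ids:
            self.variant_ids = [f"var{i + 1}" for i in range(self.chromosomes.shape[1])]

    @property
    def n_variants(self) -> int:
        return self.chromosomes.shape[1]

    @property
    def n_chromosomes(self) -> int:
        return self.chromosomes.shape[0]

    @property
    def chromosome_populations(self) -> list[str]:
        return [p for p in self.populations for _ in (0, 1)]


@dataclass
class HaplotypeTable:
    """Observed allele patterns with global and per-population frequencies.

    ``table`` columns: ``pattern`` (string of 0/1 over the variant set),
    ``count``, ``frequency``, plus one ``freq_<POP>`` column per population.
    Rows are ordered by descending global frequency (ties by pattern string).
    """

    table: pd.DataFrame
    variant_ids: list[str]
    transcript_id: str = ""

    @property
    def patterns(self) -> list[str]:
        return list(self.table["pattern"])

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def enumerate_haplotypes(panel: PhasedPanel, variants: list[VariantRecord] | None = None,
                         transcript_id: str = "") -> HaplotypeTable:
    """Count distinct allele patterns over all chromosomes of the panel.

    Global frequency is pattern count / total chromosomes (computed over all
    chromosomes, not averaged over populations); per-population frequencies
    are computed within each population's chromosomes.
    """
    chroms = panel.chromosomes
    if np.any(chroms < 0):
        raise IncompletePanelError("panel contains missing allele calls")
    if variants is not None and len(variants) != panel.n_variants:
        raise ValueError("variant list does not match the panel's variant set")

    patterns = ["".join(map(str, row)) for row in chroms]
    pops = panel.chromosome_populations
    df = pd.DataFrame({"pattern": patterns, "population": pops})
    counts = df["pattern"].value_counts()
    total = panel.n_chromosomes

    out = pd.DataFrame({"pattern": counts.index, "count": counts.to_numpy()})
    out["frequency"] = out["count"] / total
    for pop in sorted(set(pops)):
        sub = df[df["population"] == pop]["pattern"].value_counts()
        out[f"freq_{pop}"] = out["pattern"].map(sub).fillna(0).to_numpy() / len(
            df[df["population"] == pop]
        )
    out = out.sort_values(["frequency", "pattern"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    ids = [v.id for v in variants] if variants is not None else list(panel.variant_ids)
    return HaplotypeTable(table=out, variant_ids=ids, transcript_id=transcript_id)


def filter_common(table: HaplotypeTable, min_freq: float = 0.01) -> HaplotypeTable:
    """Keep haplotypes with global frequency strictly greater than ``min_freq``."""
    kept = table.table[table.table["frequency"] > min_freq].reset_index(drop=True)
    return HaplotypeTable(table=kept, variant_ids=table.variant_ids,
                          transcript_id=table.transcript_id)


def apply_variants_to_cds(cds: str, pattern_variants: list[VariantRecord]) -> str:
    """Substitute alleles into the coding sequence and translate.

    The CDS is 1-based; translation uses the standard codon table and stops
    at the first stop codon.  The reference base of every variant must match
    the CDS at its position.
    """
    cds = str(cds).upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    seq = list(cds)
    for v in pattern_variants:
        if not v.is_substitution:
            raise UnsupportedVariantError(
                f"variant {v.id}: ref {v.ref_base!r} -> alt {v.alt_base!r} is an indel; "
                "only substitutions are supported"
            )
        start = v.cds_position - 1
        end = start + len(v.ref_base)
        if start < 0 or end > len(cds):
            raise ValueError(f"variant {v.id} at CDS position {v.cds_position} out of bounds")
        if cds[start:end] != v.ref_base.upper():
            raise ReferenceMismatchError(
                f"variant {v.id}: reference allele {v.ref_base!r} does not match "
                f"CDS {cds[start:end]!r} at position {v.cds_position}"
            )
        seq[start:end] = list(v.alt_base.upper())
    return str(Seq("".join(seq)).translate(to_stop=True))


def haplotype_protein_set(table: HaplotypeTable, cds: str,
                          variants: list[VariantRecord]) -> pd.DataFrame:
    """Translate every haplotype pattern; deduplicate identical proteins.

    Returns a frame with one row per haplotype: ``pattern``, ``protein_id``
    (shared by haplotypes yielding the same protein, e.g. through synonymous
    changes), ``protein`` sequence and ``is_wildtype`` (protein equals the
    reference translation).
    """
    if len(variants) != len(table.variant_ids):
        raise ValueError("variant list does not match the table's variant set")
    reference_protein = apply_variants_to_cds(cds, [])
    proteins: dict[str, str] = {}
    rows = []
    for pattern in table.patterns:
        chosen = [v for v, allele in zip(variants, pattern) if allele == "1"]
        protein = apply_variants_to_cds(cds, chosen)
        if protein not in proteins:
            proteins[protein] = f"P{len(proteins) + 1}"
        rows.append(
            {
                "pattern": pattern,
                "protein_id": proteins[protein],
                "protein": protein,
                "is_wildtype": protein == reference_protein,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- I/O

def write_phased_vcf(panel: PhasedPanel, variants: list[VariantRecord], path,
                     chrom: str = "1", positions: list[int] | None = None) -> None:
    """Write the panel as an uncompressed phased VCF (GT with ``|``)."""
    if positions is None:
        positions = [v.cds_position for v in variants]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Annotated effect">\n')
        for ind, pop in zip(panel.individuals, panel.populations):
            fh.write(f"##SAMPLE=<ID={ind},Population={pop}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.individuals) + "\n")
        for j, (v, pos) in enumerate(zip(variants, positions)):
            gts = [
                f"{panel.chromosomes[2 * i, j]}|{panel.chromosomes[2 * i + 1, j]}"
                for i in range(len(panel.individuals))
            ]
            fh.write(
                f"{chrom}\t{pos}\t{v.id}\t{v.ref_base}\t{v.alt_base}\t.\tPASS\t"
                f"EFFECT={v.effect}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_phased_vcf(path, populations: dict[str, str] | None = None) -> tuple[PhasedPanel, list[VariantRecord]]:
    """Read a phased VCF into a panel.  Multi-allelic sites are decomposed
    into biallelic records (one per ALT allele); unphased genotypes raise
    :class:`PhasingError`.

    ``populations`` maps sample name to population label; samples not listed
    get ``"ALL"``.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vf.fetch() if vf.index is not None else vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            calls = np.zeros(2 * len(samples), dtype=int)
            for si, name in enumerate(samples):
                sample = rec.samples[name]
                if not sample.phased and len(set(sample["GT"])) > 1:
                    raise PhasingError(
                        f"sample {name} at {rec.chrom}:{rec.pos} is not phased"
                    )
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt):
                    calls[2 * si: 2 * si + 2] = -1
                else:
                    calls[2 * si] = int(gt[0] == ai)
                    calls[2 * si + 1] = int(gt[1] == ai)
            effect = "missense_variant"
            if "EFFECT" in rec.info:
                val = rec.info["EFFECT"]
                effect = val if isinstance(val, str) else val[0]
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            if len(alts) > 1:
                vid = f"{vid}:{alt}" if rec.id else vid
            variants.append(VariantRecord(id=vid, cds_position=rec.pos,
                                          ref_base=rec.ref, alt_base=alt, effect=effect))
            columns.append(calls)
    chroms = np.column_stack(columns) if columns else np.zeros((2 * len(samples), 0), int)
    pops = [populations.get(s, "ALL") if populations else "ALL" for s in samples]
    panel = PhasedPanel(individuals=samples, chromosomes=chroms, populations=pops,
                        variant_ids=[v.id for v in variants])
    return panel, variants
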