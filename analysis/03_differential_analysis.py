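#!/usr/bin/env python
"""Differential analysis at three levels: editing sites, editing genes,
and gene expression.

Editing reads (alt counts) are tested site-by-site and gene-aggregated
with the NB Wald engine at adjusted p < 0.05; expression counts use the
additional |log2FC| > 1.2 gate. Also writes the TPM matrix. Outputs:
results/dre_sites.tsv, dre_genes.tsv, deg.tsv, tpm.tsv.
"""

from pathlib import Path

import pandas as pd

from editkit import diffstats
from editkit.formats import read_fasta, read_gff3, read_sample_sheet

STUDY = Path("scratch/study")
OUT = Path("results")


def main() -> None:
    reference = read_fasta(STUDY / "genome.fa")
    genes = read_gff3(STUDY / "genes.gff3")
    sheet = read_sample_sheet(STUDY / "samples.tsv")
    sites = pd.read_csv(OUT / "sites.tsv", sep="\t")
    conditions = [sheet.condition_of(s) for s in sheet.ids]

    site_counts = diffstats.editing_counts(sites, sheet.ids)
    dre_sites = diffstats.run_differential(site_counts, conditions, "control")
    site_to_gene = pd.Series(sites["gene"].to_numpy(), index=site_counts.index)
    dre_genes = diffstats.run_differential(
        diffstats.aggregate_gene(site_counts, site_to_gene), conditions, "control"
    )
    chrom_lengths = {c: reference.length(c) for c in reference.names}
    expr = diffstats.count_reads_per_gene(sheet, genes, chrom_lengths)
    deg = diffstats.run_differential(
        expr, conditions, "control", lfc_gate=1.2
    )
    tpm = diffstats.tpm(expr, diffstats.gene_lengths(genes))

    for name, df in [
        ("dre_sites", dre_sites), ("dre_genes", dre_genes), ("deg", deg)
    ]:
        df.to_csv(OUT / f"{name}.tsv", sep="\t")
        calls = df["call"].value_counts()
        print(f"{name}: {calls.get('up', 0)} up, {calls.get('down', 0)} down "
              f"of {len(df)} features")
    tpm.to_csv(OUT / "tpm.tsv", sep="\t")
    print(f"wrote {OUT}/dre_sites.tsv dre_genes.tsv deg.tsv tpm.tsv")


if __name__ == "__main__":
    main()
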