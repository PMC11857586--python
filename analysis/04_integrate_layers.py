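#!/usr/bin/env python
"""Integrate the editing and expression layers.

Venn overlap of the three differential gene sets, nine-quadrant
editing-vs-expression classification, PCA of editing frequencies across
replicates, a MAF-vs-expression correlation for the most-edited gene,
and the cohort summary report. Outputs: results/venn.tsv,
quadrants.tsv, pca.tsv, correlation.tsv, report.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from editkit import calling, integrate
from editkit.formats import read_sample_sheet

STUDY = Path("scratch/study")
OUT = Path("results")


def main() -> None:
    sheet = read_sample_sheet(STUDY / "samples.tsv")
    sites = pd.read_csv(OUT / "sites.tsv", sep="\t")
    dre_sites = pd.read_csv(OUT / "dre_sites.tsv", sep="\t", index_col=0)
    dre_genes = pd.read_csv(OUT / "dre_genes.tsv", sep="\t", index_col=0)
    deg = pd.read_csv(OUT / "deg.tsv", sep="\t", index_col=0)
    tpm = pd.read_csv(OUT / "tpm.tsv", sep="\t", index_col=0)

    site_idx = [f"{r.chrom}:{r.pos}:{r.alt}" for r in sites.itertuples()]
    hosts = pd.Series(sites["gene"].to_numpy(), index=site_idx)
    sig_site_hosts = {
        g for g in hosts[dre_sites["call"] != "ns"] if g not in (".", "intergenic")
    }
    venn = integrate.venn3(
        sig_site_hosts,
        set(dre_genes.index[dre_genes["call"] != "ns"]),
        set(deg.index[deg["call"] != "ns"]),
    )
    pd.Series(venn).to_csv(OUT / "venn.tsv", sep="\t", header=False)
    print("venn (site-host genes / editing genes / expression genes):", venn)

    quadrants = integrate.quadrant_classify(dre_genes, deg)
    quadrants.to_csv(OUT / "quadrants.tsv", sep="\t")
    print("nine-quadrant color classes:")
    print(quadrants["color"].value_counts().to_string())

    freq_mat, _ = calling.frequency_matrix(sites, sheet)
    coords, pct = integrate.editing_pca(freq_mat)
    coords.to_csv(OUT / "pca.tsv", sep="\t")
    print(f"PCA of editing frequencies: PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}%")

    # correlation demo: most-edited gene vs the strongest-expressed gene
    target = sites.loc[sites["gene"] != ".", "gene"].value_counts().idxmax()
    enzyme = tpm.mean(axis=1).idxmax()
    corr = integrate.maf_expression_correlation(target, sites, enzyme, tpm)
    pd.DataFrame(
        [{"target": target, "enzyme": enzyme, "r": corr.r,
          "pvalue": corr.pvalue, "n": corr.n}]
    ).to_csv(OUT / "correlation.tsv", sep="\t", index=False)
    print(f"MAF({target}) vs TPM({enzyme}): R = {corr.r:.3f}, p = {corr.pvalue:.3g}")

    report = integrate.cohort_report(sites, sheet, dre_sites)
    with open(OUT / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    print("group totals (sum of per-sample loci):", report["group_totals"])
    print("significant sites:", report["significant_sites"])


if __name__ == "__main__":
    main()
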