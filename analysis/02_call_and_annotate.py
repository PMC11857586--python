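#!/usr/bin/env python
"""Call editing sites from the simulated alignments and annotate them.

Applies the filter set (base quality >= 25, depth >= 5, alt depth >= 3,
frequency in [0.10, 1.00], >= 2 supporting samples), annotates region /
substitution class / exonic consequence, and scores recovery against
the simulator's truth table. Writes results/sites.tsv.
"""

from pathlib import Path

import pandas as pd

from editkit import annotate, calling, experiments
from editkit.formats import read_fasta, read_gff3, read_sample_sheet, write_site_table

STUDY = Path("scratch/study")
OUT = Path("results")


def main() -> None:
    reference = read_fasta(STUDY / "genome.fa")
    genes = read_gff3(STUDY / "genes.gff3")
    sheet = read_sample_sheet(STUDY / "samples.tsv")
    truth = pd.read_csv(STUDY / "truth_sites.tsv", sep="\t")

    piles = calling.build_pileups(sheet, reference)
    sites = calling.merge_cohort(piles, reference, sheet)
    annotated = annotate.annotate_sites(sites, genes, reference)
    OUT.mkdir(exist_ok=True)
    write_site_table(OUT / "sites.tsv", annotated)

    rec = experiments.caller_recovery(truth, annotated)
    print(f"retained sites: {rec['n_called']} (planted: {rec['n_planted']})")
    print(f"sensitivity (true frequency >= 0.2): {rec['sensitivity_high']:.3f}")
    print(f"precision: {rec['precision']:.3f}")
    panels = annotate.summarize_annotations(annotated, sheet.ids)
    props = panels["class_proportions"]["cohort"]
    print(f"C-to-U + A-to-I fraction: "
          f"{props.get('C-to-U', 0) + props.get('A-to-I', 0):.3f}")
    print("exonic consequences:")
    print(panels["function_counts"]["cohort"].to_string())
    print(f"wrote {OUT / 'sites.tsv'}")


if __name__ == "__main__":
    main()
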