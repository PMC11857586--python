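#!/usr/bin/env python
"""Simulate the synthetic two-condition study the rest of the analysis runs on.

Generates a ~0.6 Mb genome with 200 genes, plants 2000 editing sites
(~80% C-to-U/A-to-I, 15% with a 0.2 <-> 0.5 frequency shift between
conditions), and emits single-end reads at ~30x for 3 control + 3
treated replicates. Alignments and truth tables land in scratch/study/
(large, regenerable); downstream scripts read them from there.
"""

from pathlib import Path

from editkit import synthio

SEED = 1
OUT = Path("scratch/study")


def main() -> None:
    cfg = synthio.SimConfig(seed=SEED)
    study = synthio.simulate_study(cfg, OUT)
    sites = study.truth.sites
    print(f"genome: {cfg.genome_length:,} bp, {len(study.genes)} genes")
    print(f"planted sites: {len(sites)} "
          f"({int(sites['is_differential'].sum())} differential)")
    print("region mix:")
    print(sites["region"].value_counts().to_string())
    classes = (sites["ref"] + ">" + sites["alt"]).value_counts(normalize=True)
    dea = classes.get("C>T", 0) + classes.get("G>A", 0) + \
        classes.get("A>G", 0) + classes.get("T>C", 0)
    print(f"C-to-U + A-to-I fraction among planted sites: {dea:.3f}")
    print(f"samples: {', '.join(study.sheet.ids)}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
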