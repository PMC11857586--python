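"""Annotation: region precedence, substitution classes, consequences."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from editkit import annotate
from editkit.annotate import (
    GeneIndex,
    classify_region,
    classify_substitution,
    exonic_consequence,
    summarize_annotations,
)
from editkit.formats import Gene, Reference, Transcript


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "T", "C-to-U"),
            ("G", "A", "C-to-U"),
            ("A", "G", "A-to-I"),
            ("T", "C", "A-to-I"),
            ("A", "C", "other:A>C"),
            ("G", "T", "other:G>T"),
        ],
    )
    def test_class_map(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_twelve_distinct_classes(self):
        labels = {
            classify_substitution(r, a)
            for r in "ACGT"
            for a in "ACGT"
            if r != a
        }
        assert len(labels) == 4 + 8 - 2  # C-to-U, A-to-I cover 2 pairs each

    @pytest.mark.parametrize("ref,alt", [("N", "A"), ("A", "A"), ("A", "X")])
    def test_invalid_input_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


def _coding_gene(gid="g1", strand="+", exons=((1001, 1100), (1201, 1300))):
    order = list(exons) if strand == "+" else list(reversed(exons))
    cds, cum = [], 0
    for s, e in order:
        cds.append((s, e, (3 - cum % 3) % 3))
        cum += e - s + 1
    cds.sort()
    tx = Transcript(f"{gid}.t1", strand, list(exons), cds)
    return Gene(gid, "chr1", exons[0][0], exons[-1][1], strand, "protein_coding", [tx])


def _ncrna_gene(gid="n1", strand="+", span=(5001, 5200)):
    tx = Transcript(f"{gid}.t1", strand, [span])
    return Gene(gid, "chr1", span[0], span[1], strand, "ncRNA", [tx])


class TestClassifyRegion:
    genes = [_coding_gene(), _ncrna_gene()]
    index = GeneIndex(genes)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1050, "exonic"),       # inside first CDS exon
            (1102, "splicing"),     # 2 bp into the intron
            (1150, "intronic"),     # mid-intron
            (1199, "splicing"),     # 2 bp before next exon
            (501, "upstream"),      # 500 bp 5' of a plus-strand gene
            (1800, "downstream"),   # within 1 kb 3'
            (5100, "ncRNA_exonic"),
            (3500, "intergenic"),
        ],
    )
    def test_precedence_labels(self, pos, expected):
        label, _ = classify_region("chr1", pos, self.index)
        assert label == expected

    def test_minus_strand_flanks_follow_strand(self):
        g = _coding_gene("gm", strand="-", exons=((2001, 2300),))
        idx = GeneIndex([g])
        assert classify_region("chr1", 2500, idx)[0] == "upstream"
        assert classify_region("chr1", 1800, idx)[0] == "downstream"

    def test_ncrna_intron_and_splice(self):
        tx = Transcript("nn.t1", "+", [(7001, 7100), (7301, 7400)])
        g = Gene("nn", "chr1", 7001, 7400, "+", "ncRNA", [tx])
        idx = GeneIndex([g])
        assert classify_region("chr1", 7200, idx)[0] == "ncRNA_intronic"
        assert classify_region("chr1", 7101, idx)[0] == "splicing"

    def test_utr_exon_not_cds(self):
        # exon extends past the CDS: positions in the overhang are UTR
        tx = Transcript(
            "gu.t1", "+", exons=[(9001, 9200)], cds=[(9051, 9150, 0)]
        )
        g = Gene("gu", "chr1", 9001, 9200, "+", "protein_coding", [tx])
        idx = GeneIndex([g])
        assert classify_region("chr1", 9020, idx)[0] == "UTR"
        assert classify_region("chr1", 9100, idx)[0] == "exonic"

    def test_random_sites_match_interval_scan_oracle(self, tiny_study):
        """Brute force: evaluate every transcript window independently and
        take the highest-precedence label."""
        genes = tiny_study.genes
        index = GeneIndex(genes)
        rank = {r: i for i, r in enumerate(annotate.REGION_PRECEDENCE)}
        rng = np.random.default_rng(17)
        chrom = tiny_study.reference.names[0]
        L = tiny_study.reference.length(chrom)

        def oracle(pos):
            best = "intergenic"
            for g in genes:
                for tx in g.transcripts:
                    coding = tx.is_coding
                    label = None
                    if tx.start <= pos <= tx.end:
                        if any(s <= pos <= e for s, e in tx.exons):
                            if coding:
                                in_cds = any(s <= pos <= e for s, e, _ in tx.cds)
                                label = "exonic" if in_cds else "UTR"
                            else:
                                label = "ncRNA_exonic"
                        else:
                            near = any(
                                0 < s - pos <= 2 or 0 < pos - e <= 2
                                for s, e in tx.exons
                            )
                            label = (
                                "splicing" if near
                                else ("intronic" if coding else "ncRNA_intronic")
                            )
                    else:
                        five = pos < tx.start
                        within_start = tx.start - 1000 <= pos < tx.start
                        within_end = tx.end < pos <= tx.end + 1000
                        if tx.strand == "+":
                            if within_start:
                                label = "upstream"
                            elif within_end:
                                label = "downstream"
                        else:
                            if within_end:
                                label = "upstream"
                            elif within_start:
                                label = "downstream"
                    if label and rank[label] < rank[best]:
                        best = label
            return best

        for pos in rng.integers(1, L + 1, size=400):
            assert classify_region(chrom, int(pos), index)[0] == oracle(int(pos))


class TestExonicConsequence:
    def _single_codon_setup(self, codon, strand="+"):
        """Genome carrying ATG + codon + TAA as a single-exon CDS."""
        pad = "GG" * 10
        cds = "ATG" + codon + "TAA"
        if strand == "-":
            ins = str(Seq(cds).reverse_complement())
        else:
            ins = cds
        seq = pad + ins + pad
        start = len(pad) + 1
        end = start + 8
        tx = Transcript("t1", strand, [(start, end)], [(start, end, 0)])
        ref = Reference({"chr1": seq})
        return ref, tx, start

    def test_synonymous_leucine_substitution(self):
        ref, tx, start = self._single_codon_setup("CTT")
        # codon occupies positions start+3..start+5; third base T->C keeps Leu
        label, codon_change, aa = exonic_consequence(
            "chr1", start + 5, "T", "C", tx, ref
        )
        assert label == "synonymous SNV"
        assert codon_change == "CTT>CTC"

    def test_stopgain_from_tryptophan(self):
        ref, tx, start = self._single_codon_setup("TGG")
        label, codon_change, _ = exonic_consequence(
            "chr1", start + 5, "G", "A", tx, ref
        )
        assert label == "stopgain"
        assert codon_change == "TGG>TGA"

    def test_position_outside_cds_rejected(self):
        ref, tx, start = self._single_codon_setup("AAA")
        with pytest.raises(ValueError, match="outside the CDS"):
            exonic_consequence("chr1", start - 1, "G", "A", tx, ref)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_576_codon_substitutions_match_translation_oracle(self, strand):
        """Exhaustive: every codon x position x alt base, both strands,
        compared against direct codon translation."""
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        table = unambiguous_dna_by_id[1]

        def translate(c):
            return "*" if c in table.stop_codons else table.forward_table[c]

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bases = "ACGT"
        checked = 0
        for codon in ("".join((a, b, c)) for a in bases for b in bases for c in bases):
            ref, tx, start = self._single_codon_setup(codon, strand)
            for within in range(3):
                tx_pos = 3 + within  # offset of the middle codon in the CDS
                if strand == "+":
                    gpos = start + tx_pos
                else:
                    gpos = (start + 8) - tx_pos
                ref_base_genome = ref.base("chr1", gpos)
                for alt_tx in bases:
                    if alt_tx == codon[within]:
                        continue
                    alt_genome = comp[alt_tx] if strand == "-" else alt_tx
                    label, codon_change, _ = exonic_consequence(
                        "chr1", gpos, ref_base_genome, alt_genome, tx, ref
                    )
                    new_codon = codon[:within] + alt_tx + codon[within + 1 :]
                    old_aa, new_aa = translate(codon), translate(new_codon)
                    if old_aa == new_aa:
                        expected = "synonymous SNV"
                    elif new_aa == "*":
                        expected = "stopgain"
                    elif old_aa == "*":
                        expected = "stoploss"
                    else:
                        expected = "nonsynonymous SNV"
                    assert label == expected, (codon, within, alt_tx, strand)
                    assert codon_change == f"{codon}>{new_codon}"
                    checked += 1
        assert checked == 576


class TestAnnotateSites:
    def test_planted_consequences_recovered(self, tiny_study):
        truth = tiny_study.truth.sites
        annotated = annotate.annotate_sites(
            truth[["chrom", "pos", "ref", "alt"]].copy(),
            tiny_study.genes,
            tiny_study.reference,
        )
        exonic = truth["region"] == "exonic"
        assert exonic.any()
        assert (
            annotated.loc[exonic.to_numpy(), "exonic_func"].to_numpy()
            == truth.loc[exonic, "consequence"].to_numpy()
        ).all()

    def test_strand_invariance_of_labels(self, tiny_study):
        """Reverse-complementing genome, annotation, and alleles leaves
        region and consequence labels unchanged."""
        ref = tiny_study.reference
        chrom = ref.names[0]
        L = ref.length(chrom)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_seq = str(Seq(ref.sequence(chrom)).reverse_complement())
        rc_ref = Reference({chrom: rc_seq})

        def flip_iv(s, e):
            return L - e + 1, L - s + 1

        rc_genes = []
        for g in tiny_study.genes:
            txs = []
            for tx in g.transcripts:
                exons = sorted(flip_iv(s, e) for s, e in tx.exons)
                cds = sorted(
                    (*flip_iv(s, e), ph) for s, e, ph in tx.cds
                )
                # phases must be recomputed in the flipped transcription order
                if cds:
                    order = cds if tx.strand == "-" else list(reversed(cds))
                    # flipped strand: "+" becomes "-" and vice versa
                    new_cds, cum = [], 0
                    for s, e, _ in (order if tx.strand == "-" else order):
                        new_cds.append((s, e, (3 - cum % 3) % 3))
                        cum += e - s + 1
                    new_cds.sort()
                    cds = new_cds
                strand = "-" if tx.strand == "+" else "+"
                txs.append(Transcript(tx.id, strand, exons, cds))
            s2, e2 = flip_iv(g.start, g.end)
            rc_genes.append(Gene(g.id, chrom, s2, e2, txs[0].strand, g.biotype, txs))

        truth = tiny_study.truth.sites.head(60)
        fwd = annotate.annotate_sites(
            truth[["chrom", "pos", "ref", "alt"]].copy(), tiny_study.genes, ref
        )
        flipped = truth.copy()
        flipped["pos"] = L - truth["pos"] + 1
        flipped["ref"] = truth["ref"].map(comp)
        flipped["alt"] = truth["alt"].map(comp)
        rev = annotate.annotate_sites(
            flipped[["chrom", "pos", "ref", "alt"]].copy(), rc_genes, rc_ref
        )
        assert (fwd["region"].to_numpy() == rev["region"].to_numpy()).all()
        assert (fwd["exonic_func"].to_numpy() == rev["exonic_func"].to_numpy()).all()
        # the biological classes pair complementary substitutions, so those
        # labels are strand-invariant; residual classes flip to the complement
        for f, r in zip(fwd["class"], rev["class"]):
            if f in ("C-to-U", "A-to-I"):
                assert r == f
            else:
                x, y = f.removeprefix("other:").split(">")
                assert r == f"other:{comp[x]}>{comp[y]}"


class TestSummarize:
    def test_even_split_gives_half_proportions(self):
        df = pd.DataFrame(
            {
                "region": ["exonic", "exonic", "intronic", "intronic"],
                "class": ["C-to-U"] * 4,
                "exonic_func": ["n/a"] * 4,
            }
        )
        panels = summarize_annotations(df)
        props = panels["region_proportions"]["cohort"]
        assert props["exonic"] == pytest.approx(0.5)
        assert props["intronic"] == pytest.approx(0.5)

    def test_empty_input_no_division_error(self):
        df = pd.DataFrame({"region": [], "class": [], "exonic_func": []})
        panels = summarize_annotations(df)
        assert panels["region_counts"].empty

    def test_proportions_sum_to_one_per_panel(self, tiny_study):
        truth = tiny_study.truth.sites
        annotated = annotate.annotate_sites(
            truth[["chrom", "pos", "ref", "alt"]].copy(),
            tiny_study.genes,
            tiny_study.reference,
        )
        panels = summarize_annotations(annotated)
        for name in ("region_proportions", "class_proportions"):
            assert panels[name]["cohort"].sum() == pytest.approx(1.0)
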