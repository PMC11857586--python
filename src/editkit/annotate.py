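"""Annotation of editing sites: genomic region, substitution class, and
protein-level consequence.

Substitutions are reported reference-forward: C-to-U editing on a
minus-strand transcript appears as G→A on the genome, so the class map
pairs C→T with G→A and A→G with T→C. Region labels follow a fixed
precedence so every site gets exactly one label; the splicing window is
±2 bp inside an intron and the upstream/downstream flanks are 1 kb,
strand-aware.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .formats import Gene, Reference, Transcript

FLANK = 1000          # upstream/downstream window, bp
SPLICE_WINDOW = 2     # bp into the intron counted as "splicing"

REGION_PRECEDENCE = [
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
]
_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_substitution(ref: str, alt: str) -> str:
    """Map a reference-forward base substitution to its editing class.

    C→T / G→A are C-to-U deamination (the G→A arm is the minus-strand
    appearance); A→G / T→C are A-to-I. The remaining 8 pairs are kept as
    ``other:X>Y``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if (ref, alt) in {("C", "T"), ("G", "A")}:
        return "C-to-U"
    if (ref, alt) in {("A", "G"), ("T", "C")}:
        return "A-to-I"
    return f"other:{ref}>{alt}"


@dataclass
class RegionHit:
    label: str
    gene_id: str


class GeneIndex:
    """Bisect-backed lookup of genes whose ±1 kb window covers a position."""

    def __init__(self, genes: list[Gene]):
        self._by_chrom: dict[str, list[tuple[int, int, Gene]]] = {}
        self._maxspan: dict[str, int] = {}
        for g in genes:
            w = (g.start - FLANK, g.end + FLANK, g)
            self._by_chrom.setdefault(g.chrom, []).append(w)
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda t: t[0])
            self._maxspan[chrom] = max(e - s for s, e, _ in lst)

    def query(self, chrom: str, pos: int) -> list[Gene]:
        lst = self._by_chrom.get(chrom, [])
        if not lst:
            return []
        starts = [s for s, _, _ in lst]
        i = bisect_right(starts, pos)
        lo = bisect_right(starts, pos - self._maxspan[chrom] - 1)
        return [g for s, e, g in lst[lo:i] if s <= pos <= e]


def _transcript_region(pos: int, tx: Transcript, coding: bool) -> str | None:
    """Region label contributed by one transcript, or None if out of range."""
    if tx.start <= pos <= tx.end:
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        if in_exon:
            if coding:
                in_cds = any(s <= pos <= e for s, e, _ in tx.cds)
                return "exonic" if in_cds else "UTR"
            return "ncRNA_exonic"
        # intronic; check splice proximity to the flanking exon edges
        for s, e in tx.exons:
            if 0 < s - pos <= SPLICE_WINDOW or 0 < pos - e <= SPLICE_WINDOW:
                return "splicing"
        return "intronic" if coding else "ncRNA_intronic"
    if tx.strand == "+":
        if tx.start - FLANK <= pos < tx.start:
            return "upstream"
        if tx.end < pos <= tx.end + FLANK:
            return "downstream"
    else:
        if tx.end < pos <= tx.end + FLANK:
            return "upstream"
        if tx.start - FLANK <= pos < tx.start:
            return "downstream"
    return None


def classify_region(
    chrom: str, pos: int, index: GeneIndex
) -> tuple[str, list[str]]:
    """Label one position; returns (region, host gene ids for that region)."""
    best = "intergenic"
    hosts: list[str] = []
    for gene in index.query(chrom, pos):
        for tx in gene.transcripts:
            label = _transcript_region(pos, tx, tx.is_coding)
            if label is None:
                continue
            if _RANK[label] < _RANK[best]:
                best, hosts = label, [gene.id]
            elif label == best and gene.id not in hosts:
                hosts.append(gene.id)
    return best, hosts


# ---------------------------------------------------------------------------
# Exonic consequence

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _spliced_cds_positions(tx: Transcript) -> list[int]:
    """Genomic positions of the CDS in transcription order."""
    pos: list[int] = []
    for s, e, _ in tx.cds:
        pos.extend(range(s, e + 1))
    if tx.strand == "-":
        pos.reverse()
    return pos


def exonic_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    tx: Transcript,
    reference: Reference,
) -> tuple[str, str, str]:
    """Consequence of substituting ``alt`` at ``pos`` within ``tx``'s CDS.

    Returns (label, codon_change, aa_change) where label is one of
    synonymous SNV / nonsynonymous SNV / stopgain / stoploss. The edited
    base is complemented for minus-strand transcripts before translation.
    """
    positions = _spliced_cds_positions(tx)
    # phase of the first CDS segment in transcription order trims partial codons
    if tx.strand == "+":
        offset = tx.cds[0][2]
    else:
        offset = tx.cds[-1][2]
    try:
        idx = positions.index(pos)
    except ValueError:
        raise ValueError(f"position {chrom}:{pos} is outside the CDS of {tx.id}")
    idx -= offset
    if idx < 0:
        raise ValueError(f"position {chrom}:{pos} falls in a partial codon of {tx.id}")
    codon_i, within = divmod(idx, 3)
    codon_pos = positions[offset + 3 * codon_i : offset + 3 * codon_i + 3]
    if len(codon_pos) < 3:
        raise ValueError(f"position {chrom}:{pos} falls in a partial codon of {tx.id}")

    def genome_base(p: int) -> str:
        b = reference.base(chrom, p)
        return COMPLEMENT[b] if tx.strand == "-" else b

    old_codon = "".join(genome_base(p) for p in codon_pos)
    alt_tx = COMPLEMENT[alt] if tx.strand == "-" else alt
    ref_tx = COMPLEMENT[ref] if tx.strand == "-" else ref
    if old_codon[within] != ref_tx:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: codon has {old_codon[within]}, "
            f"site says {ref_tx}"
        )
    new_codon = old_codon[:within] + alt_tx + old_codon[within + 1 :]

    old_aa = str(Seq(old_codon).translate(table=_STANDARD_TABLE))
    new_aa = str(Seq(new_codon).translate(table=_STANDARD_TABLE))
    if old_aa == new_aa:
        label = "synonymous SNV"
    elif old_aa != "*" and new_aa == "*":
        label = "stopgain"
    elif old_aa == "*" and new_aa != "*":
        label = "stoploss"
    else:
        label = "nonsynonymous SNV"
    return label, f"{old_codon}>{new_codon}", f"{old_aa}{codon_i + 1}{new_aa}"


# ---------------------------------------------------------------------------
# Table-level annotation

def annotate_sites(
    sites: pd.DataFrame, genes: list[Gene], reference: Reference
) -> pd.DataFrame:
    """Append region / class / exonic_func / gene / codon and aa change columns.

    When a site lands in the CDS of several transcripts the one with the
    longest CDS is used and the others are recorded in ``secondary_tx``.
    """
    index = GeneIndex(genes)
    by_id = {g.id: g for g in genes}
    out = sites.copy()
    regions, hosts_col, classes = [], [], []
    funcs, codons, aas, secondary = [], [], [], []
    for r in sites.itertuples():
        region, hosts = classify_region(r.chrom, int(r.pos), index)
        regions.append(region)
        hosts_col.append(",".join(hosts) if hosts else ".")
        classes.append(classify_substitution(r.ref, r.alt))
        func, codon, aa, sec = "n/a", ".", ".", "."
        if region == "exonic":
            cands = []
            for gid in hosts:
                for tx in by_id[gid].transcripts:
                    if tx.is_coding and any(
                        s <= r.pos <= e for s, e, _ in tx.cds
                    ):
                        cands.append(tx)
            cands.sort(key=lambda t: (-t.cds_length(), t.id))
            if cands:
                func, codon, aa = exonic_consequence(
                    r.chrom, int(r.pos), r.ref, r.alt, cands[0], reference
                )
                if len(cands) > 1:
                    sec = ",".join(t.id for t in cands[1:])
        funcs.append(func)
        codons.append(codon)
        aas.append(aa)
        secondary.append(sec)
    out["region"] = regions
    out["gene"] = hosts_col
    out["class"] = classes
    out["exonic_func"] = funcs
    out["codon_change"] = codons
    out["aa_change"] = aas
    out["secondary_tx"] = secondary
    return out


def summarize_annotations(
    annotated: pd.DataFrame, sample_ids: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-sample (and cohort) proportions of region, class, and function.

    A site counts toward a sample's tally when that sample's pass flag is
    set; the ``cohort`` column tallies every retained site. Each panel's
    proportions sum to 1 for every non-empty column.
    """
    panels = {}
    for panel, column in (
        ("region", "region"),
        ("class", "class"),
        ("function", "exonic_func"),
    ):
        sub = annotated
        if column == "exonic_func":
            sub = annotated[annotated[column] != "n/a"]
        counts = {"cohort": sub[column].value_counts()}
        if sample_ids:
            for sid in sample_ids:
                flag = f"{sid}_pass"
                if flag in annotated.columns:
                    counts[sid] = sub.loc[sub[flag].astype(bool), column].value_counts()
        df = pd.DataFrame(counts).fillna(0).astype(int)
        props = df / df.sum(axis=0).replace(0, pd.NA)
        panels[f"{panel}_counts"] = df
        panels[f"{panel}_proportions"] = props
    return panels
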