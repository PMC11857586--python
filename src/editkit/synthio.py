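"""Synthetic two-condition RNA-seq study with planted RNA-editing events.

The generator emulates the study design the pipeline is meant for: a
control and a treated group with three replicates each, editing sites
spanning frequencies 0.10-1.00 whose substitution classes are ~80%
C-to-U / A-to-I, a subset of sites with condition-specific frequency
shifts, and negative-binomial gene expression with a differential
subset.

Coverage model: each gene is transcribed together with a 1 kb flank on
either side (a pre-mRNA-plus-readthrough abstraction), with reads
placed uniformly in that window. This gives exonic, intronic, upstream
and downstream positions real coverage without splice-aware CIGARs,
which the pipeline does not need. Reads are single-end, all-match
alignments; base quality is uniform 35 except at simulated sequencing
errors, which are written with quality 15 so the base-quality filter
has something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import annotate
from .formats import (
    Gene,
    Reference,
    Sample,
    SampleSheet,
    Transcript,
    write_fasta,
    write_gff3,
    write_sample_sheet,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_STR = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join((a, b, c)) for a in BASE_STR for b in BASE_STR for c in BASE_STR]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS and c != "ATG"] + ["ATG"]
_COMP = bytes.maketrans(b"ACGT", b"TGCA")

#: the 12 reference-forward substitution classes
SUBSTITUTIONS = [(r, a) for r in BASE_STR for a in BASE_STR if r != a]


def default_type_mix() -> dict[tuple[str, str], float]:
    """~80% C-to-U + A-to-I (20% on each arm), remainder spread evenly."""
    major = {("C", "T"): 0.2, ("G", "A"): 0.2, ("A", "G"): 0.2, ("T", "C"): 0.2}
    minor = [s for s in SUBSTITUTIONS if s not in major]
    mix = dict(major)
    for s in minor:
        mix[s] = 0.2 / len(minor)
    return mix


class SizingError(ValueError):
    """The requested study does not fit in the configured genome."""


@dataclass
class SimConfig:
    genome_length: int = 600_000
    n_genes: int = 200
    n_replicates_per_condition: int = 3
    n_editing_sites: int = 2000
    frac_differential_sites: float = 0.15
    # non-differential per-site frequency ~ Beta(a, b) truncated to the band
    freq_beta: tuple[float, float] = (2.0, 2.0)
    freq_band: tuple[float, float] = (0.10, 1.00)
    # differential sites toggle between these two frequencies across conditions
    diff_freq_low: float = 0.2
    diff_freq_high: float = 0.5
    type_mix: dict[tuple[str, str], float] = field(default_factory=default_type_mix)
    mean_depth: float = 30.0
    depth_dispersion: float = 0.05
    seq_error_rate: float = 0.001
    read_length: int = 100
    frac_de_genes: float = 0.10
    de_log2fc: float = 1.5
    frac_ncrna_genes: float = 0.15
    expr_lognorm_sigma: float = 0.3
    min_spacer: int = 2100
    allow_subthreshold: bool = False
    seed: int = 0

    conditions: tuple[str, str] = ("control", "treated")

    def __post_init__(self):
        for name in (
            "frac_differential_sites",
            "seq_error_rate",
            "frac_de_genes",
            "frac_ncrna_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not a proportion")
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mix sums to {total}, not 1")
        if self.n_replicates_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")
        if not (0 <= self.freq_band[0] <= self.freq_band[1] <= 1):
            raise ValueError("freq_band must be within [0, 1]")
        if self.diff_freq_low >= self.diff_freq_high:
            raise ValueError("diff_freq_low must be < diff_freq_high")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond in self.conditions
            for i in range(self.n_replicates_per_condition)
        ]


@dataclass
class TruthTable:
    """The simulator's record of what it planted, for recovery scoring."""

    sites: pd.DataFrame  # one row per planted site
    genes: pd.DataFrame  # one row per gene: expression truth

    def differential_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["is_differential"]]


# ---------------------------------------------------------------------------
# Genome + annotation

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + one stop; no internal stop codons."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[Gene]]:
    """Random genome with non-overlapping gene models on both strands.

    Every coding transcript's CDS starts with ATG, ends with a stop, is a
    multiple of 3 long and contains no internal stop. Genes are separated
    by at least ``min_spacer`` so the 1 kb flank windows never reach into
    a neighboring gene body.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome = rng.choice(BASES, size=config.genome_length).tobytes().decode()
    genome = bytearray(genome, "ascii")
    genes: list[Gene] = []
    cursor = config.min_spacer + 1  # 1-based; leave a leading spacer
    for gi in range(config.n_genes):
        is_ncrna = rng.random() < config.frac_ncrna_genes
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{gi + 1:04d}"
        if is_ncrna:
            length = int(rng.integers(200, 601))
            start, end = cursor, cursor + length - 1
            if end + config.min_spacer > config.genome_length:
                raise SizingError(
                    f"genome_length={config.genome_length} too small to place "
                    f"{config.n_genes} genes with spacer {config.min_spacer}"
                )
            tx = Transcript(id=f"{gid}.t1", strand=strand, exons=[(start, end)])
            genes.append(
                Gene(gid, chrom, start, end, strand, "ncRNA", [tx])
            )
        else:
            n_codons = int(rng.integers(100, 301))
            cds_seq = _random_cds(rng, n_codons)
            n_exons = int(rng.integers(1, 4))
            # split CDS into exon chunks (each >= 20 bp to keep splice sites apart)
            if n_exons > 1:
                cuts = np.sort(
                    rng.choice(
                        np.arange(20, len(cds_seq) - 20), size=n_exons - 1, replace=False
                    )
                )
            else:
                cuts = np.array([], dtype=int)
            chunks = np.split(np.frombuffer(cds_seq.encode(), dtype=np.uint8), cuts)
            introns = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]

            if strand == "-":
                # write the reverse complement; transcription order is reversed
                chunks = [
                    np.frombuffer(bytes(c).translate(_COMP)[::-1], dtype=np.uint8)
                    for c in reversed(chunks)
                ]
            exons: list[tuple[int, int]] = []
            pos = cursor
            for k, chunk in enumerate(chunks):
                s, e = pos, pos + len(chunk) - 1
                exons.append((s, e))
                genome[s - 1 : e] = chunk.tobytes()
                pos = e + 1 + (introns[k] if k < len(introns) else 0)
            start, end = exons[0][0], exons[-1][1]
            if end + config.min_spacer > config.genome_length:
                raise SizingError(
                    f"genome_length={config.genome_length} too small to place "
                    f"{config.n_genes} genes with spacer {config.min_spacer}"
                )
            # GFF3 phase per segment, in transcription order
            order = exons if strand == "+" else list(reversed(exons))
            cds = []
            cum = 0
            for s, e in order:
                cds.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            cds.sort()
            tx = Transcript(id=f"{gid}.t1", strand=strand, exons=exons, cds=cds)
            genes.append(
                Gene(gid, chrom, start, end, strand, "protein_coding", [tx])
            )
        cursor = end + 1 + config.min_spacer
    return {chrom: bytes(genome).decode()}, genes


# ---------------------------------------------------------------------------
# Planting

def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=max(size, 64))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def plant_editing_sites(
    config: SimConfig,
    reference: Reference,
    genes: list[Gene],
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Choose editing positions, classes, and per-condition frequencies.

    Classes are drawn from ``type_mix`` and matched to positions whose
    reference base fits; sites land only in gene bodies or their 1 kb
    flanks so non-intergenic region classes dominate. Region and
    consequence labels are computed at planting time with the same
    classifier the pipeline uses.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom = reference.names[0]
    L = reference.length(chrom)

    pool: set[int] = set()
    for g in genes:
        lo = max(1, g.start - annotate.FLANK)
        hi = min(L, g.end + annotate.FLANK)
        pool.update(range(lo, hi + 1))
    positions = np.array(sorted(pool))
    if config.n_editing_sites > len(positions):
        raise SizingError(
            f"{config.n_editing_sites} sites requested but only "
            f"{len(positions)} plantable positions exist"
        )
    seq = np.frombuffer(reference.sequence(chrom).encode(), dtype=np.uint8)
    by_base: dict[str, list[int]] = {}
    for b in BASE_STR:
        cand = positions[seq[positions - 1] == ord(b)]
        perm = rng.permutation(len(cand))
        by_base[b] = [int(x) for x in cand[perm]]

    classes = list(config.type_mix)
    probs = np.array([config.type_mix[c] for c in classes])
    class_idx = rng.choice(len(classes), size=config.n_editing_sites, p=probs)

    n_diff = int(round(config.frac_differential_sites * config.n_editing_sites))
    is_diff = np.zeros(config.n_editing_sites, dtype=bool)
    is_diff[rng.permutation(config.n_editing_sites)[:n_diff]] = True

    lo, hi = (0.01, 1.0) if config.allow_subthreshold else config.freq_band
    base_freq = _truncated_beta(
        rng, *config.freq_beta, lo, hi, config.n_editing_sites
    )
    up_in_treated = rng.random(config.n_editing_sites) < 0.5

    index = annotate.GeneIndex(genes)
    by_id = {g.id: g for g in genes}
    rows = []
    for i in range(config.n_editing_sites):
        ref_b, alt_b = classes[class_idx[i]]
        if not by_base[ref_b]:
            raise SizingError(f"ran out of plantable positions with base {ref_b}")
        pos = by_base[ref_b].pop()
        if is_diff[i]:
            f_ctrl, f_trt = (
                (config.diff_freq_low, config.diff_freq_high)
                if up_in_treated[i]
                else (config.diff_freq_high, config.diff_freq_low)
            )
        else:
            f_ctrl = f_trt = float(base_freq[i])
        region, hosts = annotate.classify_region(chrom, pos, index)
        consequence = "n/a"
        if region == "exonic":
            cands = [
                tx
                for gid in hosts
                for tx in by_id[gid].transcripts
                if tx.is_coding and any(s <= pos <= e for s, e, _ in tx.cds)
            ]
            cands.sort(key=lambda t: (-t.cds_length(), t.id))
            consequence, _, _ = annotate.exonic_consequence(
                chrom, pos, ref_b, alt_b, cands[0], reference
            )
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref_b,
                "alt": alt_b,
                "freq_control": f_ctrl,
                "freq_treated": f_trt,
                "is_differential": bool(is_diff[i]),
                "gene": hosts[0] if hosts else "intergenic",
                "region": region,
                "consequence": consequence,
            }
        )
    site_columns = [
        "chrom", "pos", "ref", "alt", "freq_control", "freq_treated",
        "is_differential", "gene", "region", "consequence",
    ]
    sites = (
        pd.DataFrame(rows, columns=site_columns)
        .sort_values("pos", kind="mergesort")
        .reset_index(drop=True)
    )

    # gene expression truth
    n_de = int(round(config.frac_de_genes * len(genes)))
    de_mask = np.zeros(len(genes), dtype=bool)
    de_mask[rng.permutation(len(genes))[:n_de]] = True
    base = rng.lognormal(mean=0.0, sigma=config.expr_lognorm_sigma, size=len(genes))
    de_sign = np.where(rng.random(len(genes)) < 0.5, 1.0, -1.0)
    lfc = np.where(de_mask, de_sign * config.de_log2fc, 0.0)
    gene_truth = pd.DataFrame(
        {
            "gene": [g.id for g in genes],
            "expr_control": base,
            "expr_treated": base * np.power(2.0, lfc),
            "is_de": de_mask,
            "true_log2fc": lfc,
        }
    )
    return TruthTable(sites=sites, genes=gene_truth)


# ---------------------------------------------------------------------------
# Read emission

QUAL_GOOD = 35
QUAL_ERR = 15


def emit_reads(
    config: SimConfig,
    reference: Reference,
    genes: list[Gene],
    truth: TruthTable,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[SampleSheet, pd.DataFrame]:
    """Write one coordinate-sorted SAM per sample; returns sheet + gene counts.

    Per gene and sample the read count is NB-distributed around
    ``mean_depth × window / read_length`` scaled by the gene's true
    expression for that condition. Each read covering a planted site
    carries the alt allele with that condition's frequency; independent
    errors mutate bases at ``seq_error_rate`` and are written with
    quality 15. Truth columns ``<sample>_alt`` / ``<sample>_ref`` record
    the quality-35 allele counts actually emitted at each site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = reference.names[0]
    L = reference.length(chrom)
    seq_arr = np.frombuffer(reference.sequence(chrom).encode(), dtype=np.uint8)
    rl = config.read_length

    site_pos = truth.sites["pos"].to_numpy()
    site_alt = np.array([ord(a) for a in truth.sites["alt"]], dtype=np.uint8)
    site_ref = np.array([ord(r) for r in truth.sites["ref"]], dtype=np.uint8)
    gene_expr = truth.genes.set_index("gene")

    truth_counts = {
        f"{sid}_{k}": np.zeros(len(truth.sites), dtype=int)
        for sid in config.sample_ids
        for k in ("alt", "ref")
    }
    gene_count_rows: dict[str, dict[str, int]] = {g.id: {} for g in genes}
    samples = []
    for cond in config.conditions:
        freq_col = truth.sites[f"freq_{cond}"].to_numpy()
        for rep in range(config.n_replicates_per_condition):
            sid = f"{cond}_{rep + 1}"
            path = outdir / f"{sid}.sam"
            starts_all, seqs_all, quals_all = [], [], []
            for g in genes:
                wlo = max(1, g.start - annotate.FLANK)
                whi = min(L, g.end + annotate.FLANK)
                if whi - wlo + 1 < rl:
                    continue
                expr = float(gene_expr.loc[g.id, f"expr_{cond}"])
                mean_reads = config.mean_depth * (whi - wlo + 1) / rl * expr
                if config.depth_dispersion > 0:
                    lam = rng.gamma(
                        1.0 / config.depth_dispersion,
                        mean_reads * config.depth_dispersion,
                    )
                else:
                    lam = mean_reads
                n = int(rng.poisson(lam))
                gene_count_rows[g.id][sid] = n
                if n == 0:
                    continue
                starts = rng.integers(wlo, whi - rl + 2, size=n)  # 1-based
                reads = np.empty((n, rl), dtype=np.uint8)
                for j, s in enumerate(starts):
                    reads[j] = seq_arr[s - 1 : s - 1 + rl]
                quals = np.full((n, rl), QUAL_GOOD, dtype=np.uint8)

                in_win = np.nonzero((site_pos >= wlo) & (site_pos <= whi))[0]
                for si in in_win:
                    p = site_pos[si]
                    cov = np.nonzero((starts <= p) & (starts + rl > p))[0]
                    if len(cov) == 0:
                        continue
                    edited = cov[rng.random(len(cov)) < freq_col[si]]
                    reads[edited, p - starts[edited]] = site_alt[si]
                if config.seq_error_rate > 0:
                    err = rng.random((n, rl)) < config.seq_error_rate
                    er, ec = np.nonzero(err)
                    if len(er):
                        old = reads[er, ec]
                        # uniform over the three other bases
                        shift = rng.integers(1, 4, size=len(er)).astype(np.uint8)
                        idx = np.searchsorted(BASES, old)
                        reads[er, ec] = BASES[(idx + shift) % 4]
                        quals[er, ec] = QUAL_ERR
                # emitted-truth allele counts at q35
                for si in in_win:
                    p = site_pos[si]
                    cov = np.nonzero((starts <= p) & (starts + rl > p))[0]
                    if len(cov) == 0:
                        continue
                    base_at = reads[cov, p - starts[cov]]
                    q_at = quals[cov, p - starts[cov]]
                    good = q_at == QUAL_GOOD
                    truth_counts[f"{sid}_alt"][si] += int(
                        np.sum(good & (base_at == site_alt[si]))
                    )
                    truth_counts[f"{sid}_ref"][si] += int(
                        np.sum(good & (base_at == site_ref[si]))
                    )
                starts_all.append(starts)
                seqs_all.append(reads)
                quals_all.append(quals)

            if starts_all:
                starts_cat = np.concatenate(starts_all)
                seqs_cat = np.concatenate(seqs_all)
                quals_cat = np.concatenate(quals_all)
            else:
                starts_cat = np.array([], dtype=int)
                seqs_cat = np.empty((0, rl), dtype=np.uint8)
                quals_cat = np.empty((0, rl), dtype=np.uint8)
            order = np.argsort(starts_cat, kind="mergesort")
            _write_sam(
                path, chrom, L, starts_cat[order], seqs_cat[order], quals_cat[order], sid
            )
            samples.append(
                Sample(sid, str(path), cond, rep + 1)
            )

    for k, v in truth_counts.items():
        truth.sites[k] = v
    gene_counts = pd.DataFrame(gene_count_rows).T.reindex(
        [g.id for g in genes]
    ).fillna(0).astype(int)
    gene_counts.index.name = "gene"
    gene_counts = gene_counts[config.sample_ids]
    sheet = SampleSheet(samples)
    return sheet, gene_counts


def _write_sam(path, chrom, chrom_len, starts, seqs, quals, sid):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(chrom_len)}],
        "RG": [{"ID": sid, "SM": sid}],
    }
    rl = seqs.shape[1] if len(seqs) else 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(len(starts)):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"{sid}.r{i}"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = int(starts[i]) - 1
            rec.mapping_quality = 60
            rec.cigartuples = [(0, rl)]
            rec.query_sequence = seqs[i].tobytes().decode()
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals[i])
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# Whole-study convenience

@dataclass
class SimStudy:
    config: SimConfig
    reference: Reference
    genes: list[Gene]
    truth: TruthTable
    sheet: SampleSheet
    gene_counts: pd.DataFrame
    outdir: Path


def simulate_study(config: SimConfig, outdir: str | Path) -> SimStudy:
    """Run genome → planting → read emission and write every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_plant, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    sequences, genes = simulate_genome(config, rng_genome)
    write_fasta(outdir / "genome.fa", sequences)
    write_gff3(outdir / "genes.gff3", genes)
    reference = Reference(sequences)
    truth = plant_editing_sites(config, reference, genes, rng_plant)
    sheet, gene_counts = emit_reads(
        config, reference, genes, truth, outdir, rng_reads
    )
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    gene_counts.to_csv(outdir / "true_gene_counts.tsv", sep="\t")
    write_sample_sheet(outdir / "samples.tsv", sheet)
    return SimStudy(config, reference, genes, truth, sheet, gene_counts, outdir)
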