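"""Readers and writers for the standard formats the pipeline touches.

All serialized coordinates are 1-based inclusive (GFF3 convention). Any
half-open arithmetic is internal and never leaks into an output file.
Plain-text formats are read and written transparently through gzip when
the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed input file (duplicate ids, orphan parents, bad columns)."""


class BoundsError(IndexError):
    """A genomic slice fell outside the sequence it addresses."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

class Reference:
    """In-memory reference genome with random access, uppercase-normalized.

    ``slice`` takes 1-based inclusive coordinates, mirroring GFF3 and the
    site tables, and raises :class:`BoundsError` on out-of-range queries.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        if chrom not in self._seqs:
            raise BoundsError(f"unknown sequence {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise BoundsError(
                f"slice {chrom}:{start}-{end} outside sequence of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.slice(chrom, pos, pos)


def read_fasta(path: str | Path) -> Reference:
    """Load a FASTA file into a :class:`Reference` (uppercase)."""
    seqs: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seqs:
                raise FormatError(f"duplicate sequence name {record.id!r}")
            seqs[record.id] = str(record.seq)
    return Reference(seqs)


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3

@dataclass
class Transcript:
    id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"  # or "ncRNA"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts)


def read_gff3(path: str | Path) -> list[Gene]:
    """Parse a gene/mRNA/exon/CDS GFF3 hierarchy into :class:`Gene` models.

    Orphan ``Parent`` references raise :class:`FormatError` naming the ids.
    A gene whose transcripts carry no CDS row is flagged ``ncRNA``.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    tx_parent: dict[str, str] = {}
    orphans: list[str] = []

    rows = []
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"GFF3 row with {len(parts)} columns: {line!r}")
            rows.append(parts)

    def attrs(s: str) -> dict[str, str]:
        out = {}
        for item in s.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                out[k.strip()] = v.strip()
        return out

    for chrom, _src, ftype, start, end, _score, strand, phase, attr in rows:
        a = attrs(attr)
        start_i, end_i = int(start), int(end)
        if ftype == "gene":
            gid = a["ID"]
            if gid in genes:
                raise FormatError(f"duplicate gene id {gid!r}")
            genes[gid] = Gene(
                id=gid, chrom=chrom, start=start_i, end=end_i, strand=strand,
                biotype=a.get("biotype", "protein_coding"),
            )
        elif ftype in ("mRNA", "transcript", "ncRNA"):
            tid, parent = a["ID"], a["Parent"]
            transcripts[tid] = Transcript(id=tid, strand=strand)
            tx_parent[tid] = parent
        elif ftype == "exon":
            parent = a["Parent"]
            if parent not in transcripts:
                orphans.append(parent)
                continue
            transcripts[parent].exons.append((start_i, end_i))
        elif ftype == "CDS":
            parent = a["Parent"]
            if parent not in transcripts:
                orphans.append(parent)
                continue
            ph = 0 if phase == "." else int(phase)
            transcripts[parent].cds.append((start_i, end_i, ph))

    for tid, parent in tx_parent.items():
        if parent not in genes:
            orphans.append(parent)
            continue
        tx = transcripts[tid]
        tx.exons.sort()
        tx.cds.sort()
        genes[parent].transcripts.append(tx)

    if orphans:
        raise FormatError(f"orphan Parent references: {sorted(set(orphans))}")

    out = list(genes.values())
    for g in out:
        if not g.is_coding:
            g.biotype = "ncRNA"
        g.transcripts.sort(key=lambda t: t.id)
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def write_gff3(path: str | Path, genes: list[Gene]) -> None:
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            out.write(
                f"{g.chrom}\tsynthio\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id};biotype={g.biotype}\n"
            )
            for tx in g.transcripts:
                ftype = "mRNA" if tx.is_coding else "ncRNA"
                out.write(
                    f"{g.chrom}\tsynthio\t{ftype}\t{tx.start}\t{tx.end}\t.\t"
                    f"{tx.strand}\t.\tID={tx.id};Parent={g.id}\n"
                )
                for s, e in tx.exons:
                    out.write(
                        f"{g.chrom}\tsynthio\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                        f"Parent={tx.id}\n"
                    )
                for s, e, ph in tx.cds:
                    out.write(
                        f"{g.chrom}\tsynthio\tCDS\t{s}\t{e}\t.\t{tx.strand}\t{ph}\t"
                        f"Parent={tx.id}\n"
                    )


# ---------------------------------------------------------------------------
# Sample sheets

@dataclass(frozen=True)
class Sample:
    sample_id: str
    path: str
    condition: str  # "control" | "treated"
    replicate: int


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("sample ids are not unique")
        for cond in self.conditions:
            if sum(s.condition == cond for s in self.samples) < 2:
                raise FormatError(f"condition {cond!r} has fewer than 2 replicates")

    @property
    def ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def condition_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.condition
        raise KeyError(sample_id)

    def ids_for(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    samples = [
        Sample(r.sample_id, r.path, r.condition, int(r.replicate))
        for r in df.itertuples()
    ]
    return SampleSheet(samples)


def write_sample_sheet(path: str | Path, sheet: SampleSheet) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "path": s.path,
                "condition": s.condition,
                "replicate": s.replicate,
            }
            for s in sheet.samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments

class AlignmentReader:
    """Iterate mapped, primary, non-duplicate records of a sorted SAM/BAM.

    Unmapped, secondary and supplementary records are skipped and counted
    in :attr:`skipped`. Iteration raises if coordinates go backwards,
    which catches unsorted input without an upfront pass.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.skipped = 0
        self._af = pysam.AlignmentFile(self.path, check_sq=False)

    @property
    def references(self) -> list[str]:
        return list(self._af.references)

    def __iter__(self) -> Iterator[pysam.AlignedSegment]:
        last: tuple[int, int] | None = None
        for rec in self._af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                self.skipped += 1
                continue
            key = (rec.reference_id, rec.reference_start)
            if last is not None and key < last:
                raise FormatError(
                    f"{self.path} is not coordinate-sorted; sort it first "
                    "(samtools sort or equivalent)"
                )
            last = key
            yield rec

    def close(self) -> None:
        self._af.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_alignments(path: str | Path) -> AlignmentReader:
    return AlignmentReader(path)


# ---------------------------------------------------------------------------
# Site tables

SITE_KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


def write_site_table(path: str | Path, table: pd.DataFrame) -> None:
    """Serialize a site table as TSV; positions stay 1-based."""
    df = table.sort_values(["chrom", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"site table missing columns {missing}")
    return df


def write_vcf_like(path: str | Path, table: pd.DataFrame, sample_ids: list[str]) -> None:
    """Convenience VCF-style export with editing frequency in an INFO column."""
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##INFO=<ID=EF,Number=.,Type=Float,Description=\"Per-sample editing frequency\">\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in table.sort_values(["chrom", "pos"]).itertuples():
            freqs = ",".join(
                f"{getattr(r, f'{sid}_freq'):.4f}"
                if pd.notna(getattr(r, f"{sid}_freq")) else "."
                for sid in sample_ids
            )
            out.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tEF={freqs}\n"
            )
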