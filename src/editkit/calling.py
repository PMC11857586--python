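"""Pileup construction and editing-site calling.

The caller applies the filter set: base quality >= 25 before any
counting, site depth (ref+alt) >= 5, alternative allele depth >= 3,
per-sample editing frequency inside [0.10, 1.00], and cohort retention
when at least two samples pass with frequency >= 0.10. All reference
mismatches surviving the filters are candidate editing sites — there is
no genomic-DNA subtraction, which is a documented caveat of the method.

Counting is commutative, so the site list is independent of read
iteration order; a brute-force per-position recount must agree exactly
(see the test suite's oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import AlignmentReader, Reference, SampleSheet

BASE_ORDER = "ACGT"
_BASE_IDX = {ord(b): i for i, b in enumerate(BASE_ORDER)}
_IDX_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_IDX.items():
    _IDX_LUT[_b] = _i


class CallerError(ValueError):
    pass


@dataclass
class FilterConfig:
    min_base_quality: int = 25
    min_depth: int = 5
    min_alt_depth: int = 3
    frequency_band: tuple[float, float] = (0.10, 1.00)
    min_supporting_samples: int = 2
    min_editing_level: float = 0.10

    def __post_init__(self):
        lo, hi = self.frequency_band
        if not (0 <= lo <= hi <= 1):
            raise ValueError("frequency_band must lie within [0, 1]")
        for name in ("min_base_quality", "min_depth", "min_alt_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PileupColumn:
    """Quality-filtered base observations of one sample at one position."""

    chrom: str
    pos: int  # 1-based
    bases: list[str] = field(default_factory=list)
    quals: list[int] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        out = np.zeros(4, dtype=int)
        for b in self.bases:
            i = _BASE_IDX.get(ord(b), -1)
            if i >= 0:
                out[i] += 1
        return out


@dataclass
class Observation:
    """One sample's passing evidence for a candidate site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def frequency(self) -> float:
        return self.alt_count / self.depth


class SamplePileup:
    """Per-chromosome 4 x L matrices of quality-filtered base counts."""

    def __init__(self, counts: dict[str, np.ndarray], sample_id: str = ""):
        self.counts = counts
        self.sample_id = sample_id

    def column(self, chrom: str, pos: int) -> np.ndarray:
        """Base counts (A,C,G,T) at a 1-based position."""
        return self.counts[chrom][:, pos - 1]


def build_pileup(
    reader: AlignmentReader,
    reference: Reference,
    min_base_quality: int = 25,
    sample_id: str = "",
) -> SamplePileup:
    """Count quality-passing bases per position for one sample.

    Base calls with quality below ``min_base_quality`` and N bases never
    enter the counts. Reads naming a chromosome absent from the
    reference raise :class:`CallerError`.
    """
    counts = {
        chrom: np.zeros((4, reference.length(chrom)), dtype=np.uint32)
        for chrom in reference.names
    }
    buf_pos: list[np.ndarray] = []
    buf_base: list[np.ndarray] = []
    buffered = 0

    def flush(chrom: str):
        nonlocal buffered
        if not buf_pos:
            return
        pos = np.concatenate(buf_pos)
        base = np.concatenate(buf_base)
        np.add.at(counts[chrom], (base, pos), 1)
        buf_pos.clear()
        buf_base.clear()
        buffered = 0

    current_chrom: str | None = None
    for rec in reader:
        chrom = rec.reference_name
        if chrom not in counts:
            raise CallerError(f"read {rec.query_name} maps to unknown chromosome {chrom!r}")
        if chrom != current_chrom:
            if current_chrom is not None:
                flush(current_chrom)
            current_chrom = chrom
        quals = np.asarray(rec.query_qualities, dtype=np.int16)
        seq = np.frombuffer(rec.query_sequence.encode(), dtype=np.uint8)
        ct = rec.cigartuples
        if len(ct) == 1 and ct[0][0] == 0:
            refpos = np.arange(rec.reference_start, rec.reference_start + len(seq))
            qpos = np.arange(len(seq))
        else:
            pairs = rec.get_aligned_pairs(matches_only=True)
            qpos = np.array([q for q, _ in pairs], dtype=int)
            refpos = np.array([r for _, r in pairs], dtype=int)
        bidx = _IDX_LUT[seq[qpos]]
        keep = (quals[qpos] >= min_base_quality) & (bidx >= 0)
        buf_pos.append(refpos[keep])
        buf_base.append(bidx[keep].astype(np.int64))
        buffered += int(keep.sum())
        if buffered > 2_000_000:
            flush(chrom)
    if current_chrom is not None:
        flush(current_chrom)
    return SamplePileup(counts, sample_id)


def build_pileups(
    sheet: SampleSheet, reference: Reference, min_base_quality: int = 25
) -> dict[str, SamplePileup]:
    pileups = {}
    for s in sheet.samples:
        with AlignmentReader(s.path) as reader:
            pileups[s.sample_id] = build_pileup(
                reader, reference, min_base_quality, s.sample_id
            )
    return pileups


def call_candidate(
    column: PileupColumn | np.ndarray,
    ref_base: str,
    filt: FilterConfig,
    chrom: str = "",
    pos: int = 0,
) -> Observation | None:
    """Apply the per-sample site filters to one pileup column.

    The alt allele is the most frequent non-reference base, ties broken
    in A<C<G<T order (argmax on that ordering). Depth is ref+alt after
    quality filtering; a column passes iff depth >= min_depth, alt count
    >= min_alt_depth and frequency within the closed band.
    """
    if isinstance(column, PileupColumn):
        chrom, pos = column.chrom, column.pos
        base_counts = column.counts()
    else:
        base_counts = np.asarray(column)
    ref_i = _BASE_IDX[ord(ref_base)]
    nonref = base_counts.copy()
    nonref[ref_i] = 0
    alt_i = int(np.argmax(nonref))
    alt_count = int(nonref[alt_i])
    if alt_count == 0:
        return None
    ref_count = int(base_counts[ref_i])
    depth = ref_count + alt_count
    freq = alt_count / depth
    lo, hi = filt.frequency_band
    if depth < filt.min_depth or alt_count < filt.min_alt_depth:
        return None
    if not (lo <= freq <= hi):
        return None
    return Observation(chrom, pos, ref_base, BASE_ORDER[alt_i], ref_count, alt_count)


def _sample_candidates(
    pileup: SamplePileup, reference: Reference, filt: FilterConfig
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized per-sample calling: per chrom (pos, alt_idx, ref_c, alt_c, ambiguous)."""
    out = {}
    lo, hi = filt.frequency_band
    for chrom, counts in pileup.counts.items():
        seq = np.frombuffer(reference.sequence(chrom).encode(), dtype=np.uint8)
        ref_idx = _IDX_LUT[seq]
        Lpos = np.arange(counts.shape[1])
        valid_ref = ref_idx >= 0
        ref_c = np.where(valid_ref, counts[np.clip(ref_idx, 0, 3), Lpos], 0)
        nonref = counts.copy()
        nonref[np.clip(ref_idx, 0, 3), Lpos] = 0
        alt_idx = np.argmax(nonref, axis=0)
        alt_c = np.take_along_axis(nonref, alt_idx[None, :], axis=0)[0]
        depth = ref_c + alt_c
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(depth > 0, alt_c / np.maximum(depth, 1), 0.0)
        passing = (
            valid_ref
            & (alt_c >= filt.min_alt_depth)
            & (depth >= filt.min_depth)
            & (freq >= lo)
            & (freq <= hi)
        )
        # a second non-ref allele that would itself pass marks the column ambiguous
        nonref2 = nonref.copy()
        np.put_along_axis(nonref2, alt_idx[None, :], 0, axis=0)
        alt2_c = nonref2.max(axis=0)
        depth2 = ref_c + alt2_c
        with np.errstate(invalid="ignore", divide="ignore"):
            freq2 = np.where(depth2 > 0, alt2_c / np.maximum(depth2, 1), 0.0)
        ambiguous = (
            passing
            & (alt2_c >= filt.min_alt_depth)
            & (depth2 >= filt.min_depth)
            & (freq2 >= lo)
            & (freq2 <= hi)
        )
        idx = np.nonzero(passing)[0]
        out[chrom] = (
            idx + 1,
            alt_idx[idx],
            ref_c[idx],
            alt_c[idx],
            ambiguous[idx],
        )
    return out


def merge_cohort(
    pileups: dict[str, SamplePileup],
    reference: Reference,
    sheet: SampleSheet,
    filt: FilterConfig | None = None,
) -> pd.DataFrame:
    """Cohort-level site table under the retention rule.

    A site keyed by (chrom, pos, alt) is retained iff at least
    ``min_supporting_samples`` samples have a passing observation with
    frequency >= ``min_editing_level``. For retained sites, ref/alt
    counts and frequency are filled for every sample by re-querying the
    pileups; samples with zero ref+alt depth get a missing frequency.
    """
    filt = filt or FilterConfig()
    sample_ids = sheet.ids
    if len(sample_ids) < 2:
        raise CallerError("cohort calling needs at least 2 samples")

    support: dict[tuple[str, int, int], int] = {}
    passing_by_sample: dict[str, set[tuple[str, int, int]]] = {}
    ambiguous_keys: set[tuple[str, int, int]] = set()
    for sid in sample_ids:
        cands = _sample_candidates(pileups[sid], reference, filt)
        mine = set()
        for chrom, (pos, alt_i, ref_c, alt_c, amb) in cands.items():
            freq = alt_c / (ref_c + alt_c)
            ok = freq >= filt.min_editing_level
            for p, a, f, amb_f in zip(pos[ok], alt_i[ok], freq[ok], amb[ok]):
                key = (chrom, int(p), int(a))
                support[key] = support.get(key, 0) + 1
                mine.add(key)
                if amb_f:
                    ambiguous_keys.add(key)
        passing_by_sample[sid] = mine

    retained = sorted(
        k for k, n in support.items() if n >= filt.min_supporting_samples
    )
    rows = []
    for chrom, pos, alt_i in retained:
        ref_base = reference.base(chrom, pos)
        row: dict = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref_base,
            "alt": BASE_ORDER[alt_i],
            "n_supporting": support[(chrom, pos, alt_i)],
            "ambiguous": (chrom, pos, alt_i) in ambiguous_keys,
        }
        ref_i = _BASE_IDX[ord(ref_base)]
        for sid in sample_ids:
            col = pileups[sid].column(chrom, pos)
            rc, ac = int(col[ref_i]), int(col[alt_i])
            depth = rc + ac
            row[f"{sid}_ref"] = rc
            row[f"{sid}_alt"] = ac
            row[f"{sid}_freq"] = ac / depth if depth > 0 else np.nan
            row[f"{sid}_pass"] = (chrom, pos, alt_i) in passing_by_sample[sid]
        rows.append(row)
    columns = (
        ["chrom", "pos", "ref", "alt", "n_supporting", "ambiguous"]
        + [f"{sid}_{k}" for sid in sample_ids for k in ("ref", "alt", "freq", "pass")]
    )
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def frequency_matrix(
    sites: pd.DataFrame, sheet: SampleSheet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sites x samples editing-frequency matrix plus per-condition means.

    Depth-0 entries are missing (NaN) and excluded from group means; a
    group with no defined value yields a missing mean.
    """
    idx = [
        f"{r.chrom}:{r.pos}:{r.alt}" for r in sites.itertuples()
    ]
    mat = pd.DataFrame(
        {sid: sites[f"{sid}_freq"].to_numpy() for sid in sheet.ids}, index=idx
    )
    means = pd.DataFrame(
        {
            cond: mat[sheet.ids_for(cond)].mean(axis=1, skipna=True)
            for cond in sheet.conditions
        },
        index=idx,
    )
    return mat, means
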