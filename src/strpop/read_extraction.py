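"""Informative-read selection and per-read attributes.

For each marker, informative reads come from three sources: (1) reads
aligned across the marker that carry a repeat tract of its motif, (2)
unaligned reads whose mates align close to the marker (placed at the
mate's coordinate by the aligner), and (3) reads aligned inside another
catalog marker of the same canonical motif whose mates align close to the
target marker.  Source (3) recovers reads from dramatically expanded
alleles that the aligner mapped to a longer repeat elsewhere.

Each recruited read gets a repeat tract (maximal window matching the
periodic extension of the motif on either strand) and a fixed-order
vector of six quality attributes consumed by the genotyping model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from . import config as cfg
from .markers import MarkerDef, canonical_motif, reverse_complement

logger = logging.getLogger(__name__)

SOURCES = ("overlap", "unaligned_mate", "offsite_same_motif")

READ_TABLE_COLUMNS = [
    "marker_id", "sample_id", "read_id", "reported_units", "purity",
    "a1", "a2", "a3", "a4", "a5", "a6", "source",
    "lower_bound", "fully_repetitive",
]


@dataclass(frozen=True)
class RepeatTract:
    """A detected repeat tract within one read (offsets are 0-based, end-exclusive)."""

    read_offset_start: int
    read_offset_end: int
    units: float
    purity: float

    def __post_init__(self) -> None:
        if not 0 <= self.read_offset_start < self.read_offset_end:
            raise ValueError("invalid tract offsets")
        if not 0.0 <= self.purity <= 1.0 + 1e-12:
            raise ValueError("purity outside [0,1]")

    @property
    def length_bp(self) -> int:
        return self.read_offset_end - self.read_offset_start


@dataclass(frozen=True)
class RepeatRead:
    """One informative read for one marker."""

    read_id: str
    sample_id: str
    marker_id: str
    reported_units: float
    tract: RepeatTract
    fully_repetitive: bool
    source: str
    attributes: tuple[float, ...]
    lower_bound: bool = False
    read_length: int = 0

    def __post_init__(self) -> None:
        if len(self.attributes) != 6:
            raise ValueError("exactly 6 attributes required")
        if not all(np.isfinite(self.attributes)):
            raise ValueError("attributes must be finite")
        if self.reported_units < 0:
            raise ValueError("reported_units must be >= 0")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


def _pattern_rows(motif: str, n: int) -> np.ndarray:
    """Periodic extensions of the motif and its reverse complement, all phases.

    Returns a (2*len(motif), n) uint8 array; row order (forward phases
    0..L-1, then reverse-complement phases 0..L-1) is part of the
    tie-breaking contract.
    """
    L = len(motif)
    idx = np.arange(n)
    rows = []
    for variant in (motif, reverse_complement(motif)):
        vb = np.frombuffer(variant.encode(), dtype=np.uint8)
        for p in range(L):
            rows.append(vb[(idx + p) % L])
    return np.stack(rows)


def detect_repeat_tract(
    sequence: str,
    motif: str,
    min_units: float = cfg.MIN_UNITS,
    min_purity: float = cfg.MIN_PURITY,
) -> RepeatTract | None:
    """Find the maximal repeat tract of ``motif`` in ``sequence``.

    Among all windows whose per-base identity to the periodic extension of
    the motif (best phase, best strand) is at least ``min_purity``, the
    longest wins; ties break to higher purity, then leftmost.  Terminal
    bases of the winning window that mismatch its best-phase extension are
    then trimmed, so the tract starts and ends on a matching base.
    Returns ``None`` when no tract of at least ``min_units`` motif copies
    exists.
    """
    n = len(sequence)
    L = len(motif)
    min_bp = int(np.ceil(min_units * L))
    if n == 0 or min_bp == 0 or n < min_bp:
        return None
    M = _pattern_rows(motif, n) == np.frombuffer(
        sequence.upper().encode(), dtype=np.uint8
    )[None, :]
    C = np.zeros((M.shape[0], n + 1), dtype=np.int32)
    np.cumsum(M, axis=1, out=C[:, 1:])
    # a window of length w needs >= min_purity*w matches, and no window can
    # hold more matches than its best row holds in the whole read
    max_matches = int(C[:, n].max())
    w_hi = n if min_purity <= 0 else min(n, int(max_matches / min_purity + 1e-9))
    for w in range(w_hi, min_bp - 1, -1):
        matches = C[:, w:] - C[:, : n + 1 - w]          # (rows, n-w+1)
        best = matches.max(axis=0)
        valid = best >= min_purity * w - 1e-9
        if not valid.any():
            continue
        scored = np.where(valid, best, -1)
        start = int(np.argmax(scored))                   # leftmost max purity
        row = int(np.argmax(matches[:, start]))          # first best phase/strand
        end = start + w
        # trim terminal mismatching bases at the winning phase
        while start < end and not M[row, start]:
            start += 1
        while end > start and not M[row, end - 1]:
            end -= 1
        if end - start < min_bp:
            return None
        units = (end - start) / L
        purity = float(C[row, end] - C[row, start]) / (end - start)
        return RepeatTract(start, end, units, purity)
    return None


def _exhaustive_tract_oracle(
    sequence: str, motif: str, min_units: float, min_purity: float
) -> RepeatTract | None:
    """Brute-force reference: score every (start, end, phase, strand) window.

    Same selection and trimming contract as :func:`detect_repeat_tract`;
    quadratic, for testing on short sequences only.
    """
    n = len(sequence)
    L = len(motif)
    min_bp = int(np.ceil(min_units * L))
    if n == 0 or min_bp == 0:
        return None
    M = _pattern_rows(motif, n) == np.frombuffer(
        sequence.upper().encode(), dtype=np.uint8
    )[None, :]
    best = None  # (length, matches, -start, start, end, row)
    for s in range(n):
        for e in range(s + min_bp, n + 1):
            counts = M[:, s:e].sum(axis=1)
            row = int(np.argmax(counts))
            m = int(counts[row])
            if m < min_purity * (e - s) - 1e-9:
                continue
            key = (e - s, m, -s)
            if best is None or key > best[0]:
                best = (key, s, e, row)
    if best is None:
        return None
    _, s, e, row = best
    while s < e and not M[row, s]:
        s += 1
    while e > s and not M[row, e - 1]:
        e -= 1
    if e - s < min_bp:
        return None
    units = (e - s) / L
    purity = float(M[row, s:e].sum()) / (e - s)
    return RepeatTract(s, e, units, purity)


def _effective_min_units(motif: str, min_units: float) -> float:
    """Mononucleotide tracts must span at least MIN_TRACT_BP_MONO bases."""
    if len(motif) == 1:
        return max(min_units, cfg.MIN_TRACT_BP_MONO)
    return min_units


def _aligned_read_positions(read: pysam.AlignedSegment) -> np.ndarray:
    """Boolean per read position: consumed by an aligned (M/=/X) op."""
    out = np.zeros(read.query_length or 0, dtype=bool)
    pos = 0
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):          # M, =, X
            out[pos : pos + length] = True
            pos += length
        elif op in (1, 4):           # I, S consume the query only
            pos += length
    return out


def compute_attributes(
    read: pysam.AlignedSegment,
    marker: MarkerDef,
    tract: RepeatTract,
    flank_cap: int = cfg.FLANK_CAP,
    insert_max: int = cfg.INSERT_MAX,
    indel_cap: int = cfg.INDEL_CAP,
) -> tuple[float, ...]:
    """Six quality attributes of a read, in frozen order.

    1. tract purity;
    2. matched left-flank length (bp, capped) — contiguous aligned bases
       immediately left of the tract (raw flank length for unmapped reads);
    3. matched right-flank length, same convention;
    4. mean base quality over the tract rescaled to [0,1] (Q40 -> 1);
    5. mate-consistency indicator;
    6. indel-in-flank count from the CIGAR, capped.
    """
    n = read.query_length or len(read.query_sequence or "")
    s, e = tract.read_offset_start, tract.read_offset_end

    if read.is_unmapped or read.cigartuples is None:
        left = float(min(s, flank_cap))
        right = float(min(n - e, flank_cap))
        indels = 0.0
    else:
        aligned = _aligned_read_positions(read)
        left = 0.0
        for i in range(s - 1, -1, -1):
            if not aligned[i]:
                break
            left += 1
        right = 0.0
        for i in range(e, n):
            if not aligned[i]:
                break
            right += 1
        left = min(left, flank_cap)
        right = min(right, flank_cap)
        indels = 0.0
        pos = 0
        for op, length in read.cigartuples:
            if op == 1:              # insertion: in-flank if not inside the tract
                if not (s <= pos and pos + length <= e):
                    indels += 1
                pos += length
            elif op == 2:            # deletion: sits between read positions
                if pos <= s or pos >= e:
                    indels += 1
            elif op in (0, 4, 7, 8):
                pos += length
        indels = min(indels, indel_cap)

    quals = read.query_qualities
    if quals is None:
        logger.warning("read %s has no base qualities; tract quality set to 0.5",
                       read.query_name)
        mean_q = 0.5
    else:
        mean_q = float(np.clip(np.mean(quals[s:e]) / 40.0, 0.0, 1.0))

    if read.mate_is_unmapped or not read.is_paired:
        mate_ok = 0.0
    elif read.is_unmapped:
        mate_ok = 1.0
    else:
        same_chrom = read.reference_id == read.next_reference_id
        mate_ok = float(same_chrom and 0 < abs(read.template_length) <= insert_max)

    return (float(tract.purity), left, right, mean_q, mate_ok, indels)


def _read_key(read: pysam.AlignedSegment) -> str:
    suffix = "/1" if read.is_read1 else "/2" if read.is_read2 else ""
    return f"{read.query_name}{suffix}"


def _basic_filter(read: pysam.AlignedSegment) -> bool:
    return not (read.is_duplicate or read.is_secondary or read.is_supplementary)


def _make_repeat_read(
    read: pysam.AlignedSegment,
    marker: MarkerDef,
    tract: RepeatTract,
    source: str,
    sample_id: str,
    edge_slack: int = cfg.EDGE_SLACK,
) -> RepeatRead:
    n = read.query_length or len(read.query_sequence or "")
    fully = tract.length_bp >= n - 2 * edge_slack
    lower = tract.read_offset_start == 0 or tract.read_offset_end == n
    return RepeatRead(
        read_id=_read_key(read),
        sample_id=sample_id,
        marker_id=marker.marker_id,
        reported_units=tract.units,
        tract=tract,
        fully_repetitive=fully,
        source=source,
        attributes=compute_attributes(read, marker, tract),
        lower_bound=lower,
        read_length=n,
    )


def extract_informative_reads(
    alignments: pysam.AlignmentFile,
    marker: MarkerDef,
    all_markers: Sequence[MarkerDef] = (),
    *,
    sample_id: str | None = None,
    min_units: float = cfg.MIN_UNITS,
    min_purity: float = cfg.MIN_PURITY,
    flank_pad: int = cfg.FLANK_PAD,
    mate_window: int = cfg.MATE_WINDOW,
) -> list[RepeatRead]:
    """Collect informative reads for ``marker`` from an indexed alignment file.

    Returns the union of the three read sources, deduplicated by read id
    with priority overlap > unaligned_mate > offsite_same_motif, in a
    deterministic order (sorted by read id).  Raises ``KeyError`` if the
    marker's chromosome is absent from the alignment header and
    ``ValueError`` if the file has no index.
    """
    if not alignments.has_index():
        raise ValueError(f"{alignments.filename!r} has no index")
    if marker.chrom not in alignments.references:
        raise KeyError(f"chromosome {marker.chrom!r} not in alignment header")
    if sample_id is None:
        sample_id = _infer_sample_id(alignments)
    mu = _effective_min_units(marker.motif, min_units)
    start0, end0 = marker.start - 1, marker.end  # half-open 0-based
    found: dict[str, RepeatRead] = {}

    def try_add(read: pysam.AlignedSegment, source: str) -> None:
        key = _read_key(read)
        if key in found or read.query_sequence is None:
            return
        tract = detect_repeat_tract(read.query_sequence, marker.motif, mu, min_purity)
        if tract is None:
            return
        found[key] = _make_repeat_read(read, marker, tract, source, sample_id)

    # (1) aligned reads overlapping the padded marker interval
    for read in alignments.fetch(marker.chrom, max(0, start0 - flank_pad),
                                 end0 + flank_pad):
        if not _basic_filter(read) or read.is_unmapped:
            continue
        if read.mapping_quality == 0:
            continue
        try_add(read, "overlap")

    # (2) unaligned reads placed at a mate mapped close to the marker
    for read in alignments.fetch(marker.chrom, max(0, start0 - mate_window),
                                 end0 + mate_window):
        if not _basic_filter(read) or not read.is_unmapped:
            continue
        if read.mate_is_unmapped:
            continue
        try_add(read, "unaligned_mate")

    # (3) reads aligned inside another same-motif marker, mate near the target
    for other in all_markers:
        if other.marker_id == marker.marker_id:
            continue
        if canonical_motif(other.motif) != marker.motif:
            continue
        if other.chrom not in alignments.references:
            continue
        for read in alignments.fetch(other.chrom, max(0, other.start - 1),
                                     other.end):
            if not _basic_filter(read) or read.is_unmapped:
                continue
            if read.mate_is_unmapped or read.next_reference_name != marker.chrom:
                continue
            mpos = read.next_reference_start
            if not (start0 - mate_window <= mpos <= end0 + mate_window):
                continue
            try_add(read, "offsite_same_motif")

    return [found[k] for k in sorted(found)]


def _infer_sample_id(alignments: pysam.AlignmentFile) -> str:
    header = alignments.header.to_dict()
    for rg in header.get("RG", []):
        if "SM" in rg:
            return rg["SM"]
    name = str(alignments.filename or "sample")
    return name.rsplit("/", 1)[-1].split(".")[0]


def reads_to_table(reads: Iterable[RepeatRead]) -> pd.DataFrame:
    """Columnar view of RepeatReads used by the population pipeline."""
    rows = [
        (r.marker_id, r.sample_id, r.read_id, r.reported_units, r.tract.purity,
         *r.attributes, r.source, r.lower_bound, r.fully_repetitive)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)


def write_read_table(reads: Iterable[RepeatRead] | pd.DataFrame, path) -> None:
    table = reads if isinstance(reads, pd.DataFrame) else reads_to_table(reads)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
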