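"""Clinical repeat-expansion screen over the pathogenic panel.

An expanded allele often exceeds the read length, so few or no reads span
it and a genotyping model that assumes equal read draw probabilities from
the two haplotypes is unreliable.  The screen therefore never genotypes:
it recruits informative reads at each panel locus (all three sources),
looks for any repeat tract at or above the pathogenicity threshold,
counts fully repetitive reads (reads consisting only of the motif — the
signature of an allele longer than the read), and flags loci for manual
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pysam

from . import config as cfg
from .markers import PanelEntry
from .read_extraction import extract_informative_reads

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "marker_id", "disease", "threshold_units", "n_informative_reads",
    "max_units_observed", "n_fully_repetitive", "flagged",
]


@dataclass(frozen=True)
class ExpansionReport:
    marker_id: str
    disease: str
    threshold_units: int
    n_informative_reads: int
    max_units_observed: float
    n_fully_repetitive: int
    flagged: bool

    def __post_init__(self) -> None:
        if self.n_fully_repetitive > self.n_informative_reads:
            raise ValueError("more fully repetitive reads than informative reads")


def scan_sample(
    alignments: pysam.AlignmentFile,
    panel: Sequence[PanelEntry],
    *,
    sample_id: str | None = None,
    min_full_reads: int = cfg.MIN_FULL_READS,
    min_flank: int = cfg.MIN_FLANK,
    default_read_length: int = 150,
) -> list[ExpansionReport]:
    """Screen one sample's alignments at every panel locus.

    A locus is flagged when any informative read carries a tract of at
    least ``threshold_units`` copies (lower-bound reads count at their
    observed value), or when the threshold exceeds what a single read
    could span and at least ``min_full_reads`` fully repetitive reads are
    present.  Loci on chromosomes absent from the alignment header yield
    an empty, unflagged report with a logged warning.
    """
    if not panel:
        raise ValueError("empty panel")
    markers = [e.marker for e in panel]
    reports = []
    for entry in panel:
        m = entry.marker
        try:
            reads = extract_informative_reads(
                alignments, m, markers, sample_id=sample_id
            )
        except KeyError:
            logger.warning("marker %s: chromosome %s absent from alignment header",
                           m.marker_id, m.chrom)
            reads = []
        n_info = len(reads)
        max_units = max((r.reported_units for r in reads), default=0.0)
        n_full = sum(r.fully_repetitive for r in reads)
        read_len = max((r.read_length for r in reads), default=default_read_length)
        beyond_read = entry.threshold_units * len(m.motif) > read_len - 2 * min_flank
        flagged = bool(
            max_units >= entry.threshold_units
            or (beyond_read and n_full >= min_full_reads)
        )
        reports.append(ExpansionReport(
            marker_id=m.marker_id,
            disease=entry.disease,
            threshold_units=entry.threshold_units,
            n_informative_reads=n_info,
            max_units_observed=float(max_units),
            n_fully_repetitive=int(n_full),
            flagged=flagged,
        ))
    return reports


def render_report(reports: Sequence[ExpansionReport]) -> tuple[str, str]:
    """Human-readable summary (flagged loci first) and a machine TSV.

    Byte-identical output for identical input.
    """
    flagged = [r for r in reports if r.flagged]
    lines = ["Repeat-expansion screen", "=" * 23, ""]
    if flagged:
        lines.append(f"FLAGGED LOCI ({len(flagged)}) - manual inspection advised:")
        for r in flagged:
            lines.append(
                f"  {r.marker_id}: {r.disease} "
                f"(threshold {r.threshold_units} units) - "
                f"max observed {r.max_units_observed:g} units, "
                f"{r.n_fully_repetitive} fully repetitive of "
                f"{r.n_informative_reads} informative reads"
            )
    else:
        lines.append("No evidence of a pathogenic repeat expansion found.")
    lines.append("")
    lines.append(f"Loci screened: {len(reports)}")
    text = "\n".join(lines) + "\n"

    tsv_lines = ["\t".join(REPORT_COLUMNS)]
    for r in reports:
        tsv_lines.append(
            f"{r.marker_id}\t{r.disease}\t{r.threshold_units}"
            f"\t{r.n_informative_reads}\t{r.max_units_observed:g}"
            f"\t{r.n_fully_repetitive}\t{int(r.flagged)}"
        )
    return text, "\n".join(tsv_lines) + "\n"


def write_report(reports: Sequence[ExpansionReport], prefix: str | Path) -> None:
    text, tsv = render_report(reports)
    Path(f"{prefix}.report.txt").write_text(text)
    Path(f"{prefix}.report.tsv").write_text(tsv)


def parse_report_tsv(path_or_text: str | Path) -> list[ExpansionReport]:
    """Inverse of the TSV side of :func:`render_report`."""
    p = Path(path_or_text) if "\t" not in str(path_or_text) else None
    text = p.read_text() if p is not None and p.exists() else str(path_or_text)
    lines = [ln for ln in text.splitlines() if ln]
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        out.append(ExpansionReport(
            f[0], f[1], int(f[2]), int(f[3]), float(f[4]), int(f[5]), bool(int(f[6]))
        ))
    return out
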