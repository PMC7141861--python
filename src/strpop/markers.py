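"""Marker catalog and pathogenic-expansion panel.

A *marker* is one microsatellite locus: genomic coordinates, repeat motif
(1-6 bp) and the repeat copy number of the reference allele.  The panel
extends markers with a disease label and a pathogenicity threshold in
repeat copies.  Marker files are 1-based inclusive TSV; all internal
half-open 0-based arithmetic happens in the modules that consume markers,
never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MARKER_COLUMNS = ["chrom", "start", "end", "motif", "ref_units", "marker_id"]
PANEL_COLUMNS = MARKER_COLUMNS + ["disease", "threshold_units"]


class MarkerError(ValueError):
    """Invalid marker, panel entry or marker/panel file."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primitive(motif: str) -> str:
    """Smallest period of ``motif`` (e.g. ``ACAC`` -> ``AC``)."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return motif[:p]
    return motif


def canonical_motif(motif: str) -> str:
    """Canonical form of a repeat motif.

    The canonical form is the lexicographically smallest string among all
    cyclic rotations of the (primitive) motif and of its reverse
    complement, so that reads from either strand and any repeat phase map
    to a single motif class.  Idempotent.
    """
    if not motif:
        raise MarkerError("empty motif")
    motif = motif.upper()
    if set(motif) - _ALPHABET:
        raise MarkerError(f"motif {motif!r} contains non-ACGT characters")
    if len(motif) > 6:
        raise MarkerError(f"motif {motif!r} longer than 6 bp")
    motif = _primitive(motif)
    candidates = []
    for variant in (motif, reverse_complement(motif)):
        for i in range(len(variant)):
            candidates.append(variant[i:] + variant[:i])
    return min(candidates)


@dataclass(frozen=True)
class MarkerDef:
    """One STR locus; coordinates are 1-based inclusive."""

    marker_id: str
    chrom: str
    start: int
    end: int
    motif: str
    ref_units: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MarkerError(f"{self.marker_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise MarkerError(f"{self.marker_id}: coordinates are 1-based (start >= 1)")
        if not 1 <= len(self.motif) <= 6:
            raise MarkerError(f"{self.marker_id}: motif length must be 1-6")
        if self.motif != canonical_motif(self.motif):
            raise MarkerError(
                f"{self.marker_id}: motif {self.motif!r} not canonical "
                f"(expected {canonical_motif(self.motif)!r})"
            )
        if self.ref_units < 0:
            raise MarkerError(f"{self.marker_id}: negative ref_units")
        span = self.end - self.start + 1
        if abs(self.ref_units * len(self.motif) - span) > len(self.motif):
            raise MarkerError(
                f"{self.marker_id}: ref_units {self.ref_units} inconsistent with "
                f"span {span} bp for a {len(self.motif)} bp motif"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def create(
        cls,
        chrom: str,
        start: int,
        end: int,
        motif: str,
        ref_units: float,
        marker_id: str | None = None,
    ) -> "MarkerDef":
        """Build a marker, canonicalizing the motif first."""
        motif = canonical_motif(motif)
        if marker_id is None:
            marker_id = f"{chrom}_{start}_{motif}"
        return cls(marker_id, chrom, int(start), int(end), motif, float(ref_units))


@dataclass(frozen=True)
class PanelEntry:
    """A pathogenic repeat-expansion locus."""

    marker: MarkerDef
    disease: str
    threshold_units: int

    def __post_init__(self) -> None:
        if not self.disease:
            raise MarkerError(f"{self.marker.marker_id}: empty disease label")
        if int(self.threshold_units) < 1:
            raise MarkerError(
                f"{self.marker.marker_id}: pathogenicity threshold must be >= 1"
            )


def _parse_rows(path: str | Path, n_min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # optional header
                continue
            if len(fields) < n_min_cols:
                raise MarkerError(
                    f"{path}:{lineno}: expected >= {n_min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def _marker_from_fields(path: str | Path, lineno: int, fields: list[str]) -> MarkerDef:
    chrom, start, end, motif, ref_units = fields[:5]
    marker_id = fields[5] if len(fields) > 5 and fields[5] else None
    try:
        return MarkerDef.create(
            chrom, int(start), int(end), motif, float(ref_units), marker_id
        )
    except MarkerError as exc:
        raise MarkerError(f"{path}:{lineno}: {exc}") from None
    except ValueError as exc:
        raise MarkerError(f"{path}:{lineno}: malformed row ({exc})") from None


def load_markers(path: str | Path) -> list[MarkerDef]:
    """Read a marker catalog TSV, in file order.

    Columns: ``chrom start end motif ref_units [marker_id]``; header line
    and ``#`` comments are ignored.  Motifs are canonicalized; duplicate
    loci (same chrom/start/end) are rejected.
    """
    markers: list[MarkerDef] = []
    seen: set[tuple[str, int, int]] = set()
    for lineno, fields in _parse_rows(path, 5):
        marker = _marker_from_fields(path, lineno, fields)
        key = (marker.chrom, marker.start, marker.end)
        if key in seen:
            raise MarkerError(f"{path}:{lineno}: duplicate locus {key}")
        seen.add(key)
        markers.append(marker)
    return markers


def write_markers(markers: Iterable[MarkerDef], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for m in markers:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.motif}\t{m.ref_units:g}"
                f"\t{m.marker_id}\n"
            )


def load_panel(path: str | Path | None = None) -> list[PanelEntry]:
    """Read an expansion panel TSV; ``None`` loads the packaged 31-locus panel.

    Columns: marker columns plus ``disease`` and ``threshold_units``.
    """
    if path is None:
        ref = resources.files("strpop").joinpath("data/expansion_panel.tsv")
        with resources.as_file(ref) as p:
            return load_panel(p)
    entries: list[PanelEntry] = []
    seen: set[tuple[str, int, int]] = set()
    for lineno, fields in _parse_rows(path, 8):
        marker = _marker_from_fields(path, lineno, fields)
        disease = fields[6]
        try:
            threshold = int(fields[7])
        except ValueError:
            raise MarkerError(
                f"{path}:{lineno}: malformed threshold_units {fields[7]!r}"
            ) from None
        key = (marker.chrom, marker.start, marker.end)
        if key in seen:
            raise MarkerError(f"{path}:{lineno}: duplicate panel locus {key}")
        seen.add(key)
        try:
            entries.append(PanelEntry(marker, disease, threshold))
        except MarkerError as exc:
            raise MarkerError(f"{path}:{lineno}: {exc}") from None
    return entries


def write_panel(entries: Iterable[PanelEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in entries:
            m = e.marker
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.motif}\t{m.ref_units:g}"
                f"\t{m.marker_id}\t{e.disease}\t{e.threshold_units}\n"
            )
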