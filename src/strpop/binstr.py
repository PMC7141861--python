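"""Allele binning for association analysis.

Association pipelines mostly assume biallelic variants, which wastes the
multi-allelic structure of microsatellites when pathogenicity tracks
allele length.  Binning collapses a marker's alleles (sorted ascending by
repeat units) into user-defined groups — including plain binarization at
a length threshold — so a standard biallelic test can consume them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinScheme:
    """Ordered allele groups; indices address the marker's sorted allele list."""

    groups: tuple[tuple[str, tuple[int, ...]], ...]
    marker_id: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a bin scheme needs at least 2 groups")
        seen: set[int] = set()
        for label, idxs in self.groups:
            if not label:
                raise ValueError("empty group label")
            overlap = seen & set(idxs)
            if overlap:
                raise ValueError(f"allele indices {sorted(overlap)} in multiple groups")
            seen |= set(idxs)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    def covered_indices(self) -> set[int]:
        return {i for _, idxs in self.groups for i in idxs}


def parse_bin_scheme(spec: str, n_alleles: int, marker_id: str = "") -> BinScheme:
    """Parse ``"g1:0,1,2;g2:3,4"`` into a validated :class:`BinScheme`.

    Every allele index in ``range(n_alleles)`` must appear in exactly one
    group; there is no implicit remainder group.
    """
    groups = []
    for part in spec.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ValueError(f"malformed group {part!r} (expected label:i,j,...)")
        label, idx_str = part.split(":", 1)
        try:
            idxs = tuple(int(x) for x in idx_str.split(",") if x.strip() != "")
        except ValueError:
            raise ValueError(f"malformed indices in group {part!r}") from None
        groups.append((label.strip(), idxs))
    scheme = BinScheme(tuple(groups), marker_id)
    covered = scheme.covered_indices()
    out_of_range = covered - set(range(n_alleles))
    if out_of_range:
        raise ValueError(f"allele indices {sorted(out_of_range)} out of range "
                         f"for {n_alleles} alleles")
    missing = set(range(n_alleles)) - covered
    if missing:
        raise ValueError(f"allele indices {sorted(missing)} not assigned to any group")
    return scheme


def binarize_scheme(alleles: Sequence[float], threshold: float,
                    marker_id: str = "") -> BinScheme:
    """Two groups split at a length threshold: ``short`` < threshold <= ``long``."""
    alleles = sorted(alleles)
    short = tuple(i for i, a in enumerate(alleles) if a < threshold)
    long = tuple(i for i, a in enumerate(alleles) if a >= threshold)
    if not short or not long:
        raise ValueError(f"threshold {threshold} does not split alleles {alleles}")
    return BinScheme((("short", short), ("long", long)), marker_id)


def apply_bins(
    genotypes: pd.DataFrame,
    scheme: BinScheme,
    alleles: Sequence[float] | None = None,
    *,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Map each sample's allele pair to an unordered pair of group labels.

    ``genotypes`` is a per-marker call table with ``allele_a``/``allele_b``
    columns; sample order, posteriors and read counts pass through.
    ``alleles`` defaults to the sorted distinct alleles of the table.
    An allele absent from the scheme's allele list raises (default) or is
    assigned to the group of the nearest-length listed allele
    (``on_missing="nearest"``).
    """
    if on_missing not in ("error", "nearest"):
        raise ValueError("on_missing must be 'error' or 'nearest'")
    if alleles is None:
        alleles = sorted(
            set(genotypes["allele_a"]).union(genotypes["allele_b"])
        )
    alleles = sorted(float(a) for a in alleles)
    label_of_index: dict[int, str] = {}
    order_of_label = {label: i for i, (label, _) in enumerate(scheme.groups)}
    for label, idxs in scheme.groups:
        for i in idxs:
            if i >= len(alleles):
                raise ValueError(f"scheme index {i} out of range for allele list")
            label_of_index[i] = label

    def to_label(value: float) -> str:
        arr = np.asarray(alleles)
        hits = np.flatnonzero(np.isclose(arr, value))
        if len(hits):
            return label_of_index[int(hits[0])]
        if on_missing == "error":
            raise ValueError(f"allele {value} not in the scheme's allele list")
        nearest = int(np.argmin(np.abs(arr - value)))
        return label_of_index[nearest]

    out = genotypes.copy()
    ga = out["allele_a"].map(to_label)
    gb = out["allele_b"].map(to_label)
    # unordered pair: order by group position in the scheme
    swap = ga.map(order_of_label) > gb.map(order_of_label)
    out["group_a"] = ga.where(~swap, gb)
    out["group_b"] = gb.where(~swap, ga)
    return out


def write_binned_vcf(
    binned: pd.DataFrame,
    scheme: BinScheme,
    path: str | Path,
    *,
    chrom: str = "NA",
    pos: int = 1,
    marker_id: str | None = None,
) -> None:
    """Export binned genotypes as one symbolic multi-allelic VCF record.

    Each group becomes one symbolic allele (first group is REF-like but
    written as an ALT so tools treat all groups uniformly via GT indices).
    """
    labels = scheme.labels
    alts = ",".join(f"<{lab.upper()}>" for lab in labels[1:]) or "."
    idx = {lab: i for i, lab in enumerate(labels)}
    mid = marker_id or scheme.marker_id or "marker"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##INFO=<ID=GROUPS,Number=1,Type=String,Description="Allele group labels">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        + "".join(f"\t{s}" for s in binned["sample_id"]),
    ]
    row = [chrom, str(pos), mid, "N", alts, ".", "PASS",
           "GROUPS=" + "|".join(labels), "GT:GQ"]
    for rec in binned.itertuples(index=False):
        gq = int(min(99, -10 * np.log10(max(1e-10, 1 - float(rec.posterior))))) \
            if "posterior" in binned.columns else 99
        row.append(f"{idx[rec.group_a]}/{idx[rec.group_b]}:{gq}")
    lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def group_counts(binned: pd.DataFrame) -> pd.Series:
    """Allele counts per group (each sample contributes two alleles)."""
    return pd.concat([binned["group_a"], binned["group_b"]]).value_counts().sort_index()
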