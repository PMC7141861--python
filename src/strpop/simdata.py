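"""Synthetic diploid STR data with known truth.

The generator mirrors the genotyping model exactly: each read samples one
of the two haplotypes (50/50), suffers a whole-motif slippage event with
probability ``s_i + s_j`` (magnitude geometric with decay ``gamma``,
direction Bernoulli(``p_up``)), and accumulates per-base substitution
errors.  Two granularities share this slippage draw:

* sequence level — full reads with flanks, qualities, mates and alignment
  records on a toy per-marker reference, written as sorted indexed BAM;
* allele level — the read table consumed by the population pipeline,
  generated directly (reported units + attributes) for large cohorts.

Toy references put every marker on its own contig with 600 bp flanks.
The 24 bp of flank adjacent to the repeat tract is generated to break the
motif's periodic extension at every position, as a catalog marker
delimits a maximal repeat; detection is therefore exact when slippage and
error rates are zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from . import config as cfg
from .markers import MarkerDef

FLANK_LEN = 600          # bp of toy reference flank on each side of the repeat
HOSTILE_BP = 24          # flank bases adjacent to the tract break periodicity
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = ["sample_id", "marker_id", "allele_a", "allele_b"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation."""

    read_length: int = 150
    coverage: float = 30.0
    marker_slippage: float = 0.02
    sample_slippage: float = 0.0
    p_up: float = 0.15
    step_decay: float = 0.8
    base_error_rate: float = 0.001
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("marker_slippage", "sample_slippage", "p_up",
                     "step_decay", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def s_total(self) -> float:
        return self.marker_slippage + self.sample_slippage


@dataclass
class SimRead:
    """One simulated repeat-bearing read plus its anchoring mate."""

    name: str
    sample_id: str
    marker_id: str
    seq: str
    chrom: str
    pos: int | None            # 0-based leftmost aligned base; None if unmapped
    cigar: list[tuple[int, int]] | None
    unmapped: bool
    mate_pos: int
    mate_seq: str
    # truth
    hap_allele: int
    realized_units: int
    slip: int


class TruthSet:
    """Ground truth of a simulation: genotypes plus per-read slip events."""

    def __init__(self, genotypes: pd.DataFrame, read_log: pd.DataFrame):
        self.genotypes = genotypes.reset_index(drop=True)
        self.read_log = read_log.reset_index(drop=True)

    def genotype(self, sample_id: str, marker_id: str) -> tuple[int, int]:
        g = self.genotypes
        row = g[(g.sample_id == sample_id) & (g.marker_id == marker_id)].iloc[0]
        return int(row.allele_a), int(row.allele_b)

    def write(self, path: str | Path) -> None:
        self.genotypes.to_csv(path, sep="\t", index=False)


# --- toy reference ---------------------------------------------------------

def make_marker_catalog(
    n_markers: int,
    rng: np.random.Generator,
    motifs: Sequence[str] = ("AC", "AAG", "AGC", "AT", "AAAT"),
    ref_units_range: tuple[int, int] = (8, 16),
) -> list[MarkerDef]:
    """Markers on per-marker toy contigs ``sim0000``, ``sim0001``, ..."""
    markers = []
    for i in range(n_markers):
        motif = motifs[int(rng.integers(len(motifs)))]
        units = int(rng.integers(ref_units_range[0], ref_units_range[1] + 1))
        start = FLANK_LEN + 1
        end = start + units * len(motif) - 1
        markers.append(MarkerDef.create(f"sim{i:04d}", start, end, motif, units,
                                        marker_id=f"m{i:04d}"))
    return markers


def _hostile_flanks(marker: MarkerDef, rng: np.random.Generator) -> tuple[str, str]:
    """Random flanks whose HOSTILE_BP bases next to the tract never continue
    the motif's periodic extension."""
    L = len(marker.motif)
    mb = np.frombuffer(marker.motif.encode(), dtype=np.uint8)
    left = BASES[rng.integers(0, 4, FLANK_LEN)].copy()
    right = BASES[rng.integers(0, 4, FLANK_LEN)].copy()
    for j in range(1, HOSTILE_BP + 1):        # j bases left of the tract
        forbidden = mb[(-j) % L]
        if left[FLANK_LEN - j] == forbidden:
            others = BASES[BASES != forbidden]
            left[FLANK_LEN - j] = others[rng.integers(0, 3)]
    for j in range(HOSTILE_BP):               # j bases right of the tract
        forbidden = mb[j % L]
        if right[j] == forbidden:
            others = BASES[BASES != forbidden]
            right[j] = others[rng.integers(0, 3)]
    return left.tobytes().decode(), right.tobytes().decode()


def build_reference(
    markers: Sequence[MarkerDef], rng: np.random.Generator
) -> dict[str, str]:
    """Toy reference: one contig per marker, flanks + reference repeat."""
    ref = {}
    for m in markers:
        left, right = _hostile_flanks(m, rng)
        tract = (m.motif * (int(np.ceil(m.ref_units)) + 1))[: round(m.ref_units * len(m.motif))]
        ref[m.chrom] = left + tract + right
    return ref


# --- slippage draws --------------------------------------------------------

def draw_slips(
    n: int, cfg_sim: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Signed whole-unit slip per read (0 = no slippage event)."""
    slip = np.zeros(n, dtype=int)
    hit = rng.random(n) < cfg_sim.s_total
    k = rng.geometric(cfg_sim.step_decay, n)
    sign = np.where(rng.random(n) < cfg_sim.p_up, 1, -1)
    slip[hit] = (k * sign)[hit]
    return slip


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits) == 0:
        return seq
    seq = seq.copy()
    shift = rng.integers(1, 4, len(hits))
    idx = np.searchsorted(BASES, seq[hits])
    seq[hits] = BASES[(idx + shift) % 4]
    return seq


# --- sequence-level simulation --------------------------------------------

def simulate_marker_reads(
    genotype: tuple[int, int],
    marker: MarkerDef,
    cfg_sim: SimConfig,
    rng: np.random.Generator,
    *,
    sample_id: str = "S0",
    flanks: tuple[str, str] | None = None,
) -> list[SimRead]:
    """Reads over one marker for one diploid genotype.

    Read count ~ Poisson(coverage); each read picks a haplotype 50/50,
    applies a slippage event to its template, and is placed uniformly
    over positions overlapping the (realized) tract.  Reads with fewer
    than MIN_FLANK anchoring bases on both sides are emitted unmapped,
    placed at their mate's coordinate, as an aligner would leave them.
    """
    if min(genotype) <= 0:
        raise ValueError("alleles must be positive repeat counts")
    L = len(marker.motif)
    rl = cfg_sim.read_length
    if flanks is None:
        flanks = _hostile_flanks(marker, rng)
    left, right = flanks
    ref_tract_bp = round(marker.ref_units * L)
    n_reads = int(rng.poisson(cfg_sim.coverage))
    haps = rng.integers(0, 2, n_reads)
    slips = draw_slips(n_reads, cfg_sim, rng)
    reads: list[SimRead] = []
    for i in range(n_reads):
        allele = int(genotype[haps[i]])
        units = max(1, allele + int(slips[i]))
        tract_bp = units * L
        molecule = left + (marker.motif * units) + right
        tract_start = len(left)
        # read placement: spanning when the tract fits, sliding otherwise
        if tract_bp <= rl - 2:
            lf = int(rng.integers(0, rl - tract_bp + 1))
            start = tract_start - lf
        else:
            start = int(rng.integers(tract_start - rl + 8, tract_start + tract_bp - 8))
        start = max(0, min(start, len(molecule) - rl))
        raw = np.frombuffer(molecule[start : start + rl].encode(), dtype=np.uint8)
        seq = _mutate(raw, cfg_sim.base_error_rate, rng).tobytes().decode()
        lf_bp = max(0, tract_start - start)
        rf_bp = max(0, (start + rl) - (tract_start + tract_bp))
        tract_in_read = rl - lf_bp - rf_bp

        # mate entirely in the left flank (or right, when the left is short)
        insert = max(rl + 20, int(round(rng.normal(cfg_sim.insert_mean,
                                                   cfg_sim.insert_sd))))
        mate_start = start - insert + rl
        if mate_start < 0:
            mate_start = min(start + insert - rl, len(molecule) - rl)
        mate_seq = molecule[mate_start : mate_start + rl]
        mate_pos = _molecule_to_ref(mate_start, tract_start, tract_bp, ref_tract_bp)

        anchored_left = lf_bp >= cfg.MIN_FLANK
        anchored_right = rf_bp >= cfg.MIN_FLANK
        if not (anchored_left or anchored_right):
            pos, cigar, unmapped = None, None, True
        elif anchored_left and anchored_right:
            pos = start
            cigar = [(0, lf_bp)] if lf_bp else []
            m = min(tract_in_read, ref_tract_bp)
            cigar.append((0, m))
            if tract_in_read > ref_tract_bp:
                cigar.append((1, tract_in_read - ref_tract_bp))
            elif tract_in_read < ref_tract_bp:
                cigar.append((2, ref_tract_bp - tract_in_read))
            if rf_bp:
                cigar.append((0, rf_bp))
            cigar = _merge_cigar(cigar)
            unmapped = False
        elif anchored_left:
            pos = start
            m = lf_bp + min(tract_in_read, ref_tract_bp)
            cigar = _merge_cigar([(0, m), (4, rl - m)] if rl > m else [(0, m)])
            unmapped = False
        else:
            m = rf_bp + min(tract_in_read, ref_tract_bp)
            pos = _molecule_to_ref(start + rl - m + (tract_in_read - min(tract_in_read, ref_tract_bp)),
                                   tract_start, tract_bp, ref_tract_bp)
            pos = max(0, tract_start + ref_tract_bp + rf_bp - m) if rf_bp else pos
            cigar = _merge_cigar([(4, rl - m), (0, m)] if rl > m else [(0, m)])
            unmapped = False

        reads.append(SimRead(
            name=f"{sample_id}_{marker.marker_id}_r{i}",
            sample_id=sample_id,
            marker_id=marker.marker_id,
            seq=seq,
            chrom=marker.chrom,
            pos=pos,
            cigar=cigar,
            unmapped=unmapped,
            mate_pos=mate_pos,
            mate_seq=mate_seq,
            hap_allele=allele,
            realized_units=units,
            slip=int(slips[i]),
        ))
    return reads


def _molecule_to_ref(pos: int, tract_start: int, tract_bp: int, ref_tract_bp: int) -> int:
    if pos < tract_start:
        return pos
    if pos >= tract_start + tract_bp:
        return pos - tract_bp + ref_tract_bp
    return min(pos, tract_start + ref_tract_bp - 1)


def _merge_cigar(ops: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for op, length in ops:
        if length <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return merged


def write_bam(
    sim_reads: Iterable[SimRead],
    reference: Mapping[str, str],
    path: str | Path,
    sample_id: str,
) -> str:
    """Write repeat reads and their mates as a sorted, indexed BAM."""
    path = str(path)
    contigs = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for r in sim_reads:
            rl = len(r.seq)
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("D" * rl)  # Q35
            a.reference_id = tid[r.chrom]
            a.is_paired = True
            a.is_read1 = True
            a.mate_is_reverse = True
            a.next_reference_id = tid[r.chrom]
            a.next_reference_start = r.mate_pos
            a.set_tag("RG", r.sample_id)
            if r.unmapped:
                a.is_unmapped = True
                a.reference_start = r.mate_pos   # placed at the mate
                a.mapping_quality = 0
            else:
                a.reference_start = r.pos
                a.cigartuples = r.cigar
                a.mapping_quality = 60
                a.template_length = abs(r.mate_pos - r.pos) + rl
            bam.write(a)

            b = pysam.AlignedSegment(bam.header)
            b.query_name = r.name
            b.query_sequence = r.mate_seq
            b.query_qualities = pysam.qualitystring_to_array("D" * len(r.mate_seq))
            b.reference_id = tid[r.chrom]
            b.reference_start = r.mate_pos
            b.cigartuples = [(0, len(r.mate_seq))]
            b.mapping_quality = 60
            b.is_paired = True
            b.is_read2 = True
            b.is_reverse = True
            b.next_reference_id = tid[r.chrom]
            b.set_tag("RG", r.sample_id)
            if r.unmapped:
                b.mate_is_unmapped = True
                b.next_reference_start = r.mate_pos
            else:
                b.next_reference_start = r.pos
                b.template_length = -(abs(r.mate_pos - (r.pos or 0)) + rl)
            bam.write(b)
    pysam.sort("-o", path, unsorted)
    Path(unsorted).unlink()
    pysam.index(path)
    return path


# --- genotype sampling -----------------------------------------------------

def default_allele_freqs(
    markers: Sequence[MarkerDef], rng: np.random.Generator,
    offsets: Sequence[int] = (-2, -1, 0, 1, 2),
) -> dict[str, dict[int, float]]:
    """Per-marker allele spectra around the reference allele (Dirichlet draws)."""
    freqs = {}
    for m in markers:
        alleles = [max(2, round(m.ref_units) + o) for o in offsets]
        alleles = sorted(set(alleles))
        w = rng.dirichlet(np.ones(len(alleles)))
        freqs[m.marker_id] = {a: float(p) for a, p in zip(alleles, w)}
    return freqs


def draw_genotype(
    freqs: Mapping[int, float], rng: np.random.Generator
) -> tuple[int, int]:
    alleles = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in alleles], dtype=float)
    p = p / p.sum()
    g = rng.choice(alleles, size=2, p=p)
    return int(min(g)), int(max(g))


# --- allele-level (fast) simulation ----------------------------------------

def simulate_read_table(
    genotypes: pd.DataFrame,
    markers: Sequence[MarkerDef],
    cfg_sim: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read table for the population pipeline, generated at allele level.

    ``genotypes`` has columns sample_id, marker_id, allele_a, allele_b.
    Returns (read table, per-read truth log with slip events); fully
    vectorized, no sequences are synthesized.
    """
    mk = {m.marker_id: m for m in markers}
    n_pairs = len(genotypes)
    counts = rng.poisson(cfg_sim.coverage, n_pairs)
    total = int(counts.sum())
    pair_idx = np.repeat(np.arange(n_pairs), counts)
    a = genotypes["allele_a"].to_numpy()[pair_idx]
    b = genotypes["allele_b"].to_numpy()[pair_idx]
    hap = rng.random(total) < 0.5
    allele = np.where(hap, a, b).astype(int)
    slip = draw_slips(total, cfg_sim, rng)
    units = np.maximum(1, allele + slip)

    motif_len = genotypes["marker_id"].map(
        lambda mid: len(mk[mid].motif)
    ).to_numpy()[pair_idx]
    tract_bp = units * motif_len
    errors = rng.binomial(tract_bp, cfg_sim.base_error_rate)
    purity = 1.0 - errors / np.maximum(tract_bp, 1)
    span_slack = np.maximum(cfg_sim.read_length - tract_bp, 1)
    lf = rng.integers(0, span_slack + 1)
    table = pd.DataFrame({
        "marker_id": genotypes["marker_id"].to_numpy()[pair_idx],
        "sample_id": genotypes["sample_id"].to_numpy()[pair_idx],
        "read_id": np.arange(total),
        "reported_units": units.astype(float),
        "purity": purity,
        "a1": purity,
        "a2": np.minimum(lf, cfg.FLANK_CAP).astype(float),
        "a3": np.minimum(span_slack - lf, cfg.FLANK_CAP).astype(float),
        "a4": np.full(total, 35.0 / 40.0),
        "a5": np.ones(total),
        "a6": np.zeros(total),
        "source": "overlap",
        "lower_bound": (lf == 0) | (lf == span_slack),
        "fully_repetitive": tract_bp >= cfg_sim.read_length - 2 * cfg.EDGE_SLACK,
    })
    truth = pd.DataFrame({
        "marker_id": table["marker_id"],
        "sample_id": table["sample_id"],
        "hap_allele": allele,
        "realized_units": units,
        "slip": slip,
    })
    return table, truth


# --- cohorts and trios -----------------------------------------------------

class CohortResult(NamedTuple):
    reads: pd.DataFrame | None
    bam_paths: dict[str, str]
    reference: dict[str, str]
    truth: TruthSet
    markers: list[MarkerDef]


def simulate_cohort(
    markers: Sequence[MarkerDef],
    n_samples: int,
    cfg_sim: SimConfig,
    *,
    allele_freqs: Mapping[str, Mapping[int, float]] | None = None,
    out_dir: str | Path | None = None,
    sequence_level: bool = False,
    sample_prefix: str = "S",
    expanded: Mapping[str, tuple[int, Sequence[str]]] | None = None,
) -> CohortResult:
    """Simulate a cohort; genotypes drawn from per-marker allele spectra.

    With ``sequence_level`` (requires ``out_dir``) one sorted indexed BAM
    is written per sample; otherwise the read table is returned directly.
    ``expanded`` maps marker_id -> (expanded allele units, carrier sample
    ids); carriers get one expanded haplotype at that marker.
    """
    rng = np.random.default_rng(cfg_sim.seed)
    if allele_freqs is None:
        allele_freqs = default_allele_freqs(markers, rng)
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    rows = []
    for sid in sample_ids:
        for m in markers:
            g = draw_genotype(allele_freqs[m.marker_id], rng)
            if expanded and m.marker_id in expanded:
                exp_units, carriers = expanded[m.marker_id]
                if sid in carriers:
                    g = (min(g[0], exp_units), max(g[0], exp_units))
            rows.append((sid, m.marker_id, g[0], g[1]))
    genotypes = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    if not sequence_level:
        table, read_log = simulate_read_table(genotypes, markers, cfg_sim, rng)
        return CohortResult(table, {}, {}, TruthSet(genotypes, read_log), list(markers))

    if out_dir is None:
        raise ValueError("sequence_level simulation needs out_dir")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = build_reference(markers, rng)
    flank_by_marker = {
        m.marker_id: (reference[m.chrom][: m.start - 1],
                      reference[m.chrom][m.start - 1 + round(m.ref_units * len(m.motif)):])
        for m in markers
    }
    bam_paths = {}
    log_rows = []
    by_marker = {m.marker_id: m for m in markers}
    for sid in sample_ids:
        sim_reads: list[SimRead] = []
        sub = genotypes[genotypes.sample_id == sid]
        for row in sub.itertuples(index=False):
            m = by_marker[row.marker_id]
            sim_reads.extend(simulate_marker_reads(
                (row.allele_a, row.allele_b), m, cfg_sim, rng,
                sample_id=sid, flanks=flank_by_marker[m.marker_id],
            ))
        bam_paths[sid] = write_bam(sim_reads, reference,
                                   str(out_dir / f"{sid}.bam"), sid)
        log_rows.extend(
            (r.sample_id, r.marker_id, r.hap_allele, r.realized_units, r.slip)
            for r in sim_reads
        )
    read_log = pd.DataFrame(
        log_rows,
        columns=["sample_id", "marker_id", "hap_allele", "realized_units", "slip"],
    )
    truth = TruthSet(genotypes, read_log)
    truth.write(out_dir / "truth.tsv")
    return CohortResult(None, bam_paths, reference, truth, list(markers))


def simulate_trio_genotypes(
    markers: Sequence[MarkerDef],
    n_trios: int,
    cfg_sim: SimConfig,
    *,
    allele_freqs: Mapping[str, Mapping[int, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mendelian trio genotypes: parents from the allele spectra, child one
    transmission per parent.  Returns (genotypes, pedigree)."""
    if rng is None:
        rng = np.random.default_rng(cfg_sim.seed)
    if allele_freqs is None:
        allele_freqs = default_allele_freqs(markers, rng)
    rows, ped = [], []
    for t in range(n_trios):
        father, mother, child = f"t{t:03d}_F", f"t{t:03d}_M", f"t{t:03d}_C"
        ped.append((child, father, mother))
        for m in markers:
            gf = draw_genotype(allele_freqs[m.marker_id], rng)
            gm = draw_genotype(allele_freqs[m.marker_id], rng)
            cf = gf[int(rng.integers(2))]
            cm = gm[int(rng.integers(2))]
            gc = (min(cf, cm), max(cf, cm))
            rows.append((father, m.marker_id, *gf))
            rows.append((mother, m.marker_id, *gm))
            rows.append((child, m.marker_id, *gc))
    genotypes = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    pedigree = pd.DataFrame(ped, columns=["child", "father", "mother"])
    return genotypes, pedigree


def simulate_trio(
    parent_genotypes: tuple[tuple[int, int], tuple[int, int]],
    marker: MarkerDef,
    cfg_sim: SimConfig,
    rng: np.random.Generator,
    *,
    sample_ids: tuple[str, str, str] = ("father", "mother", "child"),
) -> tuple[dict[str, list[SimRead]], dict[str, tuple[int, int]]]:
    """Sequence-level reads for one trio at one marker; Mendelian by construction."""
    gf, gm = parent_genotypes
    cf = gf[int(rng.integers(2))]
    cm = gm[int(rng.integers(2))]
    gc = (min(cf, cm), max(cf, cm))
    flanks = _hostile_flanks(marker, rng)
    truth = dict(zip(sample_ids, (tuple(sorted(gf)), tuple(sorted(gm)), gc)))
    reads = {
        sid: simulate_marker_reads(truth[sid], marker, cfg_sim, rng,
                                   sample_id=sid, flanks=flanks)
        for sid in sample_ids
    }
    return reads, truth
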