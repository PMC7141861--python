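"""Frozen defaults and run configuration.

Every tunable named elsewhere in the package has exactly one default,
defined here, so a run is fully described by a :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# --- read selection -------------------------------------------------------
MIN_UNITS = 2.0            # minimum motif copies for a qualifying tract
MIN_TRACT_BP_MONO = 6      # mononucleotide tracts must span >= 6 bp
MIN_PURITY = 0.85          # per-base identity to the periodic motif extension
FLANK_PAD = 150            # bp around the marker fetched for overlap reads
MATE_WINDOW = 1000         # bp: "close to the repeat region" for mate rules
INSERT_MAX = 1000          # bp: proper-pair insert bound for attribute 5
FLANK_CAP = 32             # bp cap on matched-flank attributes
INDEL_CAP = 4              # cap on the indel-in-flank attribute
EDGE_SLACK = 3             # bp: tract within this of both read ends => fully repetitive

# --- genotyping model -----------------------------------------------------
SLIPPAGE_FLOOR = 1e-3      # lower clamp on any slippage rate
SLIPPAGE_CEIL = 0.95       # upper clamp on combined marker+sample slippage
CONF_THRESHOLD = 0.90      # posterior for a high-confidence call
MIN_SAMPLES = 20           # cohort size below which packaged defaults are used
MIN_SLIP_READS_DECAY = 5   # slippage reads needed to fit the step decay
MAX_ITER = 10              # genotyping <-> read-weighting iterations
CONVERGENCE_TOL = 1e-3     # changed-call fraction declaring convergence
REGRESSION_C = 1.0         # L2 inverse regularization for the read model

# packaged default marker parameters (used below MIN_SAMPLES)
DEFAULT_SLIPPAGE = 0.02
DEFAULT_P_UP = 0.15        # legacy: whole repeats added
DEFAULT_P_DOWN = 0.85      # legacy: whole repeats removed
DEFAULT_STEP_DECAY = 0.85  # geometric decay of multi-motif slips

# --- kernel ---------------------------------------------------------------
KERNEL_MIN_CALL_RATE = 0.95
KERNEL_MAX_SLIPPAGE = 0.05
KERNEL_MIN_ALLELE_FREQ = 0.05
KERNEL_MIN_POSTERIOR = 0.95
MIN_KERNEL_MARKERS = 50
SAMPLE_SLIPPAGE_MAX = 0.5

# --- expansion screen -----------------------------------------------------
MIN_FULL_READS = 1         # fully repetitive reads needed to flag a long locus
MIN_FLANK = 6              # bp of anchoring flank a spanning read needs


@dataclass
class RunConfig:
    """All tunables plus the I/O paths of one pipeline run.

    Round-trips through YAML so that a run can be replayed exactly.
    """

    bams: list[str] = field(default_factory=list)
    markers: str | None = None
    panel: str | None = None
    kernel: str | None = None
    out_dir: str = "strpop_out"
    seed: int = 1
    log_level: str = "INFO"

    min_units: float = MIN_UNITS
    min_purity: float = MIN_PURITY
    flank_pad: int = FLANK_PAD
    mate_window: int = MATE_WINDOW
    insert_max: int = INSERT_MAX
    flank_cap: int = FLANK_CAP
    indel_cap: int = INDEL_CAP
    edge_slack: int = EDGE_SLACK

    slippage_floor: float = SLIPPAGE_FLOOR
    slippage_ceil: float = SLIPPAGE_CEIL
    conf_threshold: float = CONF_THRESHOLD
    min_samples: int = MIN_SAMPLES
    max_iter: int = MAX_ITER
    convergence_tol: float = CONVERGENCE_TOL
    regression_c: float = REGRESSION_C

    min_kernel_markers: int = MIN_KERNEL_MARKERS
    min_full_reads: int = MIN_FULL_READS
    min_flank: int = MIN_FLANK

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
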