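"""Kernel of reliable markers and sample-specific slippage estimation.

Iterative joint estimation of read weights and marker parameters is
expensive, so a sample's individual slippage rate is instead estimated
once against a *kernel*: a curated set of well-behaved markers with known
stutter parameters and population allele frequencies.  A marker enters
the kernel when its population results show a high call rate, low
slippage, real polymorphism and confident calls.  A new sample's rate is
then the 1-D maximizer of the marginal read likelihood over the kernel,
with genotypes integrated out under Hardy-Weinberg weights from the
kernel allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from . import config as cfg
from .genotyping import MarkerParams, SampleParams, stutter_kernel
from .markers import MarkerDef

KERNEL_COLUMNS = [
    "chrom", "start", "end", "motif", "ref_units", "marker_id",
    "slippage", "p_up", "p_down", "step_decay", "n_samples_used", "allele_freqs",
]


@dataclass(frozen=True)
class KernelMarker:
    marker: MarkerDef
    params: MarkerParams
    allele_freqs: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.marker.marker_id}: allele frequencies sum to {total}"
            )


def build_kernel(
    calls: pd.DataFrame,
    marker_params: Mapping[str, MarkerParams],
    markers: Sequence[MarkerDef],
    n_samples: int,
    *,
    min_call_rate: float = cfg.KERNEL_MIN_CALL_RATE,
    max_slippage: float = cfg.KERNEL_MAX_SLIPPAGE,
    min_allele_freq: float = cfg.KERNEL_MIN_ALLELE_FREQ,
    min_posterior: float = cfg.KERNEL_MIN_POSTERIOR,
    min_samples: int = cfg.MIN_SAMPLES,
) -> list[KernelMarker]:
    """Select reliable markers from population genotyping output.

    A marker passes when all hold: call rate >= ``min_call_rate``,
    estimated slippage <= ``max_slippage``, at least two alleles at
    frequency >= ``min_allele_freq``, and mean posterior >=
    ``min_posterior``.  Deterministic; sorted by marker_id.
    """
    if calls.empty or n_samples <= 0:
        raise ValueError("empty population input")
    if n_samples < min_samples:
        raise ValueError(f"kernel construction needs >= {min_samples} samples")
    by_id = {m.marker_id: m for m in markers}
    kernel: list[KernelMarker] = []
    any_polymorphic = False
    for mid, sub in calls.groupby("marker_id", sort=True):
        params = marker_params.get(mid)
        if params is None or mid not in by_id:
            continue
        alleles = np.concatenate([sub["allele_a"].to_numpy(),
                                  sub["allele_b"].to_numpy()]).astype(int)
        vals, counts = np.unique(alleles, return_counts=True)
        freqs = counts / counts.sum()
        if (freqs >= min_allele_freq).sum() >= 2:
            any_polymorphic = True
        if len(sub) / n_samples < min_call_rate:
            continue
        if params.slippage > max_slippage:
            continue
        if (freqs >= min_allele_freq).sum() < 2:
            continue
        if sub["posterior"].mean() < min_posterior:
            continue
        kernel.append(KernelMarker(
            by_id[mid], params,
            {int(v): float(f) for v, f in zip(vals, freqs)},
        ))
    if not kernel:
        if not any_polymorphic:
            raise ValueError("all markers monomorphic; no polymorphic kernel possible")
        raise ValueError(
            "no marker passed the kernel criteria; relax call-rate/slippage/"
            "frequency/posterior thresholds"
        )
    return sorted(kernel, key=lambda k: k.marker.marker_id)


def _marker_loglik(
    units: np.ndarray,
    p_r: np.ndarray,
    km: KernelMarker,
    s_total: float,
) -> float:
    """Marginal log-likelihood of one sample's reads at one kernel marker."""
    alleles = np.array(sorted(km.allele_freqs))
    support = np.unique(np.concatenate([alleles, units, units - 1, units + 1]))
    support = support[support >= 1].astype(float)
    Q = stutter_kernel(alleles.astype(float), support, km.params, s_total)
    uniform = 1.0 / len(support)
    pos = np.searchsorted(support, units.astype(float))
    ok = (pos < len(support)) & (support[np.minimum(pos, len(support) - 1)] == units)
    q_rows = np.where(ok[:, None], Q[np.minimum(pos, len(support) - 1), :], 0.0)
    P = p_r[:, None] * q_rows + (1.0 - p_r)[:, None] * uniform  # (reads, n_alleles)
    f = np.array([km.allele_freqs[int(a)] for a in alleles])
    ia, ib = np.triu_indices(len(alleles))
    w = np.where(ia == ib, f[ia] * f[ib], 2.0 * f[ia] * f[ib])
    mix = 0.5 * (P[:, ia] + P[:, ib])
    pair_ll = np.log(np.maximum(mix, 1e-300)).sum(axis=0)
    return float(logsumexp(pair_ll + np.log(np.maximum(w, 1e-300))))


def estimate_sample_slippage(
    reads: pd.DataFrame,
    kernel: Sequence[KernelMarker],
    *,
    sample_id: str | None = None,
    p_r: np.ndarray | None = None,
    min_kernel_markers: int = cfg.MIN_KERNEL_MARKERS,
    floor: float = cfg.SLIPPAGE_FLOOR,
    ceil: float = cfg.SAMPLE_SLIPPAGE_MAX,
) -> SampleParams:
    """Maximum-likelihood sample slippage rate over the kernel markers.

    ``reads`` is the sample's read table restricted to kernel markers;
    ``p_r`` defaults to reliabilities under the packaged read model.
    1-D bounded optimization on [floor, ceil]; deterministic.
    """
    from .genotyping import DEFAULT_REGRESSION_MODEL, read_true_probs

    usable = reads[~reads["lower_bound"].astype(bool)]
    if usable.empty:
        raise ValueError("no kernel reads for this sample")
    if sample_id is None:
        sample_id = str(usable["sample_id"].iloc[0])
    if p_r is None:
        attrs = usable[["a1", "a2", "a3", "a4", "a5", "a6"]].to_numpy(dtype=float)
        p_r = read_true_probs(DEFAULT_REGRESSION_MODEL, attrs)
    p_r = np.asarray(p_r, dtype=float)

    by_id = {km.marker.marker_id: km for km in kernel}
    per_marker: list[tuple[KernelMarker, np.ndarray, np.ndarray]] = []
    mids = usable["marker_id"].to_numpy()
    units_all = np.maximum(np.round(usable["reported_units"].to_numpy()), 1).astype(int)
    for mid in np.unique(mids):
        km = by_id.get(mid)
        if km is None:
            continue
        mask = mids == mid
        per_marker.append((km, units_all[mask], p_r[mask]))
    if len(per_marker) < min_kernel_markers:
        raise ValueError(
            f"only {len(per_marker)} kernel markers with reads "
            f"(need >= {min_kernel_markers})"
        )

    def negloglik(s_j: float) -> float:
        total = 0.0
        for km, u, w in per_marker:
            s_total = float(np.clip(km.params.slippage + s_j,
                                    cfg.SLIPPAGE_FLOOR, cfg.SLIPPAGE_CEIL))
            total += _marker_loglik(u, w, km, s_total)
        return -total

    res = minimize_scalar(negloglik, bounds=(floor, ceil), method="bounded",
                          options={"xatol": 1e-5})
    return SampleParams(sample_id, float(np.clip(res.x, floor, ceil)))


# --- kernel file I/O -------------------------------------------------------

def write_kernel(kernel: Sequence[KernelMarker], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(KERNEL_COLUMNS) + "\n")
        for km in kernel:
            m, p = km.marker, km.params
            freqs = ";".join(f"{a}:{f:.6g}" for a, f in sorted(km.allele_freqs.items()))
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.motif}\t{m.ref_units:g}"
                f"\t{m.marker_id}\t{p.slippage:.6g}\t{p.p_up:.6g}\t{p.p_down:.6g}"
                f"\t{p.step_decay:.6g}\t{p.n_samples_used}\t{freqs}\n"
            )


def load_kernel(path: str | Path) -> list[KernelMarker]:
    kernel = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            marker = MarkerDef.create(f[0], int(f[1]), int(f[2]), f[3],
                                      float(f[4]), f[5])
            params = MarkerParams(float(f[6]), float(f[7]), float(f[8]),
                                  float(f[9]), int(f[10]))
            freqs = {}
            for pair in f[11].split(";"):
                a, fr = pair.split(":")
                freqs[int(a)] = float(fr)
            total = sum(freqs.values())
            freqs = {a: fr / total for a, fr in freqs.items()}
            kernel.append(KernelMarker(marker, params, freqs))
    return kernel
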