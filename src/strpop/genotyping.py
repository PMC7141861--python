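"""Slippage-aware joint genotyping of microsatellites.

The model: a read's reported repeat count ``x`` given a template allele
``a`` is, with probability ``p_r`` (the read's reliability from a
six-attribute logistic regression), drawn from a stutter kernel
``Q(x|a)`` and otherwise uniform over the candidate support.  ``Q``
places mass ``1 - s`` on the template allele and distributes ``s`` over
whole-motif offsets ``+-k`` geometrically (``gamma (1-gamma)^(k-1)``),
split between the up direction (probability ``p_up``) and down
(``p_down = 1 - p_up``); the kernel is truncated to the support and
renormalized.  ``s`` combines a marker-specific and a sample-specific
slippage rate.  A diploid genotype (A, B) contributes an equal read
mixture from its two haplotypes, and the caller maximizes the summed read
log-likelihood over all unordered allele pairs.

Marker parameters are estimated from population data once enough samples
are present: the slippage rate as the reliability-weighted fraction of
reads deviating from their sample's called genotype by whole motif
units, and the direction probability as the weighted fraction of those
slippage reads that gained repeats (its complement gives the loss
probability).  With no observed slippage reads the legacy constants
(0.15 add / 0.85 remove) are used.  Genotyping and read weighting
alternate until the set of calls stabilizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from sklearn.linear_model import LogisticRegression

from . import config as cfg
from .markers import MarkerDef
from .read_extraction import RepeatRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionModel:
    """Logistic model mapping six read attributes to a reliability p_r."""

    intercept: float
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefficients) != 6:
            raise ValueError("exactly 6 coefficients required")
        if not (np.isfinite(self.intercept) and np.all(np.isfinite(self.coefficients))):
            raise ValueError("model parameters must be finite")


#: Packaged default read model: rewards purity, flank anchoring, base quality
#: and pair consistency, penalizes flank indels.  p_r models the chance the
#: read reports a value from the stutter kernel around its template (stutter
#: itself lives in Q), so a clean, well-anchored read scores ~0.99; the
#: population refit replaces this model once labels exist.
DEFAULT_REGRESSION_MODEL = RegressionModel(-2.0, (4.0, 0.04, 0.04, 1.0, 0.5, -0.5))


@dataclass(frozen=True)
class MarkerParams:
    """Per-marker stutter parameters."""

    slippage: float = cfg.DEFAULT_SLIPPAGE
    p_up: float = cfg.DEFAULT_P_UP
    p_down: float = cfg.DEFAULT_P_DOWN
    step_decay: float = cfg.DEFAULT_STEP_DECAY
    n_samples_used: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.slippage < 1.0:
            raise ValueError("slippage must be in [0, 1)")
        if abs(self.p_up + self.p_down - 1.0) > 1e-9:
            raise ValueError("p_up + p_down must equal 1")
        if not 0.0 < self.step_decay < 1.0:
            raise ValueError("step_decay must be in (0, 1)")


@dataclass(frozen=True)
class SampleParams:
    """Sample-specific slippage rate."""

    sample_id: str
    slippage: float = cfg.SLIPPAGE_FLOOR

    def __post_init__(self) -> None:
        if not cfg.SLIPPAGE_FLOOR <= self.slippage <= cfg.SAMPLE_SLIPPAGE_MAX:
            raise ValueError(
                f"sample slippage must be in [{cfg.SLIPPAGE_FLOOR}, "
                f"{cfg.SAMPLE_SLIPPAGE_MAX}]"
            )


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    sample_id: str
    allele_a: float
    allele_b: float
    posterior: float
    log_lik: float
    n_reads: int
    high_confidence: bool

    def __post_init__(self) -> None:
        if self.allele_a > self.allele_b:
            raise ValueError("alleles must be ordered allele_a <= allele_b")
        if not 0.0 <= self.posterior <= 1.0 + 1e-12:
            raise ValueError("posterior outside [0,1]")

    @property
    def alleles(self) -> tuple[float, float]:
        return (self.allele_a, self.allele_b)


def combined_slippage(params: MarkerParams, sample: SampleParams) -> float:
    """Additive marker+sample slippage, clamped away from 0 and 1."""
    return float(np.clip(params.slippage + sample.slippage,
                         cfg.SLIPPAGE_FLOOR, cfg.SLIPPAGE_CEIL))


def read_true_prob(model: RegressionModel, attributes: Sequence[float]) -> float:
    """Probability that a read reports a true allele, strictly in (0, 1)."""
    attrs = np.asarray(attributes, dtype=float)
    if attrs.shape != (6,) or not np.all(np.isfinite(attrs)):
        raise ValueError("attributes must be 6 finite reals")
    z = model.intercept + float(np.dot(model.coefficients, attrs))
    return float(np.clip(expit(z), 1e-12, 1.0 - 1e-12))


def read_true_probs(model: RegressionModel, attrs: np.ndarray) -> np.ndarray:
    """Vectorized :func:`read_true_prob` over an (n, 6) attribute matrix."""
    z = model.intercept + attrs @ np.asarray(model.coefficients)
    return np.clip(expit(z), 1e-12, 1.0 - 1e-12)


def stutter_kernel(
    candidates: np.ndarray,
    support: np.ndarray,
    params: MarkerParams,
    s_total: float,
) -> np.ndarray:
    """Q[x, a]: stutter kernel over ``support`` for each candidate allele.

    Mass ``1 - s_total`` on the template allele; whole-motif offsets of
    ``+-k`` units receive ``s_total * dir * gamma * (1-gamma)^(k-1)``;
    the kernel is truncated at the support boundary and renormalized
    column-wise.  Shape (len(support), len(candidates)).
    """
    gamma = params.step_decay
    diff = support[:, None] - candidates[None, :]
    k = np.abs(diff)
    direction = np.where(diff > 0, params.p_up, params.p_down)
    with np.errstate(over="ignore"):
        mass = s_total * direction * gamma * (1.0 - gamma) ** np.maximum(k - 1.0, 0.0)
    mass = np.where(diff == 0, 1.0 - s_total, mass)
    z = mass.sum(axis=0)
    return mass / z


def read_allele_likelihood(
    reported_units: float,
    allele: float,
    p_r: float,
    params: MarkerParams,
    s_total: float,
    support: Iterable[float],
) -> float:
    """P(read reports ``reported_units`` | template ``allele``).

    ``support`` is the finite candidate set; reported values that are not
    whole-motif members of the support receive only the uniform
    ``(1 - p_r)/|support|`` mass.
    """
    sup = np.asarray(sorted(set(float(x) for x in support)))
    if not np.any(np.isclose(sup, allele)):
        raise ValueError(f"allele {allele} outside support")
    if not 0.0 < p_r < 1.0 + 1e-12:
        raise ValueError("p_r must be in (0, 1)")
    uniform = 1.0 / len(sup)
    q = 0.0
    if abs(reported_units - round(reported_units)) < 1e-6:
        hits = np.isclose(sup, round(reported_units))
        if hits.any():
            Q = stutter_kernel(np.array([float(allele)]), sup, params, s_total)
            q = float(Q[int(np.argmax(hits)), 0])
    return p_r * q + (1.0 - p_r) * uniform


class _CallCore(NamedTuple):
    allele_a: int
    allele_b: int
    posterior: float
    log_lik: float


def _call_core(
    units: np.ndarray,
    p_r: np.ndarray,
    params: MarkerParams,
    s_total: float,
    candidates: np.ndarray,
) -> _CallCore:
    """Exhaustive maximization over unordered candidate pairs.

    ``units`` are whole-motif read values; the support equals the
    candidate set.  Ties break to smaller allele sum, then lexicographic.
    """
    support = candidates
    Q = stutter_kernel(candidates.astype(float), support.astype(float),
                       params, s_total)
    uniform = 1.0 / len(support)
    pos = np.searchsorted(support, units)
    pos_ok = (pos < len(support)) & (support[np.minimum(pos, len(support) - 1)] == units)
    q_rows = np.where(pos_ok[:, None], Q[np.minimum(pos, len(support) - 1), :], 0.0)
    P = p_r[:, None] * q_rows + (1.0 - p_r)[:, None] * uniform   # (reads, m)

    m = len(candidates)
    mix = 0.5 * (P[:, :, None] + P[:, None, :])                   # (reads, m, m)
    ll = np.log(np.maximum(mix, 1e-300)).sum(axis=0)              # (m, m)
    iu, ju = np.triu_indices(m)
    flat = ll[iu, ju]
    best_ll = flat.max()
    tied = np.flatnonzero(flat >= best_ll)
    # ties: smaller allele sum, then lexicographically smaller pair
    keys = [(int(candidates[iu[t]]) + int(candidates[ju[t]]),
             int(candidates[iu[t]]), int(candidates[ju[t]])) for t in tied]
    best = int(tied[min(range(len(keys)), key=keys.__getitem__)])
    posterior = float(np.exp(best_ll - logsumexp(flat)))
    a, b = int(candidates[iu[best]]), int(candidates[ju[best]])
    if a > b:
        a, b = b, a
    return _CallCore(a, b, min(posterior, 1.0), float(best_ll))


def default_candidates(units: np.ndarray) -> np.ndarray:
    """Distinct whole-unit reported values plus a +-1 unit neighborhood."""
    base = np.unique(units.astype(int))
    cands = np.unique(np.concatenate([base, base - 1, base + 1]))
    return cands[cands >= 1]


def call_genotype(
    reads: Sequence[RepeatRead] | np.ndarray,
    p_r: Sequence[float] | np.ndarray,
    params: MarkerParams,
    sample: SampleParams,
    candidate_alleles: Iterable[float] | None = None,
    *,
    marker_id: str = "",
    conf_threshold: float = cfg.CONF_THRESHOLD,
) -> GenotypeCall | None:
    """Maximum-likelihood genotype over all unordered candidate pairs.

    Reads whose tract touches a read end only bound the allele from below
    and are excluded unless no bounded read exists.  Returns ``None``
    (no-call) for an empty read list.
    """
    if len(reads) == 0:
        return None
    p_r = np.asarray(p_r, dtype=float)
    if isinstance(reads[0], RepeatRead):
        lower = np.array([r.lower_bound for r in reads])
        raw = np.array([r.reported_units for r in reads])
        if not lower.all():
            raw, p_r = raw[~lower], p_r[~lower]
        units = np.round(raw).astype(int)
        if not marker_id:
            marker_id = reads[0].marker_id
        sample_id = reads[0].sample_id
    else:
        units = np.round(np.asarray(reads, dtype=float)).astype(int)
        sample_id = sample.sample_id
    units = np.maximum(units, 1)
    if candidate_alleles is None:
        candidates = default_candidates(units)
    else:
        candidates = np.unique(np.asarray(list(candidate_alleles), dtype=int))
    s_total = combined_slippage(params, sample)
    res = _call_core(units, p_r, params, s_total, candidates)
    return GenotypeCall(
        marker_id=marker_id,
        sample_id=sample_id,
        allele_a=float(res.allele_a),
        allele_b=float(res.allele_b),
        posterior=res.posterior,
        log_lik=res.log_lik,
        n_reads=int(len(units)),
        high_confidence=res.posterior >= conf_threshold,
    )


def estimate_direction_probs(
    up_weights: Sequence[float],
    down_weights: Sequence[float],
) -> tuple[float, float]:
    """Fraction of slippage events that added whole repeats, read-weighted.

    ``p_up = sum(w_up) / sum(w_all)``; ``p_down = 1 - p_up``.  With no
    slippage reads at all, falls back to the legacy constants
    (add 0.15 / remove 0.85).
    """
    up = np.asarray(list(up_weights), dtype=float)
    down = np.asarray(list(down_weights), dtype=float)
    if ((up <= 0).any()) or ((down <= 0).any()):
        raise ValueError("slippage-read weights must be positive")
    denom = up.sum() + down.sum()
    if denom == 0:
        return cfg.DEFAULT_P_UP, cfg.DEFAULT_P_DOWN
    p_up = float(up.sum() / denom)
    return p_up, 1.0 - p_up


def estimate_marker_params(
    units: np.ndarray,
    p_r: np.ndarray,
    called_a: np.ndarray,
    called_b: np.ndarray,
    n_samples: int,
    *,
    min_samples: int = cfg.MIN_SAMPLES,
) -> MarkerParams:
    """Estimate slippage rate, direction and step decay for one marker.

    Inputs are aligned per read: whole-unit reported value, reliability
    weight, and the sample's current called alleles.  Below
    ``min_samples`` contributing samples the packaged defaults are
    returned unchanged (``n_samples_used = 0``).
    """
    if n_samples < min_samples:
        return MarkerParams()
    units = np.asarray(units, dtype=int)
    p_r = np.asarray(p_r, dtype=float)
    dev_a = units - np.asarray(called_a, dtype=int)
    dev_b = units - np.asarray(called_b, dtype=int)
    dev = np.where(np.abs(dev_a) <= np.abs(dev_b), dev_a, dev_b)
    slipped = dev != 0
    # a read equidistant from both alleles of a het has unambiguous slip
    # magnitude but unknowable direction; keep it out of the direction tally
    ambiguous = slipped & (np.abs(dev_a) == np.abs(dev_b)) & (dev_a != dev_b)
    total_w = p_r.sum()
    slippage = float(p_r[slipped].sum() / total_w) if total_w > 0 else 0.0
    slippage = float(np.clip(slippage, cfg.SLIPPAGE_FLOOR, 0.95))
    directed = slipped & ~ambiguous
    if directed.any():
        p_up, p_down = estimate_direction_probs(
            p_r[directed & (dev > 0)], p_r[directed & (dev < 0)]
        )
    else:
        p_up, p_down = cfg.DEFAULT_P_UP, cfg.DEFAULT_P_DOWN
    if slipped.sum() >= cfg.MIN_SLIP_READS_DECAY:
        # geometric step: mean |k| = 1/gamma
        mean_k = float(np.average(np.abs(dev[slipped]), weights=p_r[slipped]))
        step_decay = float(np.clip(1.0 / max(mean_k, 1.0), 1e-3, 1.0 - 1e-3))
    else:
        step_decay = cfg.DEFAULT_STEP_DECAY
    return MarkerParams(slippage, p_up, p_down, step_decay, n_samples_used=n_samples)


def trio_consistency(
    child: GenotypeCall, mother: GenotypeCall, father: GenotypeCall
) -> bool:
    """True iff the child genotype is explainable by one transmission per parent."""
    if not (child.marker_id == mother.marker_id == father.marker_id):
        raise ValueError("trio calls must be at the same marker")
    c1, c2 = child.alleles
    m, f = set(mother.alleles), set(father.alleles)
    return (c1 in m and c2 in f) or (c2 in m and c1 in f)


class PopulationResult(NamedTuple):
    calls: pd.DataFrame
    marker_params: dict[str, MarkerParams]
    model: RegressionModel
    converged: bool
    n_iter: int


_ATTR_COLS = ["a1", "a2", "a3", "a4", "a5", "a6"]


def _refit_regression(
    attrs: np.ndarray, labels: np.ndarray, current: RegressionModel, C: float
) -> RegressionModel:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 10:
        logger.info("regression refit skipped (labels nearly single-class)")
        return current
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=200)
    lr.fit(attrs, labels)
    return RegressionModel(float(lr.intercept_[0]), tuple(lr.coef_[0]))


def iterate_population_genotyping(
    reads: pd.DataFrame,
    markers: Sequence[MarkerDef],
    samples: Mapping[str, SampleParams] | None = None,
    init_model: RegressionModel = DEFAULT_REGRESSION_MODEL,
    *,
    max_iter: int = cfg.MAX_ITER,
    tol: float = cfg.CONVERGENCE_TOL,
    min_samples: int = cfg.MIN_SAMPLES,
    conf_threshold: float = cfg.CONF_THRESHOLD,
    regression_c: float = cfg.REGRESSION_C,
) -> PopulationResult:
    """Alternate genotyping, read labeling, regression refit and
    marker-parameter re-estimation until the call set stabilizes.

    ``reads`` is the columnar read table (see
    :data:`strpop.read_extraction.READ_TABLE_COLUMNS`); lower-bound reads
    are dropped from the likelihood.  Deterministic for a fixed input.
    """
    if reads.empty:
        raise ValueError("empty read table")
    needed = ["marker_id", "sample_id", "reported_units", *_ATTR_COLS]
    usable = reads.loc[~reads["lower_bound"].astype(bool), needed] \
        .reset_index(drop=True)
    if usable.empty:
        raise ValueError("no bounded reads available for genotyping")

    units = np.maximum(np.round(usable["reported_units"].to_numpy()), 1).astype(int)
    attrs = usable[_ATTR_COLS].to_numpy(dtype=float)
    sample_ids = usable["sample_id"].to_numpy()
    if samples is None:
        samples = {}
    sp_by_id = {
        sid: samples.get(sid, SampleParams(sid, cfg.SLIPPAGE_FLOOR))
        for sid in pd.unique(sample_ids)
    }
    n_samples_total = len(sp_by_id)

    # stable group index: (marker, sample) -> row positions
    groups: dict[str, dict[str, np.ndarray]] = {}
    mkr_arr = usable["marker_id"].to_numpy()
    order = np.lexsort((sample_ids, mkr_arr))
    sorted_m, sorted_s = mkr_arr[order], sample_ids[order]
    boundaries = np.flatnonzero(
        (sorted_m[1:] != sorted_m[:-1]) | (sorted_s[1:] != sorted_s[:-1])
    )
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(order)]])
    for s0, e0 in zip(starts, ends):
        groups.setdefault(sorted_m[s0], {})[sorted_s[s0]] = order[s0:e0]

    params: dict[str, MarkerParams] = {
        mid: MarkerParams() for mid in groups
    }
    model = init_model
    prev_calls: dict[tuple[str, str], tuple[int, int]] = {}
    calls_rows: list[tuple] = []
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        p_r = read_true_probs(model, attrs)
        calls_rows = []
        call_a = np.zeros(len(usable), dtype=int)
        call_b = np.zeros(len(usable), dtype=int)
        cur_calls: dict[tuple[str, str], tuple[int, int]] = {}
        for mid, by_sample in groups.items():
            mp = params[mid]
            for sid, idx in by_sample.items():
                sp = sp_by_id[sid]
                u, w = units[idx], p_r[idx]
                cands = default_candidates(u)
                res = _call_core(u, w, mp, combined_slippage(mp, sp), cands)
                cur_calls[(mid, sid)] = (res.allele_a, res.allele_b)
                call_a[idx], call_b[idx] = res.allele_a, res.allele_b
                calls_rows.append(
                    (mid, sid, float(res.allele_a), float(res.allele_b),
                     res.posterior, res.log_lik, len(idx),
                     res.posterior >= conf_threshold)
                )
        changed = sum(
            1 for k, v in cur_calls.items() if prev_calls.get(k) != v
        )
        frac_changed = changed / len(cur_calls)
        prev_calls = cur_calls

        labels = ((units == call_a) | (units == call_b)).astype(int)
        model = _refit_regression(attrs, labels, model, regression_c)
        p_r = read_true_probs(model, attrs)
        for mid, by_sample in groups.items():
            idx = np.concatenate(list(by_sample.values()))
            params[mid] = estimate_marker_params(
                units[idx], p_r[idx], call_a[idx], call_b[idx],
                n_samples=n_samples_total, min_samples=min_samples,
            )
        logger.info("iteration %d: %.4f%% of calls changed", it, 100 * frac_changed)
        if frac_changed < tol:
            converged = True
            break
    if not converged:
        logger.warning("population genotyping did not converge in %d iterations",
                       max_iter)
    calls = pd.DataFrame(
        calls_rows,
        columns=["marker_id", "sample_id", "allele_a", "allele_b",
                 "posterior", "log_lik", "n_reads", "high_confidence"],
    ).sort_values(["marker_id", "sample_id"], kind="stable").reset_index(drop=True)
    return PopulationResult(calls, params, model, converged, it)


# --- per-marker population output -----------------------------------------

def write_marker_calls(
    marker: MarkerDef, params: MarkerParams, calls: pd.DataFrame, path
) -> None:
    """One output file per marker: all samples' calls plus the marker params."""
    sub = calls[calls["marker_id"] == marker.marker_id]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"#marker\t{marker.marker_id}\t{marker.chrom}\t{marker.start}"
            f"\t{marker.end}\t{marker.motif}\t{marker.ref_units:g}\n"
        )
        fh.write(
            f"#params\tslippage={params.slippage:.6g}\tp_up={params.p_up:.6g}"
            f"\tp_down={params.p_down:.6g}\tstep_decay={params.step_decay:.6g}"
            f"\tn_samples_used={params.n_samples_used}\n"
        )
        fh.write("sample_id\tallele_a\tallele_b\tposterior\tn_reads\thc_flag\n")
        for row in sub.itertuples(index=False):
            fh.write(
                f"{row.sample_id}\t{row.allele_a:g}\t{row.allele_b:g}"
                f"\t{row.posterior:.6f}\t{row.n_reads}"
                f"\t{int(row.high_confidence)}\n"
            )


def read_marker_calls(path) -> tuple[dict, MarkerParams, pd.DataFrame]:
    """Parse a per-marker output file back into (marker info, params, calls)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    mfields = lines[0].split("\t")
    info = {
        "marker_id": mfields[1], "chrom": mfields[2], "start": int(mfields[3]),
        "end": int(mfields[4]), "motif": mfields[5], "ref_units": float(mfields[6]),
    }
    pfields = dict(kv.split("=") for kv in lines[1].split("\t")[1:])
    params = MarkerParams(
        float(pfields["slippage"]), float(pfields["p_up"]),
        float(pfields["p_down"]), float(pfields["step_decay"]),
        int(pfields["n_samples_used"]),
    )
    rows = [ln.split("\t") for ln in lines[3:] if ln]
    calls = pd.DataFrame(
        rows, columns=["sample_id", "allele_a", "allele_b", "posterior",
                       "n_reads", "hc_flag"],
    )
    for col, typ in [("allele_a", float), ("allele_b", float),
                     ("posterior", float), ("n_reads", int), ("hc_flag", int)]:
        calls[col] = calls[col].astype(typ)
    return info, params, calls
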