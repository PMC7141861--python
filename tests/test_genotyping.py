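"""Genotyping model: likelihoods, calling, parameter estimation, trios."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strpop import config as cfg
from strpop import simdata
from strpop.genotyping import (
    DEFAULT_REGRESSION_MODEL,
    GenotypeCall,
    MarkerParams,
    RegressionModel,
    SampleParams,
    call_genotype,
    estimate_direction_probs,
    estimate_marker_params,
    iterate_population_genotyping,
    read_allele_likelihood,
    read_true_prob,
    trio_consistency,
)

from conftest import cohort_genotypes


def kernel_prob_oracle(reported, allele, p_r, params, s_total, support):
    """Pure-python enumeration of p_r*Q + (1-p_r)*U, independent of the
    vectorized implementation."""
    support = sorted(support)
    mass = {}
    for x in support:
        k = round(x - allele)
        if k == 0:
            mass[x] = 1.0 - s_total
        else:
            d = params.p_up if k > 0 else params.p_down
            mass[x] = s_total * d * params.step_decay * \
                (1 - params.step_decay) ** (abs(k) - 1)
    z = sum(mass.values())
    q = mass.get(reported, 0.0) / z if reported in mass else 0.0
    return p_r * q + (1 - p_r) / len(support)


def call_oracle(units, p_r, params, s_total):
    """Exhaustive pair enumeration with the oracle per-read likelihood."""
    cands = sorted({u for u in units} | {u - 1 for u in units} | {u + 1 for u in units})
    cands = [c for c in cands if c >= 1]
    best = None
    for a, b in itertools.combinations_with_replacement(cands, 2):
        ll = 0.0
        for u, w in zip(units, p_r):
            pa = kernel_prob_oracle(u, a, w, params, s_total, cands)
            pb = kernel_prob_oracle(u, b, w, params, s_total, cands)
            ll += math.log(max(0.5 * pa + 0.5 * pb, 1e-300))
        key = (-ll, a + b, (a, b))
        if best is None or key < best[0]:
            best = (key, (a, b))
    return best[1]


PARAMS = MarkerParams(slippage=0.02, p_up=0.3, p_down=0.7, step_decay=0.8)


class TestReadTrueProb:
    def test_zero_model_gives_half(self):
        model = RegressionModel(0.0, (0.0,) * 6)
        assert read_true_prob(model, [1, 2, 3, 4, 5, 6]) == 0.5

    def test_saturation(self):
        model = RegressionModel(-20.0, (0.0,) * 6)
        assert read_true_prob(model, [0] * 6) < 1e-8

    def test_scalar_arithmetic(self):
        model = RegressionModel(0.5, (1.0, 0, 0, 0, 0, 0))
        expected = 1 / (1 + math.exp(-1.5))
        assert read_true_prob(model, [1, 9, 9, 9, 9, 9]) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            read_true_prob(DEFAULT_REGRESSION_MODEL, [np.nan, 0, 0, 0, 0, 0])


class TestReadAlleleLikelihood:
    def test_noise_free_match(self):
        p = MarkerParams(slippage=0.0, p_up=0.5, p_down=0.5)
        v = read_allele_likelihood(10, 10, 1.0 - 1e-12, p, 0.0, range(8, 13))
        assert v == pytest.approx(1.0)

    def test_noise_free_mismatch(self):
        p = MarkerParams(slippage=0.0, p_up=0.5, p_down=0.5)
        v = read_allele_likelihood(11, 10, 1.0 - 1e-12, p, 0.0, range(8, 13))
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_truncated_renormalized_value(self):
        # support a-2..a+2; hand-enumerated truncation normalizer
        a, s, pu, g = 10, 0.1, 0.3, 0.8
        p = MarkerParams(slippage=0.02, p_up=pu, p_down=1 - pu, step_decay=g)
        masses = {
            8: s * 0.7 * g * (1 - g), 9: s * 0.7 * g, 10: 1 - s,
            11: s * pu * g, 12: s * pu * g * (1 - g),
        }
        z = sum(masses.values())
        expected = 0.9 * (s * pu * g / z) + 0.1 * (1 / 5)
        got = read_allele_likelihood(11, a, 0.9, p, s, range(8, 13))
        assert got == pytest.approx(expected)

    def test_fractional_report_gets_uniform_mass_only(self):
        v = read_allele_likelihood(10.5, 10, 0.9, PARAMS, 0.1, range(8, 13))
        assert v == pytest.approx(0.1 / 5)

    def test_allele_outside_support_rejected(self):
        with pytest.raises(ValueError):
            read_allele_likelihood(10, 20, 0.9, PARAMS, 0.1, range(8, 13))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.0, 0.5), p_up=st.floats(0.0, 1.0),
        gamma=st.floats(0.05, 0.95), p_r=st.floats(0.01, 0.99),
        allele=st.integers(9, 11),
    )
    def test_total_probability_is_one(self, s, p_up, gamma, p_r, allele):
        p = MarkerParams(slippage=0.02, p_up=p_up, p_down=1 - p_up,
                         step_decay=gamma)
        support = list(range(7, 14))
        total = sum(read_allele_likelihood(x, allele, p_r, p, s, support)
                    for x in support)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        support = list(range(7, 14))
        for x in support:
            got = read_allele_likelihood(x, 10, 0.9, PARAMS, 0.1, support)
            exp = kernel_prob_oracle(x, 10, 0.9, PARAMS, 0.1, support)
            assert got == pytest.approx(exp)


class TestCallGenotype:
    SAMPLE = SampleParams("s1", 0.001)

    def test_unanimous_reads(self):
        call = call_genotype(np.full(20, 10.0), np.full(20, 0.99), PARAMS,
                             self.SAMPLE, marker_id="m")
        assert call.alleles == (10.0, 10.0)
        assert call.high_confidence

    def test_clear_het(self):
        units = np.array([10.0] * 10 + [12.0] * 10)
        call = call_genotype(units, np.full(20, 0.95), PARAMS, self.SAMPLE,
                             marker_id="m")
        assert call.alleles == (10.0, 12.0)

    def test_stutter_versus_het_matches_oracle(self):
        units = np.array([10.0] * 18 + [9.0] * 2)
        p = MarkerParams(slippage=0.02, p_up=0.15, p_down=0.85, step_decay=0.8)
        sp = SampleParams("s1", 0.08)  # s_total ~ 0.1
        p_r = np.full(20, 0.95)
        call = call_genotype(units, p_r, p, sp, marker_id="m")
        s_total = min(0.95, p.slippage + sp.slippage)
        assert call.alleles == tuple(map(float, call_oracle(
            units.astype(int), p_r, p, s_total)))

    def test_empty_reads_is_no_call(self):
        assert call_genotype([], [], PARAMS, self.SAMPLE) is None

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        sp = SampleParams("s1", 0.01)
        for _ in range(200):
            n = rng.integers(1, 12)
            units = rng.integers(8, 13, n).astype(float)
            p_r = rng.uniform(0.5, 0.99, n)
            params = MarkerParams(
                slippage=float(rng.uniform(0, 0.2)),
                p_up=(pu := float(rng.uniform(0.05, 0.95))),
                p_down=1 - pu,
                step_decay=float(rng.uniform(0.3, 0.95)),
            )
            s_total = min(0.95, params.slippage + sp.slippage)
            call = call_genotype(units, p_r, params, sp, marker_id="m")
            assert call.alleles == tuple(map(float, call_oracle(
                units.astype(int), p_r, params, s_total)))

    def test_lower_bound_reads_excluded_when_bounded_exist(self, ac_marker):
        from strpop.read_extraction import RepeatRead, RepeatTract
        tract = RepeatTract(0, 20, 10.0, 1.0)
        mk = dict(sample_id="s1", marker_id="mAC", fully_repetitive=False,
                  source="overlap", attributes=(1.0, 10, 10, 0.9, 1, 0),
                  read_length=50)
        reads = (
            [RepeatRead(read_id=f"b{i}", reported_units=10.0, tract=tract,
                        lower_bound=False, **mk) for i in range(5)]
            + [RepeatRead(read_id="lb", reported_units=40.0,
                          tract=RepeatTract(0, 50, 40.0, 1.0),
                          lower_bound=True, **mk)]
        )
        call = call_genotype(reads, np.full(6, 0.95), PARAMS, self.SAMPLE)
        assert call.alleles == (10.0, 10.0)
        assert call.n_reads == 5


class TestDirectionProbs:
    def test_all_upward(self):
        assert estimate_direction_probs([0.4, 0.9, 1.0, 0.2], []) == (1.0, 0.0)

    def test_unweighted_counts(self):
        assert estimate_direction_probs([1, 1, 1], [1]) == (0.75, 0.25)

    def test_weighted_hand_arithmetic(self):
        p_up, p_down = estimate_direction_probs([0.9, 0.8], [0.5, 0.3])
        assert p_up == pytest.approx(1.7 / 2.5)
        assert p_down == pytest.approx(0.8 / 2.5)

    def test_legacy_fallback_without_slippage_reads(self):
        assert estimate_direction_probs([], []) == (0.15, 0.85)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            estimate_direction_probs([0.5, 0.0], [0.3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        up=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        down=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        c=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, up, down, c):
        base = estimate_direction_probs(up, down)
        scaled = estimate_direction_probs([c * w for w in up],
                                          [c * w for w in down])
        assert base[0] == pytest.approx(scaled[0])


class TestEstimateMarkerParams:
    def test_small_cohort_uses_packaged_defaults(self):
        p = estimate_marker_params(
            np.array([10, 10, 11]), np.ones(3), np.array([10] * 3),
            np.array([10] * 3), n_samples=19)
        assert p == MarkerParams()
        assert p.n_samples_used == 0

    def test_large_cohort_estimates(self):
        rng = np.random.default_rng(7)
        n = 6000
        a = np.full(n, 10)
        slip = np.where(rng.random(n) < 0.05,
                        np.where(rng.random(n) < 0.3, 1, -1), 0)
        units = a + slip
        p = estimate_marker_params(units, np.ones(n), a, a, n_samples=200)
        assert p.n_samples_used == 200
        assert p.slippage == pytest.approx(0.05, abs=0.01)
        assert p.p_up == pytest.approx(0.3, abs=0.05)

    def test_zero_deviation_cohort(self):
        n = 100
        a = np.full(n, 10)
        p = estimate_marker_params(a, np.ones(n), a, a, n_samples=30)
        assert p.slippage == cfg.SLIPPAGE_FLOOR
        assert (p.p_up, p.p_down) == (0.15, 0.85)


class TestTrioConsistency:
    def mk(self, a, b):
        return GenotypeCall("m", "x", float(min(a, b)), float(max(a, b)),
                            0.99, -1.0, 30, True)

    def brute_force(self, child, mother, father):
        return any(
            {child.allele_a, child.allele_b} == {cm, cf} or
            (child.allele_a == cm and child.allele_b == cf) or
            (child.allele_a == cf and child.allele_b == cm)
            for cm in mother.alleles for cf in father.alleles
        )

    def test_valid_transmission(self):
        assert trio_consistency(self.mk(10, 14), self.mk(10, 12), self.mk(12, 14))

    def test_impossible_transmission(self):
        assert not trio_consistency(self.mk(11, 15), self.mk(10, 12),
                                    self.mk(12, 14))

    def test_homozygous_child_matches_brute_force(self):
        c, m, f = self.mk(12, 12), self.mk(10, 12), self.mk(12, 14)
        assert trio_consistency(c, m, f) == self.brute_force(c, m, f)

    def test_exhaustive_small_allele_space(self):
        for alleles in itertools.product(range(9, 12), repeat=6):
            c = self.mk(alleles[0], alleles[1])
            m = self.mk(alleles[2], alleles[3])
            f = self.mk(alleles[4], alleles[5])
            assert trio_consistency(c, m, f) == self.brute_force(c, m, f)

    def test_marker_mismatch_rejected(self):
        other = GenotypeCall("m2", "x", 10.0, 10.0, 0.99, -1.0, 30, True)
        with pytest.raises(ValueError):
            trio_consistency(self.mk(10, 10), self.mk(10, 10), other)


class TestIteratePopulationGenotyping:
    def test_noise_free_recovers_truth_quickly(self, rng):
        markers = simdata.make_marker_catalog(10, rng)
        freqs = simdata.default_allele_freqs(markers, rng)
        geno = cohort_genotypes(markers, 25, freqs, rng)
        cfg_sim = simdata.SimConfig(marker_slippage=0.0, base_error_rate=0.0)
        table, _ = simdata.simulate_read_table(geno, markers, cfg_sim, rng)
        res = iterate_population_genotyping(table, markers)
        assert res.converged and res.n_iter <= 2
        merged = res.calls.merge(geno, on=["marker_id", "sample_id"],
                                 suffixes=("_call", ""))
        assert (merged["allele_a_call"] == merged["allele_a"]).all()
        assert (merged["allele_b_call"] == merged["allele_b"]).all()

    def test_noisy_cohort_high_accuracy(self, rng):
        markers = simdata.make_marker_catalog(25, rng)
        freqs = simdata.default_allele_freqs(markers, rng)
        geno = cohort_genotypes(markers, 50, freqs, rng)
        cfg_sim = simdata.SimConfig(marker_slippage=0.02)
        table, _ = simdata.simulate_read_table(geno, markers, cfg_sim, rng)
        res = iterate_population_genotyping(table, markers)
        merged = res.calls.merge(geno, on=["marker_id", "sample_id"],
                                 suffixes=("_call", ""))
        hc = merged["high_confidence"]
        correct = ((merged["allele_a_call"] == merged["allele_a"])
                   & (merged["allele_b_call"] == merged["allele_b"]))
        assert correct[hc].mean() >= 0.99

    def test_single_read_single_sample(self):
        table = pd.DataFrame({
            "marker_id": ["m1"], "sample_id": ["s1"], "read_id": ["r1"],
            "reported_units": [10.0], "purity": [1.0],
            "a1": [1.0], "a2": [20.0], "a3": [20.0], "a4": [0.9],
            "a5": [1.0], "a6": [0.0], "source": ["overlap"],
            "lower_bound": [False], "fully_repetitive": [False],
        })
        from strpop.markers import MarkerDef
        m = MarkerDef.create("c", 601, 620, "AC", 10, marker_id="m1")
        res = iterate_population_genotyping(table, [m])
        assert res.converged
        (row,) = res.calls.itertuples(index=False)
        assert (row.allele_a, row.allele_b) == (10.0, 10.0)

    def test_small_cohort_keeps_default_params(self, rng):
        markers = simdata.make_marker_catalog(3, rng)
        freqs = simdata.default_allele_freqs(markers, rng)
        geno = cohort_genotypes(markers, 10, freqs, rng)
        table, _ = simdata.simulate_read_table(
            geno, markers, simdata.SimConfig(), rng)
        res = iterate_population_genotyping(table, markers)
        for p in res.marker_params.values():
            assert p.n_samples_used == 0
            assert p == MarkerParams()
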