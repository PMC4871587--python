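import numpy as np
import pytest
from scipy import stats

from oracles import bh_by_hand, ls_power_direct
from somitime import (
    CHICKEN,
    SampleStaging,
    benjamini_hochberg,
    detect_cyclic,
    lomb_scargle_power,
    ls_pvalue,
    make_expression_dataset,
)


class TestLombScarglePower:
    def test_pure_tone_base_frequency(self):
        t = np.arange(18) / 18
        y = np.cos(2 * np.pi * t)
        p1, a1 = lomb_scargle_power(y, t, 1)
        assert a1 == pytest.approx(1.0, abs=1e-9)
        assert p1 == pytest.approx((18 - 1) / 2, abs=1e-9)  # all variance explained
        assert p1 > max(lomb_scargle_power(y, t, k)[0] for k in (2, 3))

    def test_double_frequency_orthogonality(self):
        t = np.arange(18) / 18
        y = np.cos(4 * np.pi * t)
        p2, _ = lomb_scargle_power(y, t, 2)
        p1, _ = lomb_scargle_power(y, t, 1)
        assert p2 == pytest.approx((18 - 1) / 2, abs=1e-9)
        assert p1 == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_scores_zero(self):
        t = np.arange(10) / 10
        assert lomb_scargle_power(np.full(10, 2.0), t, 1) == (0.0, 0.0)

    def test_matches_direct_least_squares(self, rng):
        # uneven designs: the tau-offset classical form must agree with a
        # plain two-column least-squares computation
        for k in (1, 2):
            for _ in range(25):
                t = rng.uniform(0, 1, 12)
                y = rng.normal(size=12)
                power, _ = lomb_scargle_power(y, t, k)
                assert power == pytest.approx(ls_power_direct(y, t, k), abs=1e-8)

    def test_invariant_under_phase_rotation(self, rng):
        t = rng.uniform(0, 1, 15)
        y = rng.normal(size=15)
        base, _ = lomb_scargle_power(y, t, 1)
        rotated, _ = lomb_scargle_power(y, np.mod(t + 0.41, 1.0), 1)
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_uniform_design_parseval(self):
        # on an even grid the k=1 and k=2 harmonic powers decompose the
        # variance additively
        t = np.arange(16) / 16
        rng = np.random.default_rng(3)
        y = (
            0.7 * np.cos(2 * np.pi * t + 0.3)
            + 0.4 * np.sin(4 * np.pi * t + 1.0)
        )
        p1, _ = lomb_scargle_power(y, t, 1)
        p2, _ = lomb_scargle_power(y, t, 2)
        assert p1 + p2 == pytest.approx((16 - 1) / 2, rel=1e-9)


class TestPermutationPValue:
    def test_lower_bound_when_observed_beats_all(self):
        t = np.arange(18) / 18
        y = np.cos(2 * np.pi * t)
        p = ls_pvalue(y, t, 1, n_permutations=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 1, 12)
        pvals = [
            ls_pvalue(rng.normal(size=12), t, 1, n_permutations=999, seed=i)
            for i in range(120)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_high_snr(self):
        rng = np.random.default_rng(8)
        hits = 0
        for i in range(60):
            t = rng.uniform(0, 1, 18)
            y = np.cos(2 * np.pi * (t - rng.uniform())) + rng.normal(0, 0.2, 18)
            if ls_pvalue(y, t, 1, n_permutations=999, seed=i) <= 0.01:
                hits += 1
        assert hits >= 0.95 * 60

    def test_minimum_permutations_enforced(self):
        t = np.arange(6) / 6
        with pytest.raises(ValueError):
            ls_pvalue(np.ones(6), t, 1, n_permutations=99)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    def test_matches_hand_computation(self, rng):
        p = rng.uniform(1e-6, 1, 40)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_by_hand(p), atol=1e-12)


class TestDetectCyclic:
    def test_vacuous_gates_return_everything(self, chick_dataset):
        matrix, _, truth = chick_dataset
        staging = SampleStaging(matrix.sample_ids, truth.sample_phases)
        cfg = CHICKEN.with_thresholds(p_max=1.01, fdr_max_unimodal=1.01)
        det = detect_cyclic(matrix, staging, cfg, 1, method="analytic")
        assert det["passed"].all()
        assert len(det) == matrix.shape[0]

    def test_sensitivity_and_fdr_calibration(self):
        # zebrafish-like conditions: the wide posterior-half kernel makes the
        # bulk signal near-sinusoidal, which is where the base-frequency LS
        # gate is expected to reach full sensitivity at SNR 3
        from somitime import ZEBRAFISH

        cfg = ZEBRAFISH
        matrix, _, truth = make_expression_dataset(
            cfg,
            n_genes=120,
            n_samples=21,
            frac_cyclic=0.25,
            frac_bimodal=0.0,
            amplitude=0.3,
            noise_sd=0.1,
            seed=5,
        )
        staging = SampleStaging(matrix.sample_ids, truth.sample_phases)
        det = detect_cyclic(matrix, staging, cfg, 1, n_permutations=999, seed=0)
        det = det.set_index("probe_id")
        cyclic = truth.genes.index[
            (truth.genes["is_cyclic"]) & (truth.genes["n_peaks"] == 1)
        ]
        sens = det.loc[cyclic, "passed"].mean()
        assert sens >= 0.8
        null = truth.genes.index[~truth.genes["is_cyclic"]]
        n_fp = det.loc[null, "passed"].sum()
        n_detected = det["passed"].sum()
        # observed false-discovery proportion within 2x the nominal FDR
        assert n_fp <= max(2, 2 * cfg.thresholds.fdr_max_unimodal * n_detected)

    def test_double_frequency_gate_separates_peak_counts(self):
        cfg = CHICKEN
        matrix, _, truth = make_expression_dataset(
            cfg,
            n_genes=60,
            n_samples=18,
            frac_cyclic=0.5,
            frac_bimodal=0.5,
            amplitude=0.5,
            noise_sd=0.1,
            seed=9,
        )
        staging = SampleStaging(matrix.sample_ids, truth.sample_phases)
        det2 = detect_cyclic(matrix, staging, cfg, 2, n_permutations=999, seed=1)
        det2 = det2.set_index("probe_id")
        bimodal = truth.genes.index[truth.genes["n_peaks"] == 2]
        onepeak = truth.genes.index[
            (truth.genes["n_peaks"] == 1) & truth.genes.index.str.startswith("g")
        ]
        assert det2.loc[bimodal, "passed"].mean() >= 0.6
        assert det2.loc[bimodal, "passed"].mean() > 2 * max(
            det2.loc[onepeak, "passed"].mean(), 0.05
        )
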