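import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpglights import motif_models as mm
from cpglights.errors import ConfigurationError, DegenerateModelError, InputError
from cpglights.synthetic_data import simulate_alignment

from conftest import random_pcm


class TestPwm:
    def test_background_matching_column_scores_zero(self):
        pcm = mm.PositionCountMatrix("X", np.full((4, 2), 4.0), 16)
        pwm = mm.build_pwm(pcm)
        assert np.allclose(pwm.matrix, 0.0)

    def test_degenerate_alignment_consensus_attains_max(self, degenerate_alignment):
        pcm = mm.build_pcm(degenerate_alignment)
        pwm = mm.build_pwm(pcm, pseudocount=1e-9)
        consensus = degenerate_alignment.sequences[0]
        assert pwm.score(consensus) == pytest.approx(pwm.max_score)
        assert pwm.max_score == pytest.approx(6 * np.log(4), rel=1e-6)

    def test_hand_computed_matrix(self, toy_alignment):
        pcm = mm.build_pcm(toy_alignment)
        # column counts: j0 A=3,C=1; j1 C=3,T=1; j2 G=4
        assert pcm.counts[:, 0].tolist() == [3, 1, 0, 0]
        pwm = mm.build_pwm(pcm, pseudocount=1.0)
        # w[a,j] = ln((x + 0.25) / ((4 + 1) * 0.25))
        expected_a0 = np.log((3 + 0.25) / 1.25)
        expected_g0 = np.log(0.25 / 1.25)
        assert pwm.matrix[mm.A, 0] == pytest.approx(expected_a0)
        assert pwm.matrix[mm.G, 0] == pytest.approx(expected_g0)
        assert pwm.score("ACG") == pytest.approx(
            np.log(3.25 / 1.25) + np.log(3.25 / 1.25) + np.log(4.25 / 1.25)
        )

    def test_non_acgt_word_raises(self, toy_alignment):
        pwm = mm.build_pwm(mm.build_pcm(toy_alignment))
        with pytest.raises(InputError):
            pwm.score("ANG")


class TestFilterAlignment:
    def test_identity_when_all_pass(self, degenerate_alignment):
        pwm = mm.build_pwm(mm.build_pcm(degenerate_alignment))
        out = mm.filter_alignment(degenerate_alignment, pwm, threshold=-np.inf)
        assert out.sequences == degenerate_alignment.sequences

    def test_discard_below_min_15(self):
        seqs = tuple(["ACGT"] * 14 + ["TTTT"] * 2)
        alignment = mm.MotifAlignment("X", seqs)
        pwm = mm.build_pwm(mm.build_pcm(alignment))
        thr = pwm.score("ACGT") - 1e-9  # the 2 divergent sequences fall below
        assert mm.filter_alignment(alignment, pwm, thr) is None
        thr_low = pwm.score("TTTT") - 1e-9
        kept = mm.filter_alignment(alignment, pwm, thr_low)
        assert kept.n == 16


class TestRdm:
    def test_degenerate_alignment_uniform_pair_weights(self):
        L = 5
        alignment = mm.MotifAlignment("X", tuple(["ACGTA"] * 8))
        rdm = mm.build_rdm(alignment)
        n_pairs = L * (L - 1) // 2
        observed = rdm.weights.max(axis=0)
        assert np.allclose(observed, 1.0 / n_pairs)  # 2 / (L (L-1))
        assert mm.score_word_rdm("ACGTA", rdm) == pytest.approx(1.0)

    def test_absent_word_scores_zero(self):
        alignment = mm.MotifAlignment("X", tuple(["AAAA"] * 8))
        rdm = mm.build_rdm(alignment)
        assert mm.score_word_rdm("CCCC", rdm) == 0.0

    def test_hand_computed_tensor(self, toy_alignment):
        rdm = mm.build_rdm(toy_alignment)
        # pair (0,1): AC x3? sequences AC,AC,AT,CC -> f(AC)=0.5, f(AT)=0.25, f(CC)=0.25
        # pair (0,2): AG 0.75, CG 0.25 ; pair (1,2): CG 0.75, TG 0.25
        denom = 0.5 + 0.75 + 0.75
        k01 = rdm.pairs.index((0, 1))
        assert rdm.frequencies[4 * 0 + 1, k01] == pytest.approx(0.5)  # AC
        assert rdm.weights[4 * 0 + 1, k01] == pytest.approx(0.5 / denom)
        assert mm.score_word_rdm("ACG", rdm) == pytest.approx((0.5 + 0.75 + 0.75) / denom)
        assert mm.score_word_rdm("ATG", rdm) == pytest.approx((0.25 + 0.75 + 0.25) / denom)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 9), st.integers(2, 30))
    def test_normalization_identity(self, seed, length, n_seqs):
        rng = np.random.default_rng(seed)
        pcm = random_pcm(rng, length)
        alignment = simulate_alignment(pcm, n_seqs, rng)
        rdm = mm.build_rdm(alignment)
        assert rdm.weights.max(axis=0).sum() == pytest.approx(1.0, abs=1e-12)


def _enumeration_tail(pwm: mm.PWM, threshold: float, resolution: float = mm.SCORE_RESOLUTION):
    """Brute-force oracle: tail of the grid-rounded score over all 4**L words."""
    iw = np.rint(pwm.matrix / resolution).astype(np.int64)
    tail = 0.0
    thr_grid = int(round(threshold / resolution))
    for word in itertools.product(range(4), repeat=pwm.length):
        score = sum(iw[a, j] for j, a in enumerate(word))
        if score >= thr_grid:
            tail += np.prod([pwm.background[a] for a in word])
    return tail


class TestCalibration:
    def test_dp_tail_matches_enumeration(self):
        rng = np.random.default_rng(42)
        pcm = random_pcm(rng, 6)
        pwm = mm.build_pwm(pcm)
        thr, achieved = mm.calibrate_pwm_threshold(pwm)
        assert achieved == pytest.approx(_enumeration_tail(pwm, thr), abs=1e-12)
        assert 10_000 * achieved <= 5.0  # 5 of 10,000 random words

    def test_threshold_monotone_in_target_p(self):
        rng = np.random.default_rng(1)
        pcm = random_pcm(rng, 8)
        pwm = mm.build_pwm(pcm)
        thresholds = [
            mm.calibrate_pwm_threshold(pwm, p)[0] for p in (0.00005, 0.0005, 0.005, 0.05)
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_degenerate_model_raises(self):
        pwm = mm.PWM("flat", np.zeros((4, 4)))
        with pytest.raises(DegenerateModelError):
            mm.calibrate_pwm_threshold(pwm)

    def test_rdm_enumeration_calibration(self):
        rng = np.random.default_rng(5)
        pcm = random_pcm(rng, 6)
        alignment = simulate_alignment(pcm, 30, rng)
        rdm = mm.build_rdm(alignment)
        thr, achieved, stderr = mm.calibrate_rdm_threshold(rdm)
        assert stderr == 0.0  # exact path
        scores, probs = mm.enumerate_rdm_scores(rdm)
        assert probs[scores >= thr].sum() == pytest.approx(achieved, abs=1e-12)
        assert achieved <= mm.DEFAULT_TARGET_P

    def test_rdm_monte_carlo_path(self):
        rng = np.random.default_rng(6)
        pcm = random_pcm(rng, 6)
        alignment = simulate_alignment(pcm, 30, rng)
        rdm = mm.build_rdm(alignment)
        thr_mc, achieved_mc, stderr = mm.calibrate_rdm_threshold(
            rdm, rng=np.random.default_rng(0), max_enumeration_length=4, n_monte_carlo=200_000
        )
        assert stderr > 0
        assert achieved_mc <= mm.DEFAULT_TARGET_P
        # the exact tail at the Monte-Carlo threshold sits near the target
        scores, probs = mm.enumerate_rdm_scores(rdm)
        exact_tail = probs[scores >= thr_mc].sum()
        assert 0.3 * mm.DEFAULT_TARGET_P <= exact_tail <= 2 * mm.DEFAULT_TARGET_P


class TestDic:
    def test_single_nucleotide_column_is_zero(self):
        assert mm.dic([12, 0, 0, 0]) == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        # (2 ln2! + 2 ln4! - ln12!) / 12
        assert mm.dic([2, 2, 4, 4]) == pytest.approx(-1.0204, abs=5e-5)

    def test_thresholds_at_n12(self):
        th_high, th_low = mm.dic_thresholds(12)
        assert th_high == pytest.approx(-0.8711, abs=5e-5)  # (3 ln4! - ln12!)/12
        assert th_low == pytest.approx(-1.0204, abs=5e-5)

    def test_uniform_column_minimizes_dic_exhaustively(self):
        values = {}
        n = 12
        for comp in itertools.product(range(n + 1), repeat=3):
            rest = n - sum(comp)
            if rest < 0:
                continue
            counts = (*comp, rest)
            values[counts] = mm.dic(counts)
        uniform = values[(3, 3, 3, 3)]
        assert uniform == min(values.values())
        assert all(v <= 1e-12 for v in values.values())  # dic <= 0 everywhere

    def test_threshold_order_over_n_sweep(self):
        for n in range(15, 1001):
            th_high, th_low = mm.dic_thresholds(n)
            assert th_high > th_low

    def test_negative_counts_raise(self):
        with pytest.raises(InputError):
            mm.dic([-1, 5, 0, 0])


class TestCpgPositions:
    def test_degenerate_pair_is_core(self):
        counts = np.zeros((4, 2))
        counts[mm.C, 0] = 15
        counts[mm.G, 1] = 15
        pcm = mm.PositionCountMatrix("X", counts, 15)
        pairs = mm.find_cpg_positions(pcm)
        assert len(pairs) == 1
        assert pairs[0].category == "core"
        assert pairs[0].dic_c == pytest.approx(0.0)

    def test_tie_permissive_major(self):
        counts = np.array(
            [
                [5.0, 0.0],
                [5.0, 0.0],
                [4.0, 15.0],
                [1.0, 0.0],
            ]
        )
        pcm = mm.PositionCountMatrix("X", counts, 15)
        pairs = mm.find_cpg_positions(pcm)
        assert len(pairs) == 1  # C ties with A at the maximum and still counts

    def test_mixed_category(self):
        th_high, th_low = mm.dic_thresholds(400)
        core_col = np.array([400 * 0.1 / 3] * 4)
        core_col[mm.C] = 360.0
        core_col[[0, 2, 3]] = (400 - 360) / 3
        medium_col = np.array([0.15, 0.25, 0.45, 0.15]) * 400
        counts = np.column_stack([core_col, medium_col])
        pcm = mm.PositionCountMatrix("X", counts, 400)
        pairs = mm.find_cpg_positions(pcm)
        assert len(pairs) == 1
        assert pairs[0].category == "mixed"  # DIC_C > Th but DIC_G in (th, Th)


def test_model_archive_roundtrip_files(tmp_path, degenerate_alignment):
    alignment_file = tmp_path / "deg.txt"
    alignment_file.write_text(">DEG\n" + "\n".join(degenerate_alignment.sequences) + "\n")
    read_back = mm.read_alignment(alignment_file)
    assert read_back.sequences == degenerate_alignment.sequences

    pcm = mm.build_pcm(degenerate_alignment)
    pcm_file = tmp_path / "deg.pcm"
    rows = "\n".join("\t".join(str(v) for v in pcm.counts[:, j]) for j in range(pcm.length))
    pcm_file.write_text(">DEG\n" + rows + "\n")
    pcm2 = mm.read_pcm(pcm_file)
    assert np.allclose(pcm2.counts, pcm.counts)
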