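"""Series moments, constrained DTW, glottal-cycle voice quality, MFCC stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurovibe import feature_extraction as fx
from neurovibe.config import PipelineConfig
from neurovibe.pipeline_io import VoiceRecording
from neurovibe.synthetic_data import VoiceGenSpec, gen_voice


class TestSeriesStats:
    @pytest.mark.parametrize("series,mean,var,skew", [
        ([5.0, 5.0, 5.0], 5.0, 0.0, 0.0),
        ([1, 2, 3, 4], 2.5, 1.25, 0.0),
        ([1, 1, 1, 5], 2.0, 3.0, 6.0 / 3 ** 1.5),
    ])
    def test_population_moments(self, series, mean, var, skew):
        s = fx.series_stats(series)
        assert s.mean == pytest.approx(mean)
        assert s.variance == pytest.approx(var)
        assert s.skewness == pytest.approx(skew)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            fx.series_stats([])


def brute_force_idtw(a, b, alpha, p):
    """Independent oracle: exhaustive enumeration of all monotone paths."""
    n, m = len(a), len(b)
    best = math.inf

    def walk(i, j, cost):
        nonlocal best
        cost += abs(a[i] - b[j])
        if cost >= best:
            return
        if (i, j) == (n - 1, m - 1):
            best = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost + alpha * p)
        if j + 1 < m:
            walk(i, j + 1, cost + alpha * p)

    walk(0, 0, 0.0)
    return best


class TestIdtw:
    def test_identical_sequences_zero_distance_diagonal_path(self):
        r = fx.idtw([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0, 1.0, 0.0)
        assert r.distance == 0.0
        assert r.path == [(0, 0), (1, 1), (2, 2)]

    def test_hand_dp_on_2x3_grid(self):
        r = fx.idtw([0, 1], [0, 1, 1], 1.0, 1.0, 0.0)
        assert r.distance == 0.0
        assert r.path == [(0, 0), (1, 1), (1, 2)]

    def test_matches_brute_force_enumeration(self):
        seqs = [list(s) for L in (1, 2, 3, 4)
                for s in itertools.product((0, 1, 2), repeat=L)]
        rng = np.random.default_rng(0)
        pairs = [(seqs[i], seqs[j])
                 for i, j in rng.integers(0, len(seqs), size=(120, 2))]
        for a, b in pairs:
            for alpha in (0.0, 0.5, 1.0):
                for p in (0.0, 0.5, 1.0):
                    got = fx.idtw(a, b, 1.0, alpha, p).distance
                    want = brute_force_idtw(a, b, alpha, p)
                    assert got == pytest.approx(want), (a, b, alpha, p)

    def test_local_cost_linearity_in_weights(self):
        a, b = [0.0, 2.0, 1.0], [1.0, 0.0, 2.0, 2.0]
        d1 = fx.idtw(a, b, 1.0, 1.0, 0.0).distance
        d2 = fx.idtw(a, b, 2.0, 1.0, 0.0).distance
        assert d2 == pytest.approx(2 * d1)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6),
           st.lists(st.floats(-5, 5), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=60)
    def test_symmetric_and_nonnegative(self, a, b):
        d_ab = fx.idtw(a, b, 1.0, 1.0, 0.3).distance
        d_ba = fx.idtw(b, a, 1.0, 1.0, 0.3).distance
        assert d_ab >= 0
        assert d_ab == pytest.approx(d_ba)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fx.idtw([1], [1], 1.0, -1.0, 0.0)

    def test_path_steps_are_monotone(self):
        r = fx.idtw([0, 3, 1, 2], [2, 0, 1], 1.0, 1.0, 0.5)
        assert r.path[0] == (0, 0) and r.path[-1] == (3, 2)
        steps = {(i2 - i1, j2 - j1)
                 for (i1, j1), (i2, j2) in zip(r.path, r.path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}


class TestIdtwFeatures:
    def test_self_template_distance_zero(self):
        s = [1.0, 2.0, 3.0]
        out = fx.idtw_reference_features(s, {"class0": s, "class1": [9.0]})
        assert out["idtw_class0"] == 0.0
        assert len(out) == 2

    def test_medoid_of_duplicates(self):
        s = [0.0, 1.0, 0.0]
        s2 = [5.0, 5.0, 5.0]
        assert fx.idtw_medoid([s, s, s2]) == 0

    def test_empty_template_raises(self):
        with pytest.raises(ValueError):
            fx.idtw_reference_features([1.0], {"class0": []})


class TestGlottalCycles:
    def test_ideal_pulse_train_periods(self, pulse_train):
        cycles = fx.estimate_glottal_cycles(pulse_train.samples, 16000)
        assert np.allclose(cycles.periods, 0.01, atol=1e-4)

    def test_silence_is_unvoiced(self):
        with pytest.raises(fx.UnvoicedSignalError):
            fx.estimate_glottal_cycles(np.zeros(16000), 16000)

    def test_white_noise_is_unvoiced(self):
        x = np.random.default_rng(0).normal(size=16000)
        with pytest.raises(fx.UnvoicedSignalError):
            fx.estimate_glottal_cycles(x, 16000)

    def test_alternating_periods_recovered(self):
        x = np.zeros(16000)
        pos, flip = 0, False
        marks = []
        while pos < 16000:
            x[pos] = 1.0
            marks.append(pos)
            pos += 176 if flip else 160
            flip = not flip
        cycles = fx.estimate_glottal_cycles(x, 16000)
        assert np.mean(cycles.periods) == pytest.approx(0.0105, abs=1e-4)
        recovered = np.round(cycles.periods * 16000).astype(int)
        assert set(np.unique(recovered)) <= {159, 160, 161, 175, 176, 177}


class TestVoiceQuality:
    def test_constant_periods_pitch_and_zero_jitter(self):
        c = fx.GlottalCycles(np.full(10, 0.01), np.ones(10), np.arange(11.0))
        assert fx.pitch(c) == pytest.approx(100.0)
        assert fx.jitter(c) == 0.0

    def test_hand_computed_jitter_and_shimmer(self):
        c = fx.GlottalCycles(np.array([0.010, 0.011]), np.array([1.0, 0.8]),
                             np.zeros(3))
        assert fx.jitter(c) == pytest.approx(0.1)
        assert fx.shimmer(c) == pytest.approx(0.2)

    def test_hnr_power_ratio_landmarks(self):
        assert fx.hnr_from_powers(10.0, 1.0) == pytest.approx(10.0)
        assert fx.hnr_from_powers(1.0, 1.0) == pytest.approx(0.0)
        assert fx.hnr_from_powers(1.0, 0.0) == 60.0

    def test_jitter_requires_two_cycles(self):
        c = fx.GlottalCycles(np.array([0.01]), np.array([1.0]), np.zeros(2))
        with pytest.raises(ValueError):
            fx.jitter(c)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        T = 0.01 + 0.0005 * rng.normal(size=20)
        A = 1.0 + 0.05 * rng.normal(size=20)
        c1 = fx.GlottalCycles(T, A, np.zeros(21))
        c2 = fx.GlottalCycles(2.0 * T, 3.0 * A, np.zeros(21))
        assert fx.shimmer(c2) == pytest.approx(fx.shimmer(c1))
        assert fx.jitter(c2) == pytest.approx(fx.jitter(c1))


class TestParameterRecovery:
    """Analysis chain recovers what the generator injected."""

    @pytest.mark.parametrize("target", [0.005, 0.01, 0.02, 0.04])
    def test_jitter_recovery(self, target):
        measured = []
        for seed in range(3):
            rec = gen_voice(VoiceGenSpec(f0=150, jitter_target=target,
                                         shimmer_target=0.0, hnr_target=60,
                                         seed=seed))
            cycles = fx.estimate_glottal_cycles(rec.samples, rec.rate)
            measured.append(fx.jitter(cycles))
        assert abs(np.mean(measured) - target) < 0.005

    @pytest.mark.parametrize("target", [0.02, 0.05, 0.10])
    def test_shimmer_recovery(self, target):
        measured = []
        for seed in range(3):
            rec = gen_voice(VoiceGenSpec(f0=150, jitter_target=0.0,
                                         shimmer_target=target,
                                         hnr_target=60, seed=seed))
            cycles = fx.estimate_glottal_cycles(rec.samples, rec.rate)
            measured.append(fx.shimmer(cycles))
        assert abs(np.mean(measured) - target) < 0.02

    def test_hnr_monotone_in_injected_noise(self):
        measured = [np.mean([fx.hnr(gen_voice(VoiceGenSpec(
            f0=150, jitter_target=0.0, shimmer_target=0.0,
            hnr_target=h, seed=s)).samples, 16000) for s in range(2)])
            for h in (30, 20, 10, 5)]
        assert all(a > b for a, b in zip(measured, measured[1:]))

    def test_clean_voice_near_zero_perturbations(self):
        rec = gen_voice(VoiceGenSpec(f0=150, jitter_target=0.0,
                                     shimmer_target=0.0, hnr_target=60,
                                     seed=0))
        cycles = fx.estimate_glottal_cycles(rec.samples, rec.rate)
        assert fx.jitter(cycles) < 0.005
        assert fx.shimmer(cycles) < 0.01


class TestMfccStats:
    def test_constant_row_degenerate_convention(self):
        out = fx.mfcc_stats(np.full((1, 5), 3.0))
        row = out.iloc[0]
        assert (row["mean"], row["var"], row["skew"], row["kurt"]) == \
            (3.0, 0.0, 0.0, 0.0)

    def test_hand_computed_moments(self):
        out = fx.mfcc_stats(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert out.iloc[0]["mean"] == pytest.approx(2.5)
        assert out.iloc[0]["var"] == pytest.approx(1.25)
        assert out.iloc[0]["skew"] == pytest.approx(0.0)

    def test_hand_computed_kurtosis(self):
        out = fx.mfcc_stats(np.array([[0.0, 0.0, 0.0, 4.0]]))
        assert out.iloc[0]["kurt"] == pytest.approx((84.0 / 4) / 9 - 3)
        assert out.iloc[0]["kurt"] == pytest.approx(-0.6667, abs=1e-4)

    def test_literal_moment_variant_differs(self):
        M = np.array([[1.0, 2.0, 3.0, 10.0]])
        standard = fx.mfcc_stats(M, literal_moments=False)
        literal = fx.mfcc_stats(M, literal_moments=True)
        assert standard.iloc[0]["skew"] != pytest.approx(
            literal.iloc[0]["skew"])


class TestAssembly:
    def test_voice_vector_length(self):
        cfg = PipelineConfig()
        rec = gen_voice(VoiceGenSpec(seed=0))
        vec = fx.extract_voice_vector(rec, cfg)
        assert len(vec) == 4 + 4 * cfg.mfcc_n_coeffs
        assert list(vec.index[:4]) == ["pitch", "jitter", "shimmer", "hnr"]

    def test_feature_names_stable_across_runs(self):
        cfg = PipelineConfig()
        rec = gen_voice(VoiceGenSpec(seed=1))
        v1 = fx.extract_voice_vector(rec, cfg)
        v2 = fx.extract_voice_vector(rec, cfg)
        assert list(v1.index) == list(v2.index)
        assert np.allclose(v1.to_numpy(), v2.to_numpy())

    def test_unvoiced_imputed_with_training_medians(self):
        df = pd.DataFrame({
            "pitch": [100.0, 120.0, np.nan],
            "jitter": [0.01, 0.03, np.nan]})
        filled, medians = fx.impute_unvoiced(df)
        assert filled.loc[2, "pitch"] == pytest.approx(110.0)
        assert medians["jitter"] == pytest.approx(0.02)

    def test_assemble_vectors_blocks_and_median_fill(self):
        beh = [pd.Series({"beh_mean": 1.0}), pd.Series({"beh_mean": 2.0})]
        voi = [pd.Series({"pitch": 100.0, "jitter": 0.01}),
               pd.Series({"pitch": np.nan, "jitter": 0.03})]
        vb, vv, med = fx.assemble_vectors(beh, voi)
        assert list(vb.columns) == ["beh_mean"]
        assert list(vv.columns) == ["pitch", "jitter"]
        assert vv.loc[1, "pitch"] == pytest.approx(100.0)
        assert med["pitch"] == pytest.approx(100.0)
        with pytest.raises(ValueError, match="row counts"):
            fx.assemble_vectors(beh, voi[:1])

    def test_behavior_vector_names(self):
        vec = fx.extract_behavior_vector(
            [1.0, 2.0, 3.0], {"class0": [1.0, 2.0], "class1": [9.0, 9.0]})
        assert list(vec.index) == ["beh_mean", "beh_var", "beh_skew",
                                   "idtw_class0", "idtw_class1"]
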