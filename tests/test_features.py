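"""Feature formulas against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomech.core_io import IMU_CHANNELS, PipelineConfig, Recording
from cardiomech.features import (CHUNK_LEVEL_FEATURES, FREQ_FEATURES,
                                 GCG_FEATURES, SUBJECT_LEVEL_FEATURES,
                                 TIME_HRV_FEATURES, assemble_matrix,
                                 descriptive_stats, freq_hrv_features,
                                 gcg_interval_features, interval_block,
                                 nn_series, nn_entropies, time_hrv_features)

nn_lists = st.lists(st.floats(min_value=400.0, max_value=1400.0),
                    min_size=4, max_size=40)


# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)

def oracle_poincare(nn):
    pairs = [(nn[i], nn[i + 1]) for i in range(len(nn) - 1)]
    thetas = [math.degrees(math.atan2(y, x)) for x, y in pairs]
    vai = sum(abs(t - 45.0) for t in thetas) / len(pairs)
    ls = [math.hypot(x, y) for x, y in pairs]
    L = sum(ls) / len(ls)
    vli = math.sqrt(sum((l - L) ** 2 for l in ls) / len(ls))
    return vai, vli


def oracle_stats(vals):
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    return {"mean": mean, "median": float(np.median(vals)),
            "std": math.sqrt(m2),
            "sk": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
            "ku": m4 / m2 ** 2 if m2 > 0 else 0.0,
            "min": min(vals), "max": max(vals)}


class TestNNSeries:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["chunk", "beat", "axis", "t_J",
                                           "valid"]).assign(
            t_A=0.0, t_I=0.0, t_K=0.0, t_L=0.0, t_P=0.0, MA=0.0)

    def test_consecutive_j_times(self):
        tbl = self._table([("c", i, "gcg_y", t, True)
                           for i, t in enumerate([1.0, 1.8, 2.6])])
        np.testing.assert_allclose(nn_series(tbl), [800.0, 800.0])

    def test_bridge_over_invalid_beat_dropped(self):
        tbl = self._table([("c", 0, "gcg_y", 1.0, True),
                           ("c", 1, "gcg_y", 1.8, True),
                           ("c", 2, "gcg_y", np.nan, False),
                           ("c", 3, "gcg_y", 3.5, True)])
        np.testing.assert_allclose(nn_series(tbl), [800.0])

    def test_zero_noise_nn_matches_ground_truth(self, clean_processed,
                                                clean_recording):
        rec, gt = clean_recording
        tbl = pd.concat(clean_processed["fiducial_tables"], ignore_index=True)
        nn = nn_series(tbl)
        true = gt.nn_series_true
        # every recovered interval appears in the true series within 1 sample
        tol = 1000.0 / rec.fs + 1e-9
        for v in nn:
            assert np.min(np.abs(true - v)) <= tol


class TestTimeHrv:
    def test_constant_series_collapses_dispersion(self):
        f = time_hrv_features(np.full(10, 800.0))
        assert f["AVNN_time"] == 800.0 and f["NN_med_time"] == 800.0
        for k in ("SDNN_time", "RMSSD_time", "pNN50_time", "VAI_time",
                  "VLI_time", "SD1_time", "ENN_time", "SENN_time",
                  "CENN_time"):
            assert f[k] == pytest.approx(0.0, abs=1e-12), k

    def test_hand_enumerated_oracle(self):
        nn = np.array([800.0, 860.0, 812.0, 900.0])
        f = time_hrv_features(nn)
        # diffs = [60, -48, 88]: two exceed 50 ms; denominator = total NNs
        assert f["pNN50_time"] == pytest.approx(2 / 4)
        assert f["RMSSD_time"] == pytest.approx(
            math.sqrt((60 ** 2 + 48 ** 2 + 88 ** 2) / 3))
        assert f["AVNN_time"] == pytest.approx(843.0)
        vai, vli = oracle_poincare(nn)
        assert f["VAI_time"] == pytest.approx(vai, abs=1e-12)
        assert f["VLI_time"] == pytest.approx(vli, abs=1e-12)

    def test_pnn50_denominator_switch(self):
        nn = np.array([800.0, 860.0, 812.0, 900.0])
        alt = PipelineConfig(pnn50_denominator="n_diffs")
        assert time_hrv_features(nn, alt)["pNN50_time"] == pytest.approx(2 / 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(nn_lists)
    def test_sd2_as_printed_equals_sd1(self, nn):
        """Subtracting a constant inside a std is a no-op: the printed
        long-axis formula collapses onto the short-axis one."""
        f = time_hrv_features(np.array(nn))
        assert f["SD2_time"] == pytest.approx(f["SD1_time"], abs=1e-9)
        if f["SD2_time"] > 0:
            assert f["SD1/SD2_time"] == pytest.approx(1.0)

    def test_sd2_conventional_matches_rotated_axis(self):
        rng = np.random.default_rng(0)
        nn = 800 + 50 * rng.standard_normal(200)
        cfg = PipelineConfig(sd2_convention="conventional")
        f = time_hrv_features(nn, cfg)
        x, y = nn[:-1], nn[1:]
        expected = np.sqrt(np.mean(((x + y) / np.sqrt(2)
                                    - np.mean((x + y) / np.sqrt(2))) ** 2))
        assert f["SD2_time"] == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(nn_lists)
    def test_entropy_decomposition_identity(self, nn):
        """H(NN_{i+1}) = I(NN_{i+1};NN_i) + H(NN_{i+1}|NN_i) under the
        shared joint binning."""
        enn, senn, cenn = nn_entropies(np.array(nn), 1000.0 / 128.0)
        assert enn == pytest.approx(senn + cenn, abs=1e-9)
        assert senn >= -1e-12 and cenn >= -1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(nn_lists)
    def test_poincare_indices_match_independent_loop(self, nn):
        f = time_hrv_features(np.array(nn))
        vai, vli = oracle_poincare(nn)
        assert f["VAI_time"] == pytest.approx(vai, abs=1e-12)
        assert f["VLI_time"] == pytest.approx(vli, abs=1e-12)

    def test_sdnn_and_moments_match_oracle(self):
        rng = np.random.default_rng(5)
        nn = 800 + 50 * rng.standard_normal(300)
        f = time_hrv_features(nn)
        o = oracle_stats(list(nn))
        assert f["SDNN_time"] == pytest.approx(o["std"], abs=1e-9)
        assert f["NN_sk_time"] == pytest.approx(o["sk"], abs=1e-9)
        assert f["NN_ku_time"] == pytest.approx(o["ku"], abs=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            time_hrv_features(np.array([800.0, 810.0]))


class TestGcgBlock:
    def test_width_is_88(self):
        assert len(GCG_FEATURES) == 88

    def test_five_rows_match_bruteforce(self):
        vals = [62.0, 71.0, 58.5, 90.0, 66.0]
        block = pd.DataFrame({p: vals for p in
                              ("IVCT", "LVET", "IVRT", "LI", "LJ", "KI",
                               "PI", "PJ", "KP", "LP", "MA")})
        feats = gcg_interval_features(block)
        o = oracle_stats(vals)
        for stat, key in (("mean", "IVCT_mean_GCG"), ("std", "LVET_std_GCG"),
                          ("sk", "IVRT_sk_GCG"), ("ku", "MA_ku_GCG"),
                          ("median", "PI_median_GCG"), ("min", "KP_min_GCG"),
                          ("max", "LP_max_GCG")):
            assert feats[key] == pytest.approx(o[stat], abs=1e-9), key

    def test_constant_values_degenerate_cleanly(self):
        block = pd.DataFrame({p: [5.0, 5.0, 5.0] for p in
                              ("IVCT", "LVET", "IVRT", "LI", "LJ", "KI",
                               "PI", "PJ", "KP", "LP", "MA")})
        feats = gcg_interval_features(block)
        assert feats["IVCT_std_GCG"] == 0.0
        assert feats["IVCT_sk_GCG"] == 0.0
        assert feats["IVCT_entropy_GCG"] == 0.0
        assert feats["IVCT_min_GCG"] == feats["IVCT_max_GCG"] == 5.0

    def test_too_few_rows_rejected(self):
        block = pd.DataFrame({p: [1.0, 2.0] for p in ("IVCT",)})
        with pytest.raises(ValueError):
            gcg_interval_features(block)


class TestFreqHrv:
    @staticmethod
    def _recording_from(signal, fs=256.0):
        sig = np.column_stack([signal] * 6)
        return Recording(sig, IMU_CHANNELS, fs, subject_id="f")

    def test_tone_in_lf_band_carries_half_unit_power(self):
        fs = 64.0
        t = np.arange(int(600 * fs)) / fs
        rec = self._recording_from(np.sin(2 * np.pi * 0.1 * t), fs)
        f = freq_hrv_features(rec, mask=None)
        lf = f["lf_HRV_GCG_X_freq"]
        hf = f["hf_HRV_GCG_X_freq"]
        assert lf == pytest.approx(0.5, rel=0.10)
        assert hf < 0.01 * lf
        assert f["lfhfRatio_GCG_X_freq"] > 50

    def test_white_noise_total_power_parseval(self):
        fs = 64.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(600 * fs))
        rec = self._recording_from(x, fs)
        f = freq_hrv_features(rec, mask=None)
        assert f["TotalPow_SCG_Z_freq"] == pytest.approx(np.var(x), rel=0.10)

    def test_feature_count_is_30(self):
        fs = 64.0
        rng = np.random.default_rng(3)
        rec = self._recording_from(rng.standard_normal(int(250 * fs)), fs)
        with pytest.warns(UserWarning):
            f = freq_hrv_features(rec, mask=None)
        assert len(f) == 30
        assert set(f) == set(FREQ_FEATURES)
        assert all(np.isfinite(v) for v in f.values())

    def test_short_runs_flag_axis_missing(self):
        fs = 64.0
        rng = np.random.default_rng(4)
        rec = self._recording_from(rng.standard_normal(int(40 * fs)), fs)
        from cardiomech.preprocess import ArtifactMask
        mask = ArtifactMask(np.ones(rec.n_samples, bool), 500.0, 1.0)
        with pytest.warns(UserWarning):
            f = freq_hrv_features(rec, mask)
        assert all(np.isnan(v) for v in f.values())


class TestAssembly:
    def test_block_widths(self):
        assert len(TIME_HRV_FEATURES) == 15
        assert len(FREQ_FEATURES) == 30
        assert len(GCG_FEATURES) == 88
        assert len(CHUNK_LEVEL_FEATURES) == 103

    def test_subject_level_is_union_of_blocks(self):
        s = set(SUBJECT_LEVEL_FEATURES)
        assert s == set(GCG_FEATURES) | set(TIME_HRV_FEATURES) | set(FREQ_FEATURES)
        assert len(SUBJECT_LEVEL_FEATURES) == len(s)  # no duplicates

    def test_assemble_and_policy(self):
        ok = {n: 1.0 for n in CHUNK_LEVEL_FEATURES}
        bad = dict(ok, SDNN_time=np.nan)
        m = assemble_matrix([("a", "healthy", ok), ("b", "severe", bad)],
                            "chunk", policy="drop")
        assert m.sample_ids == ("a",)
        with pytest.raises(ValueError):
            assemble_matrix([("a", "healthy", ok), ("b", "severe", bad)],
                            "chunk", policy="raise")

    def test_cohort_sample_counts(self, e2e_matrices):
        chunk, subject = e2e_matrices["chunk"], e2e_matrices["subject"]
        assert subject.n_features == 133
        assert chunk.n_features == 103
        assert 10 <= subject.n_samples <= 20
        # ~29 candidate chunks per 300 s recording at N=10, minus artifacts
        assert chunk.n_samples >= 20 * 15
        assert set(subject.labels) == {"healthy", "severe"}
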