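"""Binning, smoothing, fold-change normalization, QC and chunk averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predscan import synthetic_data as synth
from predscan.responses import (
    N_BINS,
    balanced_chunk_sizes,
    bin_and_smooth,
    chunk_average,
    moving_average_truncated,
    normalize_foldchange,
    qc_trials,
)


class TestBinAndSmooth:
    def test_single_spike_spreads_100hz_over_smoothing_window(self):
        trials = pd.DataFrame(dict(trial_id=[0], onset_s=[0.0]))
        spikes = pd.DataFrame(dict(unit_id=[1], spike_time_s=[0.125]))  # bin 12
        rates, unit_ids = bin_and_smooth(spikes, trials)
        assert unit_ids.tolist() == [1]
        # 1 spike / 10 ms = 100 Hz, spread over the 3-bin moving average
        assert rates[0, 0, 11:14] == pytest.approx([100 / 3] * 3)
        assert rates[0, 0].sum() * 0.01 == pytest.approx(1.0)  # count conserved

    def test_spike_count_conserved_across_binning(self, rng):
        trials = pd.DataFrame(dict(trial_id=np.arange(4), onset_s=np.arange(4) * 0.25))
        times = rng.uniform(0, 1.0, 200)
        spikes = pd.DataFrame(dict(unit_id=0, spike_time_s=times))
        rates, _ = bin_and_smooth(spikes, trials)
        n_in_trials = np.sum((times % 0.25) < 0.25)  # back-to-back: all fall in a trial
        assert rates.sum() * 0.01 == pytest.approx(n_in_trials)

    def test_moving_average_leaves_constant_unchanged(self):
        x = np.full((2, 3, N_BINS), 7.5)
        assert np.allclose(moving_average_truncated(x), x)

    def test_onset_outside_recording_rejected(self):
        trials = pd.DataFrame(dict(trial_id=[0], onset_s=[100.0]))
        spikes = pd.DataFrame(dict(unit_id=[0], spike_time_s=[0.1]))
        with pytest.raises(ValueError, match="outside"):
            bin_and_smooth(spikes, trials, recording_end_s=10.0)


class TestRateTensorIO:
    def test_h5_round_trip(self, tmp_path, rng):
        from predscan.responses import TIME_MS, RateTensor

        obs = pd.DataFrame(dict(stimulus_id=[0, 0, 1, 1], chunk=[0, 1, 0, 1]))
        rt = RateTensor(rng.normal(size=(3, 4, len(TIME_MS))), TIME_MS, obs,
                        np.array([10, 11, 12]))
        rt.save_h5(tmp_path / "rates.h5")
        back = RateTensor.load_h5(tmp_path / "rates.h5")
        assert np.array_equal(back.values, rt.values)
        assert np.array_equal(back.unit_ids, rt.unit_ids)
        pd.testing.assert_frame_equal(
            back.obs_index[["stimulus_id", "chunk"]].astype(int),
            obs,
        )


class TestFoldChange:
    def test_rate_equal_to_baseline_gives_zero(self):
        rates = np.full((1, 2, N_BINS), 12.0)
        assert np.allclose(normalize_foldchange(rates), 0.0)

    def test_hand_computed_values(self):
        rates = np.full((1, 1, N_BINS), 10.0)
        rates[..., :2] = 5.0  # baseline 5 Hz
        out = normalize_foldchange(rates)
        assert out[0, 0, 10] == pytest.approx((10 - 5) / 5.5)  # 0.9091
        zero_base = np.full((1, 1, N_BINS), 1.0)
        zero_base[..., :2] = 0.0
        assert normalize_foldchange(zero_base)[0, 0, 10] == pytest.approx(2.0)


class TestTrialQC:
    @staticmethod
    def _session(blink_rate, seed=3):
        return synth.gen_session(10, n_reps=20, blink_rate=blink_rate, seed=seed)

    def test_identical_traces_all_kept(self):
        trials = pd.DataFrame(dict(trial_id=range(5), onset_s=np.arange(5) * 0.25))
        t = np.arange(0, 1.5, 1 / 30)
        eye = pd.DataFrame(dict(time_s=t, x_deg=1.0, y_deg=-2.0, blink=False))
        assert qc_trials(trials, eye).all()

    def test_injected_contamination_is_flagged(self):
        sess = self._session(0.1)
        keep = qc_trials(sess.trials, sess.eye)
        injected = set(sess.injected["trial_id"])
        dropped = set(sess.trials["trial_id"][~keep])
        assert injected <= dropped  # every injected trial removed
        # flagged fraction = injected plus the natural 2-SD tail
        frac = 1 - keep.mean()
        assert frac == pytest.approx(len(injected) / len(sess.trials), abs=0.12)

    def test_clean_session_loses_no_trials_to_injection(self):
        sess = self._session(0.0)
        keep = qc_trials(sess.trials, sess.eye)
        assert len(sess.injected) == 0
        # only the natural 2-SD tail may be trimmed
        assert keep.mean() > 0.85

    def test_missing_eye_data_policy(self):
        trials = pd.DataFrame(dict(trial_id=[0], onset_s=[0.0]))
        assert qc_trials(trials, None, missing_policy="keep").all()
        assert not qc_trials(trials, None, missing_policy="drop").any()


class TestChunking:
    @given(n=st.integers(5, 200))
    @settings(max_examples=50, deadline=None)
    def test_balanced_partition_property(self, n):
        sizes = balanced_chunk_sizes(n, 5)
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes, reverse=True)

    def test_47_reps_split_10_10_9_9_9(self):
        assert balanced_chunk_sizes(47, 5) == [10, 10, 9, 9, 9]

    @staticmethod
    def _values_and_trials(n_stim=3, n_reps=50, seed=0):
        rng = np.random.default_rng(seed)
        trials = pd.DataFrame(
            dict(
                trial_id=np.arange(n_stim * n_reps),
                stimulus_id=np.tile(np.arange(n_stim), n_reps),
                rep=np.repeat(np.arange(n_reps), n_stim),
            )
        )
        values = rng.normal(size=(2, len(trials), N_BINS))
        return values, trials

    def test_full_session_gives_five_chunks_of_ten(self):
        values, trials = self._values_and_trials()
        chunked, obs = chunk_average(values, trials)
        assert chunked.shape[1] == 15  # 3 stimuli x 5 chunks
        assert (obs["n_reps"] == 10).all()

    def test_identical_repetitions_pass_through(self):
        values, trials = self._values_and_trials()
        values[:] = 3.25
        chunked, _ = chunk_average(values, trials)
        assert np.allclose(chunked, 3.25)

    def test_chunk_means_conserve_grand_mean(self):
        values, trials = self._values_and_trials()
        chunked, obs = chunk_average(values, trials)
        for sid in range(3):
            sel = obs["stimulus_id"] == sid
            w = obs.loc[sel, "n_reps"].to_numpy()
            weighted = (chunked[:, sel, :] * w[None, :, None]).sum(axis=1) / w.sum()
            direct = values[:, trials["stimulus_id"] == sid, :].mean(axis=1)
            assert np.allclose(weighted, direct, atol=1e-10)

    def test_understocked_stimulus_dropped(self):
        values, trials = self._values_and_trials(n_reps=50)
        keep = ~((trials["stimulus_id"] == 1) & (trials["rep"] >= 3)).to_numpy()
        chunked, obs = chunk_average(values, trials, keep=keep)
        assert 1 not in set(obs["stimulus_id"])

    def test_normalize_and_chunk_do_not_commute(self):
        values, trials = self._values_and_trials(seed=5)
        rates = np.abs(values) * 20.0
        a = chunk_average(normalize_foldchange(rates), trials)[0]
        b = normalize_foldchange(chunk_average(rates, trials)[0])
        assert not np.allclose(a, b)
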