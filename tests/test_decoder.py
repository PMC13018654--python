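"""TDCA and TRCA decoding: embeddings, projectors, fitting and scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import subspace_angles

from ssvepkit import pipeline
from ssvepkit.containers import EpochSet
from ssvepkit.decoder import (
    TDCAModel,
    delay_embed,
    difference_matrices,
    fit_tdca,
    fit_trca,
    reference_projection,
    score,
    score_batch,
    score_batch_trca,
    subband_weights,
)
from ssvepkit.preprocess import FilterBankSpec
from ssvepkit.synthetic_data import SimConfig, synth_dataset

FS = 250.0


class TestDelayEmbed:
    def test_l0_is_identity(self):
        x = np.random.default_rng(0).standard_normal((3, 7))
        np.testing.assert_array_equal(delay_embed(x, 0, test_mode=True), x)

    def test_shape_and_zero_padding(self):
        x = np.arange(10, dtype=float).reshape(2, 5)
        out = delay_embed(x, 2, test_mode=True)
        assert out.shape == (6, 5)
        # lag-1 block, last column is zero-padded
        out1 = delay_embed(x, 1, test_mode=True)
        assert np.all(out1[2:, -1] == 0.0)

    def test_training_mode_needs_lookahead(self):
        x = np.zeros((2, 10))
        assert delay_embed(x, 3).shape == (8, 7)
        with pytest.raises(ValueError):
            delay_embed(x, 3, n_out=8)
        with pytest.raises(ValueError):
            delay_embed(x, -1)

    @given(
        st.integers(1, 4),  # channels
        st.integers(2, 9),  # samples
        st.integers(0, 4),  # delay order
        st.integers(0, 2 ** 31 - 1),
    )
    def test_matches_bruteforce_index_oracle(self, nc, n, l, seed):
        x = np.random.default_rng(seed).standard_normal((nc, n))
        out = delay_embed(x, l, test_mode=True)
        for j in range(l + 1):
            for c in range(nc):
                for t in range(n):
                    expect = x[c, t + j] if t + j < n else 0.0
                    assert out[j * nc + c, t] == expect


class TestReferenceProjection:
    @pytest.mark.parametrize("f", [8.0, 10.6, 15.8])
    def test_symmetric_idempotent(self, f):
        p = reference_projection(f, 5, FS, 125)
        assert np.max(np.abs(p - p.T)) < 1e-8
        assert np.max(np.abs(p @ p - p)) < 1e-8

    def test_in_subspace_vector_unchanged(self):
        f = 11.0
        t = np.arange(125) / FS
        v = np.sin(2 * np.pi * f * t)
        p = reference_projection(f, 5, FS, 125)
        assert np.allclose(v @ p, v, rtol=1e-6, atol=1e-9)

    def test_trace_equals_subspace_dimension(self):
        p = reference_projection(9.0, 5, FS, 250)
        assert np.trace(p) == pytest.approx(10.0, abs=1e-6)

    def test_nyquist_and_rank_guards(self):
        with pytest.raises(ValueError):
            reference_projection(30.0, 5, FS, 100)
        with pytest.warns(UserWarning, match="rank deficient"):
            reference_projection(9.0, 5, FS, 6)


def test_subband_weights_printed_values():
    w = subband_weights(5)
    assert w[0] == pytest.approx(1.25)
    assert w[4] == pytest.approx(5.0 ** -1.25 + 0.25, abs=1e-9)


def _subbands(es, window, l=4):
    return pipeline.prepare_subbands(es, window, bank_spec=FilterBankSpec(), delay_order=l)


def _freqs(codes):
    return pipeline.frequency_map(codes)


class TestTDCAFit:
    def test_filter_row_count(self, noiseless_epochs40, codes40):
        sub = _subbands(noiseless_epochs40, 0.1)
        model = fit_tdca(sub, _freqs(codes40), 25)
        assert all(w.shape == (45, 8) for w in model.filters)  # (4+1)*9 rows
        assert all(np.linalg.matrix_rank(w) == 8 for w in model.filters)

    def test_difference_matrix_column_counts(self):
        rng = np.random.default_rng(0)
        nt, nb, rows, width = 4, 3, 6, 10  # width = 2*Np
        xa = rng.standard_normal((rows, nt * nb, width))
        labels = np.repeat(np.arange(nt), nb)
        _, hb, hw = difference_matrices(xa.copy(), labels, np.arange(nt))
        assert hb.shape == (rows, nt * width)
        assert hw.shape == (rows, nt * nb * width)

    def test_noiseless_perfect_accuracy_small_subset(self, montage9, codes40):
        codes = codes40[:4]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=1, target_snr_db=None)
        es = synth_dataset(2, codes, 0.8, cfg)
        sub = _subbands(es, 0.2)
        model = fit_tdca(sub, _freqs(codes), 50)
        _, _, pred = score_batch([e.data[:, :, :50] for e in sub], model)
        assert np.array_equal(pred, sub[0].labels)

    def test_duplicating_trials_preserves_filter_space(self, montage9, codes40):
        codes = codes40[:5]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=3, target_snr_db=10.0)
        es = synth_dataset(2, codes, 0.6, cfg)
        doubled = EpochSet(
            np.concatenate([es.data, es.data]),
            es.fs,
            np.concatenate([es.labels, es.labels]),
            np.concatenate([es.blocks, es.blocks + 2]),
            es.channels,
        )
        m1 = fit_tdca(_subbands(es, 0.2), _freqs(codes), 50)
        m2 = fit_tdca(_subbands(doubled, 0.2), _freqs(codes), 50)
        for w1, w2 in zip(m1.filters, m2.filters):
            assert np.max(subspace_angles(w1, w2)) < 1e-4

    def test_label_permutation_invariance(self, montage9, codes40):
        codes = codes40[:8]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=4, target_snr_db=15.0)
        es = synth_dataset(3, codes, 0.6, cfg)
        perm = np.random.default_rng(0).permutation(es.n_trials)
        shuffled = es.select_trials(perm)
        test = synth_dataset(1, codes, 0.6, SimConfig(
            montage=montage9, code_table=codes, fs=FS, seed=99, target_snr_db=15.0))
        sub_t = _subbands(test, 0.2)
        trials = [e.data[:, :, :50] for e in sub_t]
        m1 = fit_tdca(_subbands(es, 0.2), _freqs(codes), 50)
        m2 = fit_tdca(_subbands(shuffled, 0.2), _freqs(codes), 50)
        _, _, p1 = score_batch(trials, m1)
        _, _, p2 = score_batch(trials, m2)
        np.testing.assert_array_equal(p1, p2)

    def test_too_few_trials_rejected(self, montage9, codes40):
        codes = codes40[:3]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=0, target_snr_db=None)
        es = synth_dataset(1, codes, 0.6, cfg)
        with pytest.raises(ValueError, match="2 training trials"):
            fit_tdca(_subbands(es, 0.2), _freqs(codes), 50)


class TestTDCAScore:
    def test_training_trial_scores_r_one_for_own_class(self, montage9, codes40):
        codes = codes40[:4]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=1, target_snr_db=None)
        es = synth_dataset(2, codes, 0.8, cfg)
        # delay order 0: no test-time zero padding, so a noiseless training
        # trial reproduces its own template exactly and r = 1
        sub0 = _subbands(es, 0.2, l=0)
        m0 = fit_tdca(sub0, _freqs(codes), 50, delay_order=0)
        sv0 = score([e.data[0, :, :50] for e in sub0], m0)
        own = int(np.flatnonzero(m0.class_list == sub0[0].labels[0])[0])
        assert np.all(sv0.r[own] > 1.0 - 1e-6)
        # with the default delay order the trailing lag samples are
        # zero-padded at test time; r stays near 1 and the decision is exact
        sub = _subbands(es, 0.2)
        model = fit_tdca(sub, _freqs(codes), 50)
        sv = score([e.data[0, :, :50] for e in sub], model)
        assert np.all(sv.r[own] > 0.97)
        assert sv.predicted == sub[0].labels[0] == sv0.predicted

    def test_positive_scaling_invariance(self, noiseless_epochs40, codes40):
        sub = _subbands(noiseless_epochs40, 0.2)
        model = fit_tdca(sub, _freqs(codes40), 50)
        trial = [e.data[5, :, :50] for e in sub]
        a = score(trial, model)
        b = score([7.3 * x for x in trial], model)
        assert a.predicted == b.predicted
        np.testing.assert_allclose(a.rho, b.rho, rtol=1e-10)

    def test_short_window_zero_padded_not_rejected(self, noiseless_epochs40, codes40):
        sub = _subbands(noiseless_epochs40, 0.2)
        model = fit_tdca(sub, _freqs(codes40), 50)
        sv = score([e.data[0, :, :30] for e in sub], model)
        assert sv.predicted == sub[0].labels[0]
        with pytest.raises(ValueError, match="exceeds"):
            score([e.data[0, :, :60] for e in sub], model)

    def test_model_hdf5_roundtrip(self, tmp_path, noiseless_epochs40, codes40):
        sub = _subbands(noiseless_epochs40, 0.1)
        model = fit_tdca(sub, _freqs(codes40), 25)
        p = tmp_path / "model.h5"
        model.to_hdf5(p)
        back = TDCAModel.from_hdf5(p)
        trials = [e.data[:5, :, :25] for e in sub]
        r1, _, p1 = score_batch(trials, model)
        r2, _, p2 = score_batch(trials, back)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(r1, r2)


class TestTRCA:
    def test_noiseless_perfect_accuracy(self, noiseless_epochs40, codes40):
        sub = _subbands(noiseless_epochs40, 0.2)
        model = fit_trca(sub, 50)
        _, pred = score_batch_trca([e.data[:, :, :50] for e in sub], model)
        assert np.array_equal(pred, sub[0].labels)

    def test_single_trial_per_class_rejected(self, montage9, codes40):
        codes = codes40[:3]
        cfg = SimConfig(montage=montage9, code_table=codes, fs=FS, seed=0, target_snr_db=None)
        es = synth_dataset(1, codes, 0.6, cfg)
        with pytest.raises(ValueError, match="2 trials"):
            fit_trca(_subbands(es, 0.2), 50)

    def test_tdca_comparable_to_trca_benchmark(self, montage9, codes40):
        """Both decoders solve the default noisy 40-class benchmark, with
        mean accuracies within a tight band of each other.

        On recorded EEG the shared-filter decoder typically leads; this
        generator's evoked component is phase-locked with only mild
        trial-to-trial variability, a regime that mildly favours the
        per-class reproducibility filters, so non-inferiority is asserted
        with an 8-point band (observed gap ~4 points) over 50 seeds.
        """
        acc_tdca, acc_trca = [], []
        for seed in range(50):
            cfg = SimConfig(
                montage=montage9, code_table=codes40, fs=FS, seed=seed, target_snr_db=10.0
            )
            es = synth_dataset(5, codes40, 0.4, cfg)
            sub = _subbands(es, 0.2)
            train = [e.select_trials(e.blocks != 4) for e in sub]
            test = [e.data[e.blocks == 4][:, :, :50] for e in sub]
            truth = sub[0].labels[sub[0].blocks == 4]
            mt = fit_tdca(train, _freqs(codes40), 50)
            _, _, pt = score_batch(test, mt)
            mr = fit_trca(train, 50)
            _, pr = score_batch_trca(test, mr)
            acc_tdca.append(np.mean(pt == truth))
            acc_trca.append(np.mean(pr == truth))
        chance = 1.0 / len(codes40)
        assert np.mean(acc_tdca) > 10 * chance
        assert np.mean(acc_trca) > 10 * chance
        assert np.mean(acc_tdca) >= np.mean(acc_trca) - 0.08


class TestMonotonicity:
    def test_accuracy_increases_with_window_and_snr(self, montage9, codes40):
        # Spearman rank correlation of mean accuracy against window and SNR
        from scipy.stats import spearmanr

        codes = codes40[:10]
        windows = (0.1, 0.2, 0.3)
        snrs = (4.0, 10.0, 16.0)
        acc_w = np.zeros((50, len(windows)))
        acc_s = np.zeros((50, len(snrs)))
        for seed in range(50):
            cfg = SimConfig(
                montage=montage9, code_table=codes, fs=FS, seed=seed, target_snr_db=10.0
            )
            es = synth_dataset(3, codes, 0.62, cfg)
            sub = _subbands(es, 0.3)
            train = [e.select_trials(e.blocks != 2) for e in sub]
            test_mask = sub[0].blocks == 2
            truth = sub[0].labels[test_mask]
            for i, w in enumerate(windows):
                n = int(round(w * FS))
                m = fit_tdca(train, _freqs(codes), n)
                _, _, pred = score_batch([e.data[test_mask][:, :, :n] for e in sub], m)
                acc_w[seed, i] = np.mean(pred == truth)
            for i, s in enumerate(snrs):
                cfg_s = SimConfig(
                    montage=montage9, code_table=codes, fs=FS, seed=seed, target_snr_db=s
                )
                es_s = synth_dataset(3, codes, 0.4, cfg_s)
                sub_s = _subbands(es_s, 0.2)
                train_s = [e.select_trials(e.blocks != 2) for e in sub_s]
                m = fit_tdca(train_s, _freqs(codes), 50)
                _, _, pred = score_batch(
                    [e.data[sub_s[0].blocks == 2][:, :, :50] for e in sub_s], m
                )
                acc_s[seed, i] = np.mean(pred == sub_s[0].labels[sub_s[0].blocks == 2])
        assert spearmanr(windows, acc_w.mean(0)).statistic > 0
        assert spearmanr(snrs, acc_s.mean(0)).statistic > 0
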