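"""Decoding preprocessing transformers, AUC, decoders, and the searchlight."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import sleepreplay as sr
from sleepreplay.decoding import lda_weights_multi, make_lda
from sleepreplay.simulate import standard_layout


def toy_epochs(rng, n_ev=20, n_ch=4, n_t=50, sfreq=200.0):
    times = np.arange(n_t) / sfreq
    return sr.EpochSet(
        data=rng.standard_normal((n_ev, n_ch, n_t)),
        times=times,
        lock="stimulus-onset",
        channel_names=[f"ch{i}" for i in range(n_ch)],
        labels=rng.integers(0, 2, n_ev),
    )


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        out = sr.zscore_epochs(toy_epochs(rng))
        np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_hand_example_sample_sd(self):
        # trials (1,2,3) at one feature → (−1, 0, 1) with sample SD = 1
        eps = sr.EpochSet(
            data=np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1),
            times=np.array([0.0]),
            lock="stimulus-onset",
            channel_names=["a"],
        )
        np.testing.assert_allclose(
            sr.zscore_epochs(eps).data.ravel(), [-1.0, 0.0, 1.0]
        )

    def test_zero_variance_feature_maps_to_zero(self, rng):
        eps = toy_epochs(rng)
        eps.data[:, 0, 0] = 5.0
        out = sr.zscore_epochs(eps)
        np.testing.assert_allclose(out.data[:, 0, 0], 0.0)

    def test_duplicated_single_trial_all_zero(self):
        eps = sr.EpochSet(
            data=np.tile(np.arange(10.0).reshape(1, 2, 5), (4, 1, 1)),
            times=np.arange(5) / 200.0,
            lock="stimulus-onset",
            channel_names=["a", "b"],
        )
        np.testing.assert_allclose(sr.zscore_epochs(eps).data, 0.0)


class TestBaseline:
    def test_constant_trial_zeroed(self):
        eps = toy_epochs(np.random.default_rng(0))
        eps.data[:] = 3.3
        np.testing.assert_allclose(sr.baseline_correct(eps).data, 0.0, atol=1e-12)

    def test_window_mean_removed(self, rng):
        eps = toy_epochs(rng)
        out = sr.baseline_correct(eps, window=(0.0, 0.1))
        m = out.time_mask(0.0, 0.1)
        np.testing.assert_allclose(out.data[:, :, m].mean(axis=-1), 0, atol=1e-12)

    def test_offset_removed_sine_preserved(self):
        times = np.arange(400) / 200.0
        sine = np.sin(2 * np.pi * 10 * times)
        eps = sr.EpochSet(
            data=(sine + 7.0)[None, None, :],
            times=times,
            lock="stimulus-onset",
            channel_names=["a"],
        )
        out = sr.baseline_correct(eps)
        np.testing.assert_allclose(out.data[0, 0], sine - sine.mean(), atol=1e-12)


class TestPooledPCA:
    def test_exact_low_rank_reconstruction(self, rng):
        mixing = rng.standard_normal((5, 10))
        latents = rng.standard_normal((30, 5, 40))
        data = np.einsum("nlt,lc->nct", latents, mixing)
        wake = sr.EpochSet(data=data[:15], times=np.arange(40) / 200.0,
                           lock="stimulus-onset", channel_names=[f"c{i}" for i in range(10)])
        sleep = wake.copy()
        sleep.data = data[15:]
        pca, wake_t, sleep_t = sr.fit_pca_pooled(wake, sleep, n_components=5)
        recon = pca.inverse_transform(wake_t.data)
        np.testing.assert_allclose(recon, wake.data, atol=1e-8)

    def test_projector_orthonormal_and_ordered(self, rng):
        wake, sleep = toy_epochs(rng, n_ev=30, n_ch=8), toy_epochs(rng, n_ev=25, n_ch=8)
        pca, wake_t, _ = sr.fit_pca_pooled(wake, sleep, n_components=4)
        P = pca.components_
        np.testing.assert_allclose(P @ P.T, np.eye(4), atol=1e-10)
        variances = wake_t.data.var(axis=(0, 2))
        evr = pca.explained_variance_ratio_
        assert (np.diff(evr) <= 1e-12).all()

    def test_k_exceeding_rank_errors(self, rng):
        wake, sleep = toy_epochs(rng, n_ch=3), toy_epochs(rng, n_ch=3)
        with pytest.raises(ValueError, match="n_components"):
            sr.fit_pca_pooled(wake, sleep, n_components=10)


class TestSmoothing:
    def test_constant_unchanged(self, rng):
        eps = toy_epochs(rng)
        eps.data[:] = 2.5
        np.testing.assert_allclose(sr.smooth_running_average(eps).data, 2.5)

    def test_impulse_plateau_is_one_over_31(self):
        # 150 ms at 200 Hz → 31-sample window
        times = np.arange(200) / 200.0
        data = np.zeros((1, 1, 200))
        data[0, 0, 100] = 1.0
        eps = sr.EpochSet(data=data, times=times, lock="stimulus-onset",
                          channel_names=["a"])
        out = sr.smooth_running_average(eps, width=0.150)
        plateau = out.data[0, 0, 85:116]
        np.testing.assert_allclose(plateau, 1 / 31, atol=1e-12)
        assert out.data[0, 0, 84] == 0.0

    def test_noise_variance_reduction(self, rng):
        eps = toy_epochs(rng, n_ev=200, n_ch=1, n_t=400)
        out = sr.smooth_running_average(eps, width=0.150)
        ratio = out.data[:, :, 50:-50].var() / eps.data[:, :, 50:-50].var()
        assert ratio == pytest.approx(1 / 31, rel=0.15)


class TestAUC:
    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 50)
        scores = rng.standard_normal(50)
        assert sr.rank_auc(scores[None, :], y)[0] == pytest.approx(
            roc_auc_score(y, scores)
        )

    def test_pair_counting_oracle(self, rng):
        # 8-trial toy: AUC = fraction of concordant (B > A) score pairs
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        scores = rng.standard_normal(8)
        concordant = np.mean(
            [sb > sa for sa in scores[y == 0] for sb in scores[y == 1]]
        )
        assert sr.rank_auc(scores[None, :], y)[0] == pytest.approx(concordant)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        scores = rng.standard_normal(12)
        a1 = sr.rank_auc(scores[None, :], y)[0]
        a2 = sr.rank_auc((np.exp(scores) * 3 + 1)[None, :], y)[0]
        assert a1 == pytest.approx(a2)


class TestLDA:
    def test_fast_path_matches_sklearn(self, rng):
        X = rng.standard_normal((60, 8, 4))
        y = rng.integers(0, 2, 60)
        X[y == 1] += 0.4
        W, b = lda_weights_multi(X, y)
        for t in range(4):
            clf = make_lda().fit(X[:, :, t], y)
            ours = X[:, :, t] @ W[t] + b[t]
            theirs = clf.decision_function(X[:, :, t])
            # identical decision ordering and (up to numerical noise) scores
            assert np.corrcoef(ours, theirs)[0, 1] == pytest.approx(1.0, abs=1e-9)
            assert sr.rank_auc(ours[None, :], y)[0] == pytest.approx(
                sr.rank_auc(theirs[None, :], y)[0]
            )


class TestDecoders:
    def separable_epochs(self, rng, n_ev=40, n_ch=6, n_t=30):
        eps = toy_epochs(rng, n_ev=n_ev, n_ch=n_ch, n_t=n_t)
        labels = np.r_[np.zeros(n_ev // 2, int), np.ones(n_ev // 2, int)]
        eps.labels = rng.permutation(labels)
        eps.data[eps.labels == 1, 0, :] += 20.0
        return eps

    def test_separable_auc_is_one(self, rng):
        eps = self.separable_epochs(rng)
        auc, _, _ = sr.cv_decode_timecourse(eps, n_repeats=2, n_shuffles=0,
                                            random_state=0)
        np.testing.assert_allclose(auc, 1.0)

    def test_shuffled_labels_chance(self, rng):
        eps = toy_epochs(rng, n_ev=100, n_ch=5, n_t=20)
        eps.labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        auc, surr, _ = sr.cv_decode_timecourse(
            eps, n_repeats=2, n_shuffles=20, time_step=4, random_state=0
        )
        assert abs(auc.mean() - 0.5) < 0.05
        assert abs(surr.mean() - 0.5) < 0.02

    def test_temporal_generalization_shape_and_planted_ridge(self, rng):
        train = self.separable_epochs(rng, n_ev=60, n_t=40)
        test = toy_epochs(rng, n_ev=30, n_ch=6, n_t=25)
        test.labels = rng.integers(0, 2, 30)
        test.data[test.labels == 1, 0, 10:15] += 20.0  # pattern at test lag
        dmap = sr.temporal_generalization(train, test, n_shuffles=5, random_state=0)
        assert dmap.auc.shape == (40, 25)
        assert dmap.surrogate_auc.shape == (40, 25)
        ridge = dmap.auc[:, 10:15].mean()
        off = dmap.auc[:, :8].mean()
        assert ridge > 0.95 and abs(off - 0.5) < 0.1

    def test_feature_mismatch_errors(self, rng):
        train = self.separable_epochs(rng, n_ch=6)
        test = toy_epochs(rng, n_ch=5)
        with pytest.raises(ValueError, match="mismatch"):
            sr.temporal_generalization(train, test, n_shuffles=0)

    def test_absent_class_errors(self, rng):
        eps = toy_epochs(rng)
        eps.labels = np.zeros(eps.n_events, int)
        with pytest.raises(ValueError, match="two classes"):
            sr.cv_decode_timecourse(eps, n_shuffles=0)


class TestSearchlight:
    def test_neighborhood_sizes_in_5_to_9(self):
        names, pos = standard_layout(64)
        hoods = sr.channel_neighborhoods(pos, names)
        sizes = np.array([len(v) for v in hoods.values()])
        assert sizes.min() >= 5 and sizes.max() <= 9
        for name, idx in hoods.items():
            assert names.index(name) in idx

    def test_posterior_pattern_localized(self, rng):
        names, pos = standard_layout(32)
        n_ev, n_t = 60, 20
        posterior = pos[:, 1] < -0.3
        pattern = np.where(posterior, 1.0, 0.0)
        times = np.arange(n_t) / 200.0

        def build(n):
            labels = rng.permutation(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
            data = rng.standard_normal((n, 32, n_t))
            data[labels == 1] += 2.0 * pattern[None, :, None]
            return sr.EpochSet(data=data, times=times, lock="stimulus-onset",
                               channel_names=names, labels=labels,
                               channel_positions=pos)

        loc, slp = build(60), build(40)
        res = sr.searchlight_decode(loc, slp, (0.0, 0.1), (0.0, 0.1), test_step=2)
        auc = np.array([res[n] for n in names])
        assert auc[posterior].mean() > auc[~posterior].mean() + 0.1

    def test_pure_noise_flat_at_chance(self, rng):
        names, pos = standard_layout(32)
        times = np.arange(20) / 200.0

        def build(n):
            return sr.EpochSet(
                data=rng.standard_normal((n, 32, 20)), times=times,
                lock="stimulus-onset", channel_names=names,
                labels=rng.permutation(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]),
                channel_positions=pos,
            )

        res = sr.searchlight_decode(build(60), build(60), (0.0, 0.1), (0.0, 0.1),
                                    test_step=2)
        vals = np.array(list(res.values()))
        assert abs(vals.mean() - 0.5) < 0.05


class TestPipelineOrder:
    def test_preprocessing_log_order(self, rng):
        wake = toy_epochs(rng, n_ev=40, n_ch=8, n_t=30)
        sleep = toy_epochs(rng, n_ev=30, n_ch=8, n_t=30)
        _, _, _, log = sr.preprocess_for_decoding(
            wake, sleep, sr.PreprocSpec(n_components=4)
        )
        stages = [entry.split(":")[0] for entry in log]
        assert stages == ["baseline", "z-score", "PCA", "smooth"]
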