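"""Decoding engine: classifier correctness, CV analyses, invariances."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from featuredyn import (
    NoiseSpec,
    RegularizedLDA,
    SignalComponent,
    SignalSpec,
    build_sequences,
    build_stimulus_set,
    conjunction_decoding,
    decode_feature_timecourse,
    generate_epochs,
    interaction_decoding,
    pairwise_rdm_decoding,
    searchlight_timecourse,
    time_generalisation,
)
from featuredyn.decoding import _fold_predictions
from featuredyn.simulate import EpochedDataset, _envelope, _level_patterns, channel_layout


def binomial_band(p, n, k=3):
    return k * np.sqrt(p * (1 - p) / n)


class TestRegularizedLDA:
    def test_matches_closed_form_discriminant_on_six_points(self):
        """Independent oracle: the two-class linear discriminant computed
        from the explicit pooled-covariance formula on 6 hand-set points."""
        X = np.array([[0.0, 0.2], [1.0, -0.1], [0.5, 0.4],
                      [3.0, 2.2], [4.0, 1.9], [3.5, 2.6]])
        y = np.array([0, 0, 0, 1, 1, 1])
        mu0, mu1 = X[:3].mean(axis=0), X[3:].mean(axis=0)
        scatter = (X[:3] - mu0).T @ (X[:3] - mu0) + (X[3:] - mu1).T @ (X[3:] - mu1)
        S = scatter / (6 - 2)
        lam = 0.01
        S_reg = S + lam * np.mean(np.diag(S)) * np.eye(2)
        w = np.linalg.inv(S_reg) @ (mu1 - mu0)
        b = -0.5 * (mu1 + mu0) @ w  # equal priors
        grid = np.array([[x1, x2] for x1 in np.linspace(-1, 5, 7)
                         for x2 in np.linspace(-1, 3, 7)])
        oracle = (grid @ w + b > 0).astype(int)
        model = RegularizedLDA(reg=lam).fit(X, y)
        assert np.array_equal(model.predict(grid), oracle)

    def test_agrees_with_sklearn_lda_in_small_reg_limit(self):
        """Cross-check against sklearn's LDA (different solver, no
        shrinkage) on well-conditioned data: zero label disagreement."""
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(m, 1.0, size=(60, 5))
                            for m in (0.0, 1.5, 3.0)])
        y = np.repeat([0, 1, 2], 60)
        Xte = rng.normal(1.5, 2.0, size=(200, 5))
        ours = RegularizedLDA(reg=1e-10).fit(X, y).predict(Xte)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(Xte)
        assert np.array_equal(ours, ref)

    def test_separable_classes_perfect_identical_classes_chance(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        y = np.repeat([0, 1], 100)
        Xte = np.concatenate([rng.normal(0, 1, (50, 2)), rng.normal(10, 1, (50, 2))])
        yte = np.repeat([0, 1], 50)
        assert (RegularizedLDA().fit(X, y).predict(Xte) == yte).mean() == 1.0
        X0 = rng.normal(0, 1, (400, 4))
        y0 = np.repeat([0, 1], 200)
        acc = (RegularizedLDA().fit(X0, y0).predict(rng.normal(0, 1, (400, 4)))
               == np.repeat([0, 1], 200)).mean()
        assert abs(acc - 0.5) < binomial_band(0.5, 400)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            RegularizedLDA().fit(np.zeros((4, 2)), np.zeros(3))
        with pytest.raises(ValueError):
            RegularizedLDA().fit(np.zeros((4, 2)), [0, 0, 0, 1])  # class with 1 sample

    def test_sklearn_api_compliance(self):
        model = RegularizedLDA(reg=0.5)
        assert model.get_params() == {"reg": 0.5}
        model.set_params(reg=0.1)
        assert model.reg == 0.1


class TestFoldKernel:
    def test_kernel_matches_estimator_per_timepoint(self):
        """The batched CV kernel must reproduce RegularizedLDA exactly."""
        rng = np.random.default_rng(3)
        Xtr = rng.normal(size=(40, 6, 5))
        ytr = rng.integers(0, 3, size=40)
        while np.bincount(ytr, minlength=3).min() < 2:
            ytr = rng.integers(0, 3, size=40)
        Xte = rng.normal(size=(15, 6, 5))
        batched = _fold_predictions(Xtr, ytr, Xte, reg=0.01)
        for t in range(5):
            ref = RegularizedLDA(reg=0.01).fit(Xtr[:, :, t], ytr).predict(Xte[:, :, t])
            assert np.array_equal(batched[:, t], ref)


class TestFeatureTimecourse:
    def test_signal_feature_recovered_others_at_chance(self, tiny_dataset):
        """Only colour carries signal: colour decodes far above chance at
        the injected peak; the orthogonal features stay at chance."""
        tc = decode_feature_timecourse(tiny_dataset, "colour")
        assert tc.accuracy.max() > 0.9
        assert abs(tc.peak_time() - 100) <= 8
        n_test = tiny_dataset.n_events
        for other in ("orientation", "sf", "contrast"):
            tco = decode_feature_timecourse(tiny_dataset, other)
            assert abs(tco.accuracy.mean() - 0.25) < binomial_band(0.25, n_test)

    def test_shuffled_labels_fall_to_chance(self, tiny_dataset):
        rng = np.random.default_rng(5)
        shuffled = tiny_dataset.events.copy()
        shuffled["colour_level"] = rng.permutation(shuffled["colour_level"].to_numpy())
        ds = EpochedDataset(
            subject_id="shuf", data=tiny_dataset.data, times=tiny_dataset.times,
            events=shuffled, channel_positions=tiny_dataset.channel_positions,
        )
        tc = decode_feature_timecourse(ds, "colour")
        assert abs(tc.accuracy.mean() - 0.25) < binomial_band(0.25, ds.n_events)

    def test_channel_permutation_invariance(self, tiny_dataset):
        perm = np.random.default_rng(6).permutation(tiny_dataset.n_channels)
        ds = EpochedDataset(
            subject_id="perm", data=tiny_dataset.data[:, perm],
            times=tiny_dataset.times, events=tiny_dataset.events,
            channel_positions=tiny_dataset.channel_positions[perm],
        )
        a = decode_feature_timecourse(tiny_dataset, "colour").accuracy
        b = decode_feature_timecourse(ds, "colour").accuracy
        assert np.allclose(a, b, atol=5e-3)

    def test_unknown_feature_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            decode_feature_timecourse(tiny_dataset, "luminance")


class TestTimeGeneralisation:
    def test_diagonal_equals_timecourse(self, tiny_dataset):
        times = np.arange(0, 201, 8.0)
        tc = decode_feature_timecourse(tiny_dataset, "colour", times=times)
        gm = time_generalisation(tiny_dataset, "colour", times=times)
        assert np.array_equal(np.diag(gm.accuracy), tc.accuracy)

    def test_opposite_sign_stages_generalise_below_chance(self):
        """Two processing stages with sign-flipped spatial patterns: the
        classifier trained on stage 1 mislabels stage 2 systematically."""
        design = build_sequences(4, 6.67, seed=17)
        stimset = build_stimulus_set()
        events = design.events.merge(stimset.table[["stimulus_id", "colour_level"]],
                                     on="stimulus_id")
        times = np.arange(0, 241, 8.0)
        rng = np.random.default_rng(17)
        pats = _level_patterns(rng, 10, graded=False)
        env1 = _envelope(times, 40, 80, 40)
        env2 = _envelope(times, 140, 180, 40)
        lv = events["colour_level"].to_numpy()
        amp = 2.0
        data = (amp * pats[lv][:, :, None] * (env1 - env2)[None, None, :]
                + rng.normal(size=(len(events), 10, len(times)))).astype(np.float32)
        ds = EpochedDataset(subject_id="stages", data=data, times=times,
                            events=events, channel_positions=channel_layout(10))
        gm = time_generalisation(ds, "colour")
        t80 = np.searchsorted(times, 80)
        t180 = np.searchsorted(times, 180)
        assert gm.accuracy[t80, t80] > 0.5
        assert gm.accuracy[t180, t180] > 0.5
        assert gm.accuracy[t80, t180] < 0.25 - binomial_band(0.25, ds.n_events)
        assert gm.accuracy[t180, t80] < 0.25 - binomial_band(0.25, ds.n_events)


class TestSearchlight:
    def test_localised_signal_found_at_its_neighbourhood(self):
        """Signal confined to one 5-channel neighbourhood: the searchlight
        map peaks at that centre and stays at chance far away."""
        design = build_sequences(4, 6.67, seed=23)
        stimset = build_stimulus_set()
        events = design.events.merge(stimset.table[["stimulus_id", "sf_level"]],
                                     on="stimulus_id")
        times = np.arange(0, 161, 8.0)
        n_ch = 20
        pos = channel_layout(n_ch)
        dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        centre = 0
        hood = np.argsort(dist[centre], kind="stable")[:5]
        radius = dist[centre][hood].max()
        rng = np.random.default_rng(23)
        pats = np.zeros((4, n_ch))
        pats[:, hood] = _level_patterns(rng, 5, graded=False) * 3.0
        env = _envelope(times, 40, 80, 50)
        lv = events["sf_level"].to_numpy()
        data = (pats[lv][:, :, None] * env[None, None, :]
                + rng.normal(size=(len(events), n_ch, len(times)))).astype(np.float32)
        ds = EpochedDataset(subject_id="sl", data=data, times=times,
                            events=events, channel_positions=pos)
        sl = searchlight_timecourse(ds, "sf")
        assert sl.neighbourhood_size == 5
        assert sl.accuracy.shape == (n_ch, len(times))
        peak_per_channel = sl.accuracy.max(axis=1)
        outside = dist[centre] > 2 * radius
        assert peak_per_channel[centre] > peak_per_channel[outside].max()
        band = binomial_band(0.25, ds.n_events)
        assert np.all(np.abs(sl.accuracy[outside].mean(axis=1) - 0.25) < band)

    def test_too_few_channels_rejected(self, tiny_dataset):
        small = EpochedDataset(
            subject_id="x", data=tiny_dataset.data[:, :3],
            times=tiny_dataset.times, events=tiny_dataset.events,
            channel_positions=tiny_dataset.channel_positions[:3],
        )
        with pytest.raises(ValueError):
            searchlight_timecourse(small, "colour")


class TestInteractionDecoding:
    def test_subsets_quarter_events_and_level_independent_signal_flat(self, tiny_dataset):
        res = interaction_decoding(tiny_dataset, "colour", "sf",
                                   times=np.arange(40, 161, 8.0))
        assert len(res.timecourses) == 4
        # colour signal does not depend on sf: the four peak-window means
        # only differ by sampling noise (each subset has 1/4 of the events)
        band = binomial_band(0.5, tiny_dataset.n_events // 4)
        assert res.peak_window_means.max() - res.peak_window_means.min() < 2 * band

    def test_amplitude_scaling_with_conditioning_level_is_monotone(self):
        """Colour signal whose amplitude grows with sf level: peak-window
        colour accuracy must increase with sf level."""
        design = build_sequences(6, 6.67, seed=31)
        stimset = build_stimulus_set()
        events = design.events.merge(
            stimset.table[["stimulus_id", "colour_level", "sf_level"]],
            on="stimulus_id")
        times = np.arange(0, 161, 8.0)
        rng = np.random.default_rng(31)
        pats = _level_patterns(rng, 12, graded=False)
        env = _envelope(times, 40, 80, 50)
        col = events["colour_level"].to_numpy()
        sf = events["sf_level"].to_numpy()
        amp = 0.4 + 0.8 * sf  # amplitude scales with sf level
        data = (amp[:, None, None] * pats[col][:, :, None] * env[None, None, :]
                + rng.normal(size=(len(events), 12, len(times)))).astype(np.float32)
        ds = EpochedDataset(subject_id="scal", data=data, times=times,
                            events=events, channel_positions=channel_layout(12))
        res = interaction_decoding(ds, "colour", "sf", peak_ms=80.0)
        assert np.all(np.diff(res.peak_window_means) > 0)

    def test_same_feature_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            interaction_decoding(tiny_dataset, "sf", "sf")


class TestConjunctionDecoding:
    def test_feature_order_invariance(self, tiny_dataset):
        times = np.arange(80, 121, 8.0)
        ab, per_ab, _ = conjunction_decoding(tiny_dataset, "sf", "contrast", times=times)
        ba, per_ba, _ = conjunction_decoding(tiny_dataset, "contrast", "sf", times=times)
        assert ab.chance == 0.5
        assert per_ab.shape == (36, len(times))
        # same 36 analyses in a different enumeration order
        assert np.allclose(np.sort(per_ab, axis=0), np.sort(per_ba, axis=0), atol=1e-12)
        assert np.allclose(ab.accuracy, ba.accuracy, atol=1e-12)


class TestPairwiseRDM:
    def test_rdm_stack_structure(self, tiny_dataset):
        ids = np.arange(12)
        times = np.arange(80, 121, 8.0)
        stack, sids, tsel = pairwise_rdm_decoding(tiny_dataset, ids, times=times)
        assert stack.shape == (len(times), 12, 12)
        assert np.allclose(stack, stack.transpose(0, 2, 1))
        assert np.all(stack[:, np.arange(12), np.arange(12)] == 0)
        lower = stack[:, np.tril_indices(12, -1)[0], np.tril_indices(12, -1)[1]]
        assert np.all((lower >= 0) & (lower <= 1))

    def test_absent_stimulus_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            pairwise_rdm_decoding(tiny_dataset, [0, 1, 999])
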