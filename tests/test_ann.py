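"""MLP training, skeletonization, and auto-associative anomaly detection."""

import numpy as np
import pytest

from uroscent import (
    MlpModel,
    SimulationDesign,
    TrainSpec,
    classify,
    concordance_report,
    difference_spectrum,
    simulate_canine_calls,
    simulate_chromatograms,
    skeletonize,
    train_autoassociator,
    train_classifier,
    train_mlp,
    window_and_normalize,
)
from uroscent.ann import _grads, _init_net, encode_targets
from uroscent.simulate import default_peak_specs, PeakSpec


class TestPreprocessing:
    def test_default_grid_window_holds_205_points(self, planted_chromatograms):
        chroms, _ = planted_chromatograms
        X, rts, norm = window_and_normalize(chroms)
        assert X.shape == (100, 205)
        assert rts[0] >= 10.0 and rts[-1] < 14.0
        assert X.min() == 0.0 and X.max() == 1.0

    def test_full_span_window_is_identity_selection(self):
        d = SimulationDesign(n_case=2, n_control=2, n_points=80, rt_span=(0, 8))
        peaks = [PeakSpec(3.0, 0.1, 40.0), PeakSpec(6.0, 0.1, 25.0)]
        chroms, _ = simulate_chromatograms(d, peaks)
        X, rts, _ = window_and_normalize(chroms, rt_window=(0, 8.0), n_points=80)
        assert X.shape[1] == 80
        np.testing.assert_allclose(rts, chroms[0].retention_times)

    def test_affine_input_invariance(self, planted_chromatograms):
        """Global min/max scaling absorbs any positive affine transform."""
        chroms, _ = planted_chromatograms
        X1, _, _ = window_and_normalize(chroms[:10])
        from uroscent import Chromatogram

        shifted = [
            Chromatogram(c.retention_times, 3.5 * c.abundances + 11.0, c.sample_id)
            for c in chroms[:10]
        ]
        X2, _, _ = window_and_normalize(shifted)
        np.testing.assert_allclose(X1, X2, atol=1e-12)

    def test_constant_data_warns_and_zeroes(self):
        from uroscent import Chromatogram

        c = Chromatogram(np.linspace(10, 14, 205), np.full(205, 7.0), "s")
        with pytest.warns(UserWarning, match="constant"):
            X, _, (lo, hi) = window_and_normalize([c], (10.0, 14.01), 205)
        assert (X == 0).all() and lo == hi


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic backprop equals central differences on a random 5-3-2 net."""
        rng = np.random.default_rng(0)
        weights, biases = _init_net((5, 3, 2), rng)
        x, t = rng.random(5), rng.random(2)
        gw, gb, _ = _grads(weights, biases, x, t)

        def loss():
            a = x
            for W, b in zip(weights, biases):
                a = 1 / (1 + np.exp(-(W @ a + b)))
            return 0.5 * ((a - t) ** 2).sum()

        eps = 1e-6
        for l in range(2):
            for idx in np.ndindex(weights[l].shape):
                orig = weights[l][idx]
                weights[l][idx] = orig + eps
                up = loss()
                weights[l][idx] = orig - eps
                down = loss()
                weights[l][idx] = orig
                fd = (up - down) / (2 * eps)
                assert gw[l][idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)
            for i in range(biases[l].size):
                orig = biases[l][i]
                biases[l][i] = orig + eps
                up = loss()
                biases[l][i] = orig - eps
                down = loss()
                biases[l][i] = orig
                fd = (up - down) / (2 * eps)
                assert gb[l][i] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_xor_learnable(self):
        """The classic XOR net reaches the RMS target for most seeds."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        T = np.array([[0.1], [0.9], [0.9], [0.1]])
        ok = 0
        for seed in range(10):
            m = train_mlp(X, T, hidden=(2,), spec=TrainSpec(seed=seed, max_epochs=20000))
            ok += m.training_log["final_rms"] < 0.15
        assert ok >= 8

    def test_loss_non_increasing_at_small_learning_rate(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 4))
        T = encode_targets(
            np.array(["positive"] * 6 + ["negative"] * 6, dtype=object)
        )
        m = train_mlp(
            X, T, hidden=(3,),
            spec=TrainSpec(lr=0.01, momentum=0.0, rms_target=0.0,
                           max_epochs=150, shuffle_each_epoch=False, seed=2),
        )
        traj = np.array(m.training_log["rms_trajectory"])
        assert (np.diff(traj) <= 1e-6).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 6))
        T = rng.random((10, 2)) * 0.8 + 0.1
        a = train_mlp(X, T, spec=TrainSpec(seed=5, max_epochs=20))
        b = train_mlp(X, T, spec=TrainSpec(seed=5, max_epochs=20))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


class TestSkeletonization:
    def hand_net(self):
        """3-2-1 net with one dominant path: input0 -> hidden0 -> output."""
        W1 = np.full((2, 3), 0.1)
        W1[0, 0] = 5.0
        W2 = np.full((1, 2), 0.1)
        W2[0, 0] = 5.0
        return MlpModel(
            layer_sizes=(3, 2, 1),
            weights=[W1, W2],
            biases=[np.zeros(2), np.zeros(1)],
            norm_min=0.0,
            norm_max=1.0,
        )

    def test_retains_exactly_the_planted_path(self):
        trace = skeletonize(self.hand_net(), output_node=0, keep_per_layer=1)
        assert trace.dominant_inputs[0] == 0
        assert trace.input_saliency[0] == pytest.approx(25.0)
        kept = {(l, f, t) for l, f, t, _ in trace.retained_weights}
        assert kept == {(1, 0, 0), (0, 0, 0)}
        assert trace.input_signs[0] == 1.0

    def test_no_pruning_equals_exhaustive_path_products(self):
        rng = np.random.default_rng(4)
        weights, biases = _init_net((6, 4, 2), rng)
        model = MlpModel((6, 4, 2), weights, biases, 0.0, 1.0)
        trace = skeletonize(model, output_node=1, keep_per_layer=99)
        W1, W2 = weights
        for i in range(6):
            exhaustive = max(abs(W2[1, h]) * abs(W1[h, i]) for h in range(4))
            assert trace.input_saliency[i] == pytest.approx(exhaustive)

    def test_planted_peak_is_top_input(self):
        """A single discriminative excess peak dominates the saliency map."""
        hits = 0
        for seed in range(10):
            d = SimulationDesign(n_case=30, n_control=30, seed=seed)
            peaks = [p for p in default_peak_specs() if p.group_effect == "shared"]
            peaks.append(PeakSpec(13.18, 0.03, 60.0, "case_excess"))
            chroms, recs = simulate_chromatograms(d, peaks)
            calls = np.array(
                ["positive" if r.cohort == "cancer" else "negative" for r in recs],
                dtype=object,
            )
            X, rts, norm = window_and_normalize(chroms)
            clf = train_classifier(
                X, calls, TrainSpec(seed=seed, max_epochs=1000),
                norm=norm, retention_times=rts,
            )
            trace = skeletonize(clf, output_node=0, keep_per_layer=3)
            hits += abs(trace.dominant_rts(1)[0] - 13.18) <= 0.05
        assert hits >= 8


class TestClassifier:
    def test_emulates_simulated_dog_on_planted_data(self, planted_chromatograms):
        chroms, labels = planted_chromatograms
        calls = simulate_canine_calls(labels)
        X, rts, norm = window_and_normalize(chroms)
        clf = train_classifier(
            X, calls, TrainSpec(seed=0, max_epochs=1000),
            norm=norm, retention_times=rts,
        )
        assert (classify(clf, X) == calls).mean() >= 0.95

    def test_margin_target_encoding(self):
        T = encode_targets(np.array(["positive", "negative"], dtype=object), 0.1)
        np.testing.assert_allclose(T, [[0.9, 0.1], [0.1, 0.9]])


class TestAutoAssociator:
    @pytest.fixture(scope="class")
    def trained(self, planted_chromatograms):
        chroms, labels = planted_chromatograms
        calls = simulate_canine_calls(labels)
        X, rts, norm = window_and_normalize(chroms)
        neg = X[calls == "negative"]
        model = train_autoassociator(
            neg, TrainSpec(seed=0, rms_target=0.01, max_epochs=5000),
            norm=norm, retention_times=rts,
        )
        return model, X, calls

    def test_reconstruction_rms_below_target(self, trained):
        model, X, calls = trained
        assert model.training_log["final_rms"] <= 0.15

    def test_acts_as_nearest_exemplar_lookup(self, trained):
        """Each training spectrum reconstructs closer to itself than to any
        other training spectrum."""
        model, X, calls = trained
        neg = X[calls == "negative"]
        recon = model.predict(neg)
        good = sum(
            np.argmin(np.linalg.norm(neg - recon[i], axis=1)) == i
            for i in range(len(neg))
        )
        assert good / len(neg) >= 0.9

    def test_training_spectra_rarely_flagged(self, trained):
        model, X, calls = trained
        neg = X[calls == "negative"]
        n_regions = [
            len(difference_spectrum(model, x).excesses)
            + len(difference_spectrum(model, x).depletions)
            for x in neg
        ]
        assert np.median(n_regions) == 0
        assert np.mean(n_regions) < 0.8

    def test_planted_anomalies_localized(self, trained):
        """Positives show excesses near 13.18/13.56 and the 12.70 trough."""
        model, X, calls = trained
        pos = X[calls == "positive"]
        ds = difference_spectrum(model, pos[0])
        ex = [rt for rt, _ in ds.excesses[:3]]
        dep = [rt for rt, _ in ds.depletions]
        assert any(abs(rt - 13.177) <= 0.05 for rt in ex)
        assert any(abs(rt - 13.563) <= 0.05 for rt in ex)
        assert any(abs(rt - 12.698) <= 0.05 for rt in dep)

    def test_seeded_determinism(self, planted_chromatograms):
        chroms, labels = planted_chromatograms
        X, rts, norm = window_and_normalize(chroms[:20])
        spec = TrainSpec(seed=4, rms_target=0.05, max_epochs=50)
        a = train_autoassociator(X, spec, norm=norm)
        b = train_autoassociator(X, spec, norm=norm)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


class TestConcordance:
    def test_planted_region_flagged_by_both_methods(self, planted_chromatograms):
        chroms, labels = planted_chromatograms
        calls = simulate_canine_calls(labels)
        X, rts, norm = window_and_normalize(chroms)
        clf = train_classifier(
            X, calls, TrainSpec(seed=1, max_epochs=1000),
            norm=norm, retention_times=rts,
        )
        trace = skeletonize(clf, output_node=0, keep_per_layer=3)
        neg = X[calls == "negative"]
        auto = train_autoassociator(
            neg, TrainSpec(seed=1, rms_target=0.01, max_epochs=5000),
            norm=norm, retention_times=rts,
        )
        diffs = [
            difference_spectrum(auto, x) for x in X[calls == "positive"][:5]
        ]
        report = concordance_report(trace, diffs)
        both = [r for r in report if r["flagged_by_both"]]
        assert both, "no region flagged by both methods"
        planted = (13.177, 13.563, 12.698, 10.561, 10.899, 11.473)
        assert any(
            any(r["rt_min"] - 0.1 <= p <= r["rt_max"] + 0.1 for p in planted)
            for r in both
        )

    def test_empty_diff_set_reports_skeleton_only(self, planted_chromatograms):
        chroms, labels = planted_chromatograms
        calls = simulate_canine_calls(labels)
        X, rts, norm = window_and_normalize(chroms)
        clf = train_classifier(
            X, calls, TrainSpec(seed=2, max_epochs=500),
            norm=norm, retention_times=rts,
        )
        trace = skeletonize(clf, output_node=0, keep_per_layer=3)
        report = concordance_report(trace, [])
        assert report and all(r["methods"] == ["skeleton"] for r in report)
        assert not any(r["flagged_by_both"] for r in report)
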