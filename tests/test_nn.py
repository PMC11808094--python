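"""MLP estimators: architecture identities, losses, training, inference."""

import numpy as np
import pytest

import pcbssfp as p


@pytest.fixture(scope="module")
def small_mag_dataset(seq12):
    rng = np.random.default_rng(5)
    return p.build_dataset(p.uniform_distribution(), 12_000, seq12,
                           "magnitude", rng)


@pytest.fixture(scope="module")
def small_cx_dataset(seq12):
    rng = np.random.default_rng(6)
    return p.build_dataset(p.uniform_distribution(), 12_000, seq12,
                           "complex", rng)


RANGES_MAG = np.array([[360.0, 2080.0], [20.0, 120.0]])
RANGES_CX = np.array([[360.0, 2080.0], [20.0, 120.0], [-np.pi, np.pi]])


class TestArchitecture:
    def test_trainable_parameter_counts(self):
        rng = np.random.default_rng(0)
        mag = p.build_mlp(p.MlpSpec.for_layout("magnitude"), RANGES_MAG, rng)
        cx = p.build_mlp(p.MlpSpec.for_layout("complex"), RANGES_CX, rng)
        assert p.count_parameters(mag) == 4610
        assert p.count_parameters(cx) == 68355

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            p.build_mlp(p.MlpSpec.for_layout("magnitude"),
                        np.array([[360.0, 2080.0], [120.0, 20.0]]))
        with pytest.raises(ValueError):
            p.MlpSpec.for_layout("other")

    def test_outputs_always_inside_ranges(self, small_mag_dataset):
        est = p.MLPRelaxometer(max_epochs=1, random_state=0)
        est.fit(small_mag_dataset)
        X = np.random.default_rng(3).uniform(-5, 5, (200, 4)).astype(np.float32)
        pred = est.predict(X)
        assert np.all(pred[:, 0] > 360) and np.all(pred[:, 0] < 2080)
        assert np.all(pred[:, 1] > 20) and np.all(pred[:, 1] < 120)


class TestSupervisedLoss:
    def test_zero_at_exact_prediction(self):
        y = np.array([[1000.0, 60.0]])
        assert p.svnn_loss(y, y, RANGES_MAG) == 0.0

    def test_half_range_error_contribution(self):
        t = np.array([[360.0 + 860.0, 70.0]])
        pred = np.array([[360.0, 70.0]])  # T1 off by half its range
        assert p.svnn_loss(pred, t, RANGES_MAG) == pytest.approx(0.25 / 2)

    def test_symmetric_batch_equals_single(self):
        t = np.array([[1000.0, 70.0], [1000.0, 70.0]])
        pred = np.array([[1100.0, 70.0], [900.0, 70.0]])
        both = p.svnn_loss(pred, t, RANGES_MAG)
        one = p.svnn_loss(pred[:1], t[:1], RANGES_MAG)
        assert both == pytest.approx(one)


class TestPhysicsLoss:
    def test_vanishes_at_ground_truth(self, seq12, rng):
        ds = p.build_dataset(p.uniform_distribution(), 64, seq12, "complex", rng)
        feats = p.features_from_signal(
            ds.signals.astype(complex), "complex", ds.targets[:, 3].astype(float)
        )
        loss = p.pinn_loss(ds.targets[:, :3], ds.targets[:, 3], feats,
                           seq12, "complex", RANGES_CX)
        assert loss < 1e-10

    def test_invariant_to_input_signal_scale(self, seq12):
        t = p.TissueParams(t1=np.array([900.0]), t2=np.array([65.0]))
        sig = p.simulate_pc_signal(t, seq12).values
        pred = np.array([[1100.0, 75.0]])
        l1 = p.pinn_loss(pred, 1.0,
                         p.features_from_signal(sig, "magnitude", 1.0),
                         seq12, "magnitude", RANGES_MAG)
        l2 = p.pinn_loss(pred, 1.0,
                         p.features_from_signal(5.5 * sig, "magnitude", 1.0),
                         seq12, "magnitude", RANGES_MAG)
        assert l1 == pytest.approx(l2, rel=1e-9)

    def test_one_dimensional_sweep_minimum_at_truth(self, seq12):
        # brute-force sweep over T1 with T2 fixed: the loss minimum sits
        # at the generating T1
        t = p.TissueParams(t1=np.array([1100.0]), t2=np.array([80.0]))
        sig = p.simulate_pc_signal(t, seq12).values
        feats = p.features_from_signal(sig, "magnitude", 1.0)
        t1_grid = np.linspace(400, 2000, 161)
        losses = [
            p.pinn_loss(np.array([[g, 80.0]]), 1.0, feats, seq12,
                        "magnitude", RANGES_MAG)
            for g in t1_grid
        ]
        assert t1_grid[int(np.argmin(losses))] == pytest.approx(1100.0, abs=10.0)


class TestTraining:
    def test_deterministic_history_under_fixed_seed(self, small_mag_dataset):
        runs = []
        for _ in range(2):
            est = p.MLPRelaxometer(max_epochs=3, random_state=77)
            est.fit(small_mag_dataset)
            runs.append(est)
        assert runs[0].history_.val_loss == runs[1].history_.val_loss
        for a, b in zip(runs[0].params_, runs[1].params_):
            np.testing.assert_array_equal(a, b)

    def test_validation_loss_descends_on_easy_problem(self, small_mag_dataset):
        # median over 3 seeds: val loss after 10 epochs below epoch 1
        diffs = []
        for seed in range(3):
            est = p.MLPRelaxometer(max_epochs=10, random_state=seed)
            est.fit(small_mag_dataset)
            diffs.append(est.history_.val_loss[9] - est.history_.val_loss[0])
        assert np.median(diffs) < 0

    def test_dataset_layout_mismatch_rejected(self, small_mag_dataset):
        est = p.MLPRelaxometer(layout="complex", max_epochs=1)
        with pytest.raises(ValueError):
            est.fit(small_mag_dataset)

    def test_magnitude_variant_requires_on_resonance(self, small_cx_dataset):
        est = p.MLPRelaxometer(layout="magnitude", max_epochs=1)
        with pytest.raises(ValueError):
            est.fit(small_cx_dataset)

    def test_complex_training_thetas_exclude_wrap(self, small_cx_dataset):
        assert np.all(np.abs(small_cx_dataset.targets[:, 2]) < np.pi)

    def test_pinn_trains_without_ground_truth_targets(self, seq12,
                                                      small_mag_dataset):
        # the physics loss never sees T1/T2: zeroing them must not change
        # the fitted weights
        ds = small_mag_dataset
        est_a = p.MLPRelaxometer(strategy="pinn", max_epochs=2, random_state=9)
        est_a.fit(ds)
        blinded = p.TrainingDataset(
            signals=ds.signals,
            targets=np.column_stack(
                [np.full(ds.n_samples, 1000.0), np.full(ds.n_samples, 70.0),
                 np.zeros(ds.n_samples), ds.targets[:, 3]]
            ).astype(np.float32),
            seq=ds.seq, distribution=ds.distribution, mode=ds.mode,
        )
        est_b = p.MLPRelaxometer(strategy="pinn", max_epochs=2, random_state=9)
        est_b.fit(blinded)
        for a, b in zip(est_a.params_, est_b.params_):
            np.testing.assert_array_equal(a, b)


class TestPhysicsInformedTraining:
    def test_pinn_reaches_coarse_accuracy_quickly(self, seq12):
        # reference run of this implementation: the self-supervised
        # estimator reaches single-digit-percent median accuracy within
        # tens of epochs; the frozen bound leaves seed margin
        rng = np.random.default_rng(21)
        ds = p.build_dataset(p.uniform_distribution(), 30_000, seq12,
                             "magnitude", rng)
        est = p.MLPRelaxometer(layout="magnitude", strategy="pinn",
                               seq=seq12, max_epochs=60, patience=60,
                               random_state=2)
        est.fit(ds)
        grid = p.build_test_grid("linear_grid", n_steps=20)
        sig = p.simulate_pc_signal(grid, seq12).values
        pred = est.predict_from_signal(sig, np.ones(len(grid.t1)))
        e1 = np.abs(pred[:, 0] - grid.t1) / grid.t1 * 100
        e2 = np.abs(pred[:, 1] - grid.t2) / grid.t2 * 100
        assert np.median(e1) < 15.0 and np.median(e2) < 15.0
        # and the validation loss descends substantially from epoch 1
        assert est.history_.val_loss[-1] < 0.2 * est.history_.val_loss[0]


class TestInference:
    def test_batch_invariance(self, small_mag_dataset):
        est = p.MLPRelaxometer(max_epochs=2, random_state=1)
        est.fit(small_mag_dataset)
        sig = small_mag_dataset.signals[:1000].astype(complex)
        b1 = small_mag_dataset.targets[:1000, 3].astype(float)
        full = est.predict_from_signal(sig, b1)
        single = est.predict_from_signal(sig[:1], b1[:1])
        np.testing.assert_allclose(single[0], full[0], rtol=1e-6)

    def test_feature_length_mismatch_rejected(self, small_mag_dataset):
        est = p.MLPRelaxometer(max_epochs=1, random_state=1)
        est.fit(small_mag_dataset)
        with pytest.raises(ValueError):
            est.predict(np.zeros((3, 6), dtype=np.float32))

    def test_sklearn_protocol(self, small_mag_dataset):
        from sklearn.base import clone

        est = p.MLPRelaxometer(max_epochs=1, random_state=1)
        params = est.get_params()
        assert params["strategy"] == "svnn"
        clone(est)  # must be cloneable for model selection
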