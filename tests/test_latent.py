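"""Dimensionality reduction, elbow selection and FC-based classification."""

import numpy as np
import pytest

from latentwb.latent import (
    NoElbowError,
    classify_conditions,
    detect_elbow,
    fit_linear_reduction,
    latent_fc,
    reconstruction_curve,
    resample_to_tr,
    select_latent_dim,
    split_fc_augment,
    train_autoencoder,
)
from latentwb.fitting import ssim
from latentwb.types import BoldTimeSeries, InputError, LatentTimeSeries, ParameterError


def linear_mixture_dataset(n_subjects, d_init=40, d_latent=5, T=120, noise_sd=0.0,
                           seed=0):
    """Subjects whose region signals are a shared linear mixture of
    d_latent independent AR(1) sources."""
    rng = np.random.default_rng(seed)
    M, _ = np.linalg.qr(rng.standard_normal((d_init, d_latent)))
    out = []
    for i in range(n_subjects):
        z = np.empty((d_latent, T))
        z[:, 0] = rng.standard_normal(d_latent)
        for t in range(1, T):
            z[:, t] = 0.8 * z[:, t - 1] + rng.standard_normal(d_latent)
        x = M @ z
        if noise_sd:
            x = x + noise_sd * rng.standard_normal(x.shape)
        out.append(BoldTimeSeries(x, tr=2.0, subject_id=f"s{i:02d}"))
    return out, M


class TestResample:
    def test_grid_length_preserves_duration(self):
        series = BoldTimeSeries(np.random.default_rng(0).random((3, 200)), tr=2.4)
        out = resample_to_tr(series, 2.0)
        assert out.n_timepoints == 240
        assert out.tr == 2.0

    def test_identity_when_tr_matches(self):
        series = BoldTimeSeries(np.random.default_rng(0).random((3, 50)), tr=2.0)
        assert resample_to_tr(series, 2.0) is series

    def test_linear_ramp_reproduced_exactly(self):
        t = np.arange(100) * 2.4
        series = BoldTimeSeries(np.vstack([3.0 * t + 1.0, -t]), tr=2.4)
        out = resample_to_tr(series, 2.0)
        t_new = np.arange(out.n_timepoints) * 2.0
        inside = t_new <= t[-1]
        np.testing.assert_allclose(out.data[0, inside], 3.0 * t_new[inside] + 1.0)
        np.testing.assert_allclose(out.data[1, inside], -t_new[inside])


class TestLinearReduction:
    def test_exact_on_low_rank_data(self):
        dataset, _ = linear_mixture_dataset(4, d_init=20, d_latent=2, T=80, seed=1)
        model = fit_linear_reduction(dataset, 2)
        assert model.training_mse == pytest.approx(0.0, abs=1e-12)

    def test_mse_equals_discarded_eigenvalue_sum(self):
        dataset, _ = linear_mixture_dataset(4, d_init=20, d_latent=8, T=200,
                                            noise_sd=0.3, seed=2)
        d_keep = 4
        model = fit_linear_reduction(dataset, d_keep)
        X = np.concatenate([s.data.T for s in dataset], axis=0)
        Xz = model.standardize(X)
        evals = np.linalg.eigvalsh(np.cov(Xz.T, bias=True))[::-1]
        expected = evals[d_keep:].sum() / Xz.shape[1]
        # PCA reconstruction error per element = discarded variance / d_init
        assert model.training_mse == pytest.approx(expected, rel=1e-6)

    def test_rank_exceeded_rejected(self):
        dataset, _ = linear_mixture_dataset(2, d_init=10, d_latent=2, T=50, seed=3)
        with pytest.raises(ParameterError):
            fit_linear_reduction(dataset, 9)


class TestAutoencoder:
    hyper = {"lr": 1e-3, "epochs": 150, "batch": 20}

    def test_recovers_linear_mixture(self):
        dataset, _ = linear_mixture_dataset(6, d_init=30, d_latent=4, T=100, seed=4)
        model = train_autoencoder(dataset, 4, hyper=self.hyper, seed=0)
        X = np.concatenate([s.data.T for s in dataset], axis=0)
        Xz = model.standardize(X)
        mse = np.mean((model.reconstruct(Xz) - Xz) ** 2)
        assert mse < 0.1 * Xz.var()

    def test_capacity_ordering(self):
        dataset, _ = linear_mixture_dataset(6, d_init=30, d_latent=8, T=100, seed=5)
        mses = {}
        for d in (2, 8):
            vals = []
            for seed in range(3):
                model = train_autoencoder(dataset, d, hyper=self.hyper, seed=seed)
                vals.append(model.training_mse)
            mses[d] = np.mean(vals)
        assert mses[8] < mses[2]

    def test_training_reproducible(self):
        dataset, _ = linear_mixture_dataset(3, d_init=20, d_latent=3, T=60, seed=6)
        h = {"lr": 1e-3, "epochs": 10, "batch": 20}
        a = train_autoencoder(dataset, 3, hyper=h, seed=7)
        b = train_autoencoder(dataset, 3, hyper=h, seed=7)
        assert a.training_mse == b.training_mse

    def test_latent_dim_too_large_rejected(self):
        dataset, _ = linear_mixture_dataset(2, d_init=10, d_latent=2, T=50, seed=8)
        with pytest.raises(ParameterError):
            train_autoencoder(dataset, 10)

    def test_encoder_layer_widths(self):
        dataset, _ = linear_mixture_dataset(2, d_init=40, d_latent=3, T=50, seed=9)
        model = train_autoencoder(dataset, 3, hyper={"epochs": 1}, seed=0)
        z = model.encode(model.standardize(dataset[0].data.T))
        assert z.shape == (50, 3)


class TestReconstructionCurve:
    def test_monotone_on_linear_data(self):
        curves = []
        for seed in range(3):
            dataset, _ = linear_mixture_dataset(10, d_init=20, d_latent=6, T=60,
                                                noise_sd=0.2, seed=10 + seed)
            curves.append(reconstruction_curve(dataset, [2, 4, 6, 8], k_folds=5,
                                               seed=seed, method="linear"))
        mean_curve = {d: np.mean([c[d] for c in curves]) for d in (2, 4, 6, 8)}
        vals = [mean_curve[d] for d in (2, 4, 6, 8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_same_seed_same_curve(self):
        dataset, _ = linear_mixture_dataset(8, d_init=15, d_latent=4, T=50, seed=13)
        a = reconstruction_curve(dataset, [2, 4], k_folds=4, seed=3, method="linear")
        b = reconstruction_curve(dataset, [2, 4], k_folds=4, seed=3, method="linear")
        assert a == b

    def test_fewer_subjects_than_folds_rejected(self):
        dataset, _ = linear_mixture_dataset(3, d_init=15, d_latent=4, T=50, seed=14)
        with pytest.raises(ParameterError):
            reconstruction_curve(dataset, [2], k_folds=5, seed=0)


class TestElbow:
    def test_perfect_hinge(self):
        curve = {d: max(0.0, 5.0 - d) + 0.5 for d in range(1, 11)}
        assert detect_elbow(curve) == 5

    def test_knee_at_fifteen(self):
        dims = list(range(2, 26))
        curve = {d: (15 - d) * 0.08 + 0.2 if d <= 15 else 0.2 - (d - 15) * 0.001
                 for d in dims}
        assert detect_elbow(curve) == 15

    def test_matches_brute_force_curvature_scan(self, rng):
        dims = np.arange(2, 21)
        mse = np.exp(-0.3 * dims) + 0.01 * rng.random(len(dims))
        curve = dict(zip(dims.tolist(), mse.tolist()))
        x = (dims - dims.min()) / (dims.max() - dims.min())
        y = (mse - mse.min()) / (mse.max() - mse.min())
        best = None
        for k in range(1, len(dims) - 1):
            c = y[k - 1] - 2 * y[k] + y[k + 1]
            if best is None or c > best[1]:
                best = (dims[k], c)
        assert detect_elbow(curve) == best[0]

    def test_monotone_increasing_signals_no_elbow(self):
        with pytest.raises(NoElbowError):
            detect_elbow({d: float(d) for d in range(1, 6)})


class TestLatentFC:
    def test_identical_rows_correlate_fully(self):
        row = np.sin(np.linspace(0, 10, 50))
        series = LatentTimeSeries(np.vstack([row, row]), tr=2.0)
        fc = latent_fc(series)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_antiphase_sinusoids(self):
        t = np.linspace(0, 20 * np.pi, 400)
        series = LatentTimeSeries(np.vstack([np.sin(t), -np.sin(t)]), tr=2.0)
        assert latent_fc(series)[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        T = 5000
        series = LatentTimeSeries(rng.standard_normal((4, T)), tr=2.0)
        fc = latent_fc(series)
        off = fc[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(T))

    def test_fc_invariants(self, rng):
        series = LatentTimeSeries(rng.standard_normal((6, 100)), tr=2.0)
        fc = latent_fc(series)
        np.testing.assert_allclose(fc, fc.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(fc), 1.0)
        assert np.all(np.abs(fc) <= 1 + 1e-12)

    def test_zero_variance_rejected(self):
        series = LatentTimeSeries(np.vstack([np.ones(50), np.random.default_rng(0).random(50)]), tr=2.0)
        with pytest.raises(InputError):
            latent_fc(series)


class TestSplitAugment:
    def test_window_arithmetic(self, rng):
        series = LatentTimeSeries(rng.standard_normal((5, 300)), tr=2.0)
        fcs = split_fc_augment(series, 4)
        assert len(fcs) == 4
        assert all(fc.shape == (5, 5) for fc in fcs)

    def test_single_split_equals_latent_fc(self, rng):
        series = LatentTimeSeries(rng.standard_normal((5, 100)), tr=2.0)
        np.testing.assert_allclose(split_fc_augment(series, 1)[0], latent_fc(series))

    def test_stationary_series_splits_agree(self):
        rng = np.random.default_rng(2)
        d, T = 8, 1200
        M = rng.standard_normal((d, d)) * 0.4 + np.eye(d)
        z = np.empty((d, T))
        z[:, 0] = rng.standard_normal(d)
        for t in range(1, T):
            z[:, t] = 0.7 * z[:, t - 1] + M @ rng.standard_normal(d) * 0.3
        series = LatentTimeSeries(z, tr=2.0)
        fcs = split_fc_augment(series, 4)
        for i in range(4):
            for j in range(i + 1, 4):
                assert ssim(fcs[i], fcs[j]) > 0.5

    def test_too_short_rejected(self, rng):
        with pytest.raises(InputError):
            split_fc_augment(LatentTimeSeries(rng.random((3, 6)), tr=2.0), 4)


class TestClassification:
    @staticmethod
    def _fc_cohort(separable=True, seed=0, n_per_class=6, n_splits=4):
        """FC matrices per subject from planted class-dependent structure."""
        rng = np.random.default_rng(seed)
        fcs, labels, subjects = [], [], []
        offsets = {"A": 0.6, "B": 0.0, "C": -0.6} if separable else \
                  {"A": 0.0, "B": 0.0, "C": 0.0}
        for label, off in offsets.items():
            for s in range(n_per_class):
                sid = f"{label}{s}"
                base = np.clip(off + 0.1 * rng.standard_normal((6, 6)), -0.99, 0.99)
                for _ in range(n_splits):
                    fc = (base + base.T) / 2 + 0.02 * rng.standard_normal((6, 6))
                    fc = (fc + fc.T) / 2
                    np.fill_diagonal(fc, 1.0)
                    fcs.append(fc)
                    labels.append(label)
                    subjects.append(sid)
        return fcs, labels, subjects

    def test_separable_classes_perfect_accuracy(self):
        fcs, labels, subjects = self._fc_cohort(separable=True, seed=1)
        acc = classify_conditions(fcs, labels, subjects)
        assert acc == 1.0

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(3)
        accs = []
        for rep in range(20):
            fcs, labels, subjects = self._fc_cohort(separable=True, seed=rep)
            # permute SUBJECT labels (keeping each subject's splits together)
            ids = sorted(set(subjects))
            perm = dict(zip(ids, rng.permutation([l for l, s in
                                                  {s: l for s, l in zip(subjects, labels)}.items()
                                                  for _ in [0]])))
            # simpler: shuffle label per subject
            by_subject = {}
            for s, l in zip(subjects, labels):
                by_subject[s] = l
            shuffled_values = rng.permutation(list(by_subject.values()))
            shuffled = dict(zip(by_subject.keys(), shuffled_values))
            new_labels = [shuffled[s] for s in subjects]
            accs.append(classify_conditions(fcs, new_labels, subjects))
        # 3 balanced classes: mean accuracy within the binomial CI around 1/3
        mean_acc = np.mean(accs)
        n_eff = 20 * 18  # subjects scored per repetition
        assert abs(mean_acc - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n_eff) + 0.05

    def test_two_clique_cohort_above_chance(self):
        from latentwb.synthetic import generate_latent_cohort

        presets = {}
        for cond, neg in (("CNT", 0.3), ("MCS", 0.9), ("UWS", 1.8)):
            presets[cond] = dict(clique_split=(8, 7), pos_density=0.66,
                                 neg_density=0.5, pos_scale=1.5, neg_scale=neg)
        cohort = generate_latent_cohort(
            10, "ahp", duration_s=300, tr_s=2.0, seed=17, group_presets=presets,
            node_params=dict(sigma=5.0, X_eq=0.088, Y_eq=1.0, T_h=-30.0,
                             tau_mAHP=0.15, tau_sAHP=5.0),
            draw_params=False)
        fcs, labels, subjects = [], [], []
        for sub in cohort:
            for fc in split_fc_augment(sub.latent_series, 4):
                fcs.append(fc)
                labels.append(sub.condition)
                subjects.append(sub.subject_id)
        acc = classify_conditions(fcs, labels, subjects)
        assert acc > 1 / 3 + 0.15

    def test_subject_never_straddles_folds(self):
        # leakage guard: classify_conditions holds out whole subjects; the
        # accuracy on duplicated FCs of a subject must not benefit from its
        # own copies (they are all in the test fold together)
        fcs, labels, subjects = self._fc_cohort(separable=False, seed=5,
                                                n_per_class=4)
        acc = classify_conditions(fcs, labels, subjects)
        assert 0.0 <= acc <= 1.0


class TestSelectLatentDim:
    def test_smallest_dimension_matching_natural_accuracy(self):
        assert select_latent_dim({10: 0.7, 15: 0.85}, 0.82) == 15

    def test_all_dims_qualify_takes_smallest(self):
        assert select_latent_dim({5: 0.9, 10: 0.95}, 0.8) == 5

    def test_none_qualifies(self):
        assert select_latent_dim({5: 0.5, 10: 0.6}, 0.9) is None

    def test_tolerance_relaxes_threshold(self):
        assert select_latent_dim({5: 0.78, 10: 0.85}, 0.8, tolerance=0.05) == 5
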