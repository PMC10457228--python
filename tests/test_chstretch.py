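import numpy as np
import pytest

from ramanmap.chstretch import (
    DegenerateSpectrumError,
    EMSCModel,
    ModelSelectionResult,
    PCALDAModel,
    emsc_correct,
    emsc_correct_many,
    fit_pcalda,
    pca_rgb_map,
    restrict_window,
    select_pc_count,
    sg_filter,
    validate,
)
from ramanmap.evaluation import roc
from ramanmap.io_formats import AnalysisConfig

WINDOW_AXIS = np.arange(2800.0, 3102.0, 2.0)


def _reference():
    return np.exp(-0.5 * ((WINDOW_AXIS - 2930.0) / 30.0) ** 2) + 0.5 * np.exp(
        -0.5 * ((WINDOW_AXIS - 2850.0) / 20.0) ** 2
    )


def _water_tail():
    g = np.exp(-0.5 * ((WINDOW_AXIS - 3400.0) / 110.0) ** 2)
    g[WINDOW_AXIS < 3000.0] = 0.0
    return g


@pytest.fixture()
def emsc_model():
    return EMSCModel(
        axis=WINDOW_AXIS,
        reference=_reference(),
        interferents=_water_tail()[None, :],
        baseline_order=1,
    )


class TestEMSC:
    def test_reference_is_fixed_point(self, emsc_model):
        out = emsc_correct(_reference(), emsc_model)
        np.testing.assert_allclose(out, _reference(), atol=1e-10)

    def test_recovers_known_mixture(self, emsc_model):
        """s = 2m + 0.3·g_water maps back to m exactly."""
        s = 2.0 * _reference() + 0.3 * _water_tail()
        np.testing.assert_allclose(
            emsc_correct(s, emsc_model), _reference(), atol=1e-9
        )

    def test_offset_absorbed_by_baseline(self, emsc_model):
        out = emsc_correct(_reference() + 5.0, emsc_model)
        np.testing.assert_allclose(out, _reference(), atol=1e-9)

    def test_multiplicative_scale_invariance(self, emsc_model, rng):
        s = _reference() + 0.05 * rng.standard_normal(WINDOW_AXIS.size)
        base = emsc_correct(s, emsc_model)
        for kappa in (0.2, 3.0, 17.0):
            np.testing.assert_allclose(
                emsc_correct(kappa * s, emsc_model), base, atol=1e-8
            )

    def test_water_interferent_invariance(self, emsc_model, rng):
        """Adding any multiple of the water interferent leaves the
        corrected spectrum unchanged — the operational sense in which the
        compositional analysis is independent of the water signal."""
        s = _reference() + 0.05 * rng.standard_normal(WINDOW_AXIS.size)
        base = emsc_correct(s, emsc_model)
        for c in (0.1, 1.0, 2.0):
            out = emsc_correct(s + c * _water_tail(), emsc_model)
            rms = np.sqrt(np.mean((out - base) ** 2))
            assert rms < 1e-8

    def test_degenerate_spectrum_flagged(self, emsc_model):
        with pytest.raises(DegenerateSpectrumError):
            emsc_correct(np.zeros(WINDOW_AXIS.size), emsc_model)
        corrected, ok = emsc_correct_many(
            np.vstack([_reference(), np.zeros(WINDOW_AXIS.size)]), emsc_model
        )
        assert ok.tolist() == [True, False]

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            EMSCModel(
                axis=WINDOW_AXIS,
                reference=np.ones(WINDOW_AXIS.size),  # collinear with baseline
                interferents=np.empty((0, WINDOW_AXIS.size)),
                baseline_order=1,
            )

    def test_batch_matches_single(self, emsc_model, rng):
        X = _reference() + 0.1 * rng.standard_normal((5, WINDOW_AXIS.size))
        batch, ok = emsc_correct_many(X, emsc_model)
        assert ok.all()
        for i in range(5):
            np.testing.assert_allclose(
                batch[i], emsc_correct(X[i], emsc_model), atol=1e-10
            )


class TestSavitzkyGolay:
    def test_reproduces_cubic_polynomial(self, cfg):
        u = np.linspace(-1, 1, WINDOW_AXIS.size)
        s = 1.0 - 2.0 * u + 0.5 * u**2 + 3.0 * u**3
        np.testing.assert_allclose(sg_filter(s, cfg), s, atol=1e-10)

    def test_constant_unchanged(self, cfg):
        s = np.full(WINDOW_AXIS.size, 7.0)
        np.testing.assert_allclose(sg_filter(s, cfg), s, atol=1e-12)

    def test_impulse_response_matches_published_coefficients(self, cfg):
        """The interior impulse response is the classical order-2/3,
        window-11 smoothing kernel (−36, 9, 44, 69, 84, 89, …)/429."""
        s = np.zeros(101)
        s[50] = 1.0
        out = sg_filter(s, cfg)
        published = np.array(
            [-36, 9, 44, 69, 84, 89, 84, 69, 44, 9, -36], dtype=float
        ) / 429.0
        np.testing.assert_allclose(out[45:56], published, atol=1e-12)

    def test_noise_variance_contracts(self, rng):
        cfg = AnalysisConfig()
        noise = rng.standard_normal(1000)
        out = sg_filter(noise, cfg)
        assert out.var() < noise.var()

    def test_window_longer_than_spectrum_rejected(self, cfg):
        with pytest.raises(ValueError, match="window"):
            sg_filter(np.ones(7), cfg)


class TestPcaRgbMap:
    def test_two_regions_separate_in_color(self, rng):
        """Within-region channel variance is below between-region variance
        for two distinct noise-free profiles."""
        a = _reference()
        b = _reference()[::-1]
        spectra = np.empty((4, 6, WINDOW_AXIS.size))
        spectra[:, :3] = a + 0.001 * rng.standard_normal((4, 3, WINDOW_AXIS.size))
        spectra[:, 3:] = b + 0.001 * rng.standard_normal((4, 3, WINDOW_AXIS.size))
        rgb = pca_rgb_map(spectra, np.ones((4, 6), bool))
        ch0 = rgb[:, :, 0]
        within = ch0[:, :3].var() + ch0[:, 3:].var()
        between = (ch0[:, :3].mean() - ch0[:, 3:].mean()) ** 2
        assert within < between

    def test_identical_spectra_render_mid_gray(self):
        spectra = np.tile(_reference(), (3, 3, 1))
        rgb = pca_rgb_map(spectra, np.ones((3, 3), bool))
        np.testing.assert_allclose(rgb, 0.5)

    def test_channels_in_unit_interval_and_invalid_black(self, rng):
        spectra = rng.uniform(0, 1, size=(5, 5, WINDOW_AXIS.size))
        valid = np.ones((5, 5), bool)
        valid[0, 0] = False
        rgb = pca_rgb_map(spectra, valid)
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0
        np.testing.assert_array_equal(rgb[0, 0], 0.0)

    def test_too_few_valid_pixels_rejected(self):
        spectra = np.tile(_reference(), (2, 1, 1))
        with pytest.raises(ValueError, match="at least 3"):
            pca_rgb_map(spectra, np.array([[True], [False]]))


def _two_class_spectra(rng, n=60, sep=4.0, channels=None):
    channels = channels or WINDOW_AXIS.size
    base = rng.standard_normal(channels)
    direction = rng.standard_normal(channels)
    direction /= np.linalg.norm(direction)
    X0 = base + rng.standard_normal((n, channels))
    X1 = base + sep * direction + rng.standard_normal((n, channels))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    return X, y


class TestFitPcaLda:
    def test_separable_classes_reach_training_auc_one(self, rng):
        X, y = _two_class_spectra(rng, sep=20.0)
        model = fit_pcalda(X, y, p=3)
        assert roc(model.score(X), y).auc == 1.0
        assert model.threshold is not None

    def test_shuffled_labels_stay_near_chance(self, rng):
        X, _ = _two_class_spectra(rng, n=250, sep=0.0)
        y = rng.permutation(np.r_[np.zeros(250, bool), np.ones(250, bool)])
        model = fit_pcalda(X, y, p=3)
        auc = roc(model.score(X), y).auc
        assert 0.5 <= auc <= 0.65

    def test_tumor_scores_oriented_positive(self, rng):
        X, y = _two_class_spectra(rng, sep=6.0)
        model = fit_pcalda(X, y, p=2)
        s = model.score(X)
        assert s[y].mean() > s[~y].mean()

    def test_single_pc_matches_brute_force_lda(self, rng):
        """p=1 equals an independent eigen-based LDA on PC1 scores."""
        X, y = _two_class_spectra(rng, sep=3.0)
        model = fit_pcalda(X, y, p=1)
        # brute force: PC1 via eigh of the covariance, then 1-D Fisher.
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        pc1 = evecs[:, np.argmax(evals)]
        t = Xc @ pc1
        # 1-D Fisher direction is just the sign of the mean difference.
        sgn = np.sign(t[y].mean() - t[~y].mean())
        brute = sgn * t
        main = model.score(X)
        assert roc(main, y).auc == pytest.approx(roc(brute, y).auc, abs=1e-12)

    def test_missing_class_rejected(self, rng):
        X, y = _two_class_spectra(rng)
        with pytest.raises(ValueError, match="both classes"):
            fit_pcalda(X, np.zeros_like(y), p=2)

    def test_model_json_round_trip(self, rng, tmp_path):
        X, y = _two_class_spectra(rng, sep=5.0)
        model = fit_pcalda(X, y, p=3, training_patients=("pa", "pb"))
        model.to_json(tmp_path / "model.json")
        model2 = PCALDAModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(model2.score(X), model.score(X), atol=1e-12)
        assert model2.training_patients == ("pa", "pb")


def _toy_maps(rng, n_maps=3, n=40, sep=2.0, channels=30):
    maps = []
    direction = rng.standard_normal(channels)
    direction /= np.linalg.norm(direction)
    for k in range(n_maps):
        X0 = rng.standard_normal((n, channels))
        X1 = sep * direction + rng.standard_normal((n, channels))
        maps.append(
            (
                np.vstack([X0, X1]),
                np.r_[np.zeros(n, bool), np.ones(n, bool)],
                f"map{k}",
            )
        )
    return maps


def _brute_force_lomo_auc(maps, p):
    """Independent leave-one-map-out pooled AUC: plain loops, eigh-based
    PCA and explicit scatter matrices."""
    scores, labels = [], []
    for k in range(len(maps)):
        X = np.vstack([m[0] for i, m in enumerate(maps) if i != k])
        y = np.concatenate([m[1] for i, m in enumerate(maps) if i != k])
        mean = X.mean(axis=0)
        Xc = X - mean
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][:p]
        V = evecs[:, order]
        T = Xc @ V
        mu1, mu0 = T[y].mean(axis=0), T[~y].mean(axis=0)
        d1, d0 = T[y] - mu1, T[~y] - mu0
        w = np.linalg.solve(d1.T @ d1 + d0.T @ d0, mu1 - mu0)
        w /= np.linalg.norm(w)
        raw = T @ w
        if raw[y].mean() < raw[~y].mean():
            w, raw = -w, -raw
        offset = 0.5 * (raw[y].mean() + raw[~y].mean())
        n1, n0 = y.sum(), (~y).sum()
        pooled = (raw[y].var(ddof=1) * (n1 - 1) + raw[~y].var(ddof=1) * (n0 - 1)) / (
            n1 + n0 - 2
        )
        scale = np.sqrt(pooled)
        held = ((maps[k][0] - mean) @ V @ w - offset) / scale
        scores.append(held)
        labels.append(maps[k][1])
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    # Mann-Whitney AUC by pair counting.
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return wins / (pos.size * neg.size)


class TestSelectPcCount:
    def test_identical_separable_maps_choose_smallest_p(self, rng):
        one = _toy_maps(rng, n_maps=1, sep=25.0)[0]
        maps = [(one[0], one[1], "a"), (one[0].copy(), one[1].copy(), "b")]
        result = select_pc_count(maps, max_p=5)
        assert np.allclose(result.pooled_auc, 1.0)
        assert result.chosen_p == 1  # tie → parsimony

    def test_auc_table_covers_all_candidates(self, rng):
        result = select_pc_count(_toy_maps(rng), max_p=7)
        assert result.candidate_p.tolist() == list(range(1, 8))
        assert result.pooled_auc.shape == (7,)

    def test_pooled_auc_matches_brute_force_oracle(self, rng):
        maps = _toy_maps(rng, n_maps=3, n=30, sep=1.5)
        result = select_pc_count(maps, max_p=4)
        for p in (1, 2, 3, 4):
            assert result.pooled_auc[p - 1] == pytest.approx(
                _brute_force_lomo_auc(maps, p), abs=1e-9
            )

    def test_fold_missing_class_is_skipped_with_warning(self, rng):
        """Holding out the only map that carries both classes leaves a
        single-class training arm: the fold is skipped with a warning and
        the pooled cross-validation is reported as undefined."""
        maps = _toy_maps(rng, n_maps=1)
        all_tumor = (
            rng.standard_normal((20, 30)),
            np.ones(20, bool),
            "tumor_only",
        )
        with pytest.warns(UserWarning, match="lost a class"):
            with pytest.raises(ValueError, match="single class"):
                select_pc_count([maps[0], all_tumor], max_p=2)

    def test_single_map_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            select_pc_count(_toy_maps(rng, n_maps=1), max_p=3)


class TestValidate:
    def test_training_scores_reproduced_deterministically(self, rng):
        maps = _toy_maps(rng, n_maps=2, sep=3.0)
        X = np.vstack([m[0] for m in maps])
        y = np.concatenate([m[1] for m in maps])
        model = fit_pcalda(X, y, p=2, training_patients=("pa",))
        s1 = model.score(X)
        s2 = model.score(X)
        np.testing.assert_array_equal(s1, s2)

    def test_patient_overlap_rejected(self, rng):
        X, y = _two_class_spectra(rng, n=20, channels=30)
        model = fit_pcalda(X, y, p=2, training_patients=("pa", "pb"))
        with pytest.raises(ValueError, match="overlap"):
            validate(model, [(X, y, "m1", "pb")])

    def test_single_class_test_map_scored_without_auc(self, rng):
        X, y = _two_class_spectra(rng, n=20, channels=30)
        model = fit_pcalda(X, y, p=2, training_patients=("pa",))
        out = validate(model, [(X[:10], np.zeros(10, bool), "m1", "pz")])
        assert out["scores"].shape == (10,)
        with pytest.raises(ValueError, match="both classes"):
            roc(out["scores"], out["labels"])
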