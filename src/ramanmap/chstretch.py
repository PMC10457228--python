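"""CH-stretching-region analysis: EMSC, smoothing, PCA maps and PCA-LDA.

The compositional analysis works on the 2800–3100 cm⁻¹ window.  Each
spectrum is first normalized by extended multiplicative scatter correction
(EMSC) against the dataset mean, with a pure-water spectrum as interferent
so that varying water content cannot influence the result, then smoothed
with a Savitzky-Golay filter (order 3, window 11).  Classification is
Fisher LDA on the scores of the first *p* principal components; *p* is
chosen by leave-one-map-out validation (pooled AUC, smallest *p* on ties)
and the final model is validated on maps from held-back patients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from ramanmap.evaluation import roc, youden_point
from ramanmap.io_formats import AnalysisConfig, AnnotationMask, SpectralMap


class DegenerateSpectrumError(ValueError):
    """EMSC scale coefficient vanished: the spectrum carries no signal
    resembling the reference and must be flagged invalid."""


def restrict_window(
    spectra: np.ndarray, axis: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Slice spectra (…, channels) and axis to a wavenumber window."""
    sel = (axis >= window[0]) & (axis <= window[1])
    return axis[sel], spectra[..., sel]


@dataclass
class EMSCModel:
    """EMSC correction model on the CH window.

    Each spectrum s is fit as ``s ≈ Σ_k d_k·u^k + b·m + Σ_i c_i·g_i`` with
    reference m (mean analysis spectrum), interferents g_i (pure water)
    and a baseline polynomial of order ``baseline_order`` in the scaled
    abscissa u; the corrected spectrum ``(s − baseline − Σ c_i g_i)/b``
    keeps the residual and is invariant both to multiplicative scaling and
    to adding any multiple of an interferent.
    """

    axis: np.ndarray
    reference: np.ndarray
    interferents: np.ndarray  # (n_interferents, channels); may be empty
    baseline_order: int = 1
    _design: np.ndarray = field(init=False, repr=False)
    _n_baseline: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.interferents = np.atleast_2d(np.asarray(self.interferents, dtype=float))
        if self.interferents.size == 0:
            self.interferents = np.empty((0, self.axis.size))
        if self.reference.size != self.axis.size or (
            self.interferents.shape[1] != self.axis.size
        ):
            raise ValueError("reference/interferents must match the window axis")
        u = 2.0 * (self.axis - self.axis[0]) / (self.axis[-1] - self.axis[0]) - 1.0
        baseline = np.vstack([u**k for k in range(self.baseline_order + 1)])
        self._n_baseline = baseline.shape[0]
        design = np.vstack([baseline, self.reference[None, :], self.interferents]).T
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("EMSC design matrix is rank-deficient")
        self._design = design

    @classmethod
    def build(
        cls,
        spectra: np.ndarray,
        axis: np.ndarray,
        interferents: np.ndarray | None = None,
        baseline_order: int = 1,
    ) -> "EMSCModel":
        """Build the model with the mean of ``spectra`` as reference."""
        spectra = np.atleast_2d(spectra)
        reference = spectra.mean(axis=0)
        if interferents is None:
            interferents = np.empty((0, axis.size))
        return cls(
            axis=axis,
            reference=reference,
            interferents=interferents,
            baseline_order=baseline_order,
        )


def emsc_correct(spectrum: np.ndarray, model: EMSCModel) -> np.ndarray:
    """Apply EMSC to one window-restricted spectrum.

    Raises :class:`DegenerateSpectrumError` when the fitted reference
    coefficient b is below 1e-8 (no recognizable signal).
    """
    s = np.asarray(spectrum, dtype=float)
    coeffs, *_ = np.linalg.lstsq(model._design, s, rcond=None)
    b = coeffs[model._n_baseline]
    if b < 1e-8:
        raise DegenerateSpectrumError(f"EMSC scale coefficient b={b:.3g}")
    nuisance = model._design @ coeffs - b * model.reference
    return (s - nuisance) / b


def emsc_correct_many(spectra: np.ndarray, model: EMSCModel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EMSC over rows; returns (corrected, ok_flags).

    Degenerate rows are returned as zeros with ``ok=False`` instead of
    raising, so map-level processing can flag pixels invalid.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    coeffs, *_ = np.linalg.lstsq(model._design, X.T, rcond=None)
    b = coeffs[model._n_baseline]
    ok = b >= 1e-8
    safe_b = np.where(ok, b, 1.0)
    nuisance = (model._design @ coeffs).T - np.outer(b, model.reference)
    corrected = (X - nuisance) / safe_b[:, None]
    corrected[~ok] = 0.0
    return corrected, ok


def sg_filter(spectra: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Savitzky-Golay smoothing (default order 3, window 11) along the last
    axis; edges are handled by the polynomial fit on the one-sided window.

    A cubic polynomial input is reproduced exactly (to rounding), which is
    the defining property of the order-3 filter.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] < cfg.sg_window:
        raise ValueError("SG window exceeds the spectrum length")
    return savgol_filter(spectra, cfg.sg_window, cfg.sg_order, axis=-1, mode="interp")


def pca_rgb_map(
    map_spectra: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Render one map's corrected spectra as an RGB image.

    A per-map PCA is fit on the valid spectra; the scores on PCs 1–3 are
    min-max scaled to [0, 1] and used as the red, green and blue channels.
    Invalid pixels are black; a zero-variance map renders mid-gray.
    """
    rows, cols, channels = map_spectra.shape
    flat = map_spectra.reshape(-1, channels)
    v = np.asarray(valid, dtype=bool).ravel()
    n_valid = int(v.sum())
    if n_valid < 3:
        raise ValueError("need at least 3 valid spectra for an RGB map")
    X = flat[v]
    rgb = np.zeros((rows * cols, 3))
    if np.allclose(X.var(axis=0).sum(), 0.0):
        rgb[v] = 0.5
        return rgb.reshape(rows, cols, 3)
    n_comp = min(3, n_valid - 1, channels)
    scores = PCA(n_components=n_comp).fit_transform(X)
    for ch in range(3):
        col = scores[:, ch] if ch < n_comp else np.zeros(n_valid)
        span = col.max() - col.min()
        rgb[v, ch] = 0.5 if span == 0 else (col - col.min()) / span
    return rgb.reshape(rows, cols, 3)


def _fisher_direction(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction w ∝ S_w⁻¹(μ₁ − μ₀) on PC scores.

    A ridge of 1e-8·trace(S_w)/p is added when the within-class scatter is
    singular (logged as a warning).
    """
    y = labels.astype(bool)
    mu1 = scores[y].mean(axis=0)
    mu0 = scores[~y].mean(axis=0)
    d1 = scores[y] - mu1
    d0 = scores[~y] - mu0
    sw = d1.T @ d1 + d0.T @ d0
    diff = mu1 - mu0
    try:
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        p = sw.shape[0]
        ridge = 1e-8 * np.trace(sw) / p
        warnings.warn("singular within-class scatter; adding ridge", stacklevel=2)
        w = np.linalg.solve(sw + ridge * np.eye(p), diff)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


@dataclass
class PCALDAModel:
    """PCA-LDA tumor classifier on the CH window.

    ``score`` projects a corrected, smoothed spectrum onto the first ``p``
    principal components and then onto the Fisher direction; scores are
    standardized with the training midpoint and within-class spread so
    they are comparable across refits, and oriented so tumor is positive.
    """

    axis: np.ndarray
    pca_mean: np.ndarray
    loadings: np.ndarray  # (p, channels), orthonormal rows
    p: int
    lda_weights: np.ndarray  # (p,)
    score_offset: float
    score_scale: float
    threshold: float = float("nan")
    training_maps: tuple[str, ...] = ()
    training_patients: tuple[str, ...] = ()

    def score(self, spectra: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        pc_scores = (X - self.pca_mean) @ self.loadings.T
        raw = pc_scores @ self.lda_weights
        return (raw - self.score_offset) / self.score_scale

    def to_json(self, path: str | Path) -> None:
        data = {
            "axis": self.axis.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "loadings": self.loadings.tolist(),
            "p": self.p,
            "lda_weights": self.lda_weights.tolist(),
            "score_offset": self.score_offset,
            "score_scale": self.score_scale,
            "threshold": self.threshold,
            "training_maps": list(self.training_maps),
            "training_patients": list(self.training_patients),
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCALDAModel":
        data = json.loads(Path(path).read_text())
        return cls(
            axis=np.array(data["axis"]),
            pca_mean=np.array(data["pca_mean"]),
            loadings=np.array(data["loadings"]),
            p=int(data["p"]),
            lda_weights=np.array(data["lda_weights"]),
            score_offset=float(data["score_offset"]),
            score_scale=float(data["score_scale"]),
            threshold=float(data["threshold"]),
            training_maps=tuple(data["training_maps"]),
            training_patients=tuple(data["training_patients"]),
        )


def fit_pcalda(
    train_spectra: np.ndarray,
    train_labels: np.ndarray,
    p: int,
    axis: np.ndarray | None = None,
    training_maps: tuple[str, ...] = (),
    training_patients: tuple[str, ...] = (),
) -> PCALDAModel:
    """Fit the PCA-LDA classifier on pooled training spectra.

    PCA is mean-centered (not autoscaled); LDA is the Fisher direction on
    the first ``p`` component scores, oriented so tumor scores are higher.
    The decision threshold is the Youden point of the training ROC.
    """
    X = np.atleast_2d(np.asarray(train_spectra, dtype=float))
    y = np.asarray(train_labels, dtype=bool).ravel()
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present in training data")
    if not 1 <= p <= min(X.shape[0] - 2, X.shape[1]):
        raise ValueError(f"invalid PC count p={p} for {X.shape[0]} spectra")
    pca = PCA(n_components=p).fit(X)
    scores = pca.transform(X)
    w = _fisher_direction(scores, y)
    raw = scores @ w
    if raw[y].mean() < raw[~y].mean():
        w = -w
        raw = -raw
    # Standardize: zero at the class-mean midpoint, unit pooled
    # within-class spread — keeps scores comparable across CV folds.
    offset = 0.5 * (raw[y].mean() + raw[~y].mean())
    n1, n0 = int(y.sum()), int((~y).sum())
    pooled_var = (
        raw[y].var(ddof=1) * (n1 - 1) + raw[~y].var(ddof=1) * (n0 - 1)
    ) / max(n1 + n0 - 2, 1)
    scale = float(np.sqrt(pooled_var)) if pooled_var > 0 else 1.0
    model = PCALDAModel(
        axis=np.asarray(axis) if axis is not None else np.arange(X.shape[1], dtype=float),
        pca_mean=pca.mean_,
        loadings=pca.components_,
        p=p,
        lda_weights=w,
        score_offset=float(offset),
        score_scale=scale,
        training_maps=training_maps,
        training_patients=training_patients,
    )
    final = model.score(X)
    curve = roc(final, y)
    model.threshold = youden_point(curve)["threshold"]
    return model


@dataclass
class ModelSelectionResult:
    """Leave-one-map-out AUC for each candidate PC count."""

    candidate_p: np.ndarray
    pooled_auc: np.ndarray
    chosen_p: int
    pooled_scores: dict[int, np.ndarray] = field(default_factory=dict)
    pooled_labels: np.ndarray | None = None


def select_pc_count(
    model_maps: list[tuple[np.ndarray, np.ndarray, str]],
    max_p: int,
    axis: np.ndarray | None = None,
) -> ModelSelectionResult:
    """Choose the PC count by leave-one-map-out validation.

    For each candidate p, every map is held out in turn, the classifier is
    refit on the remaining maps, and the held-out spectra are scored; the
    pooled held-out scores give one AUC per p.  The chosen p maximizes the
    pooled AUC, with ties broken toward the smallest p (parsimony).  Folds
    whose training arm loses a class are skipped with a warning.
    """
    if len(model_maps) < 2:
        raise ValueError("need at least 2 maps for leave-one-map-out")
    n_total = sum(s.shape[0] for s, _, _ in model_maps)
    channels = model_maps[0][0].shape[1]
    max_p = min(max_p, channels)

    fold_scores: dict[int, list[np.ndarray]] = {p: [] for p in range(1, max_p + 1)}
    fold_labels: list[np.ndarray] = []
    n_folds_used = 0
    for k, (held_X, held_y, held_id) in enumerate(model_maps):
        train = [m for j, m in enumerate(model_maps) if j != k]
        X = np.vstack([s for s, _, _ in train])
        y = np.concatenate([lab for _, lab, _ in train]).astype(bool)
        if y.sum() == 0 or (~y).sum() == 0:
            warnings.warn(
                f"fold {held_id}: training arm lost a class; fold skipped",
                stacklevel=2,
            )
            continue
        p_cap = min(max_p, X.shape[0] - 2)
        pca = PCA(n_components=p_cap).fit(X)
        train_scores = pca.transform(X)
        held_scores = pca.transform(np.atleast_2d(held_X))
        for p in range(1, max_p + 1):
            pp = min(p, p_cap)
            w = _fisher_direction(train_scores[:, :pp], y)
            raw = train_scores[:, :pp] @ w
            if raw[y].mean() < raw[~y].mean():
                w = -w
                raw = -raw
            offset = 0.5 * (raw[y].mean() + raw[~y].mean())
            n1, n0 = int(y.sum()), int((~y).sum())
            pooled_var = (
                raw[y].var(ddof=1) * (n1 - 1) + raw[~y].var(ddof=1) * (n0 - 1)
            ) / max(n1 + n0 - 2, 1)
            scale = float(np.sqrt(pooled_var)) if pooled_var > 0 else 1.0
            held = (held_scores[:, :pp] @ w - offset) / scale
            fold_scores[p].append(held)
        fold_labels.append(np.asarray(held_y, dtype=bool))
        n_folds_used += 1

    if n_folds_used == 0:
        raise ValueError("every leave-one-map-out fold was skipped")

    labels = np.concatenate(fold_labels)
    if labels.all() or not labels.any():
        raise ValueError(
            "pooled held-out labels contain a single class "
            "(a class present in only one map cannot be cross-validated)"
        )
    candidate_p = np.arange(1, max_p + 1)
    pooled_auc = np.empty(max_p)
    pooled_scores: dict[int, np.ndarray] = {}
    for p in candidate_p:
        s = np.concatenate(fold_scores[p])
        pooled_scores[int(p)] = s
        pooled_auc[p - 1] = roc(s, labels).auc
    chosen = int(candidate_p[int(np.argmax(pooled_auc))])  # argmax → first max
    return ModelSelectionResult(
        candidate_p=candidate_p,
        pooled_auc=pooled_auc,
        chosen_p=chosen,
        pooled_scores=pooled_scores,
        pooled_labels=labels,
    )


def validate(
    model: PCALDAModel, test_maps: list[tuple[np.ndarray, np.ndarray, str, str]]
) -> dict[str, object]:
    """Score an independent test set with a frozen model.

    ``test_maps`` entries are (spectra, labels, map_id, patient_id).
    Raises when any test patient appears among the training patients —
    this guards the independence claim.  Returns pooled scores and labels
    plus per-map scores; no refitting happens here.
    """
    overlap = {pid for *_, pid in test_maps} & set(model.training_patients)
    if overlap:
        raise ValueError(f"test patients overlap training patients: {sorted(overlap)}")
    per_map: dict[str, np.ndarray] = {}
    scores_all: list[np.ndarray] = []
    labels_all: list[np.ndarray] = []
    for X, y, map_id, _pid in test_maps:
        s = model.score(X)
        per_map[map_id] = s
        scores_all.append(s)
        labels_all.append(np.asarray(y, dtype=bool))
    return {
        "scores": np.concatenate(scores_all),
        "labels": np.concatenate(labels_all),
        "per_map": per_map,
    }
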