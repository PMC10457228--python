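"""Synthetic hyperspectral Raman tissue scenes.

Generates spectral maps with the statistical structure the analysis
assumes — per-tissue CH-stretching band profiles, a broad OH water band
whose amplitude encodes a tissue-specific water fraction, smooth
fluorescence backgrounds, cosmic-ray spikes and shot noise — so every
downstream stage is testable without measured data.

Forward model per pixel (tissue type t, water mass fraction w)::

    s(ν) = a · [ (1 − w)/A_CH(t) · P_t(ν) + w·R/A_OH · P_OH(ν) ]
           + background(ν) + noise(ν)

where ``P_t`` is the tissue's unit-area CH-stretch profile, ``P_OH`` a
broad unit-area OH band, ``A_CH(t)`` and ``A_OH`` are their trapezoid
areas over the CH and OH quantification windows, and ``a`` a per-pixel
multiplicative amplitude.  With this scaling the OH/CH band-area ratio of
the noise-free, background-free signal is exactly ``ρ = R·w/(1 − w)``, so
the band-ratio water estimator ``w = ρ/(ρ + R)`` inverts the forward model
exactly.  The CH profiles are truncated to zero above 3250 cm⁻¹ and the OH
band to zero below 3000 cm⁻¹, so neither component leaks into the *other's
quantification window* — yet the OH tail does reach into the upper part of
the CH analysis window [2800, 3100], which is precisely the varying water
interference the EMSC step must remove before PCA-LDA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ramanmap.io_formats import (
    NON_CANCEROUS_LABELS,
    AnnotationMask,
    SpectralMap,
    TissueLabel,
    WavenumberAxis,
)

#: Default axis: 2500–4000 cm⁻¹ at 2 cm⁻¹ spacing (751 channels).
DEFAULT_AXIS = WavenumberAxis(np.arange(2500.0, 4000.0 + 1e-9, 2.0))

# Truncation bounds keep each component out of the *other's* quantification
# window, so the band-ratio estimator is exact by construction, while the OH
# tail still overlaps the CH analysis window above 3000 cm^-1.
_CH_UPPER_CUT = 3250.0
_OH_LOWER_CUT = 3000.0

_OH_CENTER = 3400.0
_OH_FWHM = 260.0

_CH_QUANT_BAND = (2910.0, 2966.0)
_OH_QUANT_BAND = (3350.0, 3550.0)


def _band_area(axis: np.ndarray, spectrum: np.ndarray, band: tuple[float, float]) -> float:
    sel = (axis >= band[0]) & (axis <= band[1])
    return float(np.trapezoid(spectrum[sel], axis[sel]))


def _gaussian_profile(
    axis: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
    weights: np.ndarray,
    upper: float | None = _CH_UPPER_CUT,
) -> np.ndarray:
    """Non-negative sum of Gaussians, truncated and normalized to unit area."""
    prof = np.zeros_like(axis)
    for c, s, w in zip(centers, widths, weights):
        prof += max(w, 0.0) * np.exp(-0.5 * ((axis - c) / s) ** 2)
    if upper is not None:
        prof[axis > upper] = 0.0
    area = np.trapezoid(prof, axis)
    if area <= 0:
        raise ValueError("degenerate profile with non-positive area")
    return prof / area


@dataclass
class TissueBandModel:
    """Band parameters and water statistics for one tissue type."""

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    water_mean: float
    water_std: float
    fluor_amp: tuple[float, float] = (0.5, 1.5)

    def profile(self, axis: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.weights if weights is None else weights
        return _gaussian_profile(axis, self.centers, self.widths, w)


@dataclass
class TissueProfileSet:
    """Per-tissue CH-stretch profiles plus the shared OH water band.

    ``calibration_r`` is the band-area ratio the forward model imposes at
    w = 0.5; the matching analysis config must use the same value for the
    water estimator to be exact.  ``pixel_jitter`` is the relative standard
    deviation of per-pixel band-weight perturbations (biochemical
    heterogeneity within a tissue type).
    """

    axis: WavenumberAxis
    tissues: dict[TissueLabel, TissueBandModel]
    calibration_r: float = 1.0
    pixel_jitter: float = 0.05
    oh_profile: np.ndarray = field(init=False)
    oh_area: float = field(init=False)

    def __post_init__(self) -> None:
        ax = self.axis.values
        sigma = _OH_FWHM / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        prof = np.exp(-0.5 * ((ax - _OH_CENTER) / sigma) ** 2)
        prof[ax < _OH_LOWER_CUT] = 0.0
        self.oh_profile = prof / np.trapezoid(prof, ax)
        self.oh_area = _band_area(ax, self.oh_profile, _OH_QUANT_BAND)
        for label, model in self.tissues.items():
            p = model.profile(ax)
            if _band_area(ax, p, _CH_QUANT_BAND) <= 0:
                raise ValueError(f"{label.name}: CH profile has no area in the CH band")

    def effect_size(self) -> float:
        """L2 distance between the tumor profile and the mean non-tumor
        profile (both unit-area), the generator's class-separation scale."""
        ax = self.axis.values
        tumor = self.tissues[TissueLabel.TUMOR].profile(ax)
        others = [
            self.tissues[t].profile(ax) for t in self.tissues if t != TissueLabel.TUMOR
        ]
        diff = tumor - np.mean(others, axis=0)
        return float(np.sqrt(np.trapezoid(diff**2, ax)))


# Base CH-stretching bands: CH2 symmetric/asymmetric stretch (lipids),
# CH3 stretches (proteins), and the olefinic/aromatic =CH band near 3060.
_BASE_CENTERS = np.array([2850.0, 2885.0, 2930.0, 2960.0, 3060.0])
_BASE_WIDTHS = np.array([18.0, 20.0, 26.0, 22.0, 26.0])

_NON_TUMOR_WEIGHTS: dict[TissueLabel, np.ndarray] = {
    TissueLabel.CONNECTIVE: np.array([0.80, 0.70, 1.00, 0.60, 0.15]),
    TissueLabel.GLAND: np.array([1.20, 0.90, 0.80, 0.70, 0.10]),
    TissueLabel.CARTILAGE: np.array([0.70, 0.80, 1.00, 0.70, 0.10]),
    TissueLabel.MUSCLE: np.array([0.90, 0.80, 1.00, 0.65, 0.12]),
    TissueLabel.NECROSIS: np.array([0.95, 0.80, 0.95, 0.62, 0.18]),
}

# Tumor base profile: exactly the centroid of the non-tumor band weights,
# so that at delta = 0 the tumor class mean coincides with the non-tumor
# pool mean and no linear discriminant separates them in expectation (the
# delta = 0 / equal-water setting is a genuine null).  The tumor-specific
# compositional shift points toward less lipid CH2, more protein CH3 and
# olefinic/aromatic =CH.
_TUMOR_BASE = np.mean(list(_NON_TUMOR_WEIGHTS.values()), axis=0)
_TUMOR_SHIFT = np.array([-0.15, 0.00, 0.20, -0.05, 0.08])

# Water fraction means/stds: all types near 0.75 with wide spread, the
# tumor slightly wetter — highly overlapping by design.  With the default
# scene classes the pairwise-normal pooled AUC is ≈ 0.56 (low water-based
# discrimination despite a real distributional difference).
_WATER_STATS: dict[TissueLabel, tuple[float, float]] = {
    TissueLabel.TUMOR: (0.755, 0.055),
    TissueLabel.CONNECTIVE: (0.740, 0.060),
    TissueLabel.GLAND: (0.750, 0.050),
    TissueLabel.CARTILAGE: (0.730, 0.060),
    TissueLabel.MUSCLE: (0.740, 0.055),
    TissueLabel.NECROSIS: (0.755, 0.065),
}


def default_profiles(
    axis: WavenumberAxis = DEFAULT_AXIS,
    delta: float = 0.5,
    equal_water: bool = False,
    calibration_r: float = 1.0,
    pixel_jitter: float = 0.05,
) -> TissueProfileSet:
    """Build the default tissue profile set.

    Parameters
    ----------
    delta
        Scale of the tumor-vs-non-tumor CH compositional shift; 0 makes
        the tumor profile indistinguishable in expectation (null case).
    equal_water
        Give every tissue type an identical water-fraction distribution
        (null case for the water arm).
    """
    tissues: dict[TissueLabel, TissueBandModel] = {}
    for label, weights in _NON_TUMOR_WEIGHTS.items():
        mean, std = _WATER_STATS[label]
        if equal_water:
            mean, std = 0.75, 0.06
        tissues[label] = TissueBandModel(
            _BASE_CENTERS, _BASE_WIDTHS, weights, mean, std
        )
    mean, std = (0.75, 0.06) if equal_water else _WATER_STATS[TissueLabel.TUMOR]
    tissues[TissueLabel.TUMOR] = TissueBandModel(
        _BASE_CENTERS,
        _BASE_WIDTHS,
        np.clip(_TUMOR_BASE + delta * _TUMOR_SHIFT, 0.0, None),
        mean,
        std,
    )
    return TissueProfileSet(
        axis=axis,
        tissues=tissues,
        calibration_r=calibration_r,
        pixel_jitter=pixel_jitter,
    )


@dataclass
class SceneSpec:
    """Geometry and noise conditions of one synthetic map.

    ``cosmic_rate`` is the expected number of cosmic-ray events per 1000
    spectra; ``snr`` is the peak-signal-to-noise-sigma ratio of the shot
    noise (None disables noise); ``fluor_scale`` scales the fluorescence
    background relative to the Raman peak.
    """

    grid_shape: tuple[int, int] = (16, 16)
    step_size: float = 500.0
    classes: tuple[TissueLabel, ...] = (
        TissueLabel.TUMOR,
        TissueLabel.CONNECTIVE,
        TissueLabel.GLAND,
        TissueLabel.MUSCLE,
    )
    label_grid: np.ndarray | None = None
    blob_smoothing: float = 3.0
    amplitude_range: tuple[float, float] = (700.0, 1300.0)
    snr: float | None = 25.0
    cosmic_rate: float = 2.0
    cosmic_amplitude: tuple[float, float] = (5.0, 50.0)
    fluor_scale: float = 0.5
    map_effect_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.cosmic_rate < 0 or self.fluor_scale < 0:
            raise ValueError("rates must be >= 0")
        if self.label_grid is not None:
            self.label_grid = np.asarray(self.label_grid, dtype=np.int8)
            if self.label_grid.shape != tuple(self.grid_shape):
                raise ValueError("label_grid shape must match grid_shape")


def make_pixel_spectrum(
    profiles: TissueProfileSet,
    tissue: TissueLabel,
    water_fraction: float,
    rng: np.random.Generator,
    *,
    amplitude: float = 1000.0,
    snr: float | None = None,
    background: np.ndarray | None = None,
    weight_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-model one pixel spectrum.

    With ``snr=None`` and ``background=None`` the output is the pure Raman
    signal, for which the band-ratio estimator recovers ``water_fraction``
    exactly.  ``weight_scale`` multiplies the tissue's band weights
    (map-level heterogeneity); per-pixel jitter is drawn here from ``rng``.
    """
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError("water_fraction must lie in [0, 1]")
    if tissue not in profiles.tissues:
        raise KeyError(f"unknown tissue label {tissue!r}")
    ax = profiles.axis.values
    model = profiles.tissues[tissue]

    weights = model.weights.astype(float).copy()
    if weight_scale is not None:
        weights = weights * weight_scale
    if profiles.pixel_jitter > 0:
        weights = weights * (
            1.0 + profiles.pixel_jitter * rng.standard_normal(weights.size)
        )
    weights = np.clip(weights, 1e-6, None)

    ch_profile = model.profile(ax, weights)
    ch_area = _band_area(ax, ch_profile, _CH_QUANT_BAND)

    w = water_fraction
    signal = (1.0 - w) / ch_area * ch_profile
    if w > 0:
        signal = signal + (w * profiles.calibration_r / profiles.oh_area) * profiles.oh_profile
    spectrum = amplitude * signal

    if background is not None:
        spectrum = spectrum + background
    if snr is not None and snr > 0:
        peak = float(np.max(spectrum))
        if peak > 0:
            sd = (peak / snr) * np.sqrt(np.clip(spectrum, 0.0, None) / peak)
            spectrum = spectrum + sd * rng.standard_normal(spectrum.size)
    return np.clip(spectrum, 0.0, None)


def _random_background(
    axis: np.ndarray, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth positive degree-3 polynomial mimicking autofluorescence."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    coeffs = rng.uniform(-1.0, 1.0, size=4)
    bg = coeffs[0] + coeffs[1] * u + coeffs[2] * u**2 + coeffs[3] * u**3
    bg = bg - bg.min()  # non-negative
    return scale * bg


def _add_cosmic_ray(
    spectrum: np.ndarray, rng: np.random.Generator, amp_range: tuple[float, float]
) -> np.ndarray:
    """Inject a 1–2 channel positive spike, 5–50× the local signal."""
    n = spectrum.size
    pos = int(rng.integers(0, n))
    width = int(rng.integers(1, 3))
    local = max(float(spectrum[pos]), float(np.median(spectrum)), 1.0)
    amp = rng.uniform(*amp_range) * local
    out = spectrum.copy()
    for k in range(width):
        if pos + k < n:
            out[pos + k] += amp * (1.0 if k == 0 else rng.uniform(0.3, 0.8))
    return out


def _random_labels(
    scene: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Tile the grid with smoothed-threshold random blobs, one field per
    class; the per-pixel argmax assigns the label."""
    fields = np.stack(
        [
            gaussian_filter(
                rng.standard_normal(scene.grid_shape), scene.blob_smoothing
            )
            for _ in scene.classes
        ]
    )
    idx = np.argmax(fields, axis=0)
    labels = np.asarray([int(c) for c in scene.classes], dtype=np.int8)[idx]
    return labels


def generate_map(
    scene: SceneSpec,
    profiles: TissueProfileSet,
    seed: int | np.random.SeedSequence = 0,
    map_id: str = "map0",
    patient_id: str = "P0",
) -> tuple[SpectralMap, AnnotationMask, dict[str, np.ndarray]]:
    """Generate one annotated map plus its per-pixel ground truth.

    Returns ``(map, mask, truth)`` where ``truth`` holds the generated
    ``water`` fractions and ``labels`` aligned to the grid.
    """
    rng = np.random.default_rng(seed)
    ax = profiles.axis.values
    labels = (
        scene.label_grid
        if scene.label_grid is not None
        else _random_labels(scene, rng)
    )
    present = set(np.unique(labels).tolist())
    if len(present) < 2:
        warnings.warn(
            f"{map_id}: degenerate geometry with a single tissue class",
            stacklevel=2,
        )

    rows, cols = labels.shape
    n_channels = ax.size
    intensities = np.empty((rows, cols, n_channels))
    water_truth = np.empty((rows, cols))

    # One band-weight multiplier per map: inter-specimen heterogeneity that
    # makes leave-one-map-out validation meaningful.
    weight_scale = 1.0 + scene.map_effect_sd * rng.standard_normal(
        _BASE_CENTERS.size
    )

    p_cosmic = scene.cosmic_rate / 1000.0
    for r in range(rows):
        for c in range(cols):
            tissue = TissueLabel(int(labels[r, c]))
            model = profiles.tissues[tissue]
            w = float(
                np.clip(
                    rng.normal(model.water_mean, model.water_std), 0.0, 1.0
                )
            )
            water_truth[r, c] = w
            amp = rng.uniform(*scene.amplitude_range)
            bg = _random_background(
                ax, scene.fluor_scale * amp * rng.uniform(*model.fluor_amp) / 100.0, rng
            ) if scene.fluor_scale > 0 else None
            spec = make_pixel_spectrum(
                profiles,
                tissue,
                w,
                rng,
                amplitude=amp,
                snr=scene.snr,
                background=bg,
                weight_scale=weight_scale,
            )
            if p_cosmic > 0 and rng.random() < p_cosmic:
                spec = _add_cosmic_ray(spec, rng, scene.cosmic_amplitude)
            intensities[r, c] = spec

    smap = SpectralMap(
        map_id=map_id,
        patient_id=patient_id,
        axis=profiles.axis,
        intensities=intensities,
        step_size=scene.step_size,
    )
    mask = AnnotationMask(labels)
    truth = {"water": water_truth, "labels": labels.copy()}
    return smap, mask, truth


@dataclass
class MapBundle:
    """One generated map with its annotation and ground truth."""

    smap: SpectralMap
    mask: AnnotationMask
    truth: dict[str, np.ndarray]


@dataclass
class Cohort:
    """A model/test cohort with a disjoint patient partition."""

    model_maps: list[MapBundle]
    test_maps: list[MapBundle]

    def all_maps(self) -> list[MapBundle]:
        return self.model_maps + self.test_maps


def generate_cohort(
    n_model_maps: int,
    n_test_maps: int,
    patients: int,
    scene: SceneSpec,
    profiles: TissueProfileSet,
    seed: int = 0,
) -> Cohort:
    """Generate a cohort of maps with a disjoint model/test patient split.

    Patients are partitioned between the arms proportionally to the map
    counts (model arm rounded up) and maps are assigned to patients
    round-robin, so every patient contributes at least one map and no
    patient straddles the split.
    """
    total = n_model_maps + n_test_maps
    if total == 0 or patients < 2:
        raise ValueError("need maps in both arms and >= 2 patients")
    n_model_patients = min(
        n_model_maps, max(1, math.ceil(patients * n_model_maps / total))
    )
    n_test_patients = patients - n_model_patients
    if not 1 <= n_test_patients <= n_test_maps:
        raise ValueError(
            "patient count incompatible with map counts "
            f"(model {n_model_patients}, test {n_test_patients})"
        )

    # Per-map child seeds derived from one master sequence: cohorts are
    # reproducible map-by-map.
    children = np.random.SeedSequence(seed).spawn(total)

    model_maps: list[MapBundle] = []
    test_maps: list[MapBundle] = []
    for i in range(n_model_maps):
        pid = f"P{i % n_model_patients:03d}"
        smap, mask, truth = generate_map(
            scene, profiles, children[i], map_id=f"model{i:03d}", patient_id=pid
        )
        model_maps.append(MapBundle(smap, mask, truth))
    for j in range(n_test_maps):
        pid = f"P{n_model_patients + (j % n_test_patients):03d}"
        smap, mask, truth = generate_map(
            scene,
            profiles,
            children[n_model_maps + j],
            map_id=f"test{j:03d}",
            patient_id=pid,
        )
        test_maps.append(MapBundle(smap, mask, truth))

    model_patients = {b.smap.patient_id for b in model_maps}
    test_patients = {b.smap.patient_id for b in test_maps}
    if model_patients & test_patients:
        raise RuntimeError("patient partition is not disjoint")
    return Cohort(model_maps=model_maps, test_maps=test_maps)
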