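"""Spectral preprocessing: cosmic-ray removal, autofluorescence background
subtraction, and the intensity-based quality gate.

Order of operations for a dataset: cosmic-ray removal per spectrum, then
degree-3 polynomial background subtraction per spectrum, then the quality
gate computed on the background-subtracted CH-region intensity — so the
gate reflects Raman signal rather than fluorescence (a pre-subtraction
gate is available via ``gate_after_background=False`` in the config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import median_filter

from ramanmap.io_formats import AnalysisConfig, SpectralMap


@dataclass
class PreprocessReport:
    """Bookkeeping of the quality gate for one or more maps."""

    n_total: int
    n_excluded_quality: int
    pixel_mean_intensity: dict[str, np.ndarray] = field(default_factory=dict)
    overall_mean_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_excluded_quality > self.n_total:
            raise ValueError("excluded count exceeds total")


def remove_cosmic_rays(
    spectrum: np.ndarray, k: float = 8.0, window: int = 9, max_width: int = 2
) -> np.ndarray:
    """Replace isolated cosmic-ray spikes by interpolation of neighbors.

    A channel is spike-suspect when it exceeds the rolling median (window
    ``window``, mirror-padded at the edges so a boundary spike cannot
    dominate its own window) by more than ``k`` times the local rolling
    median absolute deviation of the residuals (shot noise is
    heteroscedastic across the spectrum, so a global scale would misfire
    near strong bands).  Only suspect runs at most ``max_width`` channels
    wide are replaced — genuine Raman bands are wider and survive
    untouched.  Spike-free input is a fixed point.
    """
    s = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("spectrum must be finite")
    rolling = median_filter(s, size=window, mode="mirror")
    residual = s - rolling
    local_mad = median_filter(np.abs(residual), size=window, mode="mirror")
    # Floor keeps exactly-constant spectra from flagging numerical noise.
    floor = 1e-12 * max(1.0, float(np.max(np.abs(s))))
    threshold = k * np.maximum(local_mad, floor)
    suspect = residual > threshold
    if not suspect.any():
        return s.copy()

    out = s.copy()
    n = s.size
    idx = np.flatnonzero(suspect)
    # Group suspect channels into contiguous runs.
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))

    for lo, hi in runs:
        if hi - lo + 1 > max_width:
            continue  # too wide to be a cosmic ray
        left = lo - 1
        right = hi + 1
        if left < 0 and right >= n:
            continue
        if left < 0:
            out[lo : hi + 1] = s[right]
        elif right >= n:
            out[lo : hi + 1] = s[left]
        else:
            # Linear interpolation across the excised run.
            frac = (np.arange(lo, hi + 1) - left) / (right - left)
            out[lo : hi + 1] = s[left] + frac * (s[right] - s[left])
    return out


def subtract_background(
    spectrum: np.ndarray,
    axis: np.ndarray,
    degree: int = 3,
    n_iter: int = 30,
    tol: float = 1e-8,
) -> np.ndarray:
    """Subtract an iteratively fitted degree-``degree`` polynomial baseline.

    Iterative peak clipping: after each polynomial fit, points rising more
    than the residual spread ``dev`` above the fit are clamped to
    ``fit + dev`` before refitting, so the polynomial converges onto the
    baseline under the peaks instead of cutting through them (a naive
    clamp *at* the fit is biased low).  Iteration stops after ``n_iter``
    rounds or when ``dev`` stabilizes to relative ``tol``.  Output may
    contain small negatives.
    """
    s = np.asarray(spectrum, dtype=float)
    x = np.asarray(axis, dtype=float)
    if s.size != x.size:
        raise ValueError("spectrum and axis lengths differ")
    if s.size < max(8, degree + 1):
        raise ValueError("too few channels for a baseline fit")
    # Scale the abscissa to [-1, 1] for a well-conditioned fit.
    u = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    work = s.copy()
    coeffs = npoly.polyfit(u, work, degree)
    dev_prev = None
    for _ in range(n_iter):
        fit = npoly.polyval(u, coeffs)
        dev = float((work - fit).std())
        ceiling = fit + dev
        np.minimum(work, ceiling, out=work)
        coeffs = npoly.polyfit(u, work, degree)
        if dev_prev is not None and abs(dev - dev_prev) <= tol * max(dev, 1.0):
            break
        dev_prev = dev
    return s - npoly.polyval(u, coeffs)


def preprocess_map(smap: SpectralMap, cfg: AnalysisConfig) -> SpectralMap:
    """Cosmic-ray removal followed by background subtraction, per pixel."""
    out = smap.copy()
    ax = smap.axis.values
    flat = out.intensities.reshape(-1, ax.size)
    for i in range(flat.shape[0]):
        cleaned = remove_cosmic_rays(flat[i])
        flat[i] = subtract_background(cleaned, ax, degree=cfg.background_degree)
    return out


def quality_gate(
    maps: SpectralMap | list[SpectralMap], cfg: AnalysisConfig
) -> tuple[list[SpectralMap], PreprocessReport]:
    """Invalidate pixels whose CH-region intensity is below the gate.

    The signal measure is the mean intensity over the quality band
    (default 2700–3100 cm⁻¹); a pixel is excluded when its mean falls
    below ``quality_gate_fraction`` (default 5%) of the overall mean.  The
    overall mean is the mean of per-pixel means across the valid tissue
    pixels of the whole dataset (``gate_scope='dataset'``) or of each map
    separately (``'map'``).  Operates in place on copies; returns the
    gated maps and a report whose counts match a brute-force recount.
    """
    map_list = [maps] if isinstance(maps, SpectralMap) else list(maps)
    if not map_list:
        raise ValueError("no maps supplied")

    per_map_means: dict[str, np.ndarray] = {}
    gated: list[SpectralMap] = []
    for smap in map_list:
        if smap.n_pixels == 0:
            raise ValueError(f"{smap.map_id}: empty map")
        sel = smap.axis.window(*cfg.quality_band)
        means = smap.intensities[:, :, sel].mean(axis=2)
        per_map_means[smap.map_id] = means
        gated.append(smap.copy())

    def _gate(group: list[SpectralMap]) -> int:
        valid_means = np.concatenate(
            [per_map_means[m.map_id][m.pixel_valid] for m in group]
        )
        if valid_means.size == 0:
            raise ValueError("no valid pixels to gate against")
        overall = float(valid_means.mean())
        excluded = 0
        for m in group:
            low = per_map_means[m.map_id] < cfg.quality_gate_fraction * overall
            newly = low & m.pixel_valid
            excluded += int(newly.sum())
            m.pixel_valid &= ~low
        _gate.overall = overall  # type: ignore[attr-defined]
        return excluded

    if cfg.gate_scope == "dataset":
        n_excluded = _gate(gated)
        overall = _gate.overall  # type: ignore[attr-defined]
    else:
        n_excluded = 0
        overalls = []
        for m in gated:
            n_excluded += _gate([m])
            overalls.append(_gate.overall)  # type: ignore[attr-defined]
        overall = float(np.mean(overalls))

    report = PreprocessReport(
        n_total=sum(m.n_pixels for m in map_list),
        n_excluded_quality=n_excluded,
        pixel_mean_intensity=per_map_means,
        overall_mean_intensity=overall,
    )
    return gated, report
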