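"""Per-pixel water-concentration analysis.

The tissue water mass fraction is estimated per spectrum from the ratio of
the integrated OH-stretch band (default 3350–3550 cm⁻¹, water) to the
integrated CH-stretch band (default 2910–2966 cm⁻¹, protein/lipid)::

    ρ = A_OH / A_CH,          w = ρ / (ρ + R)

with a dimensionless instrument calibration constant ``R``.  Estimates
above 0.88 are treated as outliers and discarded; maps are smoothed with a
3×3 average filter for display; tumor vs pooled non-cancerous water
fractions are compared by a two-sided Wilcoxon rank-sum test and ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import correlate

from ramanmap.io_formats import (
    NON_CANCEROUS_LABELS,
    AnalysisConfig,
    AnnotationMask,
    SpectralMap,
    TissueLabel,
)


@dataclass
class WaterMap:
    """Per-pixel water fractions for one map.

    ``values`` holds NaN where no valid estimate exists; ``valid`` is the
    conjunction of map pixel validity, estimator validity and the outlier
    rule.  ``smoothed`` (filled by :func:`smooth_map`) never imputes values
    for invalid pixels — they stay NaN and are rendered black.
    """

    map_id: str
    values: np.ndarray
    valid: np.ndarray
    smoothed: np.ndarray | None = None
    n_outliers: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


@dataclass
class GroupedWaterData:
    """Tumor vs pooled non-cancerous water fractions, plus per-type subsets."""

    tumor: np.ndarray
    non_cancerous: np.ndarray
    per_type: dict[TissueLabel, np.ndarray] = field(default_factory=dict)


def estimate_water(
    spectrum: np.ndarray, axis: np.ndarray, cfg: AnalysisConfig
) -> float:
    """Water mass fraction of one preprocessed spectrum.

    Band areas are trapezoid integrals over the configured OH and CH
    windows.  Returns NaN (invalid estimate) when the CH band area is not
    positive; otherwise ``w = ρ/(ρ + R)`` clipped to [0, 1].
    """
    s = np.asarray(spectrum, dtype=float)
    x = np.asarray(axis, dtype=float)
    oh_sel = (x >= cfg.oh_band[0]) & (x <= cfg.oh_band[1])
    ch_sel = (x >= cfg.ch_band[0]) & (x <= cfg.ch_band[1])
    a_ch = np.trapezoid(s[ch_sel], x[ch_sel])
    if a_ch <= 0:
        return float("nan")
    a_oh = np.trapezoid(s[oh_sel], x[oh_sel])
    rho = max(a_oh, 0.0) / a_ch
    return float(np.clip(rho / (rho + cfg.water_r), 0.0, 1.0))


def water_map(smap: SpectralMap, cfg: AnalysisConfig) -> WaterMap:
    """Estimate water per pixel and apply the outlier rule."""
    rows, cols = smap.grid_shape
    values = np.full((rows, cols), np.nan)
    valid = smap.pixel_valid.copy()
    ax = smap.axis.values
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            w = estimate_water(smap.intensities[r, c], ax, cfg)
            if np.isnan(w):
                valid[r, c] = False
            else:
                values[r, c] = w
    values[~valid] = np.nan
    wmap = WaterMap(map_id=smap.map_id, values=values, valid=valid)
    return apply_outlier_rule(wmap, cfg)


def apply_outlier_rule(wmap: WaterMap, cfg: AnalysisConfig) -> WaterMap:
    """Discard estimates strictly above the outlier ceiling (default 0.88).

    A pixel at exactly the ceiling is retained.
    """
    outliers = wmap.valid & (wmap.values > cfg.water_outlier_ceiling)
    wmap.valid = wmap.valid & ~outliers
    wmap.values[outliers] = np.nan
    wmap.n_outliers += int(outliers.sum())
    return wmap


def smooth_map(wmap: WaterMap) -> WaterMap:
    """3×3 average filter over valid pixels.

    Each valid pixel becomes the mean of the valid pixels in its 3×3
    neighborhood; invalid neighbors are omitted from the mean, and edge
    pixels average over their in-bounds neighborhood.  Invalid pixels are
    never imputed.
    """
    filled = np.where(wmap.valid, wmap.values, 0.0)
    kernel = np.ones((3, 3))
    sums = correlate(filled, kernel, mode="constant", cval=0.0)
    counts = correlate(wmap.valid.astype(float), kernel, mode="constant", cval=0.0)
    smoothed = np.full_like(wmap.values, np.nan)
    ok = wmap.valid & (counts > 0)
    smoothed[ok] = sums[ok] / counts[ok]
    wmap.smoothed = smoothed
    return wmap


def collect_groups(wmap: WaterMap, mask: AnnotationMask) -> GroupedWaterData:
    """Split valid, unambiguously annotated water estimates into tumor vs
    pooled non-cancerous groups, keeping per-type subsets."""
    if mask.grid_shape != wmap.values.shape:
        raise ValueError("mask and water map shapes differ")
    usable = wmap.valid & mask.analysis_pixels()
    per_type: dict[TissueLabel, np.ndarray] = {}
    for label in (TissueLabel.TUMOR, *NON_CANCEROUS_LABELS):
        sel = usable & (mask.labels == label)
        if sel.any():
            per_type[label] = wmap.values[sel]
    tumor = per_type.get(TissueLabel.TUMOR, np.empty(0))
    non = [v for t, v in per_type.items() if t != TissueLabel.TUMOR]
    non_cancerous = np.concatenate(non) if non else np.empty(0)
    return GroupedWaterData(tumor=tumor, non_cancerous=non_cancerous, per_type=per_type)


def merge_groups(groups: list[GroupedWaterData]) -> GroupedWaterData:
    """Pool grouped water data across maps."""
    per_type: dict[TissueLabel, list[np.ndarray]] = {}
    for g in groups:
        for label, vals in g.per_type.items():
            per_type.setdefault(label, []).append(vals)
    merged = {label: np.concatenate(v) for label, v in per_type.items()}
    tumor = merged.get(TissueLabel.TUMOR, np.empty(0))
    non = [v for t, v in merged.items() if t != TissueLabel.TUMOR]
    return GroupedWaterData(
        tumor=tumor,
        non_cancerous=np.concatenate(non) if non else np.empty(0),
        per_type=merged,
    )


def compare_water(groups: GroupedWaterData) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum test and ROC AUC, tumor vs non-cancerous.

    The p-value uses the exact null distribution when both groups have at
    most 10 tie-free observations, and the normal approximation with the
    tie correction otherwise.  The AUC is the Mann-Whitney statistic
    ``U/(n₁·n₂)`` with ties counted half, i.e. the probability that a
    random tumor pixel shows more water than a random non-cancerous one.
    """
    x, y = groups.tumor, groups.non_cancerous
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return {"p_value": 1.0, "auc": 0.5}
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    auc = float(res.statistic) / (x.size * y.size)
    return {"p_value": float(res.pvalue), "auc": auc}
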