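"""Containers for hyperspectral Raman tissue maps.

A *map* is a rectangular grid of Raman spectra acquired over the surface of
a tissue section, all sharing one relative-wavenumber axis, together with a
per-pixel histopathological annotation transferred from an HE-stained
section.  The map is the unit of grouped cross-validation downstream.

Grid coordinates are 0-based ``(row, col)``, row-major, throughout the
package.  The on-disk container is a single self-describing HDF5 file per
map (``/axis``, ``/spectra``, ``/labels``, ``/pixel_valid`` plus root
attributes); a plain TSV export is provided for interoperability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import h5py
import numpy as np
import yaml


class FormatError(ValueError):
    """Raised when a map container violates the layout contract."""


class AnnotationError(ValueError):
    """Raised when an annotation grid is inconsistent with its map."""


class TissueLabel(IntEnum):
    """Closed vocabulary of per-pixel tissue annotations.

    ``AMBIGUOUS`` marks pixels the pathologist could not assign to a single
    tissue type at the Raman pixel size; only unambiguous, non-background
    pixels enter any analysis.
    """

    BACKGROUND = 0
    TUMOR = 1
    CONNECTIVE = 2
    GLAND = 3
    CARTILAGE = 4
    MUSCLE = 5
    NECROSIS = 6
    AMBIGUOUS = 7


#: Non-cancerous tissue types (the pooled comparison group).
NON_CANCEROUS_LABELS = (
    TissueLabel.CONNECTIVE,
    TissueLabel.GLAND,
    TissueLabel.CARTILAGE,
    TissueLabel.MUSCLE,
    TissueLabel.NECROSIS,
)

_CH_WINDOW = (2800.0, 3100.0)
_OH_WINDOW = (3350.0, 3550.0)


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing relative-wavenumber axis (cm⁻¹).

    The axis must resolve better than 5 cm⁻¹ and cover both the
    CH-stretching window [2800, 3100] and the OH window [3350, 3550] used
    for water quantification; monotonicity is enforced here once and never
    re-checked downstream.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 8:
            raise FormatError("axis must be a 1-D array with >= 8 points")
        spacing = np.diff(values)
        if not np.all(spacing > 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        if np.max(spacing) > 5.0:
            raise FormatError("axis spacing exceeds 5 cm^-1")
        for lo, hi in (_CH_WINDOW, _OH_WINDOW):
            if values[0] > lo or values[-1] < hi:
                raise FormatError(
                    f"axis [{values[0]:.0f}, {values[-1]:.0f}] does not cover "
                    f"the required window [{lo:.0f}, {hi:.0f}] cm^-1"
                )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels inside [lo, hi] (inclusive)."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class SpectralMap:
    """Grid of spectra on a shared axis, the unit of cross-validation.

    Parameters
    ----------
    map_id, patient_id
        Identifiers; maps of one patient must never straddle the
        model/test split downstream.
    axis
        Shared :class:`WavenumberAxis`.
    intensities
        Array ``(rows, cols, channels)`` of intensities (arbitrary counts).
        Negative values are permitted only after background subtraction.
    step_size
        Grid step in µm, within [250, 1000].
    pixel_valid
        Boolean ``(rows, cols)``; False marks no-tissue or quality-excluded
        pixels.
    """

    map_id: str
    patient_id: str
    axis: WavenumberAxis
    intensities: np.ndarray
    step_size: float
    pixel_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise FormatError("intensities must have shape (rows, cols, channels)")
        if self.intensities.shape[2] != len(self.axis):
            raise FormatError(
                f"spectra have {self.intensities.shape[2]} channels but the "
                f"axis has {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities must be finite")
        if not 250.0 <= self.step_size <= 1000.0:
            raise FormatError("step_size must lie in [250, 1000] µm")
        if self.pixel_valid is None:
            self.pixel_valid = np.ones(self.grid_shape, dtype=bool)
        else:
            self.pixel_valid = np.asarray(self.pixel_valid, dtype=bool)
            if self.pixel_valid.shape != self.grid_shape:
                raise FormatError("pixel_valid shape does not match the grid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def spectra_2d(self) -> np.ndarray:
        """All spectra flattened row-major to ``(n_pixels, channels)``."""
        return self.intensities.reshape(-1, len(self.axis))

    def copy(self) -> "SpectralMap":
        return SpectralMap(
            map_id=self.map_id,
            patient_id=self.patient_id,
            axis=self.axis,
            intensities=self.intensities.copy(),
            step_size=self.step_size,
            pixel_valid=self.pixel_valid.copy(),
        )


@dataclass
class AnnotationMask:
    """Per-pixel tissue labels delineated on histology.

    The registration of the HE delineation onto the Raman grid is manual in
    practice and its precision is limited to one Raman pixel; the mask
    therefore carries exactly one label per map pixel.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise AnnotationError("annotation grid must be 2-D")
        valid_codes = {int(v) for v in TissueLabel}
        codes = set(np.unique(labels).astype(int).tolist())
        if not codes <= valid_codes:
            raise AnnotationError(f"unknown label codes: {sorted(codes - valid_codes)}")
        self.labels = labels.astype(np.int8)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape

    def check_against(self, smap: SpectralMap) -> None:
        if self.grid_shape != smap.grid_shape:
            raise AnnotationError(
                f"annotation grid {self.grid_shape} does not match map grid "
                f"{smap.grid_shape}"
            )

    def analysis_pixels(self) -> np.ndarray:
        """Pixels with unambiguous tissue annotation (neither background
        nor ambiguous); only these enter any statistics."""
        return (self.labels != TissueLabel.BACKGROUND) & (
            self.labels != TissueLabel.AMBIGUOUS
        )

    def tumor_pixels(self) -> np.ndarray:
        return self.labels == TissueLabel.TUMOR


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline in one place.

    Band limits are in cm⁻¹.  ``water_r`` is the dimensionless calibration
    constant of the OH/CH band-ratio water estimator; the default 1.0 is
    exact for the synthetic generator and must be replaced by an instrument
    calibration for measured data.
    """

    oh_band: tuple[float, float] = (3350.0, 3550.0)
    ch_band: tuple[float, float] = (2910.0, 2966.0)
    ch_window: tuple[float, float] = (2800.0, 3100.0)
    quality_band: tuple[float, float] = (2700.0, 3100.0)
    water_r: float = 1.0
    quality_gate_fraction: float = 0.05
    water_outlier_ceiling: float = 0.88
    sg_order: int = 3
    sg_window: int = 11
    max_pc: int = 20
    background_degree: int = 3
    emsc_baseline_order: int = 1
    gate_scope: str = "dataset"  # or "map"
    gate_after_background: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quality_gate_fraction < 1.0:
            raise ValueError("quality_gate_fraction must lie in (0, 1)")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and exceed sg_order")
        if self.gate_scope not in ("dataset", "map"):
            raise ValueError("gate_scope must be 'dataset' or 'map'")
        for name in ("oh_band", "ch_band", "ch_window", "quality_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} limits must satisfy lo < hi")

    def validate_axis(self, axis: WavenumberAxis) -> None:
        """Check that all configured bands lie inside the axis range."""
        for name in ("oh_band", "ch_band", "ch_window", "quality_band"):
            lo, hi = getattr(self, name)
            if axis.values[0] > lo or axis.values[-1] < hi:
                raise ValueError(f"{name} [{lo}, {hi}] lies outside the axis range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("oh_band", "ch_band", "ch_window", "quality_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("oh_band", "ch_band", "ch_window", "quality_band"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_map(smap: SpectralMap, mask: AnnotationMask, path: str | Path) -> None:
    """Write a map and its annotation to one self-describing HDF5 file."""
    mask.check_against(smap)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("axis", data=smap.axis.values)
        fh.create_dataset("spectra", data=smap.intensities)
        fh.create_dataset("labels", data=mask.labels)
        fh.create_dataset("pixel_valid", data=smap.pixel_valid)
        fh.attrs["map_id"] = smap.map_id
        fh.attrs["patient_id"] = smap.patient_id
        fh.attrs["step_size"] = smap.step_size


def read_map(path: str | Path) -> tuple[SpectralMap, AnnotationMask]:
    """Read a map container written by :func:`write_map`.

    Raises
    ------
    FormatError
        If a required dataset is missing or shapes are inconsistent.
    AnnotationError
        If the label grid does not match the spectral grid or contains
        codes outside the closed vocabulary.
    """
    with h5py.File(path, "r") as fh:
        for name in ("axis", "spectra", "labels", "pixel_valid"):
            if name not in fh:
                raise FormatError(f"map container is missing /{name}")
        smap = SpectralMap(
            map_id=str(fh.attrs["map_id"]),
            patient_id=str(fh.attrs["patient_id"]),
            axis=WavenumberAxis(fh["axis"][()]),
            intensities=fh["spectra"][()],
            step_size=float(fh.attrs["step_size"]),
            pixel_valid=fh["pixel_valid"][()],
        )
        mask = AnnotationMask(fh["labels"][()])
    mask.check_against(smap)
    return smap, mask


def export_tsv(
    smap: SpectralMap,
    mask: AnnotationMask,
    path: str | Path,
    water: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> None:
    """Export per-pixel results as TSV (row, col, label, valid[, water][, score])."""
    import pandas as pd

    mask.check_against(smap)
    rows, cols = np.indices(smap.grid_shape)
    frame = {
        "row": rows.ravel(),
        "col": cols.ravel(),
        "label": [TissueLabel(code).name for code in mask.labels.ravel()],
        "valid": smap.pixel_valid.ravel().astype(int),
    }
    if water is not None:
        frame["water"] = np.asarray(water, dtype=float).ravel()
    if scores is not None:
        frame["lda_score"] = np.asarray(scores, dtype=float).ravel()
    pd.DataFrame(frame).to_csv(path, sep="\t", index=False, float_format="%.6g")
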