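"""End-to-end study orchestration.

Runs the full two-arm analysis on a synthetic cohort: generate maps →
preprocess → water-concentration arm (Wilcoxon + ROC AUC) → CH-stretching
arm (EMSC → SG → PCA-LDA with leave-one-map-out PC selection → independent
validation → Youden operating point and per-tissue false-positive
breakdown).  Every stage is a pure function of (inputs, config, seed); a
run manifest records config, seeds and content hashes per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ramanmap import chstretch, evaluation, preprocessing, synthetic, water
from ramanmap.io_formats import (
    AnalysisConfig,
    AnnotationMask,
    SpectralMap,
    TissueLabel,
)


@dataclass
class StudyConfig:
    """Shape and conditions of one synthetic study.

    The default cohort mirrors the clinical design this pipeline emulates:
    25 model maps from 17 patients and 9 independent test maps from 5
    patients, with highly overlapping water distributions and a moderate
    CH compositional effect.
    """

    n_model_maps: int = 25
    n_test_maps: int = 9
    patients: int = 22
    grid_shape: tuple[int, int] = (12, 12)
    step_size: float = 500.0
    delta: float = 0.5
    equal_water: bool = False
    snr: float | None = 25.0
    cosmic_rate: float = 2.0
    pixel_jitter: float = 0.05
    map_effect_sd: float = 0.03
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown study config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)


def _hash_arrays(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    stage_hashes: dict[str, str] = field(default_factory=dict)
    exclusion_counts: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, digest: str) -> None:
        self.stage_hashes[stage] = digest
        self.timestamps[stage] = time.time()


def _analysis_arrays(
    smap: SpectralMap, mask: AnnotationMask, cfg: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Valid, unambiguously annotated spectra with tumor labels and tissue
    codes, window-restricted to the CH analysis region."""
    usable = smap.pixel_valid & mask.analysis_pixels()
    flat = smap.spectra_2d()[usable.ravel()]
    _, windowed = chstretch.restrict_window(flat, smap.axis.values, cfg.ch_window)
    tumor = mask.tumor_pixels()[usable]
    codes = mask.labels[usable]
    return windowed, tumor, codes


def run_full_study(
    study: StudyConfig,
    cfg: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, RunManifest]:
    """Run the complete two-arm study; returns (results, manifest).

    Results contain the water-arm Wilcoxon p-value and AUC, the AUC-vs-p
    model-selection table, the chosen PC count, the validation ROC with
    its Youden sensitivity/specificity, and the per-tissue-type
    false-positive breakdown at the Youden threshold.
    """
    cfg = cfg or AnalysisConfig(seed=study.seed)
    manifest = RunManifest(config=dataclasses.asdict(study), seed=study.seed)

    # --- generate -------------------------------------------------------
    profiles = synthetic.default_profiles(
        delta=study.delta,
        equal_water=study.equal_water,
        calibration_r=cfg.water_r,
        pixel_jitter=study.pixel_jitter,
    )
    scene = synthetic.SceneSpec(
        grid_shape=study.grid_shape,
        step_size=study.step_size,
        classes=(
            TissueLabel.TUMOR,
            TissueLabel.CONNECTIVE,
            TissueLabel.GLAND,
            TissueLabel.CARTILAGE,
            TissueLabel.MUSCLE,
            TissueLabel.NECROSIS,
        ),
        snr=study.snr,
        cosmic_rate=study.cosmic_rate,
        map_effect_sd=study.map_effect_sd,
    )
    cohort = synthetic.generate_cohort(
        study.n_model_maps,
        study.n_test_maps,
        study.patients,
        scene,
        profiles,
        seed=study.seed,
    )
    manifest.record(
        "generate",
        _hash_arrays(*[b.smap.intensities for b in cohort.all_maps()]),
    )

    # --- preprocess -----------------------------------------------------
    all_bundles = cohort.all_maps()
    cleaned = [preprocessing.preprocess_map(b.smap, cfg) for b in all_bundles]
    # Only tissue pixels participate in the gate's overall mean.
    for smap, bundle in zip(cleaned, all_bundles):
        smap.pixel_valid &= bundle.mask.analysis_pixels()
    gated, report = preprocessing.quality_gate(cleaned, cfg)
    manifest.exclusion_counts["quality_gate"] = report.n_excluded_quality
    manifest.record("preprocess", _hash_arrays(*[m.intensities for m in gated]))

    n_model = study.n_model_maps
    model_maps = gated[:n_model]
    test_maps = gated[n_model:]
    model_masks = [b.mask for b in cohort.model_maps]
    test_masks = [b.mask for b in cohort.test_maps]

    # --- water arm ------------------------------------------------------
    groups = []
    n_water_outliers = 0
    water_maps = []
    for smap, mask in zip(gated, [b.mask for b in all_bundles]):
        wmap = water.water_map(smap, cfg)
        wmap = water.smooth_map(wmap)
        n_water_outliers += wmap.n_outliers
        water_maps.append(wmap)
        groups.append(water.collect_groups(wmap, mask))
    pooled = water.merge_groups(groups)
    water_stats = water.compare_water(pooled)
    manifest.exclusion_counts["water_outliers"] = n_water_outliers
    manifest.record(
        "watermap", _hash_arrays(*[w.values[w.valid] for w in water_maps])
    )

    # --- CH-stretching arm ---------------------------------------------
    axis = gated[0].axis.values
    window_axis, _ = chstretch.restrict_window(
        np.empty((0, axis.size)), axis, cfg.ch_window
    )
    model_data = [
        _analysis_arrays(smap, mask, cfg)
        for smap, mask in zip(model_maps, model_masks)
    ]
    test_data = [
        _analysis_arrays(smap, mask, cfg)
        for smap, mask in zip(test_maps, test_masks)
    ]

    pooled_model = np.vstack([X for X, _, _ in model_data])
    _, interferent = chstretch.restrict_window(
        profiles.oh_profile, axis, cfg.ch_window
    )
    emsc = chstretch.EMSCModel.build(
        pooled_model,
        window_axis,
        interferents=interferent[None, :],
        baseline_order=cfg.emsc_baseline_order,
    )

    def _correct(data, maps):
        out = []
        for (X, y, codes), smap in zip(data, maps):
            corrected, ok = chstretch.emsc_correct_many(X, emsc)
            smooth = chstretch.sg_filter(corrected[ok], cfg)
            out.append((smooth, y[ok], codes[ok], smap.map_id, smap.patient_id))
        return out

    model_corr = _correct(model_data, model_maps)
    test_corr = _correct(test_data, test_maps)
    manifest.record(
        "emsc_sg", _hash_arrays(*[X for X, *_ in model_corr + test_corr])
    )

    selection = chstretch.select_pc_count(
        [(X, y, mid) for X, y, _, mid, _ in model_corr], cfg.max_pc
    )
    model_auc = float(np.max(selection.pooled_auc))

    pooled_X = np.vstack([X for X, *_ in model_corr])
    pooled_y = np.concatenate([y for _, y, *_ in model_corr])
    final = chstretch.fit_pcalda(
        pooled_X,
        pooled_y,
        selection.chosen_p,
        axis=window_axis,
        training_maps=tuple(mid for *_, mid, _ in model_corr),
        training_patients=tuple(sorted({pid for *_, pid in model_corr})),
    )

    val = chstretch.validate(
        final, [(X, y, mid, pid) for X, y, _, mid, pid in test_corr]
    )
    val_curve = evaluation.roc(val["scores"], val["labels"])
    youden = evaluation.youden_point(val_curve)
    test_codes = np.concatenate([codes for _, _, codes, _, _ in test_corr])
    breakdown = evaluation.fp_breakdown(
        val["scores"], test_codes, youden["threshold"]
    )
    manifest.record("validate", _hash_arrays(val["scores"]))

    results = {
        "n_maps": len(gated),
        "n_excluded_quality": report.n_excluded_quality,
        "n_water_outliers": n_water_outliers,
        "water": {
            "p_value": water_stats["p_value"],
            "auc": water_stats["auc"],
            "tumor_mean": float(pooled.tumor.mean()),
            "non_cancerous_mean": float(pooled.non_cancerous.mean()),
            "n_tumor": int(pooled.tumor.size),
            "n_non_cancerous": int(pooled.non_cancerous.size),
        },
        "model_selection": {
            "candidate_p": selection.candidate_p.tolist(),
            "pooled_auc": selection.pooled_auc.tolist(),
            "chosen_p": selection.chosen_p,
            "best_auc": model_auc,
            "n": int(selection.pooled_labels.size),
        },
        "validation": {
            "auc": val_curve.auc,
            "sensitivity": youden["sensitivity"],
            "specificity": youden["specificity"],
            "threshold": youden["threshold"],
            "n": int(val["scores"].size),
        },
        "fp_breakdown": {label.name: frac for label, frac in breakdown.items()},
        "fp_counts": {
            label.name: int((test_codes == int(label)).sum())
            for label in breakdown
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, indent=2))
        (out / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2)
        )
        final.to_json(out / "pcalda_model.json")
    return results, manifest
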