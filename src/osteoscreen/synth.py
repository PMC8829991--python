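"""Synthetic cohorts: clinical tables and procedurally rendered vertebral ROIs.

No public dataset accompanies the screening problem, so every pipeline stage
is exercised on simulated subjects whose statistical contrasts mirror the
clinical picture:

* **Clinical table** — age is Normal(65.67, 9.691²) for osteoporotic and
  Normal(55.77, 10.066²) for normal subjects (the observed group-wise shift
  in a large screening cohort); menopause status (MPS) has class-dependent
  odds; a configurable number of laboratory analytes carry a standardized
  mean shift, the rest are pure noise.
* **Vertebra images** — a 64×64 ROI: a bright cortical rim around a
  cancellous interior built from Gaussian-smoothed noise thresholded into
  trabecular struts and inter-trabecular (marrow) pores.  The osteoporotic
  class gets a lower mean intensity, a larger pore scale and marrow
  fraction, and a thinner rim — the radiographic signature of trabecular
  rarefaction.  An optional per-tube-voltage intensity offset injects a
  protocol confound for the Kruskal–Wallis filter to catch.
* **Replicates** — re-segmentation copies for the ICC gate: the interior
  texture is re-cropped with a ±2 px jitter from a larger master canvas and
  the rim re-drawn, emulating a second manual segmentation.

The generator is fully deterministic given (config, seed), and ground truth
(class, which analytes are informative) is stored beside — never inside —
the feature table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .feature_table import (
    MPS_LEVELS,
    FeatureMatrix,
    SubjectRecord,
    build_matrix,
    extract_vertebra_descriptors,
    aggregate_subject,
)
from .imaging import STANDARD_SIZE, VERTEBRAE, VertebraROI, derive_cancellous_mask

__all__ = ["CohortConfig", "SyntheticCohort", "sample_clinical", "render_vertebra",
           "generate_cohort", "null_cohort_config", "strong_cohort_config"]

# baseline (mean, sd) of each synthetic lab analyte; plausible adult values
_LAB_BASELINES: dict[str, tuple[float, float]] = {
    "wbc": (6.5, 1.6), "rbc": (4.6, 0.5), "hemoglobin": (138.0, 14.0),
    "hematocrit": (0.41, 0.04), "platelets": (250.0, 60.0), "mcv": (90.0, 5.0),
    "mch": (30.0, 2.0), "mchc": (335.0, 12.0), "rdw": (13.2, 1.0),
    "neutrophils": (3.8, 1.2), "lymphocytes": (2.0, 0.6), "monocytes": (0.5, 0.15),
    "creatinine": (75.0, 15.0), "urea": (5.5, 1.5), "uric_acid": (320.0, 80.0),
    "egfr": (85.0, 15.0),
    "alt": (25.0, 12.0), "ast": (24.0, 9.0), "alp": (75.0, 20.0),
    "ggt": (30.0, 18.0), "total_bilirubin": (12.0, 4.0), "albumin": (44.0, 3.0),
    "total_protein": (71.0, 4.0),
    "fasting_glucose": (5.4, 0.9), "hba1c": (5.6, 0.5),
    "total_cholesterol": (5.0, 1.0), "ldl": (3.0, 0.8), "hdl": (1.4, 0.35),
    "triglycerides": (1.5, 0.7),
}

#: Default analytes given a class shift (alkaline phosphatase and friends
#: are plausible osteoporosis correlates; the list is a simulation choice).
_DEFAULT_INFORMATIVE_LABS = ("alp", "albumin", "rbc", "hemoglobin",
                             "creatinine", "egfr", "total_cholesterol", "hdl")

_MPS_PROBS = {
    1: (0.75, 0.05, 0.20),  # osteoporotic: mostly post-menopausal women
    0: (0.35, 0.30, 0.35),
}
_MPS_PROBS_NULL = {
    1: (0.5, 0.2, 0.3),
    0: (0.5, 0.2, 0.3),
}


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study; defaults are the standard conditions."""

    n_subjects: int = 300
    prevalence: float = 0.43
    # clinical
    age_params: Mapping[int, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {1: (65.67, 9.691), 0: (55.77, 10.066)})
    bmi_effect: float = -0.3          # standardized shift for the osteoporotic class
    lab_effect: float = 0.5           # standardized shift of informative analytes
    informative_labs: tuple[str, ...] = _DEFAULT_INFORMATIVE_LABS
    mps_class_dependent: bool = True  # False: identical MPS odds in both classes
    # image
    intensity_shift: float = 12.0     # Δμ, gray levels subtracted for osteoporosis
    pore_scale: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 2.2, 0: 1.6})  # noise-smoothing σ (px)
    marrow_fraction: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 0.52, 0: 0.40})
    rim_thickness: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: {1: 2, 0: 4})
    # protocol
    tube_voltage_probs: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {80: 0.08, 120: 0.91, 140: 0.01})
    voltage_offsets: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {80: 0.0, 120: 0.0, 140: 0.0})
    # replication
    n_replicates: int = 2             # extra jittered re-segmentations per ROI
    jitter_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        unknown = set(self.informative_labs) - set(_LAB_BASELINES)
        if unknown:
            raise ValueError(f"unknown lab analytes: {sorted(unknown)}")
        for t in self.rim_thickness.values():
            if t >= STANDARD_SIZE // 2:
                raise ValueError("rim thickness must be below half the image size")


def null_cohort_config(n_subjects: int = 300, seed: int = 0,
                       n_replicates: int = 0) -> CohortConfig:
    """A zero-effect cohort: the label influences nothing.

    Every clinical shift is zeroed, both classes share one age distribution
    and one image model, and MPS odds are class-independent — the
    calibration condition under which every classifier should score at
    chance.
    """
    return CohortConfig(
        n_subjects=n_subjects, seed=seed, n_replicates=n_replicates,
        age_params={1: (60.0, 10.0), 0: (60.0, 10.0)},
        bmi_effect=0.0, lab_effect=0.0, mps_class_dependent=False,
        intensity_shift=0.0,
        pore_scale={1: 1.9, 0: 1.9},
        marrow_fraction={1: 0.46, 0: 0.46},
        rim_thickness={1: 3, 0: 3},
    )


def strong_cohort_config(n_subjects: int = 300, seed: int = 0,
                         n_replicates: int = 0) -> CohortConfig:
    """A strong-effect cohort whose image contrast exceeds the clinical one.

    Clinical shifts stay at their defaults; the image effect is doubled
    (Δμ 24 gray levels, wider pore-scale and marrow-fraction gaps), so the
    image-equipped third layer should dominate the layer ordering.
    """
    return CohortConfig(
        n_subjects=n_subjects, seed=seed, n_replicates=n_replicates,
        intensity_shift=24.0,
        pore_scale={1: 2.6, 0: 1.5},
        marrow_fraction={1: 0.56, 0: 0.38},
        rim_thickness={1: 2, 0: 5},
    )


def sample_clinical(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample the clinical table (label + 35 clinical columns + voltage)."""
    n = config.n_subjects
    labels = (rng.random(n) < config.prevalence).astype(int)
    rows: dict[str, np.ndarray | list] = {"label": labels}
    age = np.empty(n)
    for cls, (mu, sd) in config.age_params.items():
        idx = labels == cls
        age[idx] = rng.normal(mu, sd, idx.sum())
    rows["age"] = np.round(age, 1)
    bmi = rng.normal(24.0, 3.5, n) + config.bmi_effect * 3.5 * labels
    rows["bmi"] = np.round(bmi, 1)
    systolic = rng.normal(130.0, 15.0, n)
    diastolic = rng.normal(80.0, 10.0, n)
    rows["systolic_bp"] = np.round(systolic, 0)
    rows["diastolic_bp"] = np.round(diastolic, 0)
    rows["pulse_pressure"] = rows["systolic_bp"] - rows["diastolic_bp"]
    mps_probs = _MPS_PROBS if config.mps_class_dependent else _MPS_PROBS_NULL
    mps = []
    for lab in labels:
        mps.append(MPS_LEVELS[rng.choice(3, p=mps_probs[int(lab)])])
    rows["mps"] = mps
    informative = set(config.informative_labs)
    for name, (mu, sd) in _LAB_BASELINES.items():
        shift = config.lab_effect * sd if name in informative else 0.0
        sign = -1.0 if name in ("albumin", "rbc", "hemoglobin", "egfr", "hdl") else 1.0
        rows[name] = rng.normal(mu, sd, n) + sign * shift * labels
    voltages = sorted(config.tube_voltage_probs)
    probs = np.array([config.tube_voltage_probs[v] for v in voltages], dtype=float)
    rows["tube_voltage"] = rng.choice(voltages, size=n, p=probs / probs.sum())
    ids = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))


def _draw_rim(img: np.ndarray, thickness: int, intensity: float) -> None:
    img[:thickness, :] = intensity
    img[-thickness:, :] = intensity
    img[:, :thickness] = intensity
    img[:, -thickness:] = intensity


def render_vertebra(
    status: int,
    config: CohortConfig,
    rng: np.random.Generator,
    voltage_offset: float = 0.0,
    n_crops: int = 1,
) -> list[np.ndarray]:
    """Render one vertebra; return the base crop plus jittered re-crops.

    All crops come from one master texture canvas, so successive crops of
    the same call emulate repeated manual segmentations of one vertebra.
    """
    status = int(status)
    size = STANDARD_SIZE
    j = config.jitter_px
    canvas = size + 2 * j
    noise = gaussian_filter(rng.normal(0.0, 1.0, (canvas, canvas)),
                            sigma=config.pore_scale[status])
    cut = np.quantile(noise, config.marrow_fraction[status])
    interior = np.where(noise <= cut, 70.0, 170.0)      # marrow dark, struts bright
    interior += rng.normal(0.0, 8.0, interior.shape)    # acquisition noise
    interior -= config.intensity_shift * status
    interior += voltage_offset
    crops: list[np.ndarray] = []
    offsets = [(0, 0)] + [tuple(rng.integers(-j, j + 1, 2)) for _ in range(n_crops - 1)]
    rim_val = 235.0 - config.intensity_shift * status * 0.5
    for dy, dx in offsets:
        crop = interior[j + dy : j + dy + size, j + dx : j + dx + size].copy()
        _draw_rim(crop, config.rim_thickness[status], rim_val + voltage_offset)
        crops.append(np.clip(np.round(crop), 0, 255).astype(np.uint8))
    return crops


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: records, replicate ROIs and the ground truth."""

    config: CohortConfig
    clinical: pd.DataFrame
    records: list[SubjectRecord]
    replicates: dict[str, list[list[VertebraROI]]]  # subject -> replicate -> ROIs
    ground_truth: dict

    def feature_matrix(self) -> FeatureMatrix:
        return build_matrix(self.records)

    def replicate_features(self, max_subjects: int | None = None) -> pd.DataFrame:
        """Image features per (replicate, subject) for the ICC gate.

        Columns are a (feature, replicate) MultiIndex; replicate 0 is the
        base extraction.  ``max_subjects`` caps the (costly) re-extraction.
        """
        sids = [r.subject_id for r in self.records if r.vertebrae]
        if max_subjects is not None:
            sids = sids[:max_subjects]
        by_sid = {r.subject_id: r for r in self.records}
        frames = {}
        for rep in range(self.config.n_replicates + 1):
            rows = {}
            for sid in sids:
                rois = by_sid[sid].vertebrae if rep == 0 else self.replicates[sid][rep - 1]
                descs = [extract_vertebra_descriptors(v) for v in rois]
                rows[sid] = aggregate_subject(descs)
            frames[rep] = pd.DataFrame.from_dict(rows, orient="index")
        wide = pd.concat(frames, axis=1)           # (replicate, feature)
        wide.columns = wide.columns.swaplevel(0, 1)
        return wide.sort_index(axis=1)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write cohort.csv, ROI BMPs and manifest.csv (round-trippable)."""
        outdir = Path(outdir)
        roi_dir = outdir / "rois"
        roi_dir.mkdir(parents=True, exist_ok=True)
        cohort_csv = outdir / "cohort.csv"
        clin = self.clinical.drop(columns=["tube_voltage"])
        clin.to_csv(cohort_csv, index_label="subject_id")
        manifest_rows = []
        for rec in self.records:
            for roi in rec.vertebrae:
                name = f"{rec.subject_id}_{roi.vertebra}.bmp"
                Image.fromarray(roi.image, mode="L").save(roi_dir / name)
                manifest_rows.append({
                    "subject_id": rec.subject_id, "vertebra": roi.vertebra,
                    "path": f"rois/{name}", "tube_voltage_kV": rec.tube_voltage,
                })
        manifest_csv = outdir / "manifest.csv"
        pd.DataFrame(manifest_rows).to_csv(manifest_csv, index=False)
        return {"cohort": cohort_csv, "manifest": manifest_csv, "roi_dir": roi_dir}


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Sample clinical data and render 4 vertebra ROIs (+replicates) per subject."""
    rng = np.random.default_rng(config.seed)
    clinical = sample_clinical(config, rng)
    records: list[SubjectRecord] = []
    replicates: dict[str, list[list[VertebraROI]]] = {}
    margin = 0.1
    for sid, row in clinical.iterrows():
        label = int(row["label"])
        voltage = float(row["tube_voltage"])
        v_off = float(config.voltage_offsets.get(int(voltage), 0.0))
        base_rois: list[VertebraROI] = []
        rep_rois: list[list[VertebraROI]] = [[] for _ in range(config.n_replicates)]
        for vert in VERTEBRAE:
            crops = render_vertebra(label, config, rng, voltage_offset=v_off,
                                    n_crops=1 + config.n_replicates)
            for k, crop in enumerate(crops):
                roi = VertebraROI(
                    image=crop, vertebra=vert,
                    cancellous_mask=derive_cancellous_mask(crop, margin),
                )
                if k == 0:
                    base_rois.append(roi)
                else:
                    rep_rois[k - 1].append(roi)
        clin = {c: row[c] for c in clinical.columns if c not in ("label", "tube_voltage")}
        records.append(SubjectRecord(
            subject_id=str(sid), label=label, clinical=clin,
            vertebrae=base_rois, tube_voltage=voltage,
        ))
        replicates[str(sid)] = rep_rois
    ground_truth = {
        "labels": clinical["label"].to_dict(),
        "informative_labs": list(config.informative_labs),
        "informative_demographics": ["age", "bmi", "mps"],
        "image_effects": {
            "intensity_shift": config.intensity_shift,
            "pore_scale": dict(config.pore_scale),
            "marrow_fraction": dict(config.marrow_fraction),
            "rim_thickness": dict(config.rim_thickness),
        },
    }
    return SyntheticCohort(config=config, clinical=clinical, records=records,
                           replicates=replicates, ground_truth=ground_truth)
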