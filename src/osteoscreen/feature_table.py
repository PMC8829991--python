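"""Assembly of the per-subject feature matrix.

Each subject contributes up to three blocks of features:

* **clinical** — a configurable schema, by default 35 columns: 6 demographic
  characteristics (age, BMI, systolic/diastolic/pulse pressure and the
  three-level menopause status MPS, which subsumes sex) and 29 routine
  laboratory analytes (complete blood count, renal and liver function,
  blood sugar, lipids).  The default analyte panel is a synthetic stand-in
  with plausible names; real cohorts supply their own schema.
* **image** — per vertebra, the 20 texture + 28 shape descriptors; across
  the 1–4 intact vertebrae the mean and population SD of each descriptor
  give (20 + 28) × 2 = 96 per-subject image features.
* **label** — the binary DXA-derived BMD class (osteoporosis vs normal),
  an input here, never computed.

The matrix is typed: every column carries a category (demographic,
laboratory, texture, shape), a scale (numeric or nominal) and the set of
screening-model layers it belongs to.  One-hot encoding and min–max scaling
are provided as leakage-safe operations fitted on training rows only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import VertebraROI, WindowSpec, derive_cancellous_mask, load_roi_image
from .shape import SHAPE_FEATURE_NAMES, shape_vector
from .texture import TEXTURE_FEATURE_NAMES, texture_vector

__all__ = [
    "MPS_LEVELS",
    "CLINICAL_SCHEMA",
    "IMAGE_FEATURE_NAMES",
    "SubjectRecord",
    "FeatureMatrix",
    "extract_vertebra_descriptors",
    "aggregate_subject",
    "build_matrix",
    "one_hot_encode",
    "minmax_scale",
]

MPS_LEVELS = ("menopausal_woman", "non_menopausal_woman", "man")

_DEMOGRAPHICS = ("age", "bmi", "systolic_bp", "diastolic_bp", "pulse_pressure", "mps")

_LAB_PANEL = (
    # complete blood count
    "wbc", "rbc", "hemoglobin", "hematocrit", "platelets", "mcv", "mch",
    "mchc", "rdw", "neutrophils", "lymphocytes", "monocytes",
    # renal function
    "creatinine", "urea", "uric_acid", "egfr",
    # liver function
    "alt", "ast", "alp", "ggt", "total_bilirubin", "albumin", "total_protein",
    # blood sugar
    "fasting_glucose", "hba1c",
    # lipids
    "total_cholesterol", "ldl", "hdl", "triglycerides",
)

#: Default clinical schema: column -> (category, scale).  35 columns.
CLINICAL_SCHEMA: dict[str, tuple[str, str]] = {
    **{c: ("demographic", "numeric") for c in _DEMOGRAPHICS if c != "mps"},
    "mps": ("demographic", "nominal"),
    **{c: ("laboratory", "numeric") for c in _LAB_PANEL},
}

_PER_VERTEBRA = TEXTURE_FEATURE_NAMES + SHAPE_FEATURE_NAMES  # 20 + 28 = 48

#: The 96 per-subject image feature names (vertebra-wise mean and SD).
IMAGE_FEATURE_NAMES = tuple(
    f"{p}_{agg}" for p in _PER_VERTEBRA for agg in ("vmean", "vsd")
)

# layer membership by category; shape features are extracted and audited but
# feed none of the three screening layers (texture alone carried the signal).
_CATEGORY_LAYERS = {
    "demographic": frozenset({1, 2, 3}),
    "laboratory": frozenset({2, 3}),
    "texture": frozenset({3}),
    "shape": frozenset(),
}


@dataclasses.dataclass
class SubjectRecord:
    """One subject's raw inputs: clinical values, label, and intact ROIs."""

    subject_id: str
    label: int  # 1 = osteoporosis, 0 = normal BMD
    clinical: dict[str, object]
    vertebrae: list[VertebraROI] = dataclasses.field(default_factory=list)
    tube_voltage: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        mps = self.clinical.get("mps")
        if mps is not None and mps not in MPS_LEVELS:
            raise ValueError(f"mps must be one of {MPS_LEVELS}, got {mps!r}")


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects × features with per-column metadata and binary labels.

    ``meta`` is indexed by feature name with columns ``category``, ``scale``,
    ``layers`` (frozenset of layer ids) and ``levels`` (tuple for nominal
    columns, else None).
    """

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame
    tube_voltage: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.X.index) != list(self.y.index):
            raise ValueError("X and y indices differ")
        missing = [c for c in self.X.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"columns without metadata: {missing}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def columns_of(self, *, category: str | None = None, layer: int | None = None,
                   scale: str | None = None) -> list[str]:
        keep = pd.Series(True, index=self.meta.index)
        if category is not None:
            keep &= self.meta["category"] == category
        if scale is not None:
            keep &= self.meta["scale"] == scale
        if layer is not None:
            keep &= self.meta["layers"].map(lambda s: layer in s)
        names = [c for c in self.X.columns if keep.get(c, False)]
        return names

    def subset(self, columns: Sequence[str], rows: pd.Index | None = None) -> "FeatureMatrix":
        rows = self.X.index if rows is None else rows
        return FeatureMatrix(
            X=self.X.loc[rows, list(columns)].copy(),
            y=self.y.loc[rows].copy(),
            meta=self.meta.loc[list(columns)].copy(),
            tube_voltage=None if self.tube_voltage is None else self.tube_voltage.loc[rows].copy(),
        )

    def to_csv(self, features_path: str | Path, meta_path: str | Path | None = None) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        if self.tube_voltage is not None:
            out["tube_voltage"] = self.tube_voltage
        out.to_csv(features_path, index_label="subject_id")
        if meta_path is not None:
            payload = {
                name: {
                    "category": row["category"],
                    "scale": row["scale"],
                    "layers": sorted(row["layers"]),
                    "levels": list(row["levels"]) if row["levels"] else None,
                }
                for name, row in self.meta.iterrows()
            }
            Path(meta_path).write_text(json.dumps(payload, indent=1))


def extract_vertebra_descriptors(
    roi: VertebraROI, min_region_area: int = 5
) -> tuple[dict[str, float], dict[str, float] | None]:
    """Texture and shape descriptors of one ROI.

    Shape analysis runs inside the cancellous mask only; a vertebra whose
    mask yields no inter-trabecular region returns ``None`` for the shape
    block (it still contributes texture).
    """
    tex = texture_vector(roi.image)
    try:
        shp = shape_vector(roi.image, roi.cancellous_mask,
                           min_region_area=min_region_area, vertebra=roi.vertebra)
    except ValueError:
        shp = None
    return tex, shp


def aggregate_subject(
    vertebra_vectors: Sequence[tuple[Mapping[str, float], Mapping[str, float] | None]],
) -> dict[str, float]:
    """Vertebra-wise mean and population SD of each image descriptor.

    Input: 1–4 per-vertebra (texture, shape) descriptor pairs; a shape block
    may be None (no surviving region on that vertebra).  Output: the 96
    named per-subject image features; shape aggregates are NaN only when no
    vertebra has a shape block.
    """
    if len(vertebra_vectors) == 0:
        raise ValueError("aggregate_subject requires at least one vertebra")
    out: dict[str, float] = {}
    tex_stack = {n: np.array([t[n] for t, _ in vertebra_vectors])
                 for n in TEXTURE_FEATURE_NAMES}
    shapes = [s for _, s in vertebra_vectors if s is not None]
    for p in _PER_VERTEBRA:
        if p in tex_stack:
            vals = tex_stack[p]
        elif shapes:
            vals = np.array([s[p] for s in shapes])
        else:
            out[f"{p}_vmean"] = np.nan
            out[f"{p}_vsd"] = np.nan
            continue
        out[f"{p}_vmean"] = float(vals.mean())
        out[f"{p}_vsd"] = float(vals.std(ddof=0))
    return {n: out[n] for n in IMAGE_FEATURE_NAMES}


def _feature_meta(clinical_schema: Mapping[str, tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for name, (category, scale) in clinical_schema.items():
        rows.append({
            "name": name, "category": category, "scale": scale,
            "layers": _CATEGORY_LAYERS[category],
            "levels": MPS_LEVELS if name == "mps" else None,
        })
    for name in IMAGE_FEATURE_NAMES:
        category = "texture" if name.split("_")[0] in ("glcm", "gradient", "hist") else "shape"
        rows.append({
            "name": name, "category": category, "scale": "numeric",
            "layers": _CATEGORY_LAYERS[category], "levels": None,
        })
    return pd.DataFrame(rows).set_index("name")


def build_matrix(
    records: Iterable[SubjectRecord],
    clinical_schema: Mapping[str, tuple[str, str]] = CLINICAL_SCHEMA,
) -> FeatureMatrix:
    """Typed feature matrix from subject records.

    Pulse pressure is derived as systolic − diastolic when absent.  Rows
    without CT data carry NaN in the image columns (absent by design; layer
    routing keeps them off layer 3).  Duplicate subject ids are an error.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two subjects")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    labels = pd.Series([r.label for r in records], index=ids, name="label")
    if labels.nunique() < 2:
        raise ValueError("both classes must be present")

    rows = []
    voltages = []
    for rec in records:
        row: dict[str, object] = {}
        for col in clinical_schema:
            row[col] = rec.clinical.get(col, np.nan)
        if pd.isna(row.get("pulse_pressure", np.nan)):
            s, d = row.get("systolic_bp"), row.get("diastolic_bp")
            if s is not None and d is not None and not (pd.isna(s) or pd.isna(d)):
                row["pulse_pressure"] = float(s) - float(d)
        if rec.vertebrae:
            descriptors = [extract_vertebra_descriptors(v) for v in rec.vertebrae]
            row.update(aggregate_subject(descriptors))
        else:
            row.update({n: np.nan for n in IMAGE_FEATURE_NAMES})
        rows.append(row)
        voltages.append(np.nan if rec.tube_voltage is None else rec.tube_voltage)

    columns = list(clinical_schema) + list(IMAGE_FEATURE_NAMES)
    X = pd.DataFrame(rows, index=ids)[columns]
    meta = _feature_meta(clinical_schema)
    return FeatureMatrix(
        X=X, y=labels, meta=meta,
        tube_voltage=pd.Series(voltages, index=ids, name="tube_voltage"),
    )


def one_hot_encode(matrix: FeatureMatrix) -> FeatureMatrix:
    """Expand each k-level nominal column into k binary indicator columns.

    Categories are frozen on the declared level set, so encoding is
    deterministic and an unseen level is an error rather than a silent
    all-zero row.
    """
    nominal = [c for c in matrix.X.columns if matrix.meta.loc[c, "scale"] == "nominal"]
    if not nominal:
        return matrix
    X = matrix.X.copy()
    meta = matrix.meta.copy()
    for col in nominal:
        levels = meta.loc[col, "levels"]
        if levels is None:
            levels = tuple(sorted(X[col].dropna().unique()))
        observed = set(X[col].dropna().unique()) - set(levels)
        if observed:
            raise ValueError(f"column {col!r} has unseen levels {sorted(observed)}")
        insert_at = list(X.columns).index(col)
        base = meta.loc[col]
        X = X.drop(columns=[col])
        meta = meta.drop(index=[col])
        for k, level in enumerate(levels):
            new = f"{col}__{level}"
            X.insert(insert_at + k, new, (matrix.X[col] == level).astype(float))
            meta.loc[new] = {
                "category": base["category"], "scale": "numeric",
                "layers": base["layers"], "levels": None,
            }
    meta = meta.loc[list(X.columns)]
    return FeatureMatrix(X=X, y=matrix.y, meta=meta, tube_voltage=matrix.tube_voltage)


def minmax_scale(train: FeatureMatrix, apply_to: FeatureMatrix | None = None) -> FeatureMatrix:
    """Min–max scale numeric columns using statistics of the training rows.

    x' = (x − min_train) / (max_train − min_train).  A constant training
    column maps everywhere to 0.5 (deterministic degenerate convention);
    out-of-range values in ``apply_to`` are *not* clipped.
    """
    target = train if apply_to is None else apply_to
    numeric = [c for c in target.X.columns if train.meta.loc[c, "scale"] == "numeric"]
    lo = train.X[numeric].min(axis=0)
    hi = train.X[numeric].max(axis=0)
    span = hi - lo
    X = target.X.copy()
    for c in numeric:
        if span[c] > 0:
            X[c] = (X[c] - lo[c]) / span[c]
        else:
            X[c] = X[c].where(X[c].isna(), 0.5)
    return FeatureMatrix(X=X, y=target.y, meta=target.meta, tube_voltage=target.tube_voltage)


def subject_records_from_files(
    cohort_csv: str | Path,
    roi_manifest_csv: str | Path | None = None,
    window: WindowSpec | None = None,
    cancellous_margin: float = 0.1,
) -> list[SubjectRecord]:
    """Read a cohort table (and optional ROI manifest) into subject records.

    The cohort CSV has one row per subject: ``subject_id``, ``label`` and
    clinical columns.  The manifest CSV columns are ``subject_id``,
    ``vertebra``, ``path`` and ``tube_voltage_kV``; paths are resolved
    relative to the manifest's directory.
    """
    cohort = pd.read_csv(cohort_csv, dtype={"subject_id": str})
    if "subject_id" not in cohort or "label" not in cohort:
        raise ValueError("cohort CSV must have subject_id and label columns")
    rois: dict[str, list[VertebraROI]] = {}
    voltage: dict[str, float] = {}
    if roi_manifest_csv is not None:
        manifest_path = Path(roi_manifest_csv)
        manifest = pd.read_csv(manifest_path, dtype={"subject_id": str})
        for _, m in manifest.iterrows():
            img_path = Path(m["path"])
            if not img_path.is_absolute():
                img_path = manifest_path.parent / img_path
            img = load_roi_image(img_path, window=window)
            mask = derive_cancellous_mask(img, margin_fraction=cancellous_margin)
            rois.setdefault(m["subject_id"], []).append(
                VertebraROI(image=img, vertebra=m["vertebra"], cancellous_mask=mask)
            )
            if "tube_voltage_kV" in m:
                voltage[m["subject_id"]] = float(m["tube_voltage_kV"])
    out = []
    clinical_cols = [c for c in cohort.columns if c not in ("subject_id", "label")]
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        out.append(SubjectRecord(
            subject_id=sid,
            label=int(row["label"]),
            clinical={c: row[c] for c in clinical_cols},
            vertebrae=rois.get(sid, []),
            tube_voltage=voltage.get(sid),
        ))
    return out
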