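"""The four-stage statistical feature-selection ledger.

Stages, applied in order (configurable), each with a full audit trail:

1. **Reproducibility (ICC)** — image features only.  A two-way single-measure
   absolute-agreement intraclass correlation coefficient, ICC(2,1), is
   computed across repeated segmentations; features with ICC ≤ 0.8 are
   unstable measurements and are dropped before any label is looked at.
2. **Univariate class difference** — numeric features: two-sided
   Mann–Whitney U (tie-corrected normal approximation); nominal features:
   Pearson chi-square on the level × class table without continuity
   correction.  Keep iff p < α (α = 0.05, no multiplicity correction).
3. **Correlation pruning** — among the surviving numeric features, pairs
   with |Pearson r| ≥ 0.8 are enumerated in descending |r|; from each
   still-alive pair the member with the larger univariate p is dropped
   (tie: the lexicographically later name), so the survivor set contains no
   highly collinear pair and keeps the more discriminative member.
4. **Protocol robustness (Kruskal–Wallis)** — image features only.  Features
   differing significantly across tube-voltage groups reflect the scanner
   protocol rather than bone and are dropped.

Every input feature receives exactly one verdict (kept, or dropped at a
named stage with its statistics), serialisable as CSV + JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .feature_table import FeatureMatrix

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "FeatureSelector",
    "icc_filter",
    "univariate_filter",
    "correlation_prune",
    "protocol_filter",
    "run_selection",
]

_IMAGE_CATEGORIES = ("texture", "shape")
DEFAULT_STAGES = ("icc", "univariate", "correlation", "protocol")


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    corr_threshold: float = 0.8
    icc_threshold: float = 0.8
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must lie in (0, 1]")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclasses.dataclass
class SelectionReport:
    """Per-feature audit of every stage, with keep/drop verdicts."""

    table: pd.DataFrame  # indexed by feature name
    notices: list[str] = dataclasses.field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["verdict"] == "kept"])

    def dropped_at(self, stage: str) -> list[str]:
        return list(self.table.index[self.table["verdict"] == f"dropped@{stage}"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="feature")

    def to_json(self, path: str | Path) -> None:
        summary = {
            "n_features": int(len(self.table)),
            "n_kept": int(len(self.kept)),
            "dropped_per_stage": {
                stage: int((self.table["verdict"] == f"dropped@{stage}").sum())
                for stage in DEFAULT_STAGES
            },
            "kept": self.kept,
            "notices": self.notices,
        }
        Path(path).write_text(json.dumps(summary, indent=1))


def icc_single_absolute(values: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``values`` is subjects × replicates, complete cases only.
    """
    import pingouin as pg

    n, k = values.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": values.ravel(),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score", nan_policy="omit")
    by_type = table.set_index("Type")["ICC"]
    key = "ICC(A,1)" if "ICC(A,1)" in by_type.index else "ICC2"
    icc = float(by_type.loc[key])
    return icc if np.isfinite(icc) else 0.0


def icc_filter(
    replicates: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Reproducibility gate on repeated re-extractions of image features.

    ``replicates`` has a (feature, replicate) MultiIndex on its columns and
    one row per subject.  Returns a table with columns ``icc`` and ``kept``.
    """
    if not isinstance(replicates.columns, pd.MultiIndex):
        raise ValueError("replicates needs (feature, replicate) MultiIndex columns")
    features = replicates.columns.get_level_values(0).unique()
    rows = {}
    for feat in features:
        block = replicates[feat].dropna(axis=0, how="any")
        if block.shape[1] < 2:
            raise ValueError(f"feature {feat!r} has fewer than 2 replicates")
        if block.shape[0] < 3:
            rows[feat] = {"icc": np.nan, "kept": False}
            continue
        vals = block.to_numpy(dtype=float)
        if np.allclose(vals, vals[:, [0]]):
            icc = 1.0  # replicates identical per subject
        else:
            icc = icc_single_absolute(vals)
        rows[feat] = {"icc": icc, "kept": bool(icc > threshold)}
    return pd.DataFrame.from_dict(rows, orient="index")


def _mannwhitney(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([x0, x1])) == 0:
        return float(len(x0) * len(x1) / 2.0), 1.0  # all tied: no evidence
    res = sps.mannwhitneyu(x0, x1, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return float(res.statistic), (p if np.isfinite(p) else 1.0)


def univariate_filter(matrix: FeatureMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Mann–Whitney (numeric) / chi-square (nominal) class-difference filter.

    Rows with a missing value for a feature are excluded from that feature's
    test.  Returns a table with ``test``, ``statistic``, ``p`` and ``kept``.
    """
    y = matrix.y
    if y.nunique() < 2:
        raise ValueError("both classes must be present")
    rows = {}
    for col in matrix.X.columns:
        scale = matrix.meta.loc[col, "scale"]
        series = matrix.X[col]
        ok = series.notna()
        if scale == "numeric":
            x = series[ok].astype(float).to_numpy()
            cls = y[ok].to_numpy()
            if (cls == 0).sum() == 0 or (cls == 1).sum() == 0:
                rows[col] = {"test": "mannwhitney", "statistic": np.nan, "p": np.nan,
                             "kept": False, "reason": "one class entirely missing"}
                continue
            stat, p = _mannwhitney(x[cls == 0], x[cls == 1])
            rows[col] = {"test": "mannwhitney", "statistic": stat, "p": p,
                         "kept": bool(p < alpha), "reason": ""}
        else:
            table = pd.crosstab(series[ok], y[ok])
            if table.shape[0] < 2:
                rows[col] = {"test": "chi2", "statistic": np.nan, "p": np.nan,
                             "kept": False, "reason": "degenerate"}
                continue
            chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
            rows[col] = {"test": "chi2", "statistic": float(chi2), "p": float(p),
                         "kept": bool(p < alpha), "reason": ""}
    return pd.DataFrame.from_dict(rows, orient="index")


def correlation_prune(
    matrix: FeatureMatrix,
    gamma: float = 0.8,
    univariate_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Greedy removal of highly collinear numeric features.

    Pairs with |r| ≥ γ are visited in descending |r| (deterministic name
    tie-break); from each pair whose members are both still alive, the one
    with the larger univariate p is dropped.  Returns a table with
    ``max_abs_r``, ``partner`` and ``kept``.
    """
    numeric = [c for c in matrix.X.columns if matrix.meta.loc[c, "scale"] == "numeric"]
    corr = matrix.X[numeric].corr(method="pearson")
    pvals = univariate_p if univariate_p is not None else pd.Series(0.0, index=numeric)
    pairs = []
    for a_i in range(len(numeric)):
        for b_i in range(a_i + 1, len(numeric)):
            a, b = numeric[a_i], numeric[b_i]
            r = corr.iloc[a_i, b_i]
            if np.isfinite(r) and abs(r) >= gamma:
                pairs.append((abs(r), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = {c: True for c in numeric}
    partner = {c: "" for c in numeric}
    for r, a, b in pairs:
        if not (alive[a] and alive[b]):
            continue
        pa, pb = float(pvals.get(a, 0.0)), float(pvals.get(b, 0.0))
        if pa > pb:
            victim, keeper = a, b
        elif pb > pa:
            victim, keeper = b, a
        else:
            victim, keeper = max(a, b), min(a, b)
        alive[victim] = False
        partner[victim] = keeper
    max_abs = corr.abs().where(~np.eye(len(numeric), dtype=bool)).max(axis=1)
    out = pd.DataFrame({
        "max_abs_r": max_abs,
        "partner": pd.Series(partner),
        "kept": pd.Series(alive),
    })
    return out.loc[numeric]


def protocol_filter(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    features: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Kruskal–Wallis test of each image feature across tube-voltage groups.

    Image features that differ significantly between protocol settings
    measure the scanner, not the bone, and are dropped.  Clinical features
    are never tested here.  With a single usable voltage group the filter is
    a no-op, recorded as a notice.
    """
    notices: list[str] = []
    image_cols = [c for c in matrix.X.columns
                  if matrix.meta.loc[c, "category"] in _IMAGE_CATEGORIES]
    if features is not None:
        image_cols = [c for c in image_cols if c in set(features)]
    if matrix.tube_voltage is None:
        notices.append("no tube-voltage data: protocol filter skipped")
        return pd.DataFrame(columns=["H", "p", "kept"]), notices
    voltage = matrix.tube_voltage
    counts = voltage.dropna().value_counts()
    groups = [v for v, n in counts.items() if n >= 2]
    if len(groups) < 2:
        notices.append(
            f"only {len(groups)} tube-voltage group(s) with ≥2 members: protocol filter skipped"
        )
        return pd.DataFrame(
            {"H": np.nan, "p": np.nan, "kept": True}, index=image_cols
        ), notices
    rows = {}
    for col in image_cols:
        samples = []
        for v in groups:
            vals = matrix.X.loc[(voltage == v) & matrix.X[col].notna(), col]
            samples.append(vals.astype(float).to_numpy())
        if any(len(s) == 0 for s in samples):
            rows[col] = {"H": np.nan, "p": np.nan, "kept": True}
            continue
        try:
            h, p = sps.kruskal(*samples)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        rows[col] = {"H": float(h), "p": float(p), "kept": bool(p >= alpha)}
    return pd.DataFrame.from_dict(rows, orient="index"), notices


def run_selection(
    matrix: FeatureMatrix,
    replicates: pd.DataFrame | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionReport:
    """Run the staged ledger and collect one verdict per input feature."""
    selector = FeatureSelector(config=config)
    selector.fit(matrix, replicates=replicates)
    return selector.report_


class FeatureSelector(BaseEstimator):
    """Sklearn-style wrapper around the staged selection ledger.

    Fitted attributes: ``report_`` (the full :class:`SelectionReport`) and
    ``support_`` (the kept feature names, in input column order).
    """

    def __init__(self, config: SelectionConfig = SelectionConfig()):
        self.config = config

    def fit(self, matrix: FeatureMatrix, replicates: pd.DataFrame | None = None):
        cfg = self.config
        table = pd.DataFrame(index=pd.Index(matrix.X.columns, name="feature"))
        table["verdict"] = "kept"
        table["drop_reason"] = ""
        notices: list[str] = []
        alive = list(matrix.X.columns)
        image_cols = [c for c in matrix.X.columns
                      if matrix.meta.loc[c, "category"] in _IMAGE_CATEGORIES]

        for stage in cfg.stages:
            if stage == "icc":
                if replicates is None:
                    notices.append("no replicate measurements: ICC stage skipped")
                    continue
                res = icc_filter(replicates, threshold=cfg.icc_threshold)
                table.loc[res.index, "icc"] = res["icc"]
                for feat in res.index[~res["kept"]]:
                    if feat in alive:
                        alive.remove(feat)
                        table.loc[feat, "verdict"] = "dropped@icc"
                        table.loc[feat, "drop_reason"] = (
                            f"ICC {res.loc[feat, 'icc']:.3f} ≤ {cfg.icc_threshold}"
                        )
            elif stage == "univariate":
                sub = matrix.subset(alive)
                res = univariate_filter(sub, alpha=cfg.alpha)
                table.loc[res.index, "univariate_test"] = res["test"]
                table.loc[res.index, "univariate_statistic"] = res["statistic"]
                table.loc[res.index, "univariate_p"] = res["p"]
                for feat in res.index[~res["kept"]]:
                    alive.remove(feat)
                    table.loc[feat, "verdict"] = "dropped@univariate"
                    reason = res.loc[feat, "reason"]
                    table.loc[feat, "drop_reason"] = (
                        reason or f"p {res.loc[feat, 'p']:.3g} ≥ {cfg.alpha}"
                    )
            elif stage == "correlation":
                sub = matrix.subset(alive)
                pvals = table.get("univariate_p")
                res = correlation_prune(sub, gamma=cfg.corr_threshold, univariate_p=pvals)
                table.loc[res.index, "max_abs_r"] = res["max_abs_r"]
                table.loc[res.index, "corr_partner"] = res["partner"]
                for feat in res.index[~res["kept"]]:
                    alive.remove(feat)
                    table.loc[feat, "verdict"] = "dropped@correlation"
                    table.loc[feat, "drop_reason"] = (
                        f"|r| ≥ {cfg.corr_threshold} with {res.loc[feat, 'partner']}"
                    )
            elif stage == "protocol":
                sub = matrix.subset(alive)
                res, stage_notices = protocol_filter(sub, alpha=cfg.alpha)
                notices.extend(stage_notices)
                if len(res):
                    table.loc[res.index, "kw_H"] = res["H"]
                    table.loc[res.index, "kw_p"] = res["p"]
                    for feat in res.index[~res["kept"]]:
                        alive.remove(feat)
                        table.loc[feat, "verdict"] = "dropped@protocol"
                        table.loc[feat, "drop_reason"] = (
                            f"Kruskal–Wallis p {res.loc[feat, 'p']:.3g} < {cfg.alpha}"
                        )
        # features never reached by any stage (e.g. image features with no
        # replicates in a matrix whose subjects lack CT) keep their verdict.
        del image_cols
        self.report_ = SelectionReport(table=table, notices=notices)
        self.support_ = [c for c in matrix.X.columns if c in set(self.report_.kept)]
        return self

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if not hasattr(self, "support_"):
            raise RuntimeError("FeatureSelector is not fitted")
        cols = [c for c in self.support_ if c in matrix.X.columns]
        return matrix.subset(cols)
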