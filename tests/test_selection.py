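import numpy as np
import pandas as pd
import pytest

from osteoscreen.selection import (
    SelectionConfig,
    correlation_prune,
    icc_filter,
    icc_single_absolute,
    protocol_filter,
    run_selection,
    univariate_filter,
)

from conftest import make_matrix


def _replicate_frame(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Build the (feature, replicate) MultiIndex frame from per-feature
    subject × replicate arrays."""
    frames = {}
    for feat, arr in values.items():
        frames[feat] = pd.DataFrame(
            arr, columns=range(arr.shape[1]),
            index=[f"S{i}" for i in range(arr.shape[0])])
    wide = pd.concat(frames, axis=1)
    return wide


class TestIccFilter:
    def test_identical_replicates_kept_with_icc_one(self, rng):
        base = rng.normal(size=(30, 1))
        rep = _replicate_frame({"f": np.repeat(base, 3, axis=1)})
        res = icc_filter(rep, threshold=0.8)
        assert res.loc["f", "icc"] == 1.0 and res.loc["f", "kept"]

    def test_independent_noise_dropped(self, rng):
        arr = rng.normal(size=(100, 2))  # second replicate unrelated
        res = icc_filter(_replicate_frame({"f": arr}), threshold=0.8)
        assert abs(res.loc["f", "icc"]) < 0.3
        assert not res.loc["f", "kept"]

    def test_variance_component_recovery(self, rng):
        # σ²_subject/(σ²_subject+σ²_error) = 0.9 → ICC ≈ 0.9 at n = 200
        subject = rng.normal(0, 3.0, size=(200, 1))
        noise = rng.normal(0, 1.0, size=(200, 3))
        icc = icc_single_absolute(subject + noise)
        assert icc == pytest.approx(0.9, abs=0.05)

    def test_single_replicate_rejected(self, rng):
        rep = _replicate_frame({"f": rng.normal(size=(10, 1))})
        with pytest.raises(ValueError, match="replicates"):
            icc_filter(rep)


class TestUnivariateFilter:
    def test_fully_separated_feature_kept(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(100, 1, 30)])
        y = np.array([0] * 30 + [1] * 30)
        m = make_matrix(pd.DataFrame({"sep": x}), y)
        res = univariate_filter(m)
        assert res.loc["sep", "p"] < 1e-6 and res.loc["sep", "kept"]

    def test_identical_distribution_dropped(self):
        x = np.tile(np.arange(20.0), 2)
        y = np.array([0] * 20 + [1] * 20)
        m = make_matrix(pd.DataFrame({"same": x}), y)
        res = univariate_filter(m)
        assert res.loc["same", "p"] >= 0.05 and not res.loc["same", "kept"]

    def test_constant_feature_gets_p_one(self):
        m = make_matrix(pd.DataFrame({"const": np.ones(20)}),
                        np.array([0] * 10 + [1] * 10))
        res = univariate_filter(m)
        assert res.loc["const", "p"] == 1.0

    def test_independent_factor_chi2_zero(self):
        # exact proportional 3-level factor → χ² = 0 → dropped
        levels = (["a"] * 4 + ["b"] * 2 + ["c"] * 2) * 2
        y = [0] * 8 + [1] * 8
        m = make_matrix(pd.DataFrame({"f": levels}), y, scales={"f": "nominal"})
        res = univariate_filter(m)
        assert res.loc["f", "statistic"] == pytest.approx(0.0)
        assert not res.loc["f", "kept"]

    def test_single_level_factor_degenerate(self):
        m = make_matrix(pd.DataFrame({"f": ["x"] * 10}),
                        [0] * 5 + [1] * 5, scales={"f": "nominal"})
        res = univariate_filter(m)
        assert res.loc["f", "reason"] == "degenerate"


class TestCorrelationPrune:
    def test_duplicated_feature_one_dropped(self, rng):
        base = rng.normal(size=50)
        X = pd.DataFrame({"orig": base, "copy": base})
        m = make_matrix(X, rng.integers(0, 2, 50))
        res = correlation_prune(m, gamma=0.8)
        assert res["kept"].sum() == 1

    def test_negated_feature_caught_by_absolute_rule(self, rng):
        base = rng.normal(size=50)
        m = make_matrix(pd.DataFrame({"x": base, "neg": -base}),
                        rng.integers(0, 2, 50))
        res = correlation_prune(m, gamma=0.8)
        assert res["kept"].sum() == 1

    def test_drop_rule_prefers_smaller_univariate_p(self, rng):
        base = rng.normal(size=60)
        X = pd.DataFrame({"good": base, "bad": base + rng.normal(0, 0.01, 60)})
        m = make_matrix(X, rng.integers(0, 2, 60))
        pvals = pd.Series({"good": 0.001, "bad": 0.4})
        res = correlation_prune(m, gamma=0.8, univariate_p=pvals)
        assert res.loc["good", "kept"] and not res.loc["bad", "kept"]
        assert res.loc["bad", "partner"] == "good"

    def test_independent_features_untouched(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 10)),
                         columns=[f"f{i}" for i in range(10)])
        m = make_matrix(X, rng.integers(0, 2, 500))
        res = correlation_prune(m, gamma=0.8)
        assert res["kept"].all()

    def test_survivors_have_no_high_correlation(self, rng):
        base = rng.normal(size=(100, 3))
        X = pd.DataFrame({
            "a": base[:, 0], "b": base[:, 0] + rng.normal(0, 0.1, 100),
            "c": base[:, 1], "d": base[:, 1] * -1 + rng.normal(0, 0.1, 100),
            "e": base[:, 2],
        })
        m = make_matrix(X, rng.integers(0, 2, 100))
        res = correlation_prune(m, gamma=0.8)
        kept = list(res.index[res["kept"]])
        corr = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert (corr < 0.8).all()


class TestProtocolFilter:
    def _image_matrix(self, rng, voltage, extra=None):
        X = pd.DataFrame({"tex": rng.normal(size=len(voltage))})
        if extra:
            for k, v in extra.items():
                X[k] = v
        cats = {c: "texture" for c in X.columns}
        cats.update({"clin": "laboratory"} if "clin" in X.columns else {})
        return make_matrix(X, rng.integers(0, 2, len(voltage)),
                           categories=cats, voltage=voltage)

    def test_voltage_dependent_feature_dropped(self, rng):
        voltage = np.repeat([80, 120, 140], 30)
        m = self._image_matrix(rng, voltage)
        m.X["tex"] = voltage * 0.1 + rng.normal(0, 0.1, 90)
        res, _ = protocol_filter(m)
        assert not res.loc["tex", "kept"]

    def test_voltage_independent_feature_kept(self, rng):
        voltage = np.repeat([80, 120, 140], 30)
        m = self._image_matrix(rng, voltage)
        res, _ = protocol_filter(m)
        assert res.loc["tex", "kept"]

    def test_clinical_features_never_tested(self, rng):
        voltage = np.repeat([80, 120], 20)
        m = self._image_matrix(rng, voltage,
                               extra={"clin": voltage * 1.0})
        m.meta.loc["clin", "category"] = "laboratory"
        res, _ = protocol_filter(m)
        assert "clin" not in res.index

    def test_single_group_is_noop_with_notice(self, rng):
        voltage = np.full(30, 120)
        m = self._image_matrix(rng, voltage)
        res, notices = protocol_filter(m)
        assert res["kept"].all()
        assert any("skipped" in n for n in notices)


def planted_matrix(rng, n=200):
    """A cohort with known verdict for every feature.

    informative_*  : large class shift            → kept
    exactnull_*    : identical value multisets    → dropped@univariate
    duplicate      : copy of informative_1        → dropped@correlation
    confounded     : class shift + voltage effect → dropped@protocol
    """
    y = np.array([0, 1] * (n // 2))
    voltage = rng.permuted(np.repeat([80, 120, 140], [n // 5, n - 2 * (n // 5), n // 5]))
    cols, cats = {}, {}
    for k in range(3):
        cols[f"informative_{k}"] = rng.normal(0, 1, n) + 2.5 * y
        cats[f"informative_{k}"] = "texture"
    for k in range(3):
        vals = rng.normal(0, 1, n // 2)
        col = np.empty(n)
        col[y == 0] = vals
        col[y == 1] = rng.permuted(vals)  # exact same multiset per class
        cols[f"exactnull_{k}"] = col
        cats[f"exactnull_{k}"] = "texture"
    cols["duplicate"] = cols["informative_1"].copy()
    cats["duplicate"] = "texture"
    cols["confounded"] = 2.5 * y + 0.2 * voltage + rng.normal(0, 0.5, n)
    cats["confounded"] = "texture"
    X = pd.DataFrame(cols)
    return make_matrix(X, y, categories=cats, voltage=voltage)


class TestRunSelection:
    def test_planted_cohort_verdicts_match_exactly(self, rng):
        m = planted_matrix(rng)
        report = run_selection(m)
        t = report.table
        for k in (0, 2):
            assert t.loc[f"informative_{k}", "verdict"] == "kept"
        for k in range(3):
            assert t.loc[f"exactnull_{k}", "verdict"] == "dropped@univariate"
        # exactly one of the duplicated pair survives the pruning stage
        pair = {t.loc["informative_1", "verdict"], t.loc["duplicate", "verdict"]}
        assert pair == {"kept", "dropped@correlation"}
        assert t.loc["confounded", "verdict"] == "dropped@protocol"

    def test_vacuous_thresholds_keep_everything(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 8)),
                         columns=[f"f{i}" for i in range(8)])
        m = make_matrix(X, rng.integers(0, 2, 60))
        cfg = SelectionConfig(alpha=1.0, corr_threshold=1.0, icc_threshold=0.0)
        report = run_selection(m, config=cfg)
        assert report.kept == list(X.columns)

    def test_empty_kept_set_is_legal(self, rng):
        # exact-null features only: everything dropped, nothing raised
        y = np.array([0, 1] * 25)
        vals = rng.normal(size=25)
        col = np.empty(50)
        col[y == 0] = vals
        col[y == 1] = vals
        m = make_matrix(pd.DataFrame({"f": col}), y)
        report = run_selection(m)
        assert report.kept == []

    def test_kept_set_closed_under_stages(self, rng):
        m = planted_matrix(rng)
        report = run_selection(m)
        kept = report.kept
        sub = m.subset(kept)
        again = run_selection(sub)
        assert again.kept == kept

    def test_deterministic_under_permutations(self, rng):
        m = planted_matrix(rng)
        kept_a = set(run_selection(m).kept)
        rows = rng.permutation(m.X.index)
        cols = list(rng.permutation(m.X.columns))
        m2 = m.subset(cols, rows=pd.Index(rows))
        kept_b = set(run_selection(m2).kept)
        assert kept_a == kept_b

    def test_type_one_error_rate_near_alpha(self, rng):
        # pure-noise cohorts: kept fraction after the univariate stage ≈ 0.05
        n_feat, n_sub, n_seeds = 200, 100, 20
        kept_total = 0
        for s in range(n_seeds):
            local = np.random.default_rng(1000 + s)
            X = pd.DataFrame(local.normal(size=(n_sub, n_feat)),
                             columns=[f"f{i}" for i in range(n_feat)])
            y = np.array([0, 1] * (n_sub // 2))
            res = univariate_filter(make_matrix(X, y), alpha=0.05)
            kept_total += int(res["kept"].sum())
        trials = n_feat * n_seeds
        expected = 0.05 * trials
        band = 3 * np.sqrt(trials * 0.05 * 0.95)
        assert abs(kept_total - expected) <= band

    def test_icc_stage_integrates(self, small_matrix, replicate_frame):
        report = run_selection(small_matrix, replicates=replicate_frame)
        t = report.table
        assert set(t["verdict"]) <= {
            "kept", "dropped@icc", "dropped@univariate",
            "dropped@correlation", "dropped@protocol"}
        assert (t["verdict"] == "dropped@icc").sum() > 0
        assert t["icc"].notna().sum() == 96
        assert len(report.kept) > 0

    def test_report_serialization(self, rng, tmp_path):
        report = run_selection(planted_matrix(rng))
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        back = pd.read_csv(tmp_path / "r.csv", index_col="feature")
        assert list(back.index) == list(report.table.index)
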