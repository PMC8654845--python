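"""Evaluation metrics: pair-enumeration and tail-inversion oracles for
AUC and Clopper-Pearson, confusion identities, per-stage tallies, PCA and
interference robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import salivadx.evalreport as er


def pair_count_auc(probs, labels):
    """Oracle: AUC as the fraction of (case, control) pairs ranked
    correctly, ties counting one half."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    cases = probs[labels == 1]
    controls = probs[labels == 0]
    wins = ties = 0
    for c in cases:
        for k in controls:
            wins += c > k
            ties += c == k
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def cp_bisect(k, n, level, upper):
    """Oracle: Clopper-Pearson bound by bisection on the binomial tail."""
    from scipy.stats import binom

    alpha = (1 - level) / 2
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if upper:
            if binom.cdf(k, n, mid) > alpha:
                lo = mid
            else:
                hi = mid
        else:
            if binom.sf(k - 1, n, mid) < alpha:
                lo = mid
            else:
                hi = mid
    return (lo + hi) / 2


class TestRocAuc:
    def test_perfect_ordering(self):
        roc = er.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_all_tied_probabilities(self):
        roc = er.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_six_sample_toy_matches_pair_enumeration(self):
        probs = [0.9, 0.6, 0.6, 0.4, 0.3, 0.6]
        labels = [1, 1, 0, 0, 0, 1]
        roc = er.roc_auc(probs, labels)
        assert roc.auc == pytest.approx(pair_count_auc(probs, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            er.roc_auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=4, max_size=25))
    def test_auc_equals_mwu_rank_statistic(self, data):
        """Tie-aware identity: AUC == U / (n1*n2) with midranks, and both
        equal the pair-count oracle."""
        probs = np.array([d[0] for d in data])
        labels = np.array([d[1] for d in data], dtype=int)
        if labels.sum() in (0, len(labels)):
            return
        from scipy.stats import rankdata

        roc = er.roc_auc(probs, labels)
        n1, n0 = labels.sum(), (1 - labels).sum()
        ranks = rankdata(probs)
        u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
        assert roc.auc == pytest.approx(u1 / (n1 * n0), abs=1e-9)
        assert roc.auc == pytest.approx(pair_count_auc(probs, labels), abs=1e-9)


class TestClopperPearson:
    def test_boundaries_exact(self):
        assert er.clopper_pearson(0, 10)[0] == 0.0
        assert er.clopper_pearson(10, 10)[1] == 1.0

    def test_symmetric_at_half(self):
        lo, hi = er.clopper_pearson(5, 10)
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 10), (3, 10), (7, 20), (19, 20), (50, 60)])
    def test_matches_binomial_tail_inversion(self, k, n):
        lo, hi = er.clopper_pearson(k, n, 0.95)
        if k > 0:
            assert lo == pytest.approx(cp_bisect(k, n, 0.95, upper=False), abs=1e-8)
        if k < n:
            assert hi == pytest.approx(cp_bisect(k, n, 0.95, upper=True), abs=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(2, 9), (12, 13), (276, 282)]:
            lo, hi = er.clopper_pearson(k, n)
            sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(sm_lo, abs=1e-10)
            assert hi == pytest.approx(sm_hi, abs=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(1, 50), st.integers(0, 50))
    def test_interval_contains_point_estimate(self, n, k):
        k = min(k, n)
        lo, hi = er.clopper_pearson(k, n)
        assert lo - 1e-12 <= k / n <= hi + 1e-12


class TestSensSpec:
    def test_reference_confusion_reproduces_specificity(self):
        """276 true negatives and 6 false positives give a specificity of
        97.9% at one decimal."""
        probs = np.array([0.9] * 6 + [0.1] * 276)
        labels = np.zeros(282, dtype=int)
        cc, sens, spec = er.sens_spec(probs, labels)
        assert cc.tn == 276 and cc.fp == 6
        assert round(100 * spec["estimate"], 1) == 97.9
        assert not sens["defined"]  # no cases in this cohort

    def test_stage1_twelve_of_thirteen(self):
        ids = [f"c{i}" for i in range(13)]
        p = pd.Series([0.8] * 12 + [0.2], index=ids)
        tally = er.per_stage_sensitivity(
            p, pd.Series(["case"] * 13, index=ids), pd.Series(["S1"] * 13, index=ids)
        )
        assert tally.loc["S1", "detected"] == 12
        assert round(100 * tally.loc["S1", "sensitivity"], 1) == 92.3

    def test_confusion_identities(self, rng):
        probs = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        cc, sens, spec = er.sens_spec(probs, labels, threshold=0.4)
        assert cc.tp + cc.fn == labels.sum()
        assert cc.tn + cc.fp == (1 - labels).sum()
        assert sens["estimate"] == pytest.approx(cc.sensitivity)
        assert spec["estimate"] == pytest.approx(cc.specificity)

    def test_strict_threshold_ties_are_control(self):
        cc = er.confusion(np.array([0.5, 0.50001]), np.array([1, 1]), 0.5)
        assert cc.tp == 1 and cc.fn == 1


class TestPerStage:
    def test_groupby_oracle_and_unstaged_bucket(self, rng):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(np.where(rng.random(n) < 0.6, "case", "control"), index=ids)
        stage_pool = ["OPMD", "S1", "S2", "S3", "S4", "none"]
        stages = pd.Series(rng.choice(stage_pool, size=n), index=ids)
        stages[labels == "control"] = "none"
        probs = pd.Series(rng.uniform(size=n), index=ids)
        tally = er.per_stage_sensitivity(probs, labels, stages)
        detected = probs > 0.5
        for stage in ["OPMD", "S1", "S2", "S3", "S4"]:
            mask = (labels == "case") & (stages == stage)
            assert tally.loc[stage, "total"] == int(mask.sum())
            assert tally.loc[stage, "detected"] == int((detected & mask).sum())
        unstaged = (labels == "case") & (stages == "none")
        assert tally.loc["unstaged", "total"] == int(unstaged.sum())
        assert tally["total"].sum() == (labels == "case").sum()

    def test_empty_stage_flagged_not_thrown(self):
        ids = ["a", "b"]
        tally = er.per_stage_sensitivity(
            pd.Series([0.9, 0.1], index=ids),
            pd.Series(["case", "control"], index=ids),
            pd.Series(["S2", "none"], index=ids),
        )
        assert not tally.loc["S3", "defined"]
        assert tally.loc["S3", "total"] == 0


class TestPca:
    def test_collinear_data_loads_on_single_component(self):
        t = np.linspace(-2, 2, 12)
        df = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        coefs = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        _, var = er.pca_top_features(df, coefs, k=3)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_sums_below_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 8)), columns=list("abcdefgh"))
        coefs = pd.Series(rng.normal(size=8), index=list("abcdefgh"))
        coords, var = er.pca_top_features(df, coefs, k=5)
        assert var.sum() <= 1.0 + 1e-9
        assert coords.shape[0] == 30

    def test_matches_eigendecomposition_oracle(self):
        X = np.array([[1.0, 2, 0], [2, 1, 1], [3, 4, 2], [0, 1, 1], [2, 3, 0]])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        coefs = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        _, var = er.pca_top_features(df, coefs, k=3)
        C = np.cov((X - X.mean(0)).T)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(var, eig[: len(var)] / eig.sum(), atol=1e-9)

    def test_k_too_large_rejected(self):
        df = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="exceeds"):
            er.pca_top_features(df, pd.Series({"a": 1.0}), k=2)


class TestInterferenceDelta:
    def _meta(self, rows):
        return pd.DataFrame(rows).set_index("sample_id")

    def test_identical_pairs_zero_delta(self):
        meta = self._meta(
            [
                {"sample_id": "s0", "subject_id": "u0", "interference": "none"},
                {"sample_id": "s1", "subject_id": "u0", "interference": "gum"},
            ]
        )
        probs = pd.Series({"s0": 0.42, "s1": 0.42})
        df, summary = er.interference_delta(probs, meta)
        assert summary["max_delta"] == 0.0

    def test_unpaired_subject_skipped(self):
        meta = self._meta(
            [
                {"sample_id": "s0", "subject_id": "u0", "interference": "gum"},
                {"sample_id": "s1", "subject_id": "u1", "interference": "none"},
                {"sample_id": "s2", "subject_id": "u1", "interference": "brushing"},
            ]
        )
        probs = pd.Series({"s0": 0.9, "s1": 0.2, "s2": 0.4})
        df, summary = er.interference_delta(probs, meta)
        assert summary["n_pairs"] == 1
        assert df.iloc[0]["delta"] == pytest.approx(0.2)


class TestGroupByHierarchy:
    def test_two_genera_grouping(self):
        res = pd.DataFrame({"clr_mean_diff": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        mapping = {"a": ("G1", "P1"), "b": ("G1", "P1"), "c": ("G2", "P1")}
        out = er.group_by_hierarchy(res, mapping, ("genus", "phylum"), "clr_mean_diff")
        assert set(out["genus"]) == {"G1", "G2"}
        assert out["clr_mean_diff_sum"].sum() == pytest.approx(6.0)

    def test_empty_map_all_unmapped(self):
        res = pd.DataFrame({"v": [1.0, 1.0]}, index=["a", "b"])
        out = er.group_by_hierarchy(res, {}, ("genus", "phylum"), "v")
        assert list(out["genus"]) == ["unmapped"]
        assert out["v_sum"].iloc[0] == pytest.approx(2.0)


class TestBuildReport:
    def test_report_identities_and_serialisation(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        labels = np.array(["case"] * 15 + ["control"] * 15)
        stages = np.where(labels == "case", "S2", "none")
        meta = pd.DataFrame(
            {"label": labels, "stage": stages, "sex": "F", "smoking": "never"},
            index=pd.Index(ids, name="sample_id"),
        )
        probs = pd.Series(
            np.clip(rng.normal(np.where(labels == "case", 0.8, 0.2), 0.1), 0.01, 0.99),
            index=ids,
        )
        rep = er.build_report(probs, meta)
        assert rep.confusion.tp + rep.confusion.fn == 15
        d = rep.as_dict()
        assert d["sensitivity"]["estimate"] == pytest.approx(rep.confusion.sensitivity)
        assert 0 <= d["auc"] <= 1
        import json

        json.dumps(d)  # must be serialisable
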