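import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from healthspace import (
    InsufficientDataError,
    characterize_clusters,
    two_way_anova,
)
from healthspace.response import ResponseSet
from healthspace.subgroups import summary_report

from conftest import make_table


def balanced_design(cell_means, n_per_cell=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    values, cl, tr = [], [], []
    for (c, t), mu in cell_means.items():
        for _ in range(n_per_cell):
            values.append(mu + noise * rng.normal())
            cl.append(c)
            tr.append(t)
    return np.array(values), cl, tr


class TestTwoWayAnova:
    def test_additive_cell_means_have_zero_interaction(self):
        # (1 + 4) == (2 + 3): perfectly additive cell means
        means = {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 4.0}
        rng = np.random.default_rng(1)
        values, cl, tr = [], [], []
        for (c, t), mu in means.items():
            for d in (-0.5, 0.0, 0.5):  # same within-cell pattern everywhere
                values.append(mu + d)
                cl.append(c)
                tr.append(t)
        res = two_way_anova(values, cl, tr)
        assert res["interaction"][0] == pytest.approx(0.0, abs=1e-10)
        assert res["interaction"][1] == pytest.approx(1.0, abs=1e-10)

    def test_pure_interaction_pattern_dominates(self):
        means = {("a", "x"): 0.0, ("a", "y"): 0.0, ("b", "x"): 0.0, ("b", "y"): 1.0}
        values, cl, tr = balanced_design(means, noise=1e-4, seed=2)
        res = two_way_anova(values, cl, tr)
        assert res["interaction"][0] > 1e4
        assert res["interaction"][1] < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_unbalanced_type2_matches_statsmodels_oracle(self, seed):
        """Independent GLM oracle: statsmodels anova_lm with Type II SS."""
        rng = np.random.default_rng(seed)
        n = 24
        cl = rng.choice(["a", "b", "c"], size=n)
        tr = rng.choice(["x", "y"], size=n)
        # guarantee every cell occupied
        cl[:6] = ["a", "a", "b", "b", "c", "c"]
        tr[:6] = ["x", "y", "x", "y", "x", "y"]
        y = rng.normal(size=n) + (cl == "b") * 0.5 + (tr == "y") * 1.0
        res = two_way_anova(y, cl, tr, ss_type=2)
        df = pd.DataFrame({"y": y, "cl": cl, "tr": tr})
        fit = ols("y ~ C(cl) * C(tr)", data=df).fit()
        oracle = sm.stats.anova_lm(fit, typ=2)
        assert res["cluster"][0] == pytest.approx(oracle.loc["C(cl)", "F"], abs=1e-8)
        assert res["treatment"][0] == pytest.approx(oracle.loc["C(tr)", "F"], abs=1e-8)
        assert res["interaction"][0] == pytest.approx(
            oracle.loc["C(cl):C(tr)", "F"], abs=1e-8
        )
        for eff, key in [("cluster", "C(cl)"), ("treatment", "C(tr)"),
                         ("interaction", "C(cl):C(tr)")]:
            assert res[eff][1] == pytest.approx(oracle.loc[key, "PR(>F)"], abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_balanced_type2_equals_classical_decomposition(self, seed):
        """On balanced designs Type II SS reduce to the textbook sums."""
        rng = np.random.default_rng(100 + seed)
        means = {(c, t): rng.normal() for c in "ab" for t in "xy"}
        y, cl, tr = balanced_design(means, n_per_cell=4, noise=1.0, seed=seed)
        res = two_way_anova(y, cl, tr, ss_type=2)
        df = pd.DataFrame({"y": y, "cl": cl, "tr": tr})
        fit = ols("y ~ C(cl) * C(tr)", data=df).fit()
        classical = sm.stats.anova_lm(fit, typ=1)  # Type I == classical when balanced
        assert res["cluster"][0] == pytest.approx(classical.loc["C(cl)", "F"], abs=1e-10)
        assert res["treatment"][0] == pytest.approx(classical.loc["C(tr)", "F"], abs=1e-10)

    def test_empty_cell_raises_naming_it(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        cl = ["a", "a", "a", "b", "b", "b"]
        tr = ["x", "y", "x", "x", "x", "x"]  # cell (b, y) empty
        with pytest.raises(InsufficientDataError, match="b.*y"):
            two_way_anova(values, cl, tr)

    def test_zero_residual_variance_warns_nan(self):
        means = {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 7.0}
        values, cl, tr = balanced_design(means, n_per_cell=2, noise=0.0)
        with pytest.warns(UserWarning, match="residual"):
            res = two_way_anova(values, cl, tr)
        assert np.isnan(res["interaction"][1])


def _responses_with_clusters(cluster_of):
    subjects = sorted(cluster_of)
    table = pd.DataFrame({"subject_id": subjects})
    table["x"] = 0.0
    table["cluster"] = pd.array([cluster_of[s] for s in subjects], dtype="Int64")
    table["outlier"] = False
    return ResponseSet(table=table, axis_names=["x"])


def _study_with_interaction(seed=0, delta=4.0, n_per_group=8):
    """Parameter 'ipa' responds to treatment only in cluster 1."""
    rng = np.random.default_rng(seed)
    records = []
    cluster_of = {}
    for i in range(2 * n_per_group):
        s = f"s{i:02d}"
        cluster_of[s] = 1 if i < n_per_group else 2
        for arm in ("treated", "control"):
            effect = delta if (arm == "treated" and cluster_of[s] == 1) else 0.0
            records.append(
                (s, arm, "t0", effect + rng.normal(), rng.normal())
            )
    return make_table(records, ["ipa", "background"]), cluster_of


class TestCharacterizeClusters:
    def test_planted_interaction_parameter_gets_interaction_verdict(self):
        table, cluster_of = _study_with_interaction(seed=1)
        result = characterize_clusters(table, _responses_with_clusters(cluster_of))
        row = result.set_index("parameter_id").loc["ipa"]
        assert row["verdict"] == "interaction"
        assert row["interaction_q"] <= row["interaction_p"] * 2 + 1e-12

    def test_verdicts_invariant_to_cluster_label_permutation(self):
        table, cluster_of = _study_with_interaction(seed=2)
        r1 = characterize_clusters(table, _responses_with_clusters(cluster_of))
        swapped = {s: 3 - c for s, c in cluster_of.items()}
        r2 = characterize_clusters(table, _responses_with_clusters(swapped))
        assert r1["verdict"].tolist() == r2["verdict"].tolist()

    def test_constant_parameter_verdict_none_with_warning(self):
        table, cluster_of = _study_with_interaction(seed=3)
        values = table.values.copy()
        values["background"] = 7.0
        from healthspace import SampleTable

        table2 = SampleTable(values, table.meta)
        with pytest.warns(UserWarning, match="background"):
            result = characterize_clusters(table2, _responses_with_clusters(cluster_of))
        assert (
            result.set_index("parameter_id").loc["background", "verdict"] == "none"
        )

    def test_single_cluster_raises(self):
        table, cluster_of = _study_with_interaction(seed=4)
        all_one = {s: 1 for s in cluster_of}
        with pytest.raises(InsufficientDataError):
            characterize_clusters(table, _responses_with_clusters(all_one))

    def test_treatment_main_effect_without_interaction(self):
        rng = np.random.default_rng(9)
        records = []
        cluster_of = {}
        for i in range(16):
            s = f"s{i:02d}"
            cluster_of[s] = 1 + i % 2
            for arm in ("treated", "control"):
                shift = 3.0 if arm == "treated" else 0.0  # same in both clusters
                records.append((s, arm, "t0", shift + rng.normal()))
        table = make_table(records, ["p"])
        result = characterize_clusters(table, _responses_with_clusters(cluster_of))
        assert result.iloc[0]["verdict"] == "treatment_main"

    def test_summary_report_lists_interaction_parameters(self):
        table, cluster_of = _study_with_interaction(seed=5)
        result = characterize_clusters(table, _responses_with_clusters(cluster_of))
        report = summary_report(result)
        assert "ipa" in report and "interaction" in report
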