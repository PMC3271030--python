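import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from healthspace import (
    Dendrogram,
    ResponseClustering,
    ResponseSet,
    cluster_responses,
    flag_outliers,
    response_vectors,
)
from healthspace.space import ScoreSet


def make_scores(rows, axes=("ox", "infl", "met")):
    df = pd.DataFrame(rows, columns=["subject_id", "arm", *axes])
    return ScoreSet(scores=df, axis_names=list(axes))


def make_responses(vectors, axes=None, subjects=None):
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    axes = axes or [f"a{i}" for i in range(vectors.shape[1])]
    subjects = subjects or [f"s{i + 1}" for i in range(len(vectors))]
    table = pd.DataFrame(vectors, columns=axes)
    table.insert(0, "subject_id", subjects)
    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table["outlier"] = False
    return ResponseSet(table=table, axis_names=axes)


def upgma_heights_bruteforce(X):
    """O(n^3) average-linkage agglomeration; returns sorted merge heights."""
    D = squareform(pdist(X))
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return np.sort(heights)


class TestResponseVectors:
    def test_anchor_mean_subject_has_unit_response(self):
        scores = make_scores(
            [("s1", "treated", 0.0, 0.0, 0.0), ("s1", "control", 1.0, 1.0, 1.0),
             ("s2", "treated", 0.1, 0.1, 0.1), ("s2", "control", 0.9, 0.9, 0.9)]
        )
        resp = response_vectors(scores)
        row = resp.table.set_index("subject_id").loc["s1"]
        assert [row["ox"], row["infl"], row["met"]] == [1.0, 1.0, 1.0]

    def test_identical_arms_give_zero_vector(self):
        scores = make_scores(
            [("s1", "treated", 0.3, -0.2, 0.5), ("s1", "control", 0.3, -0.2, 0.5),
             ("s2", "treated", 0.0, 0.0, 0.0), ("s2", "control", 1.0, 1.0, 1.0)]
        )
        resp = response_vectors(scores)
        row = resp.table.set_index("subject_id").loc["s1"]
        assert [row["ox"], row["infl"], row["met"]] == [0.0, 0.0, 0.0]

    def test_componentwise_subtraction(self):
        scores = make_scores(
            [("s1", "treated", 0.2, -0.1, 0.0), ("s1", "control", 1.0, 0.4, -0.2)]
        )
        resp = response_vectors(scores)
        row = resp.table.iloc[0]
        np.testing.assert_allclose(
            [row["ox"], row["infl"], row["met"]], [0.8, 0.5, -0.2], atol=1e-12
        )

    def test_incomplete_subject_dropped_with_warning(self):
        scores = make_scores(
            [("s1", "treated", 0.0, 0.0, 0.0), ("s1", "control", 1.0, 1.0, 1.0),
             ("s2", "treated", 0.5, 0.5, 0.5)]
        )
        with pytest.warns(UserWarning, match="s2"):
            resp = response_vectors(scores)
        assert resp.subject_ids == ["s1"]

    def test_sign_convention_is_configurable(self):
        scores = make_scores(
            [("s1", "treated", 0.2, 0.2, 0.2), ("s1", "control", 1.0, 1.0, 1.0)]
        )
        flipped = response_vectors(scores, sign="treated_minus_control")
        assert flipped.table.iloc[0]["ox"] == pytest.approx(-0.8)


class TestClusterResponses:
    def test_hand_worked_three_point_upgma(self):
        # points 0, 1, 10 on a line: first merge {0,1} at height 1;
        # average distance of {0,1} to {10} = (10 + 9)/2 = 9.5
        resp = make_responses([[0, 0, 0], [1, 0, 0], [10, 0, 0]])
        dendro, labelled = cluster_responses(resp, k=2)
        np.testing.assert_allclose(dendro.heights(), [1.0, 9.5], atol=1e-12)
        labels = labelled.table["cluster"].tolist()
        assert labels[0] == labels[1] != labels[2]

    def test_identical_vectors_merge_at_height_zero(self):
        resp = make_responses([[1.0, 2.0]] * 5)
        dendro, _ = cluster_responses(resp, k=1)
        np.testing.assert_allclose(dendro.heights(), 0.0, atol=1e-12)

    def test_merge_heights_match_bruteforce_upgma(self):
        rng = np.random.default_rng(0)
        for n in (4, 6, 8):
            X = rng.normal(size=(n, 3))
            resp = make_responses(X)
            dendro, _ = cluster_responses(resp, k=2)
            np.testing.assert_allclose(
                np.sort(dendro.heights()), upgma_heights_bruteforce(X), atol=1e-10
            )

    def test_labels_invariant_to_subject_order(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (5, 3)), rng.normal(4, 0.3, (5, 3))])
        resp = make_responses(X)
        _, ref = cluster_responses(resp, k=2)
        ref_labels = dict(zip(ref.table["subject_id"], ref.table["cluster"]))
        for _ in range(10):
            perm = rng.permutation(len(X))
            shuffled = make_responses(
                X[perm], subjects=[f"s{i + 1}" for i in perm]
            )
            _, out = cluster_responses(shuffled, k=2)
            labels = dict(zip(out.table["subject_id"], out.table["cluster"]))
            agreement = adjusted_rand_score(
                [ref_labels[s] for s in sorted(labels)],
                [labels[s] for s in sorted(labels)],
            )
            assert agreement == 1.0

    def test_translation_leaves_heights_and_labels_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 3))
        d1, r1 = cluster_responses(make_responses(X), k=2)
        d2, r2 = cluster_responses(make_responses(X + np.array([5.0, -3.0, 11.0])), k=2)
        np.testing.assert_allclose(d1.heights(), d2.heights(), atol=1e-10)
        assert r1.table["cluster"].tolist() == r2.table["cluster"].tolist()

    def test_well_separated_groups_recovered_at_two_cluster_cut(self):
        """Clustering machinery recovers clearly separated planted groups."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = np.repeat([0, 1], 8)
            centers = np.array([[2.0, 2.0, 0.3], [0.3, 0.3, 2.0]])
            X = centers[truth] + rng.normal(0, 0.4, size=(16, 3))
            _, labelled = cluster_responses(make_responses(X), k=2)
            hits += adjusted_rand_score(truth, labelled.table["cluster"]) >= 0.8
        assert hits >= 18

    def test_auto_k_finds_the_two_group_gap(self):
        rng = np.random.default_rng(3)
        truth = np.repeat([0, 1], 8)
        centers = np.array([[0.0, 0.0], [6.0, 6.0]])
        X = centers[truth] + rng.normal(0, 0.3, size=(16, 2))
        _, labelled = cluster_responses(make_responses(X), k="auto")
        assert labelled.table["cluster"].nunique() == 2

    def test_k_larger_than_n_rejected(self):
        resp = make_responses(np.eye(3))
        with pytest.raises(ValueError):
            cluster_responses(resp, k=5)


class TestOutliers:
    def test_extreme_singleton_is_flagged(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.5, (5, 3)), [[100.0, 100.0, 100.0]]])
        flagged = flag_outliers(make_responses(X))
        assert flagged.table["outlier"].tolist() == [False] * 5 + [True]

    def test_homogeneous_cloud_rarely_flags(self):
        false_positives = 0
        for seed in range(50):
            X = np.random.default_rng(seed).normal(size=(12, 3))
            flagged = flag_outliers(make_responses(X))
            false_positives += flagged.table["outlier"].any()
        assert false_positives <= 2  # >= 95% of clouds unflagged

    def test_three_subjects_rule_inapplicable(self):
        resp = make_responses(np.eye(3))
        with pytest.warns(UserWarning, match=">= 4"):
            flagged = flag_outliers(resp)
        assert not flagged.table["outlier"].any()

    def test_outliers_excluded_from_labels_but_kept_in_table(self):
        X = np.vstack([np.random.default_rng(1).normal(0, 0.5, (6, 3)), [[80.0, 80.0, 80.0]]])
        clusterer = ResponseClustering(n_clusters=2)
        scores_rows = []
        for i, v in enumerate(X):
            scores_rows.append((f"s{i}", "treated", 0.0, 0.0, 0.0))
            scores_rows.append((f"s{i}", "control", *v))
        clusterer.fit(make_scores(scores_rows))
        t = clusterer.responses_.table
        assert clusterer.outliers_ == [f"s{len(X) - 1}"]
        assert t.loc[t["outlier"], "cluster"].isna().all()
        assert len(t) == len(X)

    def test_explicit_exclusion_list_is_respected(self):
        rng = np.random.default_rng(5)
        scores_rows = []
        for i in range(8):
            scores_rows.append((f"s{i}", "treated", *rng.normal(0, 0.1, 3)))
            scores_rows.append((f"s{i}", "control", *(1 + rng.normal(0, 0.1, 3))))
        clusterer = ResponseClustering(n_clusters=2, exclude_subjects=["s3"])
        clusterer.fit(make_scores(scores_rows))
        t = clusterer.responses_.table
        assert "s3" in clusterer.outliers_
        assert t.loc[t["subject_id"] == "s3", "cluster"].isna().all()


class TestDendrogramExport:
    def test_newick_has_all_leaves_and_parses(self, tmp_path):
        X = np.random.default_rng(4).normal(size=(6, 3))
        dendro, _ = cluster_responses(make_responses(X), k=2)
        nwk = dendro.to_newick(tmp_path / "tree.nwk")
        assert nwk.endswith(";")
        for name in dendro.leaf_names:
            assert name in nwk
        # parseable by an external newick reader
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == 6

    def test_merge_list_tsv_shape(self, tmp_path):
        X = np.random.default_rng(6).normal(size=(5, 2))
        dendro, _ = cluster_responses(make_responses(X), k=2)
        path = tmp_path / "merges.tsv"
        dendro.to_merge_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 4  # n - 1 merges
        assert (np.diff(df["height"]) >= -1e-12).all()
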