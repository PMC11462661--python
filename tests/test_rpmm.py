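"""Beta-mixture EM, recursive partitioning, release-class naming,
silhouette ranking and CIMP calling."""

import numpy as np
import pandas as pd
import pytest

from methylrelease import (
    assign_release_class,
    classify_cimp,
    fit_beta_mixture,
    rpmm_cluster,
    silhouette_rank,
)
from methylrelease.rpmm import _clip_beta, _fit_one_class


def planted_two_class(seed=0, n=40, p=30):
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    values = np.where(
        labels[:, None] == 0,
        rng.beta(2, 20, size=(n, p)),
        rng.beta(20, 2, size=(n, p)),
    )
    beta = pd.DataFrame(
        values, index=[f"s{i:02d}" for i in range(n)],
        columns=[f"cg{j}" for j in range(p)],
    )
    return beta, labels


def planted_four_class(seed=0, n_per=15, p=40, means=(0.2, 0.4, 0.6, 0.8)):
    rng = np.random.default_rng(seed)
    m = np.repeat(means, n_per)
    values = rng.beta(m[:, None] * 30, (1 - m[:, None]) * 30, size=(len(m), p))
    beta = pd.DataFrame(
        values, index=[f"s{i:02d}" for i in range(len(m))],
        columns=[f"cg{j}" for j in range(p)],
    )
    return beta, np.repeat(np.arange(4), n_per)


class TestFitBetaMixture:
    def test_em_loglik_monotone_every_iteration(self):
        beta, _ = planted_two_class(seed=1)
        fit = fit_beta_mixture(beta, k=2, seed=0)
        trace = fit.loglik_trace
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * (np.abs(trace[:-1]) + 1.0))
        assert "non-monotone" not in fit.flags

    def test_two_planted_classes_recovered(self):
        beta, labels = planted_two_class(seed=2)
        fit = fit_beta_mixture(beta, k=2, seed=0)
        hard = fit.hard_assignments()
        acc = max((hard == labels).mean(), (hard != labels).mean())
        assert acc >= 0.95

    def test_homogeneous_data_prefers_one_class_by_bic(self):
        rng = np.random.default_rng(3)
        beta = pd.DataFrame(
            rng.beta(5, 5, size=(40, 30)), index=[f"s{i}" for i in range(40)]
        )
        one = _fit_one_class(_clip_beta(beta.to_numpy()))
        two = fit_beta_mixture(beta, k=2, seed=0)
        assert two.bic > one.bic

    def test_responsibilities_sum_to_one_and_params_positive(self):
        beta, _ = planted_two_class(seed=4, n=20, p=10)
        fit = fit_beta_mixture(beta, k=2, seed=0)
        assert np.allclose(fit.resp.sum(axis=1), 1.0)
        assert (fit.a > 0).all() and (fit.b > 0).all()

    def test_tiny_single_probe_fit_runs(self):
        beta = pd.DataFrame(
            {"cg1": [0.05, 0.1, 0.08, 0.9, 0.92, 0.95]},
            index=[f"s{i}" for i in range(6)],
        )
        fit = fit_beta_mixture(beta, k=2, seed=0)
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-8 * (np.abs(trace[:-1]) + 1.0))

    def test_missing_values_rejected(self):
        beta = pd.DataFrame({"cg1": [0.1, np.nan, 0.3, 0.4]})
        with pytest.raises(ValueError):
            fit_beta_mixture(beta, k=2, seed=0)


class TestRPMMCluster:
    def test_four_separated_classes_give_four_leaves(self):
        beta, _ = planted_four_class(seed=5)
        tree = rpmm_cluster(beta, max_level=2, seed=0)
        assert tree.n_leaves == 4

    def test_homogeneous_data_single_leaf(self):
        rng = np.random.default_rng(6)
        beta = pd.DataFrame(
            rng.beta(5, 5, size=(40, 30)), index=[f"s{i}" for i in range(40)]
        )
        tree = rpmm_cluster(beta, max_level=2, seed=0)
        assert tree.n_leaves == 1

    def test_max_level_one_two_leaves_accurate(self):
        beta, labels = planted_two_class(seed=7)
        tree = rpmm_cluster(beta, max_level=1, seed=0)
        assert tree.n_leaves == 2
        assign = tree.assignments()
        hard = (assign.loc[beta.index] == assign.iloc[0]).to_numpy().astype(int)
        acc = max((hard == labels).mean(), (hard != labels).mean())
        assert acc >= 0.95

    def test_leaf_count_bounded_by_max_level(self):
        beta, _ = planted_four_class(seed=8)
        for level in (1, 2):
            assert rpmm_cluster(beta, max_level=level, seed=0).n_leaves <= 2**level

    def test_every_sample_in_exactly_one_leaf(self):
        beta, _ = planted_four_class(seed=9)
        tree = rpmm_cluster(beta, max_level=2, seed=0)
        assigned = [s for leaf in tree.leaves() for s in leaf.sample_ids]
        assert sorted(assigned) == sorted(beta.index)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            rpmm_cluster(pd.DataFrame(), max_level=1, seed=0)


class TestAssignReleaseClass:
    def test_high_methylation_cluster_is_expected_low(self):
        beta, labels = planted_two_class(seed=10)
        tree = rpmm_cluster(beta, max_level=1, seed=0)
        sig = pd.DataFrame(index=pd.Index(beta.columns, name="probe_id"))
        preds = assign_release_class(tree, beta, sig)
        med = {
            p: np.median(beta.loc[preds.index[preds.prediction == p]].to_numpy())
            for p in ("expected-low", "expected-high")
        }
        assert med["expected-low"] > med["expected-high"]

    def test_equal_medians_error(self):
        beta = pd.DataFrame(
            np.full((4, 3), 0.5), index=list("abcd"), columns=["cg1", "cg2", "cg3"]
        )
        tree = rpmm_cluster(beta, max_level=1, seed=0)
        # force a degenerate 2-leaf tree on identical data
        if tree.n_leaves != 2:
            from methylrelease.rpmm import RPMMNode, RPMMTree

            root = RPMMNode("r", 0, list(beta.index), 0.5)
            root.children = [
                RPMMNode("rL", 1, ["a", "b"], 0.5),
                RPMMNode("rR", 1, ["c", "d"], 0.5),
            ]
            tree = RPMMTree(root, 1)
        sig = pd.DataFrame(index=pd.Index(beta.columns, name="probe_id"))
        with pytest.raises(ValueError, match="median"):
            assign_release_class(tree, beta, sig)

    def test_label_swap_invariance(self):
        # class naming depends only on medians, not on component order
        beta, _ = planted_two_class(seed=11)
        sig = pd.DataFrame(index=pd.Index(beta.columns, name="probe_id"))
        preds = {}
        for seed in (0, 1):
            tree = rpmm_cluster(beta, max_level=1, seed=seed)
            preds[seed] = assign_release_class(tree, beta, sig)["prediction"]
        pd.testing.assert_series_equal(preds[0], preds[1])


def brute_force_silhouette(points, labels):
    """Hand silhouette: a(i) mean intra-cluster, b(i) min mean inter-cluster."""
    points = np.asarray(points, dtype=float)
    widths = []
    for i in range(len(points)):
        same = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not same:
            widths.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(
            np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for j in range(len(points))
                    if labels[j] == other
                ]
            )
            for other in set(labels) - {labels[i]}
        )
        widths.append((b - a) / max(a, b))
    return np.array(widths)


class TestSilhouetteRank:
    @staticmethod
    def _preds(index, clusters, predictions):
        return pd.DataFrame(
            {"rpmm_cluster": clusters, "prediction": predictions},
            index=pd.Index(index, name="sample_id"),
        )

    def test_well_separated_tight_clusters(self):
        beta = pd.DataFrame(
            [[0.1, 0.1], [0.11, 0.1], [0.9, 0.9], [0.91, 0.9]],
            index=list("abcd"), columns=["cg1", "cg2"],
        )
        preds = self._preds(
            list("abcd"), ["rR"] * 2 + ["rL"] * 2,
            ["expected-high"] * 2 + ["expected-low"] * 2,
        )
        out = silhouette_rank(beta, preds)
        assert (out.silhouette_width > 0.9).all()

    def test_matches_hand_computed_oracle(self):
        points = [[0.1], [0.2], [0.25], [0.7], [0.8]]
        labels = ["rR", "rR", "rR", "rL", "rL"]
        beta = pd.DataFrame(points, index=list("abcde"), columns=["cg1"])
        preds = self._preds(
            list("abcde"), labels,
            ["expected-high"] * 3 + ["expected-low"] * 2,
        )
        out = silhouette_rank(beta, preds)
        oracle = brute_force_silhouette(points, labels)
        got = out.loc[list("abcde"), "silhouette_width"].to_numpy()
        np.testing.assert_allclose(got, oracle, rtol=1e-10)

    def test_ranking_order_high_confident_first(self):
        points = [[0.05], [0.2], [0.75], [0.95]]
        beta = pd.DataFrame(points, index=list("abcd"), columns=["cg1"])
        preds = self._preds(
            list("abcd"), ["rR", "rR", "rL", "rL"],
            ["expected-high", "expected-high", "expected-low", "expected-low"],
        )
        out = silhouette_rank(beta, preds)
        assert list(out["rank"]) == [1, 2, 3, 4]
        # high group sorted by decreasing width, low by increasing
        high = out[out.prediction == "expected-high"].silhouette_width.to_numpy()
        low = out[out.prediction == "expected-low"].silhouette_width.to_numpy()
        assert np.all(np.diff(high) <= 0) and np.all(np.diff(low) >= 0)
        assert set(out["rank"]) == {1, 2, 3, 4}
        assert out.columns.tolist()[:3] == ["rpmm_cluster", "prediction", "silhouette_width"]

    def test_widths_bounded(self, cohort):
        beta = cohort.beta[cohort.truth_probes]
        tree = rpmm_cluster(beta, max_level=1, seed=0)
        sig = pd.DataFrame(index=pd.Index(cohort.truth_probes, name="probe_id"))
        out = silhouette_rank(beta, assign_release_class(tree, beta, sig))
        assert out.silhouette_width.between(-1, 1).all()


class TestClassifyCIMP:
    def test_probes_with_missing_values_dropped(self):
        rng = np.random.default_rng(12)
        n_probes, n_missing = 50, 7
        beta = pd.DataFrame(
            rng.beta(2, 2, size=(30, n_probes)),
            index=[f"s{i}" for i in range(30)],
            columns=[f"cg{j}" for j in range(n_probes)],
        )
        for j in range(n_missing):
            beta.iloc[j % 30, j] = np.nan
        out = classify_cimp(beta, list(beta.columns), seed=0)
        assert out.n_probes_used.iloc[0] == n_probes - n_missing

    def test_leaf_labels_follow_planted_mean_order(self, cohort):
        calls = classify_cimp(cohort.beta, cohort.cimp_probes, seed=0)
        agreement = (calls.cimp_class == cohort.samples.cimp).mean()
        assert agreement >= 0.95

    def test_all_identical_single_leaf_cimp_h(self):
        beta = pd.DataFrame(
            np.full((10, 5), 0.5),
            index=[f"s{i}" for i in range(10)],
            columns=[f"cg{j}" for j in range(5)],
        )
        out = classify_cimp(beta, list(beta.columns), seed=0)
        assert (out.cimp_class == "CIMP-H").all()

    def test_too_few_probes_error(self):
        beta = pd.DataFrame({"cg1": [0.1, 0.2, 0.3]}, index=list("abc"))
        with pytest.raises(ValueError):
            classify_cimp(beta, ["cg1"], seed=0)
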