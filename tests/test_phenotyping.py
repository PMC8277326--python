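"""OR weights, weighted-Hamming distance, Ward linkage, aggregation, affinity."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

import phenoscreen as ps
from phenoscreen.phenotyping import (
    WeightVector,
    _kmeans_1d_3,
    aggregate_medians,
    cut_and_aggregate,
    ward_dendrogram,
)

from conftest import CLUSTER14, make_binary_cohort


# --------------------------------------------------------------------------
# crude odds ratios
# --------------------------------------------------------------------------


def _or_cohort(sev_yes, sev_no, non_yes, non_no):
    rows = (
        [({"v": "yes"}, 40)] * sev_yes
        + [({"v": "no"}, 40)] * sev_no
        + [({"v": "yes"}, 10)] * non_yes
        + [({"v": "no"}, 10)] * non_no
    )
    return make_binary_cohort(rows)


class TestCrudeOr:
    def test_printed_nocturia_counts(self):
        # severe 32 yes / 2 no, non-severe 67 yes / 35 no
        cohort = _or_cohort(32, 2, 67, 35)
        assert ps.crude_or_severe(cohort, "v") == pytest.approx(8.358, abs=1e-3)

    def test_identical_distribution_gives_unity(self):
        assert ps.crude_or_severe(_or_cohort(10, 10, 30, 30), "v") == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        cohort = _or_cohort(12, 0, 20, 15)
        expected = (12.5 * 15.5) / (0.5 * 20.5)
        got = ps.crude_or_severe(cohort, "v")
        assert np.isfinite(got) and got == pytest.approx(expected)

    def test_constant_variable_rejected(self):
        cohort = make_binary_cohort([({"v": "yes"}, 40)] * 5 + [({"v": "yes"}, 10)] * 5)
        with pytest.raises(ValueError):
            ps.crude_or_severe(cohort, "v")

    def test_compute_weights_skips_constant(self):
        rows = [({"v": "yes", "w": "yes"}, 40)] * 5 + [({"v": "no", "w": "yes"}, 10)] * 5
        cohort = make_binary_cohort(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wv = ps.compute_weights(cohort, ["v", "w"])
        assert wv.variables == ("v",)


# --------------------------------------------------------------------------
# weighted mismatch distance
# --------------------------------------------------------------------------

W3 = WeightVector(("a", "b", "c"), np.array([2.0, 1.0, 4.0]))


class TestPatientDistance:
    def test_hand_sum(self):
        x = {"a": "yes", "b": "no", "c": "yes"}
        y = {"a": "no", "b": "no", "c": "no"}  # mismatch on a and c
        assert ps.patient_distance(x, y, W3) == 6.0

    def test_identity_and_single_mismatch(self):
        x = {"a": "yes", "b": "no", "c": "yes"}
        assert ps.patient_distance(x, x, W3) == 0.0
        y = dict(x, b="yes")
        assert ps.patient_distance(x, y, W3) == 1.0

    def test_normalized_bounded_by_one(self):
        x = {"a": "yes", "b": "no", "c": "yes"}
        y = {"a": "no", "b": "yes", "c": "no"}
        assert ps.patient_distance(x, y, W3, normalize=True) == pytest.approx(1.0)

    def test_missing_selected_value_rejected(self):
        with pytest.raises(ValueError):
            ps.patient_distance({"a": "yes", "b": "no"}, {"a": "yes", "b": "no", "c": "yes"}, W3)

    @given(
        st.lists(
            st.tuples(st.sampled_from("xy"), st.sampled_from("xy"), st.sampled_from("xy")),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pseudo_metric_axioms(self, triple):
        recs = [dict(zip("abc", t)) for t in triple]
        d = lambda i, j: ps.patient_distance(recs[i], recs[j], W3)
        assert d(0, 1) == d(1, 0)
        assert d(0, 0) == 0
        assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-12


# --------------------------------------------------------------------------
# Ward linkage
# --------------------------------------------------------------------------


def brute_force_ward(dm):
    """Independent naive Lance-Williams Ward recursion (ward.D) on dicts."""
    d = {}
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dm[i][j]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(
            ((k, v) for k, v in d.items() if k[0] in active and k[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        for k in active - {i, j}:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            new = (
                (sizes[i] + sizes[k]) * dik
                + (sizes[j] + sizes[k]) * djk
                - sizes[k] * h
            ) / (sizes[i] + sizes[j] + sizes[k])
            d[tuple(sorted((nxt, k)))] = new
        sizes[nxt] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(nxt)
        merges.append((i, j, h, sizes[nxt]))
        nxt += 1
    return merges


def random_distance_matrix(rng, n):
    a = rng.random((n, n))
    dm = (a + a.T) / 2
    np.fill_diagonal(dm, 0.0)
    return dm


class TestWardDendrogram:
    def test_two_points(self):
        Z = ward_dendrogram(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert Z.shape == (1, 4)
        assert Z[0].tolist() == [0, 1, 3.0, 2]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            dm = random_distance_matrix(rng, 6)
            Z = ward_dendrogram(dm)
            oracle = brute_force_ward(dm.tolist())
            heights = np.maximum.accumulate([h for _, _, h, _ in oracle])
            for row, (i, j, _, size), h in zip(Z, oracle, heights):
                assert {int(row[0]), int(row[1])} == {i, j}
                assert row[2] == pytest.approx(h, abs=1e-9)
                assert row[3] == size

    def test_ward_d2_matches_scipy_on_euclidean_data(self, rng):
        # scipy's 'ward' implements the squared-distance convention
        pts = rng.random((12, 3))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        Z_mine = ward_dendrogram(dm, variant="ward.D2")
        Z_scipy = scipy_linkage(dm[np.triu_indices(12, 1)], method="ward")
        np.testing.assert_allclose(Z_mine[:, 2], Z_scipy[:, 2], rtol=1e-8)
        for k in range(2, 6):
            a = fcluster(Z_mine, k, criterion="maxclust")
            b = fcluster(Z_scipy, k, criterion="maxclust")
            assert len(set(zip(a, b))) == len(set(a))

    def test_heights_monotone(self, rng):
        for _ in range(10):
            Z = ward_dendrogram(random_distance_matrix(rng, 15))
            assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_separated_blobs_merge_within_first(self, rng):
        n = 10
        dm = np.full((2 * n, 2 * n), 100.0)
        within = random_distance_matrix(rng, n) * 0.1
        dm[:n, :n] = within
        dm[n:, n:] = random_distance_matrix(rng, n) * 0.1
        np.fill_diagonal(dm, 0.0)
        Z = ward_dendrogram(dm)
        # the first 2n - 2 merges stay inside the blobs
        blob = lambda idx: (idx < n) if idx < 2 * n else blob_of[idx]
        blob_of = {}
        for t, row in enumerate(Z[:-1]):
            b0, b1 = blob(int(row[0])), blob(int(row[1]))
            assert b0 == b1
            blob_of[2 * n + t] = b0

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, np.nan], [np.nan, 0.0]]),
            np.array([[0.0, -1.0], [-1.0, 0.0]]),
            np.array([[0.0, 1.0], [2.0, 0.0]]),
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            ward_dendrogram(bad)

    def test_weight_scaling_invariance(self, complete_cohort):
        osa = complete_cohort.subset(complete_cohort.data["osa"].to_numpy() == 1)
        w = ps.compute_weights(osa, CLUSTER14)
        w2 = WeightVector(w.variables, w.weights * 7.5)
        dm1 = ps.distance_matrix(osa, w)
        dm2 = ps.distance_matrix(osa, w2)
        np.testing.assert_allclose(dm2, 7.5 * dm1)
        Z1, Z2 = ward_dendrogram(dm1), ward_dendrogram(dm2)
        np.testing.assert_array_equal(Z1[:, :2], Z2[:, :2])
        np.testing.assert_allclose(Z2[:, 2], 7.5 * Z1[:, 2])
        f1 = fcluster(Z1, 10, criterion="maxclust")
        f2 = fcluster(Z2, 10, criterion="maxclust")
        np.testing.assert_array_equal(f1, f2)


# --------------------------------------------------------------------------
# cut and aggregate
# --------------------------------------------------------------------------


class TestAggregation:
    def test_reference_median_grouping(self):
        groups = aggregate_medians([8, 10, 10, 10, 10, 12, 13, 14, 31, 34])
        med = np.array([8, 10, 10, 10, 10, 12, 13, 14, 31, 34])
        grouped = [sorted(med[g]) for g in groups]
        assert grouped == [[8, 10, 10, 10, 10], [12, 13, 14], [31, 34]]

    def test_kmeans_1d_handles_three_points(self):
        groups = _kmeans_1d_3(np.array([5.0, 20.0, 50.0]))
        assert [len(g) for g in groups] == [1, 1, 1]

    def test_k_fine_three_is_identity(self, osa_cluster_model):
        Z = osa_cluster_model.linkage
        ahi = np.asarray(osa_cluster_model._reference_ahi)
        fine, _, agg, phen = cut_and_aggregate(Z, ahi, k_fine=3)
        assert sorted(agg) == sorted(np.unique(fine).tolist())
        assert len(set(agg.values())) == 3

    def test_k_fine_larger_than_n_rejected(self, osa_cluster_model):
        with pytest.raises(ValueError):
            cut_and_aggregate(osa_cluster_model.linkage, osa_cluster_model._reference_ahi, k_fine=5000)

    def test_aggregation_map_surjective_and_ordered(self, osa_cluster_model):
        m = osa_cluster_model
        assert set(m.aggregation_map.values()) == {"low", "medium", "high"}
        med = m.phenotype_median_ahi()
        assert med["low"] <= med["medium"] <= med["high"]

    def test_fine_labels_nest_in_phenotypes(self, osa_cluster_model):
        m = osa_cluster_model
        for fine, phen in zip(m.fine_labels, m.phenotypes):
            assert m.aggregation_map[int(fine)] == phen


# --------------------------------------------------------------------------
# affinity assignment and description
# --------------------------------------------------------------------------


class TestAssignment:
    def test_member_of_high_assigned_high(self, osa_cluster_model):
        m = osa_cluster_model
        idx = int(np.flatnonzero(m.phenotypes == "high")[0])
        record = m.reference_values.iloc[idx].to_dict()
        phen, aff = ps.assign_phenotype(record, m)
        assert set(aff) == {"low", "medium", "high"}
        assert phen == min(aff, key=aff.get)

    def test_tie_breaks_toward_lower_severity(self):
        # one reference patient per phenotype, equidistant query
        wv = WeightVector(("a", "b", "c"), np.ones(3))
        m = ps.ClusterModel(
            weights=wv,
            normalize=False,
            linkage=np.zeros((2, 4)),
            fine_labels=np.array([1, 2, 3]),
            fine_medians={1: 8.0, 2: 14.0, 3: 31.0},
            aggregation_map={1: "low", 2: "medium", 3: "high"},
            phenotypes=np.array(["low", "medium", "high"], dtype=object),
            reference_values=pd.DataFrame(
                {"a": ["x", "y", "y"], "b": ["y", "x", "y"], "c": ["y", "y", "x"]}
            ),
            reference_ids=["r1", "r2", "r3"],
            categories={v: ("x", "y") for v in "abc"},
        )
        phen, aff = ps.assign_phenotype({"a": "x", "b": "x", "c": "x"}, m)
        assert len(set(aff.values())) == 1
        assert phen == "low"

    def test_healthy_generated_from_high_mostly_assigned_high(self, osa_cluster_model):
        spec = ps.default_generator_spec(seed=21)
        spec.n_osa, spec.n_healthy = 1, 200
        spec.phenotype_weights_healthy = (0.0, 0.0, 1.0)
        cohort = ps.generate_cohort(spec)
        healthy = cohort.subset(cohort.data["osa"].to_numpy() == 0)
        assigned = ps.assign_phenotypes(healthy, osa_cluster_model)
        assert (assigned == "high").mean() > 0.5

    def test_medoid_method_runs(self, osa_cluster_model, complete_cohort):
        healthy = complete_cohort.subset(complete_cohort.data["osa"].to_numpy() == 0)
        a = ps.assign_phenotypes(healthy, osa_cluster_model, method="medoid")
        assert set(a) <= {"low", "medium", "high"}

    def test_model_json_round_trip(self, osa_cluster_model, complete_cohort):
        again = ps.ClusterModel.from_json(osa_cluster_model.to_json())
        healthy = complete_cohort.subset(complete_cohort.data["osa"].to_numpy() == 0)
        np.testing.assert_array_equal(
            ps.assign_phenotypes(healthy, again),
            ps.assign_phenotypes(healthy, osa_cluster_model),
        )

    def test_newick_has_all_leaves(self, osa_cluster_model):
        nwk = osa_cluster_model.to_newick()
        assert nwk.endswith(";")
        assert nwk.count(",") == len(osa_cluster_model.fine_labels) - 1


class TestDescribeClusters:
    def test_structure_and_proportions(self, complete_cohort, osa_cluster_model):
        table = ps.describe_clusters(complete_cohort, osa_cluster_model)
        freq = table[~table["variable"].isin(["median_ahi"])]
        assert ((freq["proportion"] >= 0) & (freq["proportion"] <= 1)).all()
        assert (freq["ci_low"] <= freq["proportion"] + 1e-12).all()
        assert (freq["proportion"] <= freq["ci_high"] + 1e-12).all()
        # per phenotype and variable the category counts sum to the group size
        some = freq[(freq["phenotype"] == "low") & (freq["variable"] == "gender")]
        assert some["count"].sum() == some["n"].iloc[0]

    def test_phenotype_recovery_beats_permutation_null(self):
        from sklearn.metrics import adjusted_rand_score

        spec = ps.default_generator_spec(seed=2)
        spec.n_osa, spec.n_healthy = 400, 0
        cohort = ps.generate_cohort(spec)
        model = ps.fit_phenotypes(cohort, CLUSTER14)
        truth = cohort.data["true_phenotype"].to_numpy()
        ari = adjusted_rand_score(truth, model.phenotypes)
        rng = np.random.default_rng(2)
        null = [
            adjusted_rand_score(truth, rng.permutation(model.phenotypes))
            for _ in range(100)
        ]
        assert ari > np.quantile(null, 0.95)
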