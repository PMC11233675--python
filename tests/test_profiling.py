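import numpy as np
import pandas as pd
import pytest

from volatempo import (chain_parity, cut_tree, kinetic_summary, pca_samples,
                       planted_archetype_table, scale_matrix,
                       simulate_peak_table, study_templates,
                       temporal_profile_matrix, ward_cluster)
from volatempo.simulate import NoiseModel
from volatempo.utils import rng_stream


def brute_force_ward(X):
    """Exhaustive Ward agglomeration recomputing the criterion from scratch
    at every step: d(A,B) = sqrt(2|A||B|/(|A|+|B|)) * ||centroid_A - centroid_B||."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    centroids = {i: X[i].copy() for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                na, nb = sizes[a], sizes[b]
                d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(
                    centroids[a] - centroids[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((min(a, b), max(a, b), d, sizes[a] + sizes[b]))
        centroids[next_id] = (
            sizes[a] * centroids[a] + sizes[b] * centroids[b]
        ) / (sizes[a] + sizes[b])
        sizes[next_id] = sizes[a] + sizes[b]
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    return np.array(merges)


class TestWardCluster:
    def test_first_merge_is_nearest_pair(self):
        result = ward_cluster(np.array([[0.0], [1.0], [10.0]]))
        assert set(result.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_sequence_matches_brute_force_oracle(self):
        rng = rng_stream(0, "ward-oracle-test")
        for _ in range(15):
            X = rng.normal(size=(rng.integers(3, 9), rng.integers(1, 4)))
            Z = ward_cluster(X).linkage
            O = brute_force_ward(X)
            np.testing.assert_array_equal(np.sort(Z[:, :2], axis=1),
                                          O[:, :2].astype(float))
            np.testing.assert_allclose(Z[:, 2], O[:, 2], rtol=1e-10)
            np.testing.assert_array_equal(Z[:, 3], O[:, 3])

    def test_duplicate_points_merge_at_zero_height(self):
        result = ward_cluster(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_items_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_cluster(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            ward_cluster(np.array([[1.0], [np.nan]]))

    def test_heights_monotone(self):
        rng = rng_stream(1, "ward-test")
        result = ward_cluster(rng.normal(size=(20, 5)))
        assert np.all(np.diff(result.linkage[:, 2]) >= -1e-12)


class TestCutTree:
    @pytest.fixture()
    def clustering(self):
        rng = rng_stream(2, "cut-test")
        return ward_cluster(rng.normal(size=(10, 3)))

    def test_boundary_cuts(self, clustering):
        assert cut_tree(clustering, 1).nunique() == 1
        assert cut_tree(clustering, 10).nunique() == 10

    def test_four_cut_refines_two_cut(self, clustering):
        two = cut_tree(clustering, 2)
        four = cut_tree(clustering, 4)
        mapping = pd.DataFrame({"two": two, "four": four})
        assert (mapping.groupby("four")["two"].nunique() == 1).all()

    def test_out_of_range_k_rejected(self, clustering):
        with pytest.raises(ValueError):
            cut_tree(clustering, 0)
        with pytest.raises(ValueError):
            cut_tree(clustering, 11)

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        table, labels = planted_archetype_table(seed=0)
        profiles = temporal_profile_matrix(table, standardize=True)
        clustering = ward_cluster(profiles, axis=0)
        assign = cut_tree(clustering, 4)
        truth = [labels[c] for c in assign.index]
        assert adjusted_rand_score(truth, assign.to_numpy()) >= 0.9

    def test_determinism_identical_input_same_leaf_order(self):
        table, _ = planted_archetype_table(seed=3)
        profiles = temporal_profile_matrix(table)
        a = ward_cluster(profiles, axis=0)
        b = ward_cluster(profiles, axis=0)
        assert a.leaf_order == b.leaf_order
        np.testing.assert_array_equal(a.linkage, b.linkage)


class TestPcaSamples:
    def test_rank_one_matrix_fully_explained(self):
        rng = rng_stream(3, "pca-test")
        M = np.outer(rng.normal(size=10), rng.normal(size=4))
        with pytest.warns(UserWarning):
            res = pca_samples(M, n_components=2)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_scores_equal_projection_onto_loadings(self):
        rng = rng_stream(4, "pca-test")
        M = rng.normal(size=(12, 5))
        res = pca_samples(M, n_components=3)
        centred = M - M.mean(axis=0)
        np.testing.assert_allclose(
            res.scores.to_numpy(), centred @ res.loadings.to_numpy(),
            atol=1e-10,
        )

    def test_sterile_samples_form_tight_pca_cluster(self, study_design):
        templates, _ = study_templates(study_design, n_compounds=30, seed=0)
        table, _ = simulate_peak_table(
            study_design, templates,
            NoiseModel(multiplicative_cv=0.1, additive_sd=1.0), seed=0,
        )
        scaled = scale_matrix(table)
        res = pca_samples(scaled.values, n_components=2)
        scores = res.scores.to_numpy()
        sterile = scaled.row_meta["group"].to_numpy() == "SM"
        from scipy.spatial.distance import pdist, cdist

        within_sm = np.median(pdist(scores[sterile]))
        mixed = np.median(cdist(scores[sterile], scores[~sterile]).ravel())
        assert within_sm < mixed


class TestKinetics:
    @pytest.fixture()
    def rise_table(self):
        means = {0.0: 0.0, 4.0: 1.0, 8.0: 5.0, 12.0: 9.0, 16.0: 10.0,
                 20.0: 10.0, 24.0: 10.0}
        rows = [
            (f"O-R{r}-{t:g}h", "O", r, t, "butanoic acid", v)
            for t, v in means.items()
            for r in (1, 2, 3)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                           "time_h", "compound", "intensity"])

    def test_plateau_and_steepest_window_match_definitions(self, rise_table):
        ks = kinetic_summary(rise_table, group="O", plateau_tol=0.05)
        row = ks.summary.iloc[0]
        assert row["plateau_time_h"] == 16.0
        # windows (4,8) and (8,12) tie at +4; earliest wins
        assert (row["slope_window_start_h"], row["slope_window_end_h"]) == (4.0, 8.0)
        assert row["chain_length"] == 4 and row["parity"] == "even"

    def test_constant_curve_plateaus_immediately(self):
        rows = [(f"O-R1-{t:g}h", "O", 1, t, "acetic acid", 5.0)
                for t in (0.0, 4.0, 8.0, 12.0)]
        table = pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                            "time_h", "compound", "intensity"])
        ks = kinetic_summary(table, group="O")
        row = ks.summary.iloc[0]
        assert row["plateau_time_h"] == 0.0
        assert row["max_increase"] == 0.0

    def test_reported_acid_ranking_preserved(self):
        order = ["butanoic acid", "hexanoic acid", "octanoic acid",
                 "pentanoic acid", "isovaleric acid", "heptanoic acid"]
        rows = []
        for rank, compound in enumerate(order):
            level = 600.0 - 100.0 * rank
            for t in (0.0, 12.0, 24.0):
                rows.append((f"O-R1-{t:g}h", "O", 1, t, compound,
                             level * (t + 1) / 25.0))
        table = pd.DataFrame(rows, columns=["sample_id", "group", "replicate",
                                            "time_h", "compound", "intensity"])
        ks = kinetic_summary(table, group="O")
        ranked = ks.summary.sort_values("rank_in_class")["compound"].tolist()
        assert ranked == order

    def test_row_order_invariance(self, rise_table):
        shuffled = rise_table.sample(frac=1.0, random_state=1)
        a = kinetic_summary(rise_table, group="O").summary
        b = kinetic_summary(shuffled, group="O").summary
        pd.testing.assert_frame_equal(a, b)

    def test_absent_group_and_short_series_rejected(self, rise_table):
        with pytest.raises(ValueError, match="absent"):
            kinetic_summary(rise_table, group="Z")
        short = rise_table[rise_table["time_h"] <= 4.0]
        with pytest.raises(ValueError, match="3 time points"):
            kinetic_summary(short, group="O")


class TestChainParity:
    @pytest.mark.parametrize(
        "name,length,parity",
        [
            ("butanoic acid", 4, "even"),
            ("pentanoic acid", 5, "odd"),
            ("3-methylbutanoic acid", 5, "odd"),
            ("isovaleric acid", 5, "odd"),
            ("hexanoic acid", 6, "even"),
            ("C4H8O2", 4, "even"),
        ],
    )
    def test_known_acids_and_formulas(self, name, length, parity):
        assert chain_parity(name) == (length, parity)

    def test_unknown_compound_flagged_not_guessed(self):
        with pytest.raises(ValueError, match="unknown compound"):
            chain_parity("mystery compound")
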