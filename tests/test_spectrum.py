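import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import emtspectrum as e
from emtspectrum.preprocessing import ScaledMatrix
from emtspectrum.spectrum import classify_score

from conftest import make_blobs


class TestClusterCells:
    def test_two_separated_blobs_give_two_clusters(self):
        scaled, truth = make_blobs(2, n_per_blob=40, seed=1)
        asg = e.cluster_cells(scaled, resolution=1.0, seed=0)
        assert asg.n_clusters == 2
        # clusters coincide with the blobs
        for c in (1, 2):
            assert len(np.unique(truth[asg.labels == c])) == 1

    def test_identical_cells_form_one_cluster(self):
        scaled, _ = make_blobs(1, n_per_blob=30, spread=0.0, seed=0)
        asg = e.cluster_cells(scaled, resolution=1.0, seed=0)
        assert asg.n_clusters == 1

    def test_deterministic_for_fixed_seed(self, smoothed_population):
        _, smoothed, _, _ = smoothed_population
        a1 = e.cluster_cells(smoothed, resolution=1.0, seed=4)
        a2 = e.cluster_cells(smoothed, resolution=1.0, seed=4)
        assert np.array_equal(a1.labels, a2.labels)

    def test_cluster_count_nondecreasing_in_resolution(self):
        scaled, _ = make_blobs(4, n_per_blob=30, seed=2)
        counts = [
            e.cluster_cells(scaled, resolution=r, seed=0).n_clusters
            for r in (0.25, 1.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_invalid_resolution_errors(self, smoothed_population):
        _, smoothed, _, _ = smoothed_population
        with pytest.raises(ValueError, match="resolution"):
            e.cluster_cells(smoothed, resolution=0.0)


class TestSelectResolution:
    def test_single_resolution_grid_returns_it(self):
        scaled, _ = make_blobs(2, seed=3)
        res, asg = e.select_resolution(scaled, [0.8], seed=0)
        assert res == 0.8
        assert asg.resolution == 0.8

    def test_three_blob_fixture_reaches_three_clusters(self):
        scaled, _ = make_blobs(3, seed=4)
        res, asg = e.select_resolution(
            scaled, [0.05, 1.0, 5.0], seed=0, quality_floor=0.8
        )
        assert asg.n_clusters == 3

    def test_fallback_returns_quality_maximum(self):
        scaled, _ = make_blobs(3, seed=5)
        grid = [0.1, 1.0, 3.0]
        res, asg = e.select_resolution(scaled, grid, seed=0)
        qualities = [
            e.cluster_cells(scaled, resolution=r, seed=0).quality for r in grid
        ]
        assert asg.quality == pytest.approx(max(qualities))

    def test_empty_grid_errors(self):
        scaled, _ = make_blobs(1, seed=0)
        with pytest.raises(ValueError, match="grid"):
            e.select_resolution(scaled, [])


def as_scaled(values):
    n, g = np.asarray(values).shape
    return ScaledMatrix(
        values=np.asarray(values, float),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        sample_labels=np.array(["s"] * n, dtype=object),
    )


class TestPositiveFraction:
    def test_all_positive_entries(self):
        scaled = as_scaled([[1.0, 2.0], [0.5, 3.0]])
        assert e.positive_fraction(scaled, [True, True], ["g0", "g1"]) == 1.0

    def test_three_of_four_entries(self):
        scaled = as_scaled([[1.0, 2.0], [-0.5, 3.0]])
        assert e.positive_fraction(scaled, [True, True], ["g0", "g1"]) == 0.75

    def test_symmetric_values_near_half(self):
        rng = np.random.default_rng(0)
        scaled = as_scaled(rng.normal(size=(500, 10)))
        frac = e.positive_fraction(scaled, np.ones(500, bool), [f"g{j}" for j in range(10)])
        assert abs(frac - 0.5) < 0.02

    def test_empty_cell_subset_errors(self):
        scaled = as_scaled([[1.0]])
        with pytest.raises(ValueError, match="empty"):
            e.positive_fraction(scaled, [False], ["g0"])


class TestEMScore:
    @pytest.mark.parametrize(
        "epi,mes,expected_class,expected_score",
        [
            (0.4, 0.4, "PEMT", 0.0),
            (0.8, 0.1, "EPI", 3.0),
            (0.1, 0.8, "MES", -3.0),
        ],
    )
    def test_worked_examples(self, epi, mes, expected_class, expected_score):
        score, em_class = e.em_score(epi, mes)
        assert score == pytest.approx(expected_score, abs=1e-4)
        assert em_class == expected_class

    def test_boundaries_inclusive(self):
        assert classify_score(1.5) == "EPI"
        assert classify_score(-1.5) == "MES"
        assert classify_score(1.4999) == "PEMT"
        assert classify_score(-1.4999) == "PEMT"

    def test_zero_fractions_guarded_by_pseudocount(self):
        score, em_class = e.em_score(1.0, 0.0)
        assert np.isfinite(score) and em_class == "EPI"

    @given(
        a=st.floats(0.001, 1.0),
        b=st.floats(0.001, 1.0),
    )
    def test_antisymmetry(self, a, b):
        cutoffs = e.PhenotypeCutoffs(pseudocount=1e-12)
        s_ab, _ = e.em_score(a, b, cutoffs)
        s_ba, _ = e.em_score(b, a, cutoffs)
        assert s_ab == pytest.approx(-s_ba, abs=1e-6)

    @given(
        mes=st.floats(0.01, 0.99),
        epi_lo=st.floats(0.01, 0.5),
        delta=st.floats(0.01, 0.49),
    )
    def test_monotone_in_epi_fraction(self, mes, epi_lo, delta):
        s_lo, _ = e.em_score(epi_lo, mes)
        s_hi, _ = e.em_score(epi_lo + delta, mes)
        assert s_hi > s_lo

    def test_out_of_range_fraction_errors(self):
        with pytest.raises(ValueError):
            e.em_score(1.2, 0.5)


def score_row(cluster, score, n_cells, em_class=None):
    return {
        "cluster": cluster,
        "epi_fraction": 0.5,
        "mes_fraction": 0.5,
        "score": score,
        "em_class": em_class or classify_score(score),
        "n_cells": n_cells,
    }


class TestOrderClusters:
    def make_assignment(self, labels):
        labels = np.asarray(labels)
        return e.ClusterAssignment(
            labels=labels, n_clusters=labels.max(), resolution=1.0, quality=0.5
        )

    def test_sorted_by_decreasing_score(self):
        table = pd.DataFrame(
            [score_row(1, -2.0, 5), score_row(2, 3.0, 5), score_row(3, 0.0, 5)]
        )
        asg = self.make_assignment([1, 2, 3, 1])
        ordered, new_asg = e.order_clusters(table, asg)
        assert list(ordered["score"]) == [3.0, 0.0, -2.0]
        assert list(ordered["cluster"]) == [1, 2, 3]
        # cell in old cluster 2 (score 3) is now cluster 1
        assert list(new_asg.labels) == [3, 1, 2, 3]

    def test_idempotent_on_sorted_table(self):
        table = pd.DataFrame([score_row(1, 2.0, 5), score_row(2, -1.0, 5)])
        asg = self.make_assignment([1, 2])
        once_t, once_a = e.order_clusters(table, asg)
        twice_t, twice_a = e.order_clusters(once_t, once_a)
        assert once_t.equals(twice_t)
        assert np.array_equal(once_a.labels, twice_a.labels)

    def test_score_tie_broken_by_cluster_size(self):
        table = pd.DataFrame([score_row(1, 1.0, 3), score_row(2, 1.0, 10)])
        asg = self.make_assignment([1, 2, 2])
        ordered, _ = e.order_clusters(table, asg)
        assert list(ordered["n_cells"]) == [10, 3]


class TestPhenotypeProportions:
    def test_four_cell_example(self):
        table = pd.DataFrame(
            [
                score_row(1, 2.0, 2, "EPI"),
                score_row(2, 0.0, 1, "PEMT"),
                score_row(3, -2.0, 1, "MES"),
            ]
        )
        asg = e.ClusterAssignment(
            labels=np.array([1, 1, 2, 3]), n_clusters=3, resolution=1.0, quality=0.5
        )
        props = e.phenotype_proportions(asg, table)["overall"]
        assert props == {"EPI": 50.0, "PEMT": 25.0, "MES": 25.0}

    def test_single_class_table(self):
        table = pd.DataFrame([score_row(1, -3.0, 4, "MES")])
        asg = e.ClusterAssignment(
            labels=np.array([1, 1, 1, 1]), n_clusters=1, resolution=1.0, quality=0.5
        )
        props = e.phenotype_proportions(asg, table)["overall"]
        assert props == {"EPI": 0.0, "PEMT": 0.0, "MES": 100.0}

    def test_percentages_sum_to_100_per_group(self, smoothed_population):
        _, smoothed, sig, _ = smoothed_population
        asg = e.cluster_cells(smoothed, resolution=1.0, seed=0)
        table = e.score_clusters(smoothed, asg, sig)
        props = e.phenotype_proportions(asg, table, smoothed.sample_labels)
        assert sum(props["overall"].values()) == pytest.approx(100.0, abs=1e-9)
        for block in props["by_sample"].values():
            assert sum(block.values()) == pytest.approx(100.0, abs=1e-9)

    def test_permutation_invariance(self, smoothed_population):
        """Permuting cell order (with labels permuted consistently) changes
        no cluster score and no phenotype proportion."""
        _, smoothed, sig, _ = smoothed_population
        asg = e.cluster_cells(smoothed, resolution=1.0, seed=0)
        table = e.score_clusters(smoothed, asg, sig)
        props = e.phenotype_proportions(asg, table)["overall"]

        rng = np.random.default_rng(9)
        perm = rng.permutation(smoothed.n_cells)
        permuted = ScaledMatrix(
            values=smoothed.values[perm],
            cell_ids=smoothed.cell_ids[perm],
            gene_ids=smoothed.gene_ids,
            sample_labels=smoothed.sample_labels[perm],
        )
        asg_p = e.ClusterAssignment(
            labels=asg.labels[perm], n_clusters=asg.n_clusters,
            resolution=asg.resolution, quality=asg.quality,
        )
        table_p = e.score_clusters(permuted, asg_p, sig)
        props_p = e.phenotype_proportions(asg_p, table_p)["overall"]
        pd.testing.assert_frame_equal(table, table_p)
        assert props == props_p


class TestClassifySample:
    def test_pooled_and_plurality_agree_on_pure_epithelial_sample(self):
        rng = np.random.default_rng(0)
        n = 40
        values = np.hstack([rng.uniform(0.5, 2, (n, 5)), rng.uniform(-2, -0.5, (n, 5))])
        scaled = ScaledMatrix(
            values=values,
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(10)], dtype=object),
            sample_labels=np.array(["sA"] * n, dtype=object),
        )
        sig = e.EMTSignature(tuple(f"g{j}" for j in range(5)),
                             tuple(f"g{j}" for j in range(5, 10)))
        asg = e.ClusterAssignment(
            labels=np.ones(n, int), n_clusters=1, resolution=1.0, quality=1.0
        )
        table = e.score_clusters(scaled, asg, sig)
        for rule in ("pooled", "plurality"):
            call = e.classify_sample(scaled, asg, table, sig, "sA", rule=rule)
            assert call["em_class"] == "EPI"
            assert call["rule"] == rule

    def test_balanced_pooled_fractions_give_pemt(self):
        values = np.array([[1.0, -1.0], [-1.0, 1.0]])
        scaled = ScaledMatrix(
            values=values,
            cell_ids=np.array(["c0", "c1"], dtype=object),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            sample_labels=np.array(["sA", "sA"], dtype=object),
        )
        sig = e.EMTSignature(("g0",), ("g1",))
        asg = e.ClusterAssignment(
            labels=np.array([1, 1]), n_clusters=1, resolution=1.0, quality=1.0
        )
        table = e.score_clusters(scaled, asg, sig)
        call = e.classify_sample(scaled, asg, table, sig, "sA")
        assert call["score"] == pytest.approx(0.0, abs=1e-6)
        assert call["em_class"] == "PEMT"

    def test_unknown_sample_errors(self, smoothed_population):
        _, smoothed, sig, _ = smoothed_population
        asg = e.cluster_cells(smoothed, resolution=1.0, seed=0)
        table = e.score_clusters(smoothed, asg, sig)
        with pytest.raises(KeyError, match="unknown sample"):
            e.classify_sample(smoothed, asg, table, sig, "nope")

    def test_pure_band_samples_all_called_correctly(self):
        """Twenty synthetic samples drawn purely from one latent band each
        are all assigned their generating phenotype."""
        import dataclasses

        parts = []
        weights = {"EPI": (1, 0, 0), "PEMT": (0, 1, 0), "MES": (0, 0, 1)}
        plan = [("EPI", 7), ("PEMT", 7), ("MES", 6)]
        offset = 0
        sample_names, expected = [], {}
        for cls, n_samples in plan:
            cfg = dataclasses.replace(
                e.GeneratorConfig(n_cells=n_samples * 60, seed=100 + offset),
                mixture_weights=weights[cls], n_samples=n_samples,
            )
            counts, sig, _ = e.generate_emt_population(cfg)
            labels = np.array(
                [f"{cls.lower()}_{s.split('sample')[1]}" for s in counts.sample_labels],
                dtype=object,
            )
            cells = np.array([f"{cls}_{c}" for c in counts.cell_ids], dtype=object)
            parts.append((counts.counts, cells, labels))
            for s in np.unique(labels):
                expected[s] = cls
            offset += 1
        combined = e.CountMatrix(
            counts=np.vstack([p[0] for p in parts]),
            cell_ids=np.concatenate([p[1] for p in parts]),
            gene_ids=counts.gene_ids,
            sample_labels=np.concatenate([p[2] for p in parts]),
            mito_flags=counts.mito_flags,
        )
        filtered, _ = e.qc_filter(combined)
        scaled = e.normalize_and_scale(filtered)
        sig_scaled = scaled.restrict_genes(sig.all_genes)
        smoothed = e.impute(sig_scaled, e.build_diffusion_operator(sig_scaled))
        asg = e.cluster_cells(smoothed, resolution=1.0, seed=0)
        table = e.score_clusters(smoothed, asg, sig)
        calls = e.classify_samples(smoothed, asg, table, sig)
        assert len(calls) == 20
        for _, row in calls.iterrows():
            assert row["em_class"] == expected[row["sample_id"]]
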