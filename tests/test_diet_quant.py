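import numpy as np
import pandas as pd
import pytest

from cervidiet import diet_quant, synthetic
from cervidiet.io_model import DietProfile
from conftest import make_plant_counts

MOTUS = [f"t{i}" for i in range(6)] + ["low_sim"]


class TestReplicateDistances:
    def test_identical_replicates_have_zero_pcr_distance(self):
        t = make_plant_counts([("s1", 1, "none", [10, 10, 0, 0, 0, 0, 0]),
                               ("s1", 2, "none", [20, 20, 0, 0, 0, 0, 0])],
                              MOTUS)
        rd = diet_quant.replicate_distances(t)
        assert np.allclose(rd.pcr["distance"], 0.0)

    def test_opposed_replicates_distance_half(self):
        # proportions (1,0) and (0,1): barycenter (0.5, 0.5); Bray-Curtis
        # of (1,0) vs (0.5,0.5) = (0.5+0.5)/2 = 0.5
        t = make_plant_counts([("s1", 1, "none", [100, 0, 0, 0, 0, 0, 0]),
                               ("s1", 2, "none", [0, 100, 0, 0, 0, 0, 0])],
                              MOTUS)
        rd = diet_quant.replicate_distances(t)
        assert np.allclose(rd.pcr["distance"], 0.5)

    def test_identical_barycenters_give_zero_sample_distance(self):
        rows = [("s1", 1, "none", [10, 30, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [10, 30, 0, 0, 0, 0, 0]),
                ("s2", 1, "none", [1, 3, 0, 0, 0, 0, 0]),
                ("s2", 2, "none", [2, 6, 0, 0, 0, 0, 0])]
        rd = diet_quant.replicate_distances(make_plant_counts(rows, MOTUS))
        assert rd.sample_distances == pytest.approx([0.0])

    def test_single_replicate_sample_flagged(self):
        rows = [("s1", 1, "none", [10, 0, 0, 0, 0, 0, 0]),
                ("s2", 1, "none", [0, 10, 0, 0, 0, 0, 0]),
                ("s2", 2, "none", [0, 12, 0, 0, 0, 0, 0])]
        rd = diet_quant.replicate_distances(make_plant_counts(rows, MOTUS))
        assert rd.flagged == ["s1"]
        assert len(rd.sample_distances) == 0  # s1 excluded, one left


class TestQcThreshold:
    def test_standard_normal_logs_closed_form(self):
        # log-distances with mean 0 and (population) SD 1: the fitted 5th
        # percentile is exp(-1.6449) = 0.1931
        d = np.exp(np.array([1.0, -1.0] * 10))
        thr = diet_quant.qc_threshold(d, min_n=20)
        assert thr == pytest.approx(0.19305, abs=5e-4)

    def test_degenerate_equal_distances(self):
        thr = diet_quant.qc_threshold(np.full(25, 0.37))
        assert thr == pytest.approx(0.37)

    def test_monte_carlo_matches_empirical_percentile(self):
        rng = np.random.default_rng(42)
        d = rng.lognormal(mean=-1.0, sigma=0.5, size=10_000)
        thr = diet_quant.qc_threshold(d)
        emp = np.quantile(d, 0.05)
        assert abs(thr - emp) / emp < 0.02

    def test_too_few_distances_instructs_explicit_threshold(self):
        with pytest.raises(ValueError, match="explicit threshold"):
            diet_quant.qc_threshold(np.ones(5))


class TestFilterReplicates:
    def test_low_read_boundary(self):
        rows = [("s1", 1, "none", [999, 0, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [500, 500, 0, 0, 0, 0, 0]),
                ("s1", 3, "none", [510, 510, 0, 0, 0, 0, 0])]
        report, retained = diet_quant.filter_replicates(
            make_plant_counts(rows, MOTUS), threshold=1.0)
        by_rep = report.frame.set_index("replicate_index")["status"]
        assert by_rep[1] == "discarded_low_reads"
        assert by_rep[2] == by_rep[3] == "kept"
        assert len(retained) == 2

    def test_exactly_1000_reads_kept(self):
        rows = [("s1", 1, "none", [1000, 0, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [1000, 0, 0, 0, 0, 0, 0])]
        report, _ = diet_quant.filter_replicates(
            make_plant_counts(rows, MOTUS), threshold=1.0)
        assert (report.frame["status"] == "kept").all()

    def test_outlier_replicate_discarded_sample_kept_with_two(self):
        # proportions (1,0), (0.99,0.01) and (0.5,0.5): barycenter
        # (0.830, 0.170); Bray-Curtis distances 0.170, 0.160, 0.330
        rows = [("s1", 1, "none", [3000, 0, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [3000, 30, 0, 0, 0, 0, 0]),
                ("s1", 3, "none", [1500, 1500, 0, 0, 0, 0, 0])]
        report, retained = diet_quant.filter_replicates(
            make_plant_counts(rows, MOTUS), threshold=0.25)
        by_rep = report.frame.set_index("replicate_index")["status"]
        assert by_rep[3] == "discarded_distance"
        assert by_rep[1] == by_rep[2] == "kept"
        assert sorted(retained.frame["replicate_index"]) == [1, 2]

    def test_control_like_replicate_discarded(self):
        ctrl = [0, 0, 0, 0, 0, 2000, 0]
        rows = [("s1", 1, "none", [3000, 1000, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [3100, 1000, 0, 0, 0, 0, 0]),
                ("s1", 3, "none", [0, 0, 0, 0, 0, 2500, 0])]
        for sid in ("s2", "s3"):
            for rep in (1, 2, 3):
                rows.append((sid, rep, "none",
                             [3000 + 10 * rep, 1100, 0, 0, 0, 0, 0]))
        rows += [("", i + 1, "pcr_negative", ctrl) for i in range(5)]
        report, retained = diet_quant.filter_replicates(
            make_plant_counts(rows, MOTUS), threshold=2.0, knn_k=5)
        key = report.frame.set_index(["sample_id", "replicate_index"])
        assert key.loc[("s1", 3), "status"] == "discarded_control_like"
        assert (report.frame["status"] == "kept").sum() == 8
        assert len(retained) == 8

    def test_sample_dropped_below_two_kept(self):
        rows = [("s1", 1, "none", [2000, 0, 0, 0, 0, 0, 0]),
                ("s1", 2, "none", [900, 0, 0, 0, 0, 0, 0]),
                ("s1", 3, "none", [800, 0, 0, 0, 0, 0, 0])]
        _, retained = diet_quant.filter_replicates(
            make_plant_counts(rows, MOTUS), threshold=1.0)
        assert len(retained) == 0


class TestMotuFilters:
    def _averaged(self, rows):
        frame = pd.DataFrame(rows, columns=MOTUS)
        frame.insert(0, "sample_id", [f"s{i}" for i in range(len(rows))])
        return frame

    def test_low_similarity_motu_removed(self, plant_catalog):
        avg = self._averaged([[100, 100, 0, 0, 0, 0, 800]])
        out = diet_quant.motu_filters(avg, plant_catalog)
        assert "low_sim" not in out.columns  # 94.9% < 95%

    def test_max_rra_boundary(self, plant_catalog):
        # t1 peaks at 2.4% (removed); t2 peaks at 2.6% in one sample only
        # (kept everywhere)
        avg = self._averaged([[950, 24, 26, 0, 0, 0, 0],
                              [990, 5, 5, 0, 0, 0, 0]])
        out = diet_quant.motu_filters(avg, plant_catalog)
        assert "t1" not in out.columns and "t2" in out.columns

    def test_rra_renormalizes_after_removal(self, plant_catalog):
        avg = self._averaged([[950, 24, 26, 0, 0, 0, 100]])
        out = diet_quant.motu_filters(avg, plant_catalog)
        rra = diet_quant.to_rra(out)
        assert rra.matrix().sum(axis=1) == pytest.approx([1.0])


class TestCollapseAndRra:
    def test_to_rra_examples(self):
        table = pd.DataFrame({"sample_id": ["a", "b", "c"],
                              "x": [30, 1, 3], "y": [70, 0, 7]})
        prof = diet_quant.to_rra(table)
        assert prof.matrix() == pytest.approx(
            np.array([[0.3, 0.7], [1.0, 0.0], [0.3, 0.7]]))

    def test_to_rra_drops_zero_rows(self):
        table = pd.DataFrame({"sample_id": ["a", "b"], "x": [5, 0],
                              "y": [5, 0]})
        prof = diet_quant.to_rra(table)
        assert list(prof.sample_ids) == ["a"]

    def test_collapse_sums_within_genus(self, plant_catalog):
        table = pd.DataFrame({"sample_id": ["a"], "t0": [10.0],
                              "t1": [15.0], "low_sim": [75.0]})
        out = diet_quant.collapse_taxa(table, plant_catalog, rank="genus",
                                       fallback="other")
        assert out.loc[0, "Vaccinium"] == pytest.approx(25.0)
        # total reads conserved before renormalization
        assert out.drop(columns="sample_id").to_numpy().sum() == \
            pytest.approx(100.0)

    def test_collapse_unmapped_motu_raises_listing_it(self, plant_catalog):
        table = pd.DataFrame({"sample_id": ["a"], "t0": [1.0],
                              "nope": [2.0]})
        with pytest.raises(ValueError, match="nope"):
            diet_quant.collapse_taxa(table, plant_catalog, rank="category",
                                     category_map={"t0": "vaccinium"})

    def test_collapse_then_rra_commutes_with_rra_then_sum(
            self, plant_catalog):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(4, 7)).astype(float)
        table = pd.DataFrame(counts, columns=MOTUS)
        table.insert(0, "sample_id", list("abcd"))
        cmap = {m: ("g1" if i % 2 else "g2")
                for i, m in enumerate(MOTUS)}
        left = diet_quant.to_rra(diet_quant.collapse_taxa(
            table, plant_catalog, rank="category", category_map=cmap))
        rra = diet_quant.to_rra(table)
        right_g1 = rra.frame[[m for m in MOTUS if cmap[m] == "g1"]].sum(
            axis=1)
        assert left.frame["g1"].to_numpy() == pytest.approx(
            right_g1.to_numpy())


class TestPipelineProperties:
    def test_filters_are_monotone_on_synthetic_data(self, small_sim):
        plant = small_sim.read_counts
        rd = diet_quant.replicate_distances(plant)
        thr = diet_quant.qc_threshold(rd.sample_distances)
        report, retained = diet_quant.filter_replicates(plant, thr)
        n_sample_pcrs = (plant.frame["marker"].eq("plant")
                         & plant.frame["control_kind"].eq("none")).sum()
        assert len(retained) <= n_sample_pcrs
        averaged = diet_quant.average_replicates(retained)
        filtered = diet_quant.motu_filters(averaged, small_sim.catalog)
        assert len(filtered) <= len(averaged)
        assert filtered.shape[1] <= averaged.shape[1]

    def test_rra_error_decreases_with_depth(self):
        import dataclasses
        base = synthetic.make_default_spec(
            n_transects={"coastal_boreal": 2, "boreo_nemoral": 2},
            artifact_rate=0.0, low_depth_rate=0.0, control_like_rate=0.0)

        def mae(depth):
            spec = dataclasses.replace(
                base, depth_meanlog=float(np.log(depth)), depth_sdlog=0.1)
            sim = synthetic.simulate_dataset(spec, seed=17)
            frame = sim.read_counts.samples().frame
            plant = frame[frame["marker"] == "plant"]
            counts = plant[spec.motu_ids].to_numpy(dtype=float)
            rra = counts / counts.sum(axis=1, keepdims=True)
            latent = sim.truth.set_index("sample_id").loc[
                plant["sample_id"]].to_numpy()
            return np.abs(rra - latent).mean()

        assert mae(1e5) < mae(1e3)
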