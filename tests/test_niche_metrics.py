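import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervidiet import niche_metrics as nm
from cervidiet.io_model import DietProfile, SampleMetadata


def _profile(rows, taxa=None):
    taxa = taxa or [f"x{i}" for i in range(len(rows[0]))]
    frame = pd.DataFrame(rows, columns=taxa)
    frame.insert(0, "sample_id", [f"s{i}" for i in range(len(rows))])
    return DietProfile(frame)


simplex = st.integers(2, 8).flatmap(
    lambda k: st.lists(st.floats(1e-3, 1.0), min_size=k, max_size=k)
).map(lambda w: np.array(w) / np.sum(w))


class TestRichness:
    def test_counts_positive_entries(self):
        prof = _profile([[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])
        out = nm.richness(prof)
        assert list(out["S"]) == [2, 1]

    def test_removing_a_column_never_increases_richness(self):
        rng = np.random.default_rng(0)
        mat = rng.dirichlet(np.ones(5), size=10)
        prof = _profile(mat.tolist())
        s_full = nm.richness(prof)["S"]
        reduced = mat[:, :4] / mat[:, :4].sum(axis=1, keepdims=True)
        s_red = nm.richness(_profile(reduced.tolist()))["S"]
        assert (s_red <= s_full).all()


class TestDunn:
    def test_hand_computed_z_two_groups(self):
        # groups {1,2,3} vs {4,5,6}: mid-ranks 2 vs 5, N = 6, no ties:
        # z = 3 / sqrt((6*7/12)(1/3 + 1/3)) = 3 / sqrt(2.3333) = 1.9640
        out = nm.dunn_bh([1, 2, 3, 4, 5, 6],
                         ["a", "a", "a", "b", "b", "b"])
        assert abs(out.loc[0, "z"]) == pytest.approx(1.9640, abs=1e-4)
        assert out.loc[0, "p"] == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups_give_z_zero_p_one(self):
        out = nm.dunn_bh([1, 2, 3, 1, 2, 3],
                         ["a", "a", "a", "b", "b", "b"])
        assert out.loc[0, "z"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_stepup_arithmetic(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        out = nm.dunn_bh(values, groups)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert out["p_adj"].between(0, 1).all()

    def test_small_group_excluded(self):
        out = nm.dunn_bh([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        pairs = set(zip(out["group_a"], out["group_b"]))
        assert pairs == {("a", "b")}

    def test_matches_permutation_oracle_sign_and_ordering(self):
        # brute-force exhaustive permutation of pairwise mean-rank
        # differences on an n = 8 fixture: the Dunn z must carry the same
        # sign, and the pair ordering by |z| must not invert the ordering
        # by exact permutation p
        from scipy.stats import rankdata
        values = np.array([1.0, 4.0, 5.0, 2.0, 3.0, 8.0, 6.0, 7.0])
        groups = np.array(list("aaabbbcc"))
        out = nm.dunn_bh(values, groups).set_index(["group_a", "group_b"])
        ranks = rankdata(values)
        perm_p, sign = {}, {}
        for a, b in itertools.combinations("abc", 2):
            mask = (groups == a) | (groups == b)
            r = ranks[mask]
            g = groups[mask]
            n_a = (g == a).sum()
            obs = r[g == a].mean() - r[g == b].mean()
            sign[(a, b)] = np.sign(obs)
            count, total = 0, 0
            for combo in itertools.combinations(range(len(r)), n_a):
                sel = np.zeros(len(r), bool)
                sel[list(combo)] = True
                stat = abs(r[sel].mean() - r[~sel].mean())
                count += stat >= abs(obs) - 1e-12
                total += 1
            perm_p[(a, b)] = count / total
        for pair in perm_p:
            assert np.sign(out.loc[pair, "z"]) == sign[pair]
            for other in perm_p:
                if perm_p[pair] < perm_p[other]:
                    assert abs(out.loc[pair, "z"]) >= \
                        abs(out.loc[other, "z"]) - 1e-9


class TestDnw:
    def test_uniform_diet_equals_taxon_count(self):
        assert nm.dnw(np.full((1, 4), 0.25)) == pytest.approx(4.0)

    def test_single_taxon_is_one(self):
        assert nm.dnw(np.array([[1.0, 0.0, 0.0]])) == pytest.approx(1.0)

    def test_even_two_taxa(self):
        assert nm.dnw(np.array([[0.5, 0.5]])) == pytest.approx(2.0)

    @given(simplex)
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, q):
        val = nm.dnw(q[None, :])
        assert 1.0 - 1e-9 <= val <= len(q) + 1e-9


class TestPianka:
    def test_identical_vectors_complete_overlap(self):
        u = np.array([0.4, 0.3, 0.2, 0.1])
        assert nm.pianka(u, u) == pytest.approx(1.0)

    def test_disjoint_supports_no_overlap(self):
        assert nm.pianka([1, 0, 0], [0, 0.5, 0.5]) == pytest.approx(0.0)

    def test_half_overlap_value(self):
        assert nm.pianka([0.5, 0.5], [1.0, 0.0]) == \
            pytest.approx(1 / math.sqrt(2), abs=1e-4)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            nm.pianka([0, 0], [1, 0])

    @given(simplex, simplex)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, u, v):
        k = min(len(u), len(v))
        u, v = u[:k] / u[:k].sum(), v[:k] / v[:k].sum()
        o = nm.pianka(u, v)
        assert 0.0 <= o <= 1.0
        assert o == pytest.approx(nm.pianka(v, u))


class TestJacobsD:
    @pytest.mark.parametrize("r,p,expected", [
        (0.0, 0.5, -1.0),           # absent from diet, available
        (0.3, 0.0, 1.0),            # eaten, unavailable
        (0.3, 0.3, 0.0),            # neutral
        (0.2, 0.1, 0.1 / 0.26),     # direct formula
    ])
    def test_values(self, r, p, expected):
        assert nm.jacobs_d(r, p) == pytest.approx(expected, abs=1e-9)

    def test_undefined_cases_are_nan(self):
        assert math.isnan(nm.jacobs_d(0.0, 0.0))
        assert math.isnan(nm.jacobs_d(1.0, 1.0))

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric(self, r, p):
        assert nm.jacobs_d(r, p) == pytest.approx(-nm.jacobs_d(p, r))


def _meta(rows):
    return SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "transect_id", "landscape", "season",
                       "collection_date", "putative_species"]))


class TestOverlapTable:
    def _setup(self, mats):
        rows, meta_rows, species = [], [], {}
        i = 0
        for sp, mat in mats.items():
            for v in mat:
                sid = f"s{i}"
                rows.append((sid, v))
                meta_rows.append([sid, "t1", "coastal_boreal", "winter",
                                  "2017-01-10", sp])
                species[sid] = sp
                i += 1
        frame = pd.DataFrame([r[1] for r in rows],
                             columns=["x0", "x1", "x2"])
        frame.insert(0, "sample_id", [r[0] for r in rows])
        return (DietProfile(frame), _meta(meta_rows),
                pd.Series(species))

    def test_identical_conspecific_samples_intra_one(self):
        prof, meta, sp = self._setup({"moose": [[0.5, 0.3, 0.2]] * 2})
        out = nm.overlap_table(prof, meta, sp).frame
        intra = out[out["kind"] == "intra"]
        assert intra["pianka"].iloc[0] == pytest.approx(1.0)

    def test_three_samples_mean_of_pairs(self):
        u = [0.5, 0.5, 0.0]
        v = [1.0, 0.0, 0.0]
        a = nm.pianka(u, v)
        prof, meta, sp = self._setup({"moose": [u, u, v]})
        out = nm.overlap_table(prof, meta, sp).frame
        intra = out[out["kind"] == "intra"]
        assert intra["pianka"].iloc[0] == pytest.approx((1 + 2 * a) / 3)

    def test_inter_uses_species_mean_diets(self):
        prof, meta, sp = self._setup({
            "moose": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            "red": [[0.5, 0.5, 0.0]]})
        out = nm.overlap_table(prof, meta, sp).frame
        inter = out[out["kind"] == "inter"]
        assert inter["pianka"].iloc[0] == pytest.approx(1.0)

    def test_summary_flags_low_transect_replication(self):
        prof, meta, sp = self._setup({"moose": [[0.5, 0.3, 0.2]] * 2})
        table = nm.overlap_table(prof, meta, sp)
        summary = nm.overlap_summary(table)
        assert bool(summary["low_replication"].iloc[0])


class TestSelectivity:
    def _avail(self, cats, props, hr="0-3m"):
        from cervidiet.io_model import AvailabilityTable
        rows = [{"transect_id": "t1", "season": "winter",
                 "height_range": hr, "category": c, "proportion": p}
                for c, p in zip(cats, props)]
        return AvailabilityTable(pd.DataFrame(rows))

    def test_diet_matching_availability_is_neutral(self):
        taxa = ["pine", "birch"]
        frame = pd.DataFrame([[0.6, 0.4]], columns=taxa)
        frame.insert(0, "sample_id", ["s0"])
        prof = DietProfile(frame)
        meta = _meta([["s0", "t1", "coastal_boreal", "winter",
                       "2017-01-10", "moose"]])
        avail = self._avail(taxa, [0.6, 0.4])
        out = nm.selectivity_table(prof, avail, meta,
                                   pd.Series({"s0": "moose"}))
        assert out["D"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_category_absent_from_availability_gets_p_zero(self):
        taxa = ["pine", "juniper"]
        frame = pd.DataFrame([[0.7, 0.3]], columns=taxa)
        frame.insert(0, "sample_id", ["s0"])
        prof = DietProfile(frame)
        meta = _meta([["s0", "t1", "coastal_boreal", "winter",
                       "2017-01-10", "moose"]])
        avail = self._avail(["pine"], [1.0])
        out = nm.selectivity_table(prof, avail, meta,
                                   pd.Series({"s0": "moose"}))
        juniper = out[out["category"] == "juniper"]
        assert juniper["p"].iloc[0] == 0.0
        assert juniper["D"].iloc[0] == pytest.approx(1.0)

    def test_height_range_follows_species(self):
        taxa = ["pine"]
        frame = pd.DataFrame([[1.0]], columns=taxa)
        frame.insert(0, "sample_id", ["s0"])
        prof = DietProfile(frame)
        meta = _meta([["s0", "t1", "coastal_boreal", "winter",
                       "2017-01-10", "roe"]])
        avail = self._avail(["pine"], [1.0], hr="0-1.5m")
        out = nm.selectivity_table(prof, avail, meta,
                                   pd.Series({"s0": "roe"}))
        assert out["p"].iloc[0] == 1.0  # matched on the roe height range

    def test_summary_mean_and_sd(self):
        records = pd.DataFrame([
            {"landscape": "l", "season": "winter", "species": "moose",
             "category": "pine", "transect_id": t, "r": 0.5, "p": 0.3,
             "D": d, "n_samples": 3}
            for t, d in [("t1", 0.2), ("t2", 0.4)]])
        out = nm.selectivity_summary(records)
        assert out["mean_D"].iloc[0] == pytest.approx(0.3)
        assert out["sd_D"].iloc[0] == pytest.approx(0.1414, abs=1e-3)
        assert not out["single_transect"].iloc[0]
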