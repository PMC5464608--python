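"""Differential statistics, set scores, feature construction, Sturges binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from indicell import features as feat
from indicell.features import (
    DifferentialResult,
    GeneSetCollection,
    ad_joint_score,
    aggregate_set_features,
    cluster_features,
    differential_stats,
    filter_genes_in_sets,
    gene_features,
    gsa_scores,
    maxmean_statistic,
    sturges_filter,
)

from conftest import make_expression, make_meta


# ---------------------------------------------------------------------------
# Welch statistics
# ---------------------------------------------------------------------------

class TestDifferentialStats:
    def _setup(self, disease_rows, control_rows):
        data = np.hstack([disease_rows, control_rows])
        m = make_expression(data, sample_ids=[f"d{i}" for i in range(3)]
                            + [f"c{i}" for i in range(3)])
        meta = make_meta(["carrier"] * 3 + ["non-carrier"] * 3,
                         sample_ids=list(m.sample_ids))
        return m, meta

    def test_welch_matches_hand_formula(self):
        """3v3 toy: t and p agree with the Welch-Satterthwaite arithmetic."""
        d = np.array([[1.0, 2.0, 3.0]])
        c = np.array([[4.0, 6.0, 8.0]])
        m, meta = self._setup(d, c)
        res = differential_stats(m, meta)
        # independent oracle: explicit Welch formula
        mx, my = d.mean(), c.mean()
        vx, vy = d.var(ddof=1), c.var(ddof=1)
        se2 = vx / 3 + vy / 3
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2)
        from scipy import stats
        p = 2 * stats.t.sf(abs(t), df)
        assert res.genes.loc["g0", "fold_change"] == pytest.approx(mx - my)
        assert res.genes.loc["g0", "t"] == pytest.approx(t)
        assert res.genes.loc["g0", "p"] == pytest.approx(p)

    def test_fold_change_sign_and_zero(self):
        d = np.array([[0.0, 0.0, 0.0], [-1.0, -1.0, -1.2]])
        c = np.array([[0.0, 0.1, -0.1], [0.0, 0.1, -0.1]])
        m, meta = self._setup(d, c)
        res = differential_stats(m, meta)
        assert res.genes.loc["g0", "fold_change"] == pytest.approx(0.0, abs=0.07)
        assert res.genes.loc["g1", "fold_change"] == pytest.approx(-1.1, abs=0.07)

    def test_zero_variance_convention(self):
        d = np.array([[1.0, 1.0, 1.0]])
        c = np.array([[1.0, 1.0, 1.0]])
        m, meta = self._setup(d, c)
        res = differential_stats(m, meta)
        row = res.genes.loc["g0"]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["flagged"]


# ---------------------------------------------------------------------------
# maxmean / set scores
# ---------------------------------------------------------------------------

class TestMaxmean:
    def test_worked_example(self):
        # positive-part mean (2+0)/2 = 1 beats negative-part mean 0.5
        assert maxmean_statistic(np.array([2.0, -1.0])) == pytest.approx(1.0)

    def test_all_zero(self):
        assert maxmean_statistic(np.zeros(5)) == 0.0

    def test_negative_dominates(self):
        assert maxmean_statistic(np.array([-2.0, 1.0])) == pytest.approx(-1.0)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_sign_antisymmetry(self, scores):
        s = np.array(scores)
        assert maxmean_statistic(-s) == pytest.approx(-maxmean_statistic(s))


class TestGsaScores:
    def _toy(self, seed=0, effect=-1.0):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 0.3, size=(40, 12))
        data[:8, :6] += effect  # first 8 genes down in disease
        m = make_expression(data, sample_ids=[f"d{i}" for i in range(6)]
                            + [f"c{i}" for i in range(6)])
        meta = make_meta(["carrier"] * 6 + ["non-carrier"] * 6,
                         sample_ids=list(m.sample_ids))
        sets = GeneSetCollection({
            "planted": frozenset(f"g{i}" for i in range(8)),
            "null_a": frozenset(f"g{i}" for i in range(10, 20)),
            "null_b": frozenset(f"g{i}" for i in range(20, 30)),
        })
        return m, meta, sets

    def test_planted_set_selected_down_only(self):
        m, meta, sets = self._toy()
        diff = differential_stats(m, meta)
        diff = gsa_scores(diff, sets, m, meta, n_perm=200, seed=1)
        selected = diff.selected_sets("down_only")
        assert "planted" in selected
        assert diff.set_scores.loc["planted", "score"] <= -1

    def test_all_zero_scores_select_nothing(self):
        m, meta, sets = self._toy()
        diff = differential_stats(m, meta)
        diff.genes["t"] = 0.0
        scored = gsa_scores(diff, sets, m, meta, n_perm=50, seed=1,
                            restandardize=False)
        assert (scored.set_scores["raw_score"] == 0).all()
        assert len(scored.selected_sets("two_sided")) == 0

    def test_sign_flip_negates_scores(self):
        """Negating the data flips gene scores, and with the same seed the
        restandardized set scores negate exactly."""
        m, meta, sets = self._toy()
        diff = differential_stats(m, meta)
        a = gsa_scores(diff, sets, m, meta, n_perm=100, seed=5)
        m_neg = make_expression(-m.values.to_numpy(),
                                sample_ids=list(m.sample_ids))
        diff_neg = differential_stats(m_neg, meta)
        b = gsa_scores(diff_neg, sets, m_neg, meta, n_perm=100, seed=5)
        np.testing.assert_allclose(a.set_scores["score"],
                                   -b.set_scores["score"], atol=1e-10)

    def test_unresolvable_set_excluded(self):
        m, meta, sets = self._toy()
        sets = GeneSetCollection({**dict(sets.items()),
                                  "ghost": frozenset(["zz1", "zz2"])})
        diff = differential_stats(m, meta)
        scored = gsa_scores(diff, sets, m, meta, n_perm=50, seed=1)
        assert "ghost" not in scored.set_scores.index


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

class TestAggregateSetFeatures:
    def test_mean_and_singleton(self):
        m = make_expression([[0.4, 1.0], [-0.2, 2.0], [5.0, 6.0]])
        sets = GeneSetCollection({"ab": frozenset(["g0", "g1"]),
                                  "solo": frozenset(["g2"])})
        table = aggregate_set_features(m, sets)
        assert table.values.loc["s0", "ab"] == pytest.approx(0.1)
        assert table.values.loc["s1", "ab"] == pytest.approx(1.5)
        np.testing.assert_allclose(table.values["solo"], m.values.loc["g2"])

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(0)
        m = make_expression(rng.normal(size=(10, 6)))
        sets = GeneSetCollection({"s1": frozenset(["g0", "g3", "g7"]),
                                  "s2": frozenset(["g1", "g9"])})
        a = aggregate_set_features(m, sets)
        perm = list(m.sample_ids[::-1])
        b = aggregate_set_features(m.subset_samples(perm), sets)
        pd.testing.assert_frame_equal(a.values.loc[perm], b.values)

    def test_feature_count_matches_selection(self):
        rng = np.random.default_rng(1)
        m = make_expression(rng.normal(size=(200, 4)))
        sets = GeneSetCollection({
            f"set{i}": frozenset(f"g{j}" for j in range(i, i + 3))
            for i in range(64)
        })
        table = aggregate_set_features(m, sets)
        assert table.values.shape[1] == 64


class TestFilterGenesInSets:
    def _diff(self, p, fc):
        genes = pd.DataFrame({
            "fold_change": fc, "p": p, "t": np.sign(fc), "flagged": False,
        }, index=[f"g{i}" for i in range(len(p))])
        return DifferentialResult(genes=genes, disease_class="carrier",
                                  control_class="non-carrier")

    def test_union_threshold_and_direction(self):
        diff = self._diff(p=[0.01, 0.5, 0.01, 0.01],
                          fc=[-1.0, -1.0, -1.0, +1.0])
        sets = GeneSetCollection({"A": frozenset(["g0", "g1"]),
                                  "B": frozenset(["g1", "g2", "g3"])})
        kept = filter_genes_in_sets(sets, {"A": -1, "B": -1}, diff, alpha=0.05)
        # g1 fails p, g3 has the wrong sign
        assert kept == ["g0", "g2"]

    def test_empty_result_raises(self):
        diff = self._diff(p=[0.9], fc=[-1.0])
        sets = GeneSetCollection({"A": frozenset(["g0"])})
        with pytest.raises(ValueError, match="alpha"):
            filter_genes_in_sets(sets, {"A": -1}, diff, alpha=0.05)

    def test_conflicting_directions_keep_any_match(self):
        diff = self._diff(p=[0.01], fc=[-1.0])
        sets = GeneSetCollection({"down": frozenset(["g0"]),
                                  "up": frozenset(["g0"])})
        kept = filter_genes_in_sets(sets, {"down": -1, "up": +1}, diff)
        assert kept == ["g0"]


# ---------------------------------------------------------------------------
# joint gene score
# ---------------------------------------------------------------------------

class TestJointScore:
    def _diff_with_sets(self):
        rng = np.random.default_rng(3)
        n = 20
        genes = pd.DataFrame({
            "fold_change": rng.normal(0, 1, n),
            "p": rng.uniform(0, 1, n),
            "t": rng.normal(0, 1, n),
            "flagged": False,
        }, index=[f"g{i}" for i in range(n)])
        genes.loc["g0", ["fold_change", "p"]] = [5.0, 1e-9]  # best everywhere
        sets = GeneSetCollection({"top": frozenset(["g0", "g1"])})
        set_scores = pd.DataFrame({"raw_score": [2.0], "score": [9.0],
                                   "direction": [1]}, index=["top"])
        diff = DifferentialResult(genes=genes, disease_class="carrier",
                                  control_class="non-carrier",
                                  set_scores=set_scores)
        return diff, sets

    def test_best_gene_scores_one(self):
        diff, sets = self._diff_with_sets()
        js = ad_joint_score(diff, sets)
        assert js.table.loc["g0", "score"] == pytest.approx(1.0)
        assert js.top_genes(1) == ["g0"]

    def test_geometric_mean_combination(self):
        """Combined score is the geometric mean of the three percentile
        ranks; hand value (1.0*0.5*0.5)^(1/3) ~ 0.63."""
        diff, sets = self._diff_with_sets()
        js = ad_joint_score(diff, sets)
        t = js.table
        np.testing.assert_allclose(
            t["score"], (t["fc_rank"] * t["p_rank"] * t["gsa_rank"]) ** (1 / 3)
        )
        assert (1.0 * 0.5 * 0.5) ** (1 / 3) == pytest.approx(0.6300, abs=5e-4)

    def test_monotone_in_each_component(self):
        diff, sets = self._diff_with_sets()
        base = ad_joint_score(diff, sets).table
        better = diff.genes.copy()
        better.loc["g5", "p"] = 1e-12  # improve one metric only
        diff2 = DifferentialResult(genes=better, disease_class="carrier",
                                   control_class="non-carrier",
                                   set_scores=diff.set_scores)
        after = ad_joint_score(diff2, sets).table
        assert after.loc["g5", "score"] >= base.loc["g5", "score"]

    def test_uncovered_genes_get_neutral_rank(self):
        diff, sets = self._diff_with_sets()
        js = ad_joint_score(diff, sets)
        assert js.table.loc["g7", "gsa_rank"] == 0.5


# ---------------------------------------------------------------------------
# cluster features
# ---------------------------------------------------------------------------

class TestClusterFeatures:
    def _blocked(self, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 20
        base1 = rng.normal(0, 1, n_samples)
        base2 = rng.normal(0, 1, n_samples)
        block1 = base1 + rng.normal(0, 0.2, size=(10, n_samples))
        block2 = base2 + rng.normal(0, 0.2, size=(10, n_samples))
        noise = rng.normal(0, 1, size=(30, n_samples))
        values = np.vstack([block1, block2, noise])
        ids = ([f"b1_{i}" for i in range(10)] + [f"b2_{i}" for i in range(10)]
               + [f"n_{i}" for i in range(30)])
        return make_expression(values, gene_ids=ids)

    def test_recovers_planted_blocks(self):
        """Each planted co-expression block lands >=90% inside one cluster."""
        m = self._blocked()
        table = cluster_features(m, size_bounds=(5, 15))
        blocks_found = 0
        for prefix in ("b1_", "b2_"):
            expected = {g for g in m.gene_ids if g.startswith(prefix)}
            best = max(
                (len(members & expected) for members in table.provenance.values()),
                default=0,
            )
            blocks_found += best >= 0.9 * len(expected)
        assert blocks_found == 2

    def test_label_blind(self):
        m = self._blocked()
        a = cluster_features(m, size_bounds=(5, 15))
        perm = list(m.sample_ids[::-1])
        b = cluster_features(m.subset_samples(perm), size_bounds=(5, 15))
        assert set(map(frozenset, a.provenance.values())) == \
            set(map(frozenset, b.provenance.values()))

    def test_size_bounds_respected(self):
        m = self._blocked()
        table = cluster_features(m, size_bounds=(5, 15))
        for members in table.provenance.values():
            assert 5 <= len(members) <= 15


# ---------------------------------------------------------------------------
# Sturges binning
# ---------------------------------------------------------------------------

class TestSturgesFilter:
    def test_bin_width_example_n128(self):
        fwers = pd.Series(0.0, index=[f"f{i}" for i in range(128)])
        fwers["f0"], fwers["f1"] = 0.9, 0.85  # 8 bins of width 0.125
        kept = sturges_filter(fwers)
        assert "f0" not in kept and "f1" in kept

    def test_n5_worked_example(self):
        fwers = pd.Series([0.0, 0.2, 0.5, 0.9, 1.0],
                          index=list("abcde"))
        assert sturges_filter(fwers) == ["a", "b", "c"]  # k=4, cut 0.75

    def test_all_zero_all_retained(self):
        fwers = pd.Series(0.0, index=[f"f{i}" for i in range(10)])
        assert len(sturges_filter(fwers)) == 10

    def test_empty_input(self):
        assert sturges_filter(pd.Series(dtype=float)) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sturges_filter(pd.Series([0.5, 1.2]))
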