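"""Differential testing, signature scores, methylation summaries, pathways."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import transtype as tt
from transtype.dataio import GeneSignature, ValidationError
from transtype.signatures import EMT_EPITHELIAL, EMT_MESENCHYMAL

from conftest import make_matrix


def welch_oracle(x, y):
    """Direct-formula Welch t-test (statistic, two-sided p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestDifferentialFeatures:
    def _toy(self):
        # g1 separates subtype A from B; g2 is identical in and out
        vals = [
            [2.0, 2.0, 3.0, 0.0, 0.0, 1.0],
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        ]
        labels = {f"s{j + 1}": ("A" if j < 3 else "B") for j in range(6)}
        return make_matrix(vals, normalized=True), labels

    def test_welch_statistic_matches_direct_formula(self):
        m, labels = self._toy()
        res = tt.differential_features(m, labels, top_n=2)
        row = res.per_subtype["A"].set_index("feature").loc["g1"]
        t, p = welch_oracle([2, 2, 3], [0, 0, 1])
        assert row["t_statistic"] == pytest.approx(t, abs=1e-10)
        assert row["p_value"] == pytest.approx(p, abs=1e-10)
        assert row["mean_in"] == pytest.approx(7 / 3)
        assert row["mean_out"] == pytest.approx(1 / 3)

    def test_uninformative_feature_ranked_last(self):
        m, labels = self._toy()
        res = tt.differential_features(m, labels, top_n=2)
        table = res.per_subtype["A"]
        assert list(table["feature"]) == ["g1", "g2"]
        last = table.iloc[-1]
        assert last["t_statistic"] == 0.0 and last["p_value"] == 1.0

    def test_top_n_exceeding_feature_count(self):
        m, labels = self._toy()
        res = tt.differential_features(m, labels, top_n=50)
        assert all(len(t) == 2 for t in res.per_subtype.values())

    def test_sample_order_irrelevant(self):
        m, labels = self._toy()
        perm = ["s4", "s2", "s6", "s1", "s3", "s5"]
        m2 = m.replace_values(m.data[perm])
        a = tt.differential_features(m, labels, top_n=2)
        b = tt.differential_features(m2, labels, top_n=2)
        for st in a.per_subtype:
            pd.testing.assert_frame_equal(a.per_subtype[st], b.per_subtype[st])

    def test_degenerate_group_sizes_rejected(self):
        m, _ = self._toy()
        labels = {f"s{j + 1}": ("A" if j == 0 else "B") for j in range(6)}
        with pytest.raises(ValidationError, match="A"):
            tt.differential_features(m, labels)

    def test_null_min_p_consistent_with_uniformity(self):
        """Random labels: per-feature p-values are ~Uniform(0,1) (KS test)."""
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(200, 40)), normalized=True)
        labels = {f"s{j + 1}": ("A" if j < 20 else "B") for j in range(40)}
        res = tt.differential_features(m, labels, top_n=200)
        pvals = res.per_subtype["A"]["p_value"].to_numpy()
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_classifier_genes_enriched_for_planted_features(self, mrna_cohort):
        """Classifier genes hit planted subtype features >=5x over chance."""
        m, truth = mrna_cohort
        norm = tt.center_within_lineage(m)
        sub = pd.Series({s: truth.subtype[s] for s in m.sample_ids})
        res = tt.differential_features(norm, sub, top_n=50)
        planted = {m.feature_ids[i] for i in truth.subtype_features["mrna"]}
        hits = sum(g in planted for g in res.classifier_genes)
        n_genes = len(res.classifier_genes)
        expected = n_genes * len(planted) / m.n_features
        assert hits >= 5 * expected
        p = stats.hypergeom.sf(hits - 1, m.n_features, len(planted), n_genes)
        assert p < 1e-6


class TestMeanScore:
    def test_simple_mean(self):
        m = make_matrix([[1.0], [3.0]], normalized=True)
        sig = GeneSignature("S", ["g1", "g2"])
        sv = tt.mean_signature_score(m, sig)
        assert sv.values.iloc[0] == 2.0 and sv.coverage == 1.0

    def test_absent_gene_reduces_coverage(self):
        m = make_matrix([[1.0]], normalized=True)
        sv = tt.mean_signature_score(m, GeneSignature("S", ["g1", "missing"]))
        assert sv.values.iloc[0] == 1.0 and sv.coverage == 0.5

    def test_matches_direct_mean_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(30, 8))
        m = make_matrix(vals, normalized=True)
        genes = [f"g{i + 1}" for i in rng.choice(30, 10, replace=False)]
        sv = tt.mean_signature_score(m, GeneSignature("S", genes))
        idx = [int(g[1:]) - 1 for g in genes]
        np.testing.assert_allclose(sv.values.to_numpy(), vals[idx].mean(axis=0), atol=1e-12)

    def test_no_genes_present_rejected(self):
        m = make_matrix([[1.0]], normalized=True)
        with pytest.raises(ValidationError):
            tt.mean_signature_score(m, GeneSignature("S", ["zz"]))

    def test_gene_order_irrelevant(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(6, 4)), normalized=True)
        genes = [f"g{i + 1}" for i in range(6)]
        a = tt.mean_signature_score(m, GeneSignature("S", genes))
        b = tt.mean_signature_score(m, GeneSignature("S", genes[::-1]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestTScore:
    def _sig(self):
        return GeneSignature("S", ["u1", "u2", "u3"], ["d1", "d2", "d3"], mode="tscore")

    def test_matches_welch_oracle(self):
        vals = np.array([[1.0], [2.0], [3.0], [-1.0], [-2.0], [-3.0]])
        m = make_matrix(vals, features=["u1", "u2", "u3", "d1", "d2", "d3"],
                        normalized=True)
        sv = tt.t_score(m, self._sig())
        t, _ = welch_oracle([1, 2, 3], [-1, -2, -3])
        assert sv.values.iloc[0] == pytest.approx(t, abs=1e-10)
        assert sv.values.iloc[0] > 0

    def test_identical_groups_score_zero(self):
        vals = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        m = make_matrix(vals, features=["u1", "u2", "u3", "d1", "d2", "d3"],
                        normalized=True)
        sv = tt.t_score(m, self._sig())
        assert sv.values.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_lists_flips_sign(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 5))
        m = make_matrix(vals, features=["u1", "u2", "u3", "d1", "d2", "d3"],
                        normalized=True)
        fwd = tt.t_score(m, self._sig())
        rev = tt.t_score(
            m, GeneSignature("S", ["d1", "d2", "d3"], ["u1", "u2", "u3"], mode="tscore")
        )
        np.testing.assert_allclose(fwd.values, -rev.values, atol=1e-12)

    def test_degenerate_sample_scores_zero_with_warning(self):
        vals = np.ones((6, 1))
        m = make_matrix(vals, features=["u1", "u2", "u3", "d1", "d2", "d3"],
                        normalized=True)
        with pytest.warns(UserWarning, match="degenerate"):
            sv = tt.t_score(m, self._sig())
        assert sv.values.iloc[0] == 0.0


class TestEmtScore:
    def test_all_mesenchymal_one_epithelial_zero(self):
        genes = list(EMT_MESENCHYMAL) + list(EMT_EPITHELIAL)
        vals = np.array([[1.0]] * 14 + [[0.0]] * 3)
        m = make_matrix(vals, features=genes, normalized=True)
        sv = tt.emt_score(m)
        assert sv.values.iloc[0] == 14.0 and sv.coverage == 1.0

    def test_all_zero_gives_zero(self):
        genes = list(EMT_MESENCHYMAL) + list(EMT_EPITHELIAL)
        m = make_matrix(np.zeros((17, 2)), features=genes, normalized=True)
        assert (tt.emt_score(m).values == 0.0).all()

    def test_linearity_in_expression(self):
        rng = np.random.default_rng(4)
        genes = list(EMT_MESENCHYMAL) + list(EMT_EPITHELIAL)
        vals = rng.normal(size=(17, 5))
        m = make_matrix(vals, features=genes, normalized=True)
        m3 = make_matrix(3.0 * vals, features=genes, normalized=True)
        np.testing.assert_allclose(
            tt.emt_score(m3).values, 3.0 * tt.emt_score(m).values, atol=1e-10
        )


class TestSummaryScore:
    def test_identical_vectors_equal_normalized_form(self):
        v = pd.Series([1.0, 4.0, 2.0, 8.0], index=list("abcd"))
        out = tt.summary_score([v, v.copy(), v.copy()])
        expect = (v - v.median()) / v.std(ddof=1)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(20)]
        vs = [pd.Series(rng.normal(size=20), index=idx) for _ in range(4)]
        out = tt.summary_score(vs)
        expect = np.mean(
            [(v - v.median()) / v.std(ddof=1) for v in vs], axis=0
        )
        np.testing.assert_allclose(out.to_numpy(), expect, atol=1e-12)

    def test_constant_vector_contributes_zero(self):
        idx = list("abcd")
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        flat = pd.Series(7.0, index=idx)
        with pytest.warns(UserWarning, match="constant"):
            out = tt.summary_score([v, flat])
        expect = ((v - v.median()) / v.std(ddof=1)) / 2
        np.testing.assert_allclose(out, expect, atol=1e-12)


class TestMethylationSummaries:
    def test_index_counts_strictly_above_threshold(self):
        m = make_matrix([[0.1], [0.4], [0.5], [0.2]], platform="methylation")
        assert tt.methylation_index(m, 0.3).iloc[0] == 0.5

    def test_boundary_beta_not_counted(self):
        m = make_matrix([[0.3], [0.31]], platform="methylation")
        assert tt.methylation_index(m, 0.3).iloc[0] == 0.5

    def test_extremes(self):
        m0 = make_matrix(np.zeros((4, 1)), platform="methylation")
        m1 = make_matrix(np.ones((4, 1)), platform="methylation")
        assert tt.methylation_index(m0).iloc[0] == 0.0
        assert tt.methylation_index(m1).iloc[0] == 1.0

    def test_exact_fraction_over_observed_probes(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(size=(50, 10))
        vals[rng.random(size=vals.shape) < 0.2] = np.nan
        m = make_matrix(vals, platform="methylation")
        mi = tt.methylation_index(m, 0.3)
        for j, s in enumerate(m.sample_ids):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            assert mi[s] == np.sum(obs > 0.3) / len(obs)
            assert 0.0 <= mi[s] <= 1.0

    def test_silencing_call_inclusive_boundary(self):
        m = make_matrix([[0.2, 0.19, np.nan]], features=["cg1"],
                        platform="methylation")
        calls = tt.silencing_call(m, "cg1", 0.2)
        assert calls.iloc[0] == True  # noqa: E712 - nullable boolean
        assert calls.iloc[1] == False  # noqa: E712
        assert pd.isna(calls.iloc[2])


class TestReferenceSimilarity:
    def test_matching_profiles_give_large_positive_t(self):
        """A reference group matching a subtype scores a large positive t.

        Several reference groups are needed: the per-gene median centering is
        across *all* reference profiles, so a group's signature survives it
        only relative to the other groups.
        """
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        group_profiles = {f"grp{k}": rng.normal(0, 2, 40) for k in range(3)}
        ref_cols, ref_groups = {}, {}
        for g, mu in group_profiles.items():
            for i in range(5):
                name = f"{g}_r{i}"
                ref_cols[name] = mu + rng.normal(0, 0.2, 40)
                ref_groups[name] = g
        tum = np.column_stack(
            [group_profiles["grp0"] + rng.normal(0, 0.2, 40) for _ in range(5)]
        )
        tumor = make_matrix(tum, features=genes,
                            samples=[f"t{i}" for i in range(5)], normalized=True)
        ref_df = pd.DataFrame(ref_cols, index=genes)
        out = tt.reference_similarity(
            tumor, {f"t{i}": "sub1" for i in range(5)}, ref_df, ref_groups
        )
        assert out.loc["grp0", "sub1"] > 10
        assert out.loc["grp0", "sub1"] > out.loc["grp1", "sub1"]

    def test_single_pair_cell_is_missing(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10)]
        tumor = make_matrix(rng.normal(size=(10, 1)), features=genes,
                            samples=["t0"], normalized=True)
        ref_df = pd.DataFrame(rng.normal(size=(10, 1)), index=genes, columns=["r0"])
        out = tt.reference_similarity(tumor, {"t0": "s"}, ref_df, {"r0": "g"})
        assert np.isnan(out.loc["g", "s"])

    def test_null_profiles_rarely_exceed_t3(self):
        """Independent profiles: |t| > 3 in at most 2% of cells."""
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        n_cells = 0
        n_big = 0
        for rep in range(5):
            tum = rng.normal(size=(50, 40))
            ref = rng.normal(size=(50, 40))
            tumor = make_matrix(tum, features=genes,
                                samples=[f"t{i}" for i in range(40)], normalized=True)
            ref_df = pd.DataFrame(ref, index=genes, columns=[f"r{i}" for i in range(40)])
            out = tt.reference_similarity(
                tumor, {f"t{i}": f"sub{i % 10}" for i in range(40)},
                ref_df, {f"r{i}": f"grp{i % 10}" for i in range(40)},
            )
            vals = out.to_numpy().ravel()
            n_cells += len(vals)
            n_big += int((np.abs(vals) > 3).sum())
        assert n_big / n_cells <= 0.02


class TestPathwayAlterations:
    ROLES = {"TP53": "tumor_suppressor", "KRAS": "oncogene", "MET": "always_nonsilent"}

    def test_tumor_suppressor_nonsilent_alters_pathway(self):
        variants = pd.DataFrame({"sample": ["s1"], "gene": ["TP53"], "hotspot": [False]})
        altered, frac = tt.pathway_alteration_matrix(
            variants, None, {"p53": ["TP53"]}, self.ROLES, samples=["s1"]
        )
        assert altered.loc["p53", "s1"] and frac["p53"] == 1.0

    def test_oncogene_requires_hotspot_or_amplification(self):
        variants = pd.DataFrame({"sample": ["s1"], "gene": ["KRAS"], "hotspot": [False]})
        cn = make_matrix([[0.0]], platform="copynumber", features=["KRAS"], samples=["s1"],
                         lineage={"s1": "l"})
        altered, _ = tt.pathway_alteration_matrix(
            variants, cn, {"rtk": ["KRAS"]}, self.ROLES, samples=["s1"]
        )
        assert not altered.loc["rtk", "s1"]
        cn2 = make_matrix([[2.0]], platform="copynumber", features=["KRAS"], samples=["s1"],
                          lineage={"s1": "l"})
        altered2, _ = tt.pathway_alteration_matrix(
            variants, cn2, {"rtk": ["KRAS"]}, self.ROLES, samples=["s1"]
        )
        assert altered2.loc["rtk", "s1"]

    def test_toy_cohort_matches_hand_count(self):
        samples = [f"s{i}" for i in range(1, 11)]
        variants = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s3", "s4", "s5"],
                "gene": ["TP53", "KRAS", "KRAS", "MET", "MET", "TP53"],
                "hotspot": [False, True, False, False, False, False],
                "silent": [False, False, False, False, False, True],
            }
        )
        cn_vals = np.zeros((2, 10))
        cn_vals[0, 5] = -2.0  # TP53 deep loss in s6
        cn_vals[1, 6] = 2.0   # KRAS amplification in s7
        cn = make_matrix(cn_vals, platform="copynumber", features=["TP53", "KRAS"],
                         samples=samples, lineage={s: "l" for s in samples})
        pathways = {"p53": ["TP53"], "rtk": ["KRAS", "MET"]}
        altered, frac = tt.pathway_alteration_matrix(
            variants, cn, pathways, self.ROLES, samples=samples
        )
        # hand count: p53 altered in s1 (nonsilent), s6 (deep loss); s5 silent
        assert sorted(altered.columns[altered.loc["p53"]]) == ["s1", "s6"]
        # rtk: s2 (KRAS hotspot), s3 (MET nonsilent; KRAS non-hotspot ignored),
        # s4 (MET), s7 (KRAS amp)
        assert sorted(altered.columns[altered.loc["rtk"]]) == ["s2", "s3", "s4", "s7"]
        assert frac["p53"] == 0.2 and frac["rtk"] == 0.4

    def test_gene_without_role_rejected(self):
        variants = pd.DataFrame({"sample": ["s1"], "gene": ["X"], "hotspot": [False]})
        with pytest.raises(ValidationError, match="role"):
            tt.pathway_alteration_matrix(variants, None, {"p": ["X"]}, {}, samples=["s1"])
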