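import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awmnet.awm import (Awm, SelectionRule, assign_genes, build_awm, cluster_traits,
                        dedupe_by_window, select_snps, zscore_effects)
from awmnet.simulate import TRAITS, GROWTH_TRAITS, FAT_TRAITS, simulate_cross
from awmnet.gwas import default_scheme, snp_association_scan
from awmnet.kinship import numerator_relationship_matrix

from awm_fixture import build_fixture, TRAITS4
from conftest import small_sim_config


class TestZscore:
    def test_simple_column(self):
        z = zscore_effects(pd.DataFrame({"t": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["t"], [-1, 0, 1])

    def test_postcondition_mean_zero_sd_one(self, rng):
        z = zscore_effects(pd.DataFrame(rng.normal(2, 7, size=(100, 12))))
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_matches_two_pass_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 12)))
        z = zscore_effects(X)
        for c in X.columns:
            x = X[c].to_numpy()
            mu = x.sum() / len(x)
            sd = np.sqrt(((x - mu) ** 2).sum() / (len(x) - 1))
            np.testing.assert_allclose(z[c], (x - mu) / sd, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_effects(pd.DataFrame({"t": [1.0, 1.0, 1.0]}))


class TestSelect:
    def p(self, **cols):
        base = {"HW": 0.5, "A": 0.5, "B": 0.5, "C": 0.5}
        base.update(cols)
        return pd.DataFrame(base, index=["snp"])

    def test_key_trait_branch(self):
        sel = select_snps(self.p(HW=0.03), SelectionRule())
        assert list(sel.index) == ["snp"]

    def test_three_trait_branch(self):
        sel = select_snps(self.p(HW=0.2, A=0.01, B=0.01, C=0.01), SelectionRule())
        assert sel.loc["snp", "n_traits_associated"] == 3

    def test_two_traits_not_enough(self):
        sel = select_snps(self.p(HW=0.2, A=0.01, B=0.01), SelectionRule())
        assert sel.empty

    def test_missing_key_trait_raises(self):
        with pytest.raises(ValueError, match="key trait"):
            select_snps(self.p().drop(columns=["HW"]), SelectionRule())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=48, max_size=48),
           st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_selection_monotone_in_alpha(self, vals, a1, a2):
        p = pd.DataFrame(np.array(vals).reshape(12, 4), columns=["HW", "A", "B", "C"])
        lo, hi = sorted([a1, a2])
        n_lo = len(select_snps(p, SelectionRule(alpha=lo)))
        n_hi = len(select_snps(p, SelectionRule(alpha=hi)))
        assert n_lo <= n_hi


class TestAssignDedupe:
    def test_fixture_assignment_branches(self):
        snp_map, annotation, p, _, _, _ = build_fixture()
        rule = SelectionRule(key_trait="K")
        assigned = assign_genes(snp_map["snp_id"], snp_map, annotation, rule)
        by = assigned.set_index("snp_id")
        assert by.loc["S01", "feature_id"] == "GA" and by.loc["S01", "distance"] == 0
        assert by.loc["S02", "feature_id"] == "GA" and by.loc["S02", "distance"] == 1000
        assert "S03" not in by.index  # intermediate distance -> discarded
        assert by.loc["S05", "kind"] == "miRNA" and by.loc["S05", "feature_id"] == "M1"
        assert by.loc["S06", "kind"] == "desert" and by.loc["S06", "feature_id"] == "S06"
        assert "S12" not in by.index

    def test_intermediate_snps_kept_when_policy_flipped(self):
        snp_map, annotation, p, _, _, _ = build_fixture()
        rule = SelectionRule(key_trait="K", drop_intermediate=False)
        assigned = assign_genes(["S03", "S12"], snp_map, annotation, rule)
        assert assigned.set_index("snp_id").loc["S03", "feature_id"] == "GB"

    def test_window_cluster_keeps_most_associated(self):
        rule = SelectionRule(key_trait="K")
        assigned = pd.DataFrame({
            "snp_id": ["a", "b"], "feature_id": ["a", "b"], "kind": ["desert"] * 2,
            "chrom": [1, 1], "bp": [1_000_000, 1_600_000], "distance": [0.0, 0.0]})
        sel = pd.DataFrame({"n_traits_associated": [5, 3], "key_p": [0.01, 0.01]},
                           index=pd.Index(["a", "b"], name="snp_id"))
        out = dedupe_by_window(assigned, sel, rule)
        assert list(out["snp_id"]) == ["a"]

    def test_snps_beyond_window_both_kept(self):
        rule = SelectionRule(key_trait="K")
        assigned = pd.DataFrame({
            "snp_id": ["a", "b"], "feature_id": ["a", "b"], "kind": ["desert"] * 2,
            "chrom": [1, 1], "bp": [1_000_000, 2_200_000], "distance": [0.0, 0.0]})
        sel = pd.DataFrame({"n_traits_associated": [5, 3], "key_p": [0.01, 0.01]},
                           index=pd.Index(["a", "b"], name="snp_id"))
        assert len(dedupe_by_window(assigned, sel, rule)) == 2

    def test_random_positions_match_bruteforce_oracle(self, rng):
        rule = SelectionRule(key_trait="K")
        n = 60
        bp = np.sort(rng.integers(0, 30_000_000, n))
        ids = [f"x{i}" for i in range(n)]
        assigned = pd.DataFrame({"snp_id": ids, "feature_id": ids, "kind": ["desert"] * n,
                                 "chrom": 1, "bp": bp, "distance": 0.0})
        nt = rng.integers(1, 8, n)
        kp = rng.uniform(0.001, 0.05, n)
        sel = pd.DataFrame({"n_traits_associated": nt, "key_p": kp},
                           index=pd.Index(ids, name="snp_id"))
        out = dedupe_by_window(assigned, sel, rule)

        # oracle: explicit single-linkage clustering then argmax
        clusters, cur = [], [0]
        for i in range(1, n):
            if bp[i] - bp[i - 1] < 1_000_000:
                cur.append(i)
            else:
                clusters.append(cur)
                cur = [i]
        clusters.append(cur)
        expect = []
        for cl in clusters:
            best = min(cl, key=lambda i: (-nt[i], kp[i], bp[i]))
            expect.append(ids[best])
        assert list(out["snp_id"]) == expect


class TestBuildAwm:
    def test_twenty_snp_fixture_matches_manual_enumeration(self):
        snp_map, annotation, p, effects, expected, selected = build_fixture()
        rule = SelectionRule(key_trait="K")
        sel = select_snps(p, rule)
        assert set(sel.index) == selected
        z = zscore_effects(effects)
        awm = build_awm(z, p, snp_map, annotation, rule)
        got = dict(zip(awm.provenance["feature_id"], awm.provenance["snp_id"]))
        assert got == expected
        # each row's values are the z-scores of its representative SNP
        for feat, sid in expected.items():
            np.testing.assert_array_equal(awm.values.loc[feat], z.loc[sid])

    def test_alpha_one_selects_every_snp(self):
        snp_map, annotation, p, effects, _, _ = build_fixture()
        sel = select_snps(p, SelectionRule(key_trait="K", alpha=1.0))
        assert len(sel) == len(p)

    def test_provenance_snps_all_pass_selection(self):
        snp_map, annotation, p, effects, _, _ = build_fixture()
        rule = SelectionRule(key_trait="K")
        awm = build_awm(zscore_effects(effects), p, snp_map, annotation, rule)
        sel = set(select_snps(p, rule).index)
        assert set(awm.provenance["snp_id"]) <= sel

    def test_snp_order_permutation_gives_identical_rows(self, rng):
        snp_map, annotation, p, effects, _, _ = build_fixture()
        rule = SelectionRule(key_trait="K")
        a1 = build_awm(zscore_effects(effects), p, snp_map, annotation, rule)
        perm = rng.permutation(len(p))
        a2 = build_awm(zscore_effects(effects.iloc[perm]), p.iloc[perm],
                       snp_map, annotation, rule)
        pd.testing.assert_frame_equal(a1.values, a2.values)

    def test_planted_qtl_genes_recovered(self):
        """Strong planted effects: >=90% of QTL genes appear as AWM rows."""
        st = simulate_cross(small_sim_config(
            seed=31, qtl_effect_sd=0.8, heritability_per_trait=0.6,
            generation_sizes={"f1": 12, "f2": 20, "bc1": 120, "bc": 40, "f3": 30}))
        cohort = st.phenotypes[st.phenotypes["phenotyped"]]
        geno = st.geno.subset(ind_mask=np.isin(st.geno.individual_ids,
                                               cohort["individual_id"]))
        A = numerator_relationship_matrix(st.pedigree)
        res = snp_association_scan(geno, cohort, default_scheme(), A)
        ok = res.effects.notna().all(axis=1)
        awm = build_awm(zscore_effects(res.effects.loc[ok]), res.pvalues.loc[ok],
                        st.snp_map, st.annotation.features, SelectionRule())
        planted = set(st.architecture.qtl_gene_ids.values())
        hit = planted & set(awm.feature_ids)
        assert len(hit) / len(planted) >= 0.9


class TestClusterTraits:
    def make_awm(self, values, traits):
        v = pd.DataFrame(values, columns=traits)
        v.index = [f"g{i}" for i in range(len(v))]
        prov = pd.DataFrame({"feature_id": v.index})
        return Awm(values=v, provenance=prov)

    def test_identical_columns_merge_at_zero_height(self, rng):
        x = rng.normal(size=20)
        awm = self.make_awm(np.column_stack([x, x, rng.normal(size=20)]),
                            ["a", "b", "c"])
        res = cluster_traits(awm)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.labels["a"] == res.labels["b"]

    def test_two_columns_single_merge(self, rng):
        awm = self.make_awm(rng.normal(size=(10, 2)), ["a", "b"])
        res = cluster_traits(awm)
        assert res.linkage.shape == (1, 4)

    def test_opposite_sign_blocks_recovered(self, rng):
        v = rng.choice([-1.0, 1.0], size=40)[:, None] * np.ones((40, 12))
        v[:, [TRAITS.index(t) for t in FAT_TRAITS]] *= -1
        v += rng.normal(0, 0.3, v.shape)
        res = cluster_traits(self.make_awm(v, TRAITS))
        part = res.partition()
        assert frozenset(GROWTH_TRAITS) in part and frozenset(FAT_TRAITS) in part

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_traits(self.make_awm(rng.normal(size=(5, 1)), ["a"]))
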