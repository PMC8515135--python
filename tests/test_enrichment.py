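import math

import numpy as np
import pandas as pd
import pytest

import transcompr as tc
from transcompr.enrichment import tail_genes

from conftest import make_study


def hypergeom_upper_tail_oracle(overlap, model_size, set_in_model, tail_size):
    """P(X >= overlap) by direct enumeration of the hypergeometric pmf."""
    total = 0
    hi = min(set_in_model, tail_size)
    for j in range(overlap, hi + 1):
        total += (
            math.comb(set_in_model, j)
            * math.comb(model_size - set_in_model, tail_size - j)
        )
    return total / math.comb(model_size, tail_size)


def fake_model(loadings_by_gene: dict[str, float]) -> tc.PCAModel:
    genes = pd.Index(list(loadings_by_gene))
    col = np.array([loadings_by_gene[g] for g in genes], dtype=float)
    return tc.PCAModel(
        gene_order=genes,
        loadings=col[:, None],
        explained_fraction=np.array([1.0]),
        full_fractions=np.array([1.0]),
        sample_scores=pd.DataFrame({"PC1": [0.0, 0.0, 0.0]}, index=["s0", "s1", "s2"]),
    )


class TestOraTails:
    def test_known_hypergeometric_example(self):
        # 10 model genes, set of 4, top tail of 2 fully inside the set
        model = fake_model({f"g{i}": 10.0 - i for i in range(10)})
        sets = tc.GeneSetCollection(sets={"S": frozenset(["g0", "g1", "g5", "g6"])})
        res = tc.ora_tails(model, "PC1", sets, tail_frac=0.2)
        top = res[(res["tail"] == "top") & (res["set"] == "S")].iloc[0]
        assert top["overlap"] == 2
        assert top["p"] == pytest.approx(6 / 45, abs=1e-12)

    def test_set_identical_to_tail_gets_minimal_p(self):
        g = 10
        model = fake_model({f"g{i}": float(g - i) for i in range(g)})
        tail = [f"g{i}" for i in range(2)]
        sets = tc.GeneSetCollection(sets={"S": frozenset(tail)})
        res = tc.ora_tails(model, "PC1", sets, tail_frac=0.2)
        top = res[(res["tail"] == "top") & (res["set"] == "S")].iloc[0]
        assert top["p"] == pytest.approx(1 / math.comb(g, 2), abs=1e-12)
        assert top["fdr"] <= top["p"] * len(sets.sets) + 1e-12

    def test_exhaustive_grid_matches_enumeration_oracle(self):
        # all feasible (set size, overlap) layouts for a 12-gene model, tail 3
        g, t = 12, 3
        model = fake_model({f"g{i:02d}": float(g - i) for i in range(g)})
        top_tail = [f"g{i:02d}" for i in range(t)]
        rest = [f"g{i:02d}" for i in range(t, g)]
        sets, expected = {}, {}
        for set_size in range(1, g + 1):
            for k in range(max(0, set_size - (g - t)), min(set_size, t) + 1):
                name = f"K{set_size}_k{k}"
                sets[name] = frozenset(top_tail[:k] + rest[: set_size - k])
                expected[name] = hypergeom_upper_tail_oracle(k, g, set_size, t)
        res = tc.ora_tails(
            model, "PC1", tc.GeneSetCollection(sets=sets), tail_frac=t / g
        )
        top = res[res["tail"] == "top"].set_index("set")
        for name, exp in expected.items():
            assert top.loc[name, "p"] == pytest.approx(exp, abs=1e-10), name

    def test_invariant_to_gene_order_permutation(self, rng):
        genes = [f"g{i}" for i in range(30)]
        load = dict(zip(genes, rng.normal(size=30)))
        sets = tc.GeneSetCollection(
            sets={"S1": frozenset(genes[:7]), "S2": frozenset(genes[10:18])}
        )
        res1 = tc.ora_tails(fake_model(load), "PC1", sets)
        shuffled = {g: load[g] for g in rng.permutation(genes)}
        res2 = tc.ora_tails(fake_model(shuffled), "PC1", sets)
        for tail in ("top", "bottom"):
            a = res1[res1["tail"] == tail].set_index("set")["p"]
            b = res2[res2["tail"] == tail].set_index("set")["p"]
            assert np.allclose(a.sort_index(), b.sort_index())

    def test_bh_adjustment_monotone_within_family(self, rng):
        genes = [f"g{i}" for i in range(40)]
        load = dict(zip(genes, rng.normal(size=40)))
        sets = {
            f"S{j}": frozenset(rng.choice(genes, size=8, replace=False))
            for j in range(12)
        }
        res = tc.ora_tails(fake_model(load), "PC1", tc.GeneSetCollection(sets=sets))
        for tail in ("top", "bottom"):
            fam = res[res["tail"] == tail].sort_values("p")
            assert (fam["fdr"] >= fam["p"] - 1e-15).all()
            assert fam["fdr"].is_monotonic_increasing

    def test_tail_boundary_ties_break_by_gene_id(self):
        load = {"b": 1.0, "a": 1.0, "c": 1.0, "d": 0.0, "e": -1.0}
        top, bottom = tail_genes(pd.Series(load), tail_frac=0.4)
        assert top == ["a", "b"]
        assert bottom == ["e", "d"]

    def test_contributing_genes_subset_of_tail_and_set(self, rng):
        genes = [f"g{i}" for i in range(25)]
        load = dict(zip(genes, rng.normal(size=25)))
        members = frozenset(genes[::3])
        sets = tc.GeneSetCollection(sets={"S": members})
        res = tc.ora_tails(fake_model(load), "PC1", sets)
        top, bottom = tail_genes(pd.Series(load), 0.2)
        tails = {"top": set(top), "bottom": set(bottom)}
        for _, row in res.iterrows():
            assert set(row["genes"]) <= tails[row["tail"]] & members
            assert row["overlap"] == len(row["genes"])
            assert row["overlap"] <= min(row["tail_size"], row["set_in_model"])


def mouse_study(rng, n_genes=10, per_group=6, shift=None):
    labels = ["WT"] * per_group + ["HET"] * per_group + ["HO"] * per_group
    vals = rng.normal(size=(n_genes, 3 * per_group))
    if shift is not None:
        gene, group, amount = shift
        start = {"WT": 0, "HET": per_group, "HO": 2 * per_group}[group]
        vals[gene, start: start + per_group] += amount
    return make_study(pd.DataFrame(vals), species="mouse", labels=labels)


class TestGeneLevelTests:
    def test_pooled_t_matches_hand_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])  # WT
        y = np.array([3.0, 4.0, 5.0, 6.0])  # HO
        vals = np.zeros((1, 12))
        vals[0, :4] = x
        vals[0, 8:] = y
        vals[0, 4:8] = [0.0, 1.0, 2.0, 3.0]  # HET
        study = make_study(
            pd.DataFrame(vals), species="mouse", labels=["WT"] * 4 + ["HET"] * 4 + ["HO"] * 4
        )
        table = tc.gene_level_tests(study)
        sp = math.sqrt((3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6)
        t_hand = (y.mean() - x.mean()) / (sp * math.sqrt(1 / 4 + 1 / 4))
        assert table["t_ho_vs_wt"].iloc[0] == pytest.approx(t_hand, abs=1e-12)

    def test_identical_distributions_not_significant(self, rng):
        study = mouse_study(rng)
        table = tc.gene_level_tests(study)
        assert not table["significant"].iloc[0]

    def test_planted_ho_shift_detected_het_not(self):
        # power of the pooled t + BH pair on a 2-sd shift at n=6/group is
        # ~0.72 (measured over 300 simulations); 20/40 is a safe floor
        hits = 0
        for seed in range(40):
            local = np.random.default_rng(3000 + seed)
            study = mouse_study(local, shift=(0, "HO", 2.0))
            table = tc.gene_level_tests(study, genes=["g0"])
            ok = (
                table["q_ho_vs_wt"].iloc[0] < 0.05
                and table["q_het_vs_wt"].iloc[0] >= 0.05
            )
            hits += ok
        assert hits >= 20

    def test_small_group_rejected(self, rng):
        study = make_study(
            pd.DataFrame(rng.normal(size=(3, 5))),
            species="mouse",
            labels=["WT", "WT", "HET", "HET", "HO"],
        )
        with pytest.raises(ValueError, match="HO"):
            tc.gene_level_tests(study)

    def test_significance_flag_is_min_q_rule(self, rng):
        study = mouse_study(rng, shift=(2, "HO", 3.0))
        table = tc.gene_level_tests(study)
        expected = np.minimum(table["q_het_vs_wt"], table["q_ho_vs_wt"]) < 0.05
        assert (table["significant"] == expected).all()


class TestSecretedFilter:
    @staticmethod
    def _annot(flags):
        return tc.AnnotationTable(
            pd.DataFrame({"secreted": pd.Series(flags)}, dtype=bool)
        )

    def test_keeps_secreted_significant_genes(self, rng):
        study = mouse_study(rng, n_genes=3)
        table = tc.gene_level_tests(study)
        table["significant"] = [True, True, True]
        annot = self._annot({"g0": True, "g1": False, "g2": True})
        assert tc.secreted_filter(table, annot) == ["g0", "g2"]

    def test_empty_significant_set_gives_empty_list(self, rng):
        study = mouse_study(rng, n_genes=3)
        table = tc.gene_level_tests(study)
        table["significant"] = False
        annot = self._annot({"g0": True, "g1": True, "g2": True})
        assert tc.secreted_filter(table, annot) == []

    def test_uncovered_genes_excluded(self, rng):
        study = mouse_study(rng, n_genes=3)
        table = tc.gene_level_tests(study)
        table["significant"] = True
        annot = self._annot({"g0": True})
        assert tc.secreted_filter(table, annot) == ["g0"]
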