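import math

import numpy as np
import pandas as pd
import pytest

from ppinet.genomic import (
    ForeignInteractionSet,
    FusionHitSet,
    GoAnnotationSet,
    OrthologMap,
    assemble_genomic_features,
    coexpression_pcc,
    gene_fusion_flag,
    go_similarity,
    interolog_support,
    phylo_profile_similarity,
    rpkm,
)


def expr_from_values(values: dict[str, list[float]], length=1000.0, depth=1e6):
    """Expression matrix whose RPKM equals the given values exactly."""
    counts = pd.DataFrame(
        {f"S{i}": {g: v[i] * length * depth / 1e9 for g, v in values.items()}
         for i in range(len(next(iter(values.values()))))}
    )
    lengths = pd.Series(length, index=counts.index)
    totals = pd.Series(depth, index=counts.columns)
    return rpkm(counts, lengths, totals)


class TestRpkm:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame({"S1": {"G1": 10}})
        out = rpkm(counts, pd.Series({"G1": 1000.0}), pd.Series({"S1": 1e6}))
        assert out.rpkm.loc["G1", "S1"] == pytest.approx(10.0)

    def test_zero_counts_zero_rpkm(self):
        counts = pd.DataFrame({"S1": {"G1": 0}})
        out = rpkm(counts, pd.Series({"G1": 500.0}), pd.Series({"S1": 1e6}))
        assert out.rpkm.loc["G1", "S1"] == 0.0

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(5, 4)),
            index=[f"G{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(4)],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=5).astype(float), index=counts.index)
        totals = pd.Series(rng.integers(10**6, 10**7, size=4).astype(float), index=counts.columns)
        out = rpkm(counts, lengths, totals)
        for g in counts.index:
            for s in counts.columns:
                expected = 1e9 * counts.loc[g, s] / (totals[s] * lengths[g])
                assert out.rpkm.loc[g, s] == pytest.approx(expected)

    def test_zero_length_or_total_rejected(self):
        counts = pd.DataFrame({"S1": {"G1": 5}})
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series({"G1": 0.0}), pd.Series({"S1": 1e6}))
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series({"G1": 100.0}), pd.Series({"S1": 0.0}))


class TestCoexpression:
    def test_proportional_profiles_in_log_space(self):
        # B's log2(RPKM+1) profile is a positive affine image of A's
        a = np.array([1.0, 3.0, 7.0, 15.0, 31.0])
        b = (a + 1.0) ** 2 - 1.0  # log2(b+1) = 2*log2(a+1)
        expr = expr_from_values({"A": list(a), "B": list(b)})
        assert coexpression_pcc(expr, ("A", "B")) == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        a = np.array([1.0, 3.0, 7.0, 15.0, 31.0])
        b = (2.0 ** (6.0 - np.log2(a + 1.0))) - 1.0  # log profiles sum to 6
        expr = expr_from_values({"A": list(a), "B": list(b)})
        assert coexpression_pcc(expr, ("A", "B")) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 100, size=20)
        b = rng.uniform(0, 100, size=20)
        expr = expr_from_values({"A": list(a), "B": list(b)})
        la, lb = np.log2(a + 1), np.log2(b + 1)
        cov = np.mean((la - la.mean()) * (lb - lb.mean()))
        oracle = cov / (la.std() * lb.std())
        assert coexpression_pcc(expr, ("A", "B")) == pytest.approx(oracle, abs=1e-12)

    def test_missing_cases(self):
        a = [1.0, 2.0, 3.0]
        expr = expr_from_values({"A": a, "B": [5.0, 5.0, 5.0]})
        assert math.isnan(coexpression_pcc(expr, ("A", "Z")))
        assert math.isnan(coexpression_pcc(expr, ("A", "B")))  # constant profile


def toy_annotations(gene_terms: dict[str, set[str]], parents: dict[str, set[str]], N: int):
    return GoAnnotationSet(direct={"BP": gene_terms}, parents=parents, genome_size=N)


class TestGoSimilarity:
    parents = {
        "root": set(),
        "mid50": {"root"},
        "mid8": {"mid50"},
        "leaf2": {"mid8"},
    }

    def test_upper_bound_when_class_holds_exactly_the_pair(self):
        genes = {"A": {"leaf2"}, "B": {"leaf2"}}
        # pad the annotation so term counts reflect the DAG: only A and B in leaf2
        annot = toy_annotations(genes, self.parents, N=100)
        assert go_similarity(annot, ("A", "B"), "BP") == pytest.approx(1.0)

    def test_zero_at_root(self):
        genes = {f"G{i}": {"root"} for i in range(10)}
        annot = toy_annotations(genes, self.parents, N=10)
        assert go_similarity(annot, ("G0", "G1"), "BP") == 0.0

    def test_lowest_common_class_vs_exhaustive_oracle(self):
        """Common classes with counts {50, 8}: n must be 8, matching an
        exhaustive scan over every common ancestor."""
        genes = {"A": {"leaf2"}, "B": {"mid8"}}
        for i in range(6):
            genes[f"M{i}"] = {"mid8"}  # mid8 closure count = 8
        for i in range(42):
            genes[f"F{i}"] = {"mid50"}  # mid50 closure count = 50
        annot = toy_annotations(genes, self.parents, N=100)
        counts = annot.term_counts("BP")
        assert counts["mid8"] == 8 and counts["mid50"] == 50
        common = annot.closed_terms("BP")["A"] & annot.closed_terms("BP")["B"]
        oracle_n = min(counts[t] for t in common)  # exhaustive ancestor scan
        assert oracle_n == 8
        expected = math.log(8 / 100) / math.log(2 / 100)
        assert go_similarity(annot, ("A", "B"), "BP") == pytest.approx(expected)

    def test_missing_when_unannotated_or_disjoint(self):
        parents = {"r1": set(), "r2": set(), "a": {"r1"}, "b": {"r2"}}
        annot = toy_annotations({"A": {"a"}, "B": {"b"}}, parents, N=10)
        assert math.isnan(go_similarity(annot, ("A", "Z"), "BP"))
        assert math.isnan(go_similarity(annot, ("A", "B"), "BP"))  # no common ancestor

    def test_strict_monotonicity_in_n(self):
        N = 500
        values = [
            math.log(n / N) / math.log(2 / N) for n in range(2, N + 1)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestPhyloProfiles:
    def test_identical_profiles(self):
        profiles = pd.DataFrame([[1, 0, 1, 0], [1, 0, 1, 0]], index=["A", "B"])
        assert phylo_profile_similarity(profiles, ("A", "B")) == pytest.approx(1.0)

    def test_complementary_profiles(self):
        profiles = pd.DataFrame([[1, 0, 1, 0], [0, 1, 0, 1]], index=["A", "B"])
        assert phylo_profile_similarity(profiles, ("A", "B")) == pytest.approx(-1.0)

    def test_matches_phi_coefficient(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, size=30)
        b = rng.integers(0, 2, size=30)
        profiles = pd.DataFrame([a, b], index=["A", "B"])
        n11 = int(((a == 1) & (b == 1)).sum())
        n10 = int(((a == 1) & (b == 0)).sum())
        n01 = int(((a == 0) & (b == 1)).sum())
        n00 = int(((a == 0) & (b == 0)).sum())
        phi = (n11 * n00 - n10 * n01) / math.sqrt(
            (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        )
        assert phylo_profile_similarity(profiles, ("A", "B")) == pytest.approx(phi, abs=1e-12)

    def test_constant_profile_missing(self):
        profiles = pd.DataFrame([[1, 1, 1], [1, 0, 1]], index=["A", "B"])
        assert math.isnan(phylo_profile_similarity(profiles, ("A", "B")))


class TestInterolog:
    def make(self, support_orgs):
        groups = {org: {"A": f"{org}_1", "B": f"{org}_2"} for org in support_orgs}
        groups.setdefault("human", {}).setdefault("A", "human_1")  # ortholog, no partner
        foreign = {org: {(f"{org}_1", f"{org}_2")} for org in support_orgs}
        return OrthologMap(groups=groups), ForeignInteractionSet(interactions=foreign)

    def test_single_organism(self):
        orth, foreign = self.make(["yeast"])
        assert interolog_support(orth, foreign, ("A", "B")) == 1

    def test_orthologs_without_interaction(self):
        orth = OrthologMap(groups={"human": {"A": "h1", "B": "h2"}})
        foreign = ForeignInteractionSet(interactions={"human": {("h3", "h4")}})
        assert interolog_support(orth, foreign, ("A", "B")) == 0

    def test_planted_three_organisms_vs_scan(self):
        orgs = ["yeast", "human", "fly"]
        orth, foreign = self.make(orgs)
        oracle = 0
        for org in ("ecoli", "yeast", "worm", "fly", "mouse", "human"):
            ga = orth.groups.get(org, {}).get("A")
            gb = orth.groups.get(org, {}).get("B")
            if ga and gb:
                key = tuple(sorted((ga, gb)))
                if key in foreign.interactions.get(org, set()):
                    oracle += 1
        assert oracle == 3
        assert interolog_support(orth, foreign, ("A", "B")) == oracle


class TestGeneFusion:
    def test_disjoint_hits_flag(self):
        fusions = FusionHitSet(hits={"F1": {"A": [(1, 100, 1e-9)], "B": [(120, 250, 1e-9)]}})
        assert gene_fusion_flag(fusions, ("A", "B")) == 1

    def test_same_segment_no_flag(self):
        fusions = FusionHitSet(hits={"F1": {"A": [(1, 100, 1e-9)], "B": [(1, 100, 1e-9)]}})
        assert gene_fusion_flag(fusions, ("A", "B")) == 0

    def test_insignificant_hits_ignored(self):
        fusions = FusionHitSet(hits={"F1": {"A": [(1, 100, 0.1)], "B": [(200, 300, 1e-9)]}})
        assert gene_fusion_flag(fusions, ("A", "B")) == 0

    def test_randomized_intervals_vs_brute_force(self):
        rng = np.random.default_rng(11)
        for trial in range(50):
            sa, sb = rng.integers(1, 300, size=2)
            ia = (int(sa), int(sa + rng.integers(10, 150)))
            ib = (int(sb), int(sb + rng.integers(10, 150)))
            fusions = FusionHitSet(
                hits={"F": {"A": [(*ia, 1e-9)], "B": [(*ib, 1e-9)]}}
            )
            overlap = max(0, min(ia[1], ib[1]) - max(ia[0], ib[0]) + 1)
            shorter = min(ia[1] - ia[0] + 1, ib[1] - ib[0] + 1)
            expected = 1 if overlap < 0.10 * shorter else 0
            assert gene_fusion_flag(fusions, ("A", "B")) == expected


class TestAssembly:
    def test_uncovered_pair_all_missing(self):
        out = assemble_genomic_features(("A", "B"))
        assert all(math.isnan(v) for v in out.values())

    def test_composition_matches_individual_ops(self, bundle, feature_table):
        """The vectorised bundle assembly equals calling each feature op."""
        for pair in bundle.planted_pairs[:10]:
            row = feature_table.loc[pair]
            single = assemble_genomic_features(
                pair,
                expr=bundle.expression,
                annot=bundle.annotations,
                profiles=bundle.profiles,
                orthologs=bundle.orthologs,
                foreign=bundle.foreign,
                fusions=bundle.fusions,
            )
            for name, value in single.items():
                if math.isnan(value):
                    assert math.isnan(row[name])
                else:
                    assert row[name] == pytest.approx(value, abs=1e-9), name

    def test_fully_covered_pair_has_no_missing_genomic(self, bundle, feature_table):
        genomic_cols = [
            "coexpression_pcc", "go_bp_sim", "go_mf_sim", "go_cc_sim",
            "phylo_profile_sim", "interolog_support", "gene_fusion",
        ]
        covered = feature_table[genomic_cols].notna().all(axis=1)
        assert covered.mean() > 0.9
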