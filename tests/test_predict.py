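from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import mann_whitney_exact_p
from suppnet import (
    BackgroundPairSet,
    GeneSetCollection,
    MutationMatrix,
    build_features,
    build_standard,
    evaluate_ranks,
    prioritize,
    priority_score,
    train_classifier,
)
from suppnet.predict import compare_rank_lists


def coll(**sets):
    return GeneSetCollection("x", {k: frozenset(v) for k, v in sets.items()})


def make_standards(
    complex_pairs=(), pathway_pairs=(), expression_pairs=(), localization_pairs=()
):
    """Standards relating exactly the given (query, gene) pairs."""
    out = {}
    for name, kind, pairs in (
        ("co_complex", "co_complex", complex_pairs),
        ("co_pathway", "co_pathway", pathway_pairs),
        ("co_expression", "co_expression", expression_pairs),
        ("co_localization", "co_localization", localization_pairs),
    ):
        sets = {f"S{i}": frozenset(p) for i, p in enumerate(pairs)}
        out[name] = build_standard(GeneSetCollection(name, sets), kind)
    return out


class TestPriorityScore:
    def test_score_table_matches_lexicographic_order_exhaustively(self):
        combos = list(itertools.product([0, 1], repeat=4))
        scores = {c: priority_score(c) for c in combos}
        assert len(set(scores.values())) == 16
        assert min(scores.values()) == 0 and max(scores.values()) == 1111
        for c1, c2 in itertools.combinations(combos, 2):
            # numeric score order must equal lexicographic indicator order
            assert (scores[c1] > scores[c2]) == (c1 > c2)

    def test_specific_encodings(self):
        assert priority_score((1, 1, 1, 1)) == 1111
        assert priority_score((0, 0, 0, 0)) == 0
        assert priority_score((0, 1, 0, 1)) == 101
        assert priority_score((0, 0, 1, 0)) == 10
        assert priority_score((0, 1, 0, 1)) > priority_score((0, 0, 1, 0))


class TestPrioritize:
    GENOME = {"Q", "A", "B", "C", "D"}

    def test_full_relation_candidate_ranks_first(self):
        standards = make_standards(
            complex_pairs=[("Q", "A")],
            pathway_pairs=[("Q", "A")],
            expression_pairs=[("Q", "A")],
            localization_pairs=[("Q", "A"), ("Q", "B")],
        )
        ranking = prioritize("Q", self.GENOME, standards)
        assert ranking.table.iloc[0]["gene"] == "A"
        assert ranking.table.iloc[0]["score"] == 1111
        assert ranking.rank_of("B") == 2  # score 1

    def test_no_relation_scores_zero_and_query_excluded(self):
        ranking = prioritize("Q", self.GENOME, make_standards())
        assert (ranking.table["score"] == 0).all()
        assert "Q" not in set(ranking.table["gene"])
        assert list(ranking.table["rank"]) == [1, 2, 3, 4]

    def test_ties_break_by_symbol_and_input_order_irrelevant(self):
        standards = make_standards(localization_pairs=[("Q", "C"), ("Q", "B")])
        r1 = prioritize("Q", ["Q", "A", "B", "C", "D"], standards)
        r2 = prioritize("Q", ["D", "C", "B", "A", "Q"], standards)
        assert list(r1.table["gene"]) == list(r2.table["gene"]) == ["B", "C", "A", "D"]

    def test_absent_query_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            prioritize("MISSING", self.GENOME, make_standards())

    def test_planted_co_complex_suppressors_outrank_relation_free(self, small_cfg, small_universe):
        from suppnet import gen_suppression_network
        from suppnet.mechanisms import MechanismClass
        from suppnet.simulate import SimConfig

        cfg = SimConfig(
            seed=31,
            n_genes=small_cfg.n_genes,
            n_complexes=small_cfg.n_complexes,
            n_pathways=small_cfg.n_pathways,
            n_queries=10,
            mechanism_mix={MechanismClass.SAME_COMPLEX: 1.0},
            suppressor_geometric_p=0.6,
            max_suppressors_per_query=2,
            flagged_extra_records=0,
        )
        net, truth = gen_suppression_network(cfg, small_universe)
        standards = {
            "co_complex": build_standard(small_universe.complexes, "co_complex"),
            "co_pathway": build_standard(small_universe.pathways, "co_pathway"),
            "co_expression": build_standard(small_universe.clusters, "co_expression"),
            "co_localization": build_standard(small_universe.compartments, "co_localization"),
        }
        for q, grp in truth.groupby("query"):
            ranking = prioritize(q, small_universe.gene_set, standards)
            worst_planted = max(ranking.rank_of(s) for s in grp["suppressor"])
            zero_ranks = ranking.table.loc[ranking.table["score"] == 0, "rank"]
            assert worst_planted < zero_ranks.min()


class TestBuildFeatures:
    def test_feature_rows(self):
        standards = make_standards(complex_pairs=[("Q", "A")])
        mm = MutationMatrix(
            pd.DataFrame(
                [[1, 1, 1, 1, 0], [1, 1, 1, 1, 1], [0, 0, 0, 0, 0]],
                index=["Q", "A", "B"],
                columns=list("vwxyz"),
            ).astype(bool)
        )
        feats = build_features(
            [("Q", "A"), ("Q", "B")], standards, ppi={("A", "Q")}, mm=mm
        )
        row = feats.loc[("Q", "A")]
        assert row["co_complex"] == 1 and row["ppi"] == 1
        assert row["comutation_count"] == 4
        zero = feats.loc[("Q", "B")]
        assert zero[["co_complex", "co_pathway", "co_expression", "co_localization",
                     "gi_positive", "gi_negative", "ppi", "comutation_count"]].sum() == 0


class TestTrainClassifier:
    @staticmethod
    def separable_setup(n_pos=30, n_genome=500):
        genome = [f"G{i}" for i in range(n_genome)] + ["Q"]
        positives = [("Q", f"G{i}") for i in range(n_pos)]
        standards = make_standards(complex_pairs=positives)
        bg = BackgroundPairSet({"Q"}, set(genome), excluded=set(positives))
        return positives, list(bg), standards

    def test_separable_features_reach_high_oob_auc(self):
        positives, bg, standards = self.separable_setup()
        forest = train_classifier(positives, bg, standards, seed=5, n_estimators=100)
        assert forest.oob_auc >= 0.95

    def test_label_shuffling_destroys_signal(self):
        # features vary across candidates but labels are assigned at random,
        # so out-of-bag ranking cannot beat chance
        genome = [f"G{i}" for i in range(400)] + ["Q"]
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            related = [("Q", f"G{i}") for i in rng.choice(400, size=120, replace=False)]
            standards = make_standards(
                complex_pairs=related[:40],
                expression_pairs=related[40:80],
                localization_pairs=related[80:],
            )
            mm = MutationMatrix(
                pd.DataFrame(
                    rng.random((401, 300)) < 0.1,
                    index=genome,
                    columns=[f"S{i}" for i in range(300)],
                )
            )
            positives = [("Q", f"G{i}") for i in rng.choice(400, size=25, replace=False)]
            bg = BackgroundPairSet({"Q"}, set(genome), excluded=set(positives))
            forest = train_classifier(
                positives, list(bg), standards, seed=seed, n_estimators=100, mm=mm
            )
            aucs.append(forest.oob_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_too_few_positives_rejected(self):
        positives, bg, standards = self.separable_setup(n_pos=10)
        with pytest.raises(ValueError, match=">= 20"):
            train_classifier(positives, bg, standards, seed=1)

    def test_reproducible_given_seed(self):
        positives, bg, standards = self.separable_setup()
        f1 = train_classifier(positives, bg, standards, seed=9, n_estimators=50)
        f2 = train_classifier(positives, bg, standards, seed=9, n_estimators=50)
        assert f1.oob_auc == f2.oob_auc

    def test_forest_ranking_places_positives_high(self):
        positives, bg, standards = self.separable_setup()
        forest = train_classifier(positives, bg, standards, seed=5, n_estimators=100)
        genome = {"Q"} | {g for _, g in bg} | {g for _, g in positives}
        ranking = forest.rank_genome("Q", genome, standards)
        top = set(ranking.table.head(len(positives))["gene"])
        assert top == {g for _, g in positives}


class TestEvaluateRanks:
    @staticmethod
    def ranking_for(query, genome, top_gene):
        standards = make_standards(complex_pairs=[(query, top_gene)])
        return prioritize(query, genome, standards)

    def test_unique_top_scorer_counts_at_both_thresholds(self):
        genome = {"Q"} | {f"G{i}" for i in range(200)}
        rankings = {"Q": self.ranking_for("Q", genome, "G0")}
        res = evaluate_ranks(rankings, {("Q", "G0")})
        assert res["best_ranks"]["Q"] == 1
        assert res["top_10"] == 1 and res["top_100"] == 1

    def test_missing_validated_gene_is_named(self):
        genome = {"Q", "A", "B"}
        rankings = {"Q": self.ranking_for("Q", genome, "A")}
        with pytest.raises(ValueError, match="ZZ"):
            evaluate_ranks(rankings, {("Q", "ZZ")})

    def test_chance_expectation_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        n_queries, genome_size, t = 30, 400, 40
        genome = [f"G{i}" for i in range(genome_size)]
        # analytic expectation for 1 validated suppressor per query
        expected = n_queries * (t / (genome_size - 1))
        hits = []
        for _ in range(300):
            count = 0
            for _q in range(n_queries):
                rank = rng.integers(1, genome_size)  # uniform random rank
                if rank <= t:
                    count += 1
            hits.append(count)
        assert np.mean(hits) == pytest.approx(expected, rel=0.1)
        # and the library computes the same analytic number
        standards = make_standards()
        rankings = {"Q": prioritize("Q", set(genome) | {"Q"}, standards)}
        res = evaluate_ranks(rankings, {("Q", "G5")}, thresholds=(t,))
        assert res[f"expected_top_{t}"] == pytest.approx(t / genome_size, rel=1e-9)

    def test_rank_list_comparison_matches_exact_enumeration(self):
        a, b = [1, 3, 6], [10, 20, 30, 40]
        assert compare_rank_lists(a, b) == pytest.approx(mann_whitney_exact_p(a, b))
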