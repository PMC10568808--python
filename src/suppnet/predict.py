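"""Genome-wide suppressor-gene prediction and rank-based evaluation.

Two models rank candidate suppressors for a query gene:

* **Functional prioritization** — a lexicographic score over four functional
  standards, encoded as a 4-digit indicator number (thousands digit:
  co-complex; hundreds: co-pathway; tens: co-expression; ones:
  co-localization).  Scores therefore range over 16 values from 0 to 1111,
  and numeric ordering equals lexicographic priority ordering by
  construction.
* **Random forest** — a classifier over per-pair feature vectors (the four
  standard indicators, positive/negative genetic-interaction indicators, a
  protein-protein-interaction indicator, and the co-mutation count in cancer
  cell lines), trained on curated pairs as positives against sampled
  background pairs, with out-of-bag votes providing an unbiased ranking
  score (OOB ROC AUC).

Evaluation asks where known, validated suppressors land in each query's
genome-wide ranking, and how many queries place a validated suppressor in
the top 10 / top 100, against the analytic chance expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .comutation import MutationMatrix, comutation_counts
from .relatedness import BackgroundPairSet, FunctionalStandard

__all__ = [
    "STANDARD_PRIORITY",
    "priority_score",
    "RankedGeneList",
    "prioritize",
    "build_features",
    "SuppressorForest",
    "train_classifier",
    "evaluate_ranks",
]

#: The four standards in decreasing priority; digit place values follow.
STANDARD_PRIORITY: tuple[str, ...] = (
    "co_complex",
    "co_pathway",
    "co_expression",
    "co_localization",
)
_PLACE_VALUES = (1000, 100, 10, 1)


def priority_score(indicators: Sequence[bool]) -> int:
    """Encode four standard indicators as a place-value score in [0, 1111]."""
    if len(indicators) != 4:
        raise ValueError("expected exactly 4 indicators")
    return sum(pv * int(bool(i)) for pv, i in zip(_PLACE_VALUES, indicators))


@dataclass
class RankedGeneList:
    """A genome-wide suppressor ranking for one query gene."""

    query: str
    table: pd.DataFrame  # columns: gene, score, rank (rank 1 = best)

    def __post_init__(self) -> None:
        t = self.table
        expected = np.arange(1, len(t) + 1)
        if not np.array_equal(t["rank"].to_numpy(), expected):
            raise ValueError("ranks must be 1..N without gaps")
        if np.any(np.diff(t["score"].to_numpy()) > 0):
            raise ValueError("scores must be non-increasing with rank")

    def rank_of(self, gene: str) -> int:
        hit = self.table.loc[self.table["gene"] == gene, "rank"]
        if hit.empty:
            raise KeyError(f"gene {gene!r} not present in ranking for {self.query}")
        return int(hit.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def prioritize(
    query: str,
    genome: Iterable[str],
    standards: Mapping[str, FunctionalStandard],
) -> RankedGeneList:
    """Rank all candidate genes for one query by the lexicographic priority score.

    ``standards`` maps the four standard names to functional standards; a
    missing standard contributes 0 for every candidate.  Ties are broken by
    candidate symbol order for determinism.  The query itself is excluded.
    """
    genome = sorted(set(genome))
    if query not in genome:
        raise ValueError(f"query {query!r} absent from genome")
    candidates = [g for g in genome if g != query]
    scores = []
    for gene in candidates:
        indicators = [
            standards[name].related(query, gene) if name in standards else False
            for name in STANDARD_PRIORITY
        ]
        scores.append(priority_score(indicators))
    table = pd.DataFrame({"gene": candidates, "score": scores})
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedGeneList(query, table)


FEATURE_COLUMNS = (
    "co_complex",
    "co_pathway",
    "co_expression",
    "co_localization",
    "gi_positive",
    "gi_negative",
    "ppi",
    "comutation_count",
)


def build_features(
    pairs: Iterable[tuple[str, str]],
    standards: Mapping[str, FunctionalStandard],
    gi_positive: set[tuple[str, str]] | None = None,
    gi_negative: set[tuple[str, str]] | None = None,
    ppi: set[tuple[str, str]] | None = None,
    mm: MutationMatrix | None = None,
) -> pd.DataFrame:
    """Deterministic per-pair feature table for the classifier.

    Interaction pair sets are treated as unordered.  Missing sources encode
    as zeros; availability per standard is reported in ``*_available``
    side-channel columns so downstream users can distinguish "no relation"
    from "no data".
    """
    pairs = list(dict.fromkeys(tuple(p) for p in pairs))
    rows = []
    if mm is not None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                counts = comutation_counts(pairs, mm)
            except ValueError:
                counts = pd.Series(dtype=int)
    else:
        counts = pd.Series(dtype=int)

    def in_undirected(pset, q, s):
        return pset is not None and ((q, s) in pset or (s, q) in pset)

    for q, s in pairs:
        row: dict = {"query": q, "candidate": s}
        for name in STANDARD_PRIORITY:
            std = standards.get(name)
            row[name] = int(bool(std and std.related(q, s)))
            row[f"{name}_available"] = int(bool(std and std.available(q, s)))
        row["gi_positive"] = int(in_undirected(gi_positive, q, s))
        row["gi_negative"] = int(in_undirected(gi_negative, q, s))
        row["ppi"] = int(in_undirected(ppi, q, s))
        row["comutation_count"] = int(counts.get((q, s), 0))
        rows.append(row)
    return pd.DataFrame(rows).set_index(["query", "candidate"])


@dataclass
class SuppressorForest:
    """A trained random-forest suppressor classifier with its OOB evaluation."""

    model: RandomForestClassifier
    oob_auc: float
    feature_columns: tuple[str, ...]
    n_positives: int
    n_negatives: int

    def score_pairs(self, features: pd.DataFrame) -> pd.Series:
        """Predicted suppressor probability per pair, in [0, 1]."""
        proba = self.model.predict_proba(
            features[list(self.feature_columns)].to_numpy()
        )[:, 1]
        return pd.Series(proba, index=features.index, name="score")

    def rank_genome(
        self,
        query: str,
        genome: Iterable[str],
        standards: Mapping[str, FunctionalStandard],
        **feature_sources,
    ) -> RankedGeneList:
        """Score every candidate in the genome for one query and rank them."""
        genome = sorted(set(genome))
        if query not in genome:
            raise ValueError(f"query {query!r} absent from genome")
        cand_pairs = [(query, g) for g in genome if g != query]
        feats = build_features(cand_pairs, standards, **feature_sources)
        scores = self.score_pairs(feats)
        table = pd.DataFrame(
            {"gene": [s for _, s in scores.index], "score": scores.to_numpy()}
        )
        table = table.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        return RankedGeneList(query, table)


def _oob_votes(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Average positive-class probability from each sample's out-of-bag trees.

    Samples that every tree happened to include in-bag score the uninformative
    prior 0.5.
    """
    n = X.shape[0]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for est, in_bag in zip(model.estimators_, model.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[in_bag] = False
        if not oob_mask.any():
            continue
        votes[oob_mask] += est.predict_proba(X[oob_mask])[:, 1]
        counts[oob_mask] += 1
    out = np.full(n, 0.5)
    seen = counts > 0
    out[seen] = votes[seen] / counts[seen]
    return out


def train_classifier(
    positives: Iterable[tuple[str, str]],
    background: BackgroundPairSet | Sequence[tuple[str, str]],
    standards: Mapping[str, FunctionalStandard],
    seed: int,
    negative_rate: float = 10.0,
    n_estimators: int = 500,
    gi_positive: set | None = None,
    gi_negative: set | None = None,
    ppi: set | None = None,
    mm: MutationMatrix | None = None,
) -> SuppressorForest:
    """Train a random forest on curated pairs vs sampled background pairs.

    Negatives are a seeded uniform sample of the background at
    ``negative_rate`` negatives per positive.  Performance is evaluated on
    out-of-bag samples: each pair is scored by the trees that did not see it,
    and the OOB ROC AUC is reported.
    """
    positives = list(dict.fromkeys(tuple(p) for p in positives))
    if len(positives) < 20:
        raise ValueError(f"need >= 20 positive pairs, got {len(positives)}")
    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    bg_pairs = [p for p in background if p not in pos_set]
    n_neg = int(round(negative_rate * len(positives)))
    if n_neg < 2 or len(positives) < 2:
        raise ValueError("each class needs >= 2 members")
    if n_neg > len(bg_pairs):
        raise ValueError(
            f"background too small: need {n_neg} negatives, have {len(bg_pairs)}"
        )
    idx = rng.choice(len(bg_pairs), size=n_neg, replace=False)
    negatives = [bg_pairs[i] for i in idx]

    feature_sources = dict(gi_positive=gi_positive, gi_negative=gi_negative, ppi=ppi, mm=mm)
    feats = build_features(positives + negatives, standards, **feature_sources)
    X = feats[list(FEATURE_COLUMNS)].to_numpy()
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    model.fit(X, y)
    oob_votes = _oob_votes(model, X)
    oob_auc = float(roc_auc_score(y, oob_votes))
    return SuppressorForest(
        model=model,
        oob_auc=oob_auc,
        feature_columns=FEATURE_COLUMNS,
        n_positives=len(positives),
        n_negatives=len(negatives),
    )


def evaluate_ranks(
    rankings: Mapping[str, RankedGeneList],
    validated: Iterable[tuple[str, str]],
    thresholds: Sequence[int] = (10, 100),
) -> dict:
    """Rank-of-validated-suppressor evaluation across queries.

    For each query, the best (minimum) rank over its validated suppressors is
    recorded; the summary counts queries whose best rank is within each
    threshold, alongside the analytic chance expectation under uniform random
    ranking: ``sum_q (1 - prod_s (1 - t / N_q))`` over that query's validated
    suppressors.
    """
    by_query: dict[str, list[str]] = {}
    for q, s in validated:
        by_query.setdefault(q, []).append(s)
    best_ranks: dict[str, int] = {}
    for q, supps in sorted(by_query.items()):
        if q not in rankings:
            raise ValueError(f"no ranking provided for query {q!r}")
        ranking = rankings[q]
        ranks = []
        for s in supps:
            try:
                ranks.append(ranking.rank_of(s))
            except KeyError:
                raise ValueError(
                    f"validated suppressor {s!r} missing from ranking of {q!r}"
                ) from None
        best_ranks[q] = min(ranks)
    summary: dict = {"best_ranks": best_ranks, "n_queries": len(best_ranks)}
    for t in thresholds:
        count = sum(1 for r in best_ranks.values() if r <= t)
        expected = 0.0
        for q, supps in by_query.items():
            n_q = len(rankings[q])
            miss = 1.0
            for _ in supps:
                miss *= max(0.0, 1.0 - t / n_q)
            expected += 1.0 - miss
        summary[f"top_{t}"] = count
        summary[f"expected_top_{t}"] = expected
    return summary


def compare_rank_lists(
    ranks_a: Sequence[int], ranks_b: Sequence[int], alternative: str = "two-sided"
) -> float:
    """Mann-Whitney U p-value comparing two sets of ranks (e.g., model vs random)."""
    _, p = stats.mannwhitneyu(ranks_a, ranks_b, alternative=alternative, method="auto")
    return float(p)
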