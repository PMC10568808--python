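"""Functional-relatedness standards and fold-enrichment statistics.

A *functional standard* is a symmetric binary relation on gene pairs
(co-complex, co-pathway, co-localization, co-expression, GO co-annotation)
together with a per-pair availability mask: enrichment statistics only count
pairs for which the underlying annotation source covers both genes.

Fold enrichment of a pair set against a standard is the ratio of the related
fraction among observed pairs to the related fraction among a constructed
background of all possible (query, candidate) pairs, with true suppression
pairs and self-pairs removed.  Significance is a two-sided Fisher exact test
on the 2x2 related-by-source table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from scipy import stats

from .genesets import GeneSetCollection
from .network import SuppressionNetwork

__all__ = [
    "StandardKind",
    "FunctionalStandard",
    "BackgroundPairSet",
    "build_standard",
    "fold_enrichment",
    "EnrichmentResult",
    "suppressor_set_relatedness",
    "go_slim_enrichment",
    "tf_pathway_overlap",
]


class StandardKind(str, enum.Enum):
    CO_COMPLEX = "co_complex"
    CO_PATHWAY = "co_pathway"
    CO_LOCALIZATION = "co_localization"
    CO_EXPRESSION = "co_expression"
    GO_COANNOTATION = "go_coannotation"


#: Kinds whose "not related" verdict requires both genes to be annotated to
#: distinct, non-overlapping sets (membership standards); for the rest,
#: availability only requires presence of both genes in the source dataset.
_STRICT_NONOVERLAP = frozenset({StandardKind.CO_COMPLEX, StandardKind.CO_PATHWAY})


@dataclass(frozen=True)
class FunctionalStandard:
    """A symmetric gene-pair relation with a data-availability mask."""

    kind: StandardKind
    collection: GeneSetCollection

    @property
    def name(self) -> str:
        return self.kind.value

    def related(self, a: str, b: str) -> bool:
        """True iff the two genes share at least one set in the collection."""
        return self.collection.share_set(a, b)

    def available(self, a: str, b: str) -> bool:
        """True iff the source data can assert relatedness either way for (a, b).

        For membership standards (complexes, pathways), non-membership is only
        asserted when the genes belong to distinct, non-overlapping sets;
        otherwise availability means both genes are present in the source.
        """
        sets_a = self.collection.sets_of(a)
        sets_b = self.collection.sets_of(b)
        if not sets_a or not sets_b:
            return False
        if self.kind not in _STRICT_NONOVERLAP:
            return True
        if sets_a & sets_b:
            return True
        # distinct sets: require at least one pair of sets with no common member
        sets = self.collection.sets
        return any(
            not (sets[sa] & sets[sb]) for sa in sets_a for sb in sets_b
        )


def build_standard(collection: GeneSetCollection, kind: StandardKind | str) -> FunctionalStandard:
    """Wrap a gene-set collection as a functional standard of the given kind."""
    try:
        kind = StandardKind(kind)
    except ValueError:
        allowed = ", ".join(k.value for k in StandardKind)
        raise ValueError(f"unknown standard kind {kind!r}; expected one of {allowed}") from None
    return FunctionalStandard(kind, collection)


class BackgroundPairSet:
    """All ordered (query, candidate) pairs used as the chance expectation.

    Contains every ordered pair (q, s) with q in ``queries``, s in
    ``suppressor_universe``, s != q, excluding the true suppression pairs.
    The suppressor universe is the genome for most analyses, or the set of
    dataset suppressors for the patient co-mutation analysis.
    """

    def __init__(
        self,
        queries: Iterable[str],
        suppressor_universe: Iterable[str],
        excluded: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.queries = frozenset(queries)
        self.suppressor_universe = frozenset(suppressor_universe)
        self.excluded = frozenset(tuple(p) for p in excluded)
        if not self.queries or not self.suppressor_universe:
            raise ValueError("background requires non-empty queries and universe")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for q in sorted(self.queries):
            for s in sorted(self.suppressor_universe):
                if s != q and (q, s) not in self.excluded:
                    yield (q, s)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        q, s = pair
        return (
            q in self.queries
            and s in self.suppressor_universe
            and s != q
            and (q, s) not in self.excluded
        )

    def __len__(self) -> int:
        n = 0
        for q in self.queries:
            n += len(self.suppressor_universe) - (1 if q in self.suppressor_universe else 0)
        overlap = sum(1 for p in self.excluded if self._in_grid(p))
        return n - overlap

    def _in_grid(self, pair: tuple[str, str]) -> bool:
        q, s = pair
        return q in self.queries and s in self.suppressor_universe and s != q


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    p_value: float
    n_available: int
    n_related: int
    n_background_available: int
    n_background_related: int

    def as_dict(self) -> dict:
        return {
            "fold": self.fold,
            "p_value": self.p_value,
            "n_available": self.n_available,
            "n_related": self.n_related,
            "n_background_available": self.n_background_available,
            "n_background_related": self.n_background_related,
        }


def fold_enrichment(
    pairs: Iterable[tuple[str, str]],
    standard: FunctionalStandard,
    background: BackgroundPairSet | Iterable[tuple[str, str]],
) -> EnrichmentResult:
    """Fold enrichment of observed pairs over background for one standard.

    Both pair sets are first restricted to pairs for which functional data is
    available for both genes.  ``fold`` is the ratio of related fractions; the
    p-value comes from a two-sided Fisher exact test on the 2x2 table of
    (related x pair-source) over available pairs.  A background with no
    related pairs yields ``fold = inf`` when the observed set has any.
    """
    obs = [p for p in pairs if standard.available(*p)]
    bg = [p for p in background if standard.available(*p)]
    if not obs or not bg:
        raise ValueError(
            f"no pairs with available {standard.name} data "
            f"(observed: {len(obs)}, background: {len(bg)})"
        )
    a = sum(1 for p in obs if standard.related(*p))
    c = sum(1 for p in bg if standard.related(*p))
    b, d = len(obs) - a, len(bg) - c
    _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if c == 0:
        fold = math.inf if a > 0 else math.nan
    else:
        fold = (a / len(obs)) / (c / len(bg))
    return EnrichmentResult(fold, float(p_value), len(obs), a, len(bg), c)


def suppressor_set_relatedness(
    net: SuppressionNetwork,
    standard: FunctionalStandard,
    background: BackgroundPairSet | Iterable[tuple[str, str]],
) -> EnrichmentResult:
    """Functional relatedness among independent suppressors of the same query.

    Builds all unordered suppressor-suppressor pairs that share a query gene,
    keeping only pairs whose two suppressors were reported in different
    publications (to avoid counting within-study redundancy), then computes
    fold enrichment as usual.
    """
    by_query: dict[str, dict[str, set[str]]] = {}
    for r in net.records:
        by_query.setdefault(r.query, {}).setdefault(r.suppressor, set()).add(r.pmid)
    pairs: set[tuple[str, str]] = set()
    for supp_pmids in by_query.values():
        supps = sorted(supp_pmids)
        for i, s1 in enumerate(supps):
            for s2 in supps[i + 1 :]:
                # require evidence from two distinct papers
                if supp_pmids[s1] - supp_pmids[s2] or supp_pmids[s2] - supp_pmids[s1]:
                    pairs.add((s1, s2))
    if not pairs:
        raise ValueError(
            "no qualifying suppressor-suppressor pairs (need a query with >=2 "
            "suppressors described in different publications)"
        )
    return fold_enrichment(pairs, standard, background)


def go_slim_enrichment(
    suppressors: Iterable[str],
    slim_sets: GeneSetCollection,
    class_terms: dict[str, Sequence[str]],
    genome: Iterable[str],
) -> dict[str, dict]:
    """Enrichment of suppressor genes for broad GO-slim classes.

    ``class_terms`` groups term IDs from ``slim_sets`` into general classes
    (transcription; mRNA decay & translation; protein degradation; signaling
    & stress response).  For each class the ratio between the annotated
    fraction of suppressors and the annotated fraction of the genome is
    reported; significance is a two-sided Fisher exact test comparing
    suppressors to the rest of the genome.
    """
    supp = set(suppressors)
    genome = set(genome)
    if not supp or not genome:
        raise ValueError("suppressor set and genome must be non-empty")
    other = genome - supp
    out: dict[str, dict] = {}
    for cls, terms in class_terms.items():
        annotated: set[str] = set()
        for t in terms:
            annotated |= set(slim_sets.sets.get(t, frozenset()))
        genome_frac = len(annotated & genome) / len(genome)
        if genome_frac == 0:
            raise ValueError(f"no genome genes annotated for class {cls!r}")
        supp_in = len(supp & annotated)
        supp_frac = supp_in / len(supp)
        other_in = len(other & annotated)
        _, p = stats.fisher_exact(
            [[supp_in, len(supp) - supp_in], [other_in, len(other) - other_in]],
            alternative="two-sided",
        )
        out[cls] = {
            "ratio": supp_frac / genome_frac,
            "p_value": float(p),
            "n_suppressors_annotated": supp_in,
            "n_genome_annotated": len(annotated & genome),
        }
    return out


def tf_pathway_overlap(
    net: SuppressionNetwork,
    tf_targets: GeneSetCollection,
    pathways: GeneSetCollection,
) -> dict:
    """Fraction of transcription-factor suppressors that target query pathway members.

    For each unique (query, suppressor) pair where the suppressor has a known
    target list and the query has pathway membership, the pair counts as a hit
    if the suppressor's targets intersect any pathway containing the query.
    Both collections should be pre-filtered to small, specific sets (the
    analysis convention is < 100 members).
    """
    eligible: list[tuple[str, str]] = []
    hits = 0
    for q, s in sorted(net.unique_pairs):
        target_sets = tf_targets.sets_of(s)
        query_pathways = pathways.sets_of(q)
        if not target_sets or not query_pathways:
            continue
        eligible.append((q, s))
        targets: set[str] = set()
        for ts in target_sets:
            targets |= set(tf_targets.sets[ts])
        pathway_members: set[str] = set()
        for pw in query_pathways:
            pathway_members |= set(pathways.sets[pw])
        if targets & pathway_members:
            hits += 1
    if not eligible:
        raise ValueError(
            "no (query, suppressor) pairs with both a suppressor target list "
            "and query pathway membership"
        )
    return {
        "fraction": hits / len(eligible),
        "n_hits": hits,
        "n_eligible": len(eligible),
    }
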