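"""Curated suppression-network data model, I/O, filters, and descriptive statistics.

A suppression interaction is a directed relation in which mutation of a
*suppressor* gene rescues the deleterious phenotype caused by mutation of a
*query* gene.  Networks are curated from the literature one *record* (report)
at a time; the same ordered (query, suppressor) pair may be reported by
several publications, so records and unique interactions are distinct levels
of the data model.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "StudyType",
    "EffectDirection",
    "EffectSize",
    "SuppressionRecord",
    "SuppressionNetwork",
    "InteractionFormatError",
    "read_interaction_table",
    "write_interaction_table",
    "apply_curation_filters",
    "unique_interactions",
    "exclude_queries",
    "degree_distribution",
    "subnetwork_overlap",
]

NA_TOKEN = "NA"


class InteractionFormatError(ValueError):
    """Raised when an interaction table violates the expected TSV dialect."""


class StudyType(str, enum.Enum):
    """System in which an interaction was identified."""

    CELL = "cell"
    PATIENT = "patient"


class EffectDirection(str, enum.Enum):
    """Mode of action of the mutation in a query or suppressor gene."""

    LOF = "LOF"
    GOF = "GOF"
    UNKNOWN = "unknown"


class EffectSize(str, enum.Enum):
    """Relative strength of the rescue."""

    PARTIAL = "partial"
    STRONG = "strong"
    UNKNOWN = "unknown"


def validate_gene_symbol(symbol: str) -> str:
    """Validate and return a gene symbol (non-empty, uppercased convention)."""
    if not isinstance(symbol, str) or not symbol.strip():
        raise ValueError("gene symbol must be a non-empty string")
    sym = symbol.strip()
    if sym != sym.upper():
        raise ValueError(f"gene symbol {sym!r} is not uppercase")
    return sym


@dataclass(frozen=True)
class SuppressionRecord:
    """One curated report of a suppression interaction.

    Records are reports, not deduplicated pairs: the same (query, suppressor)
    pair reported in two publications yields two records.
    """

    pmid: str
    query: str
    suppressor: str
    study_type: StudyType
    query_effect: EffectDirection = EffectDirection.UNKNOWN
    suppressor_effect: EffectDirection = EffectDirection.UNKNOWN
    context: str | None = None
    effect_size: EffectSize = EffectSize.UNKNOWN
    drug: str | None = None
    disease: str | None = None
    intragenic: bool = False
    multi_gene: bool = False
    major_allele: bool = False
    from_large_screen: bool = False
    validated_individually: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", validate_gene_symbol(self.query))
        object.__setattr__(self, "suppressor", validate_gene_symbol(self.suppressor))
        object.__setattr__(self, "study_type", StudyType(self.study_type))
        object.__setattr__(self, "query_effect", EffectDirection(self.query_effect))
        object.__setattr__(self, "suppressor_effect", EffectDirection(self.suppressor_effect))
        object.__setattr__(self, "effect_size", EffectSize(self.effect_size))
        if not self.intragenic and self.query == self.suppressor:
            raise ValueError(
                f"extragenic record has query == suppressor ({self.query}); "
                "mark intragenic records explicitly"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.query, self.suppressor)


#: Column order of the interaction-table TSV dialect.
RECORD_COLUMNS: tuple[str, ...] = (
    "pmid",
    "query",
    "suppressor",
    "study_type",
    "query_effect",
    "suppressor_effect",
    "context",
    "effect_size",
    "drug",
    "disease",
    "intragenic",
    "multi_gene",
    "major_allele",
    "from_large_screen",
    "validated_individually",
)

_BOOL_COLUMNS = (
    "intragenic",
    "multi_gene",
    "major_allele",
    "from_large_screen",
    "validated_individually",
)
_OPTIONAL_TEXT = ("context", "drug", "disease")


@dataclass
class SuppressionNetwork:
    """An ordered collection of suppression records with derived pair views."""

    records: list[SuppressionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SuppressionRecord]:
        return iter(self.records)

    @property
    def unique_pairs(self) -> set[tuple[str, str]]:
        return unique_interactions(self)

    @property
    def queries(self) -> set[str]:
        return {r.query for r in self.records}

    @property
    def suppressors(self) -> set[str]:
        return {r.suppressor for r in self.records}

    @property
    def genes(self) -> set[str]:
        return self.queries | self.suppressors

    def subset(self, predicate) -> "SuppressionNetwork":
        return SuppressionNetwork([r for r in self.records if predicate(r)])

    def by_study_type(self, study_type: StudyType | str) -> "SuppressionNetwork":
        st = StudyType(study_type)
        return self.subset(lambda r: r.study_type is st)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "pmid": r.pmid,
                    "query": r.query,
                    "suppressor": r.suppressor,
                    "study_type": r.study_type.value,
                    "query_effect": r.query_effect.value,
                    "suppressor_effect": r.suppressor_effect.value,
                    "context": r.context,
                    "effect_size": r.effect_size.value,
                    "drug": r.drug,
                    "disease": r.disease,
                    "intragenic": r.intragenic,
                    "multi_gene": r.multi_gene,
                    "major_allele": r.major_allele,
                    "from_large_screen": r.from_large_screen,
                    "validated_individually": r.validated_individually,
                }
            )
        return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def _parse_bool(token: str, column: str, line: int) -> bool:
    t = token.strip().lower()
    if t == "true":
        return True
    if t == "false":
        return False
    raise InteractionFormatError(
        f"line {line}: column {column!r} expects true/false, got {token!r}"
    )


def _parse_enum(enum_cls, token: str, column: str, line: int):
    try:
        return enum_cls(token.strip())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise InteractionFormatError(
            f"line {line}: column {column!r} expects one of {{{allowed}}}, got {token!r}"
        ) from None


def read_interaction_table(path) -> SuppressionNetwork:
    """Read a tab-separated interaction table into a :class:`SuppressionNetwork`.

    The dialect is UTF-8, tab-separated with a header naming all record
    fields; boolean columns are encoded ``true``/``false`` and missing
    optional text is ``NA``.  Unknown enum tokens raise; they are never
    silently coerced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise InteractionFormatError(
            f"interaction table is missing required column(s): {', '.join(missing)}"
        )
    records: list[SuppressionRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        data = dict(zip(df.columns, row))
        kwargs: dict = {
            "pmid": data["pmid"].strip(),
            "query": data["query"],
            "suppressor": data["suppressor"],
            "study_type": _parse_enum(StudyType, data["study_type"], "study_type", line),
            "query_effect": _parse_enum(
                EffectDirection, data["query_effect"], "query_effect", line
            ),
            "suppressor_effect": _parse_enum(
                EffectDirection, data["suppressor_effect"], "suppressor_effect", line
            ),
            "effect_size": _parse_enum(EffectSize, data["effect_size"], "effect_size", line),
        }
        for col in _OPTIONAL_TEXT:
            val = data[col].strip()
            kwargs[col] = None if val in ("", NA_TOKEN) else val
        for col in _BOOL_COLUMNS:
            kwargs[col] = _parse_bool(data[col], col, line)
        try:
            records.append(SuppressionRecord(**kwargs))
        except ValueError as exc:
            raise InteractionFormatError(f"line {line}: {exc}") from exc
    return SuppressionNetwork(records)


def write_interaction_table(net: SuppressionNetwork, path) -> None:
    """Write a network in the TSV dialect read by :func:`read_interaction_table`."""
    df = net.to_frame()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map({True: "true", False: "false"})
    for col in _OPTIONAL_TEXT:
        df[col] = df[col].fillna(NA_TOKEN)
    df.to_csv(path, sep="\t", index=False)


def apply_curation_filters(
    net: SuppressionNetwork, max_screen_hits: int = 50
) -> SuppressionNetwork:
    """Apply the curation exclusion rules, returning a new network.

    Removes records that are intragenic, involve more than two genes, or
    involve the major allele of either gene.  Records originating from
    high-throughput screens — flagged ``from_large_screen`` or whose PMID
    contributes more than ``max_screen_hits`` records to the table — are also
    removed unless they were validated individually.
    """
    pmid_counts = Counter(r.pmid for r in net.records)
    kept = []
    for r in net.records:
        if r.intragenic or r.multi_gene or r.major_allele:
            continue
        large_screen = r.from_large_screen or pmid_counts[r.pmid] > max_screen_hits
        if large_screen and not r.validated_individually:
            continue
        kept.append(r)
    return SuppressionNetwork(kept)


def unique_interactions(net: SuppressionNetwork) -> set[tuple[str, str]]:
    """Deduplicate records to the set of distinct ordered (query, suppressor) pairs.

    A pair reported in both directions contributes two entries, because the
    query and suppressor roles are not interchangeable.
    """
    return {r.pair for r in net.records}


def exclude_queries(net: SuppressionNetwork, genes: Iterable[str]) -> SuppressionNetwork:
    """Drop all records whose *query* gene is in ``genes``.

    Genes acting only as suppressors are retained.  Used to remove
    exceptionally well-studied disease genes whose large suppressor counts
    would otherwise dominate downstream statistics.
    """
    gene_set = set(genes)
    return net.subset(lambda r: r.query not in gene_set)


def degree_distribution(net: SuppressionNetwork, role: str) -> dict[int, int]:
    """Degree distribution over unique pairs for one role.

    For ``role="suppressor"``, the degree of a gene is the number of distinct
    query genes it suppresses; for ``role="query"``, the number of distinct
    suppressors described for it.  Returns a mapping degree -> number of
    genes with that degree.
    """
    if role not in ("query", "suppressor"):
        raise ValueError(f"role must be 'query' or 'suppressor', got {role!r}")
    pairs = unique_interactions(net)
    idx = 0 if role == "query" else 1
    other = 1 - idx
    partners: dict[str, set[str]] = {}
    for pair in pairs:
        partners.setdefault(pair[idx], set()).add(pair[other])
    return dict(Counter(len(v) for v in partners.values()))


def subnetwork_overlap(
    cell_pairs: set[tuple[str, str]],
    patient_pairs: set[tuple[str, str]],
    background: Iterable[tuple[str, str]],
) -> tuple[int, float]:
    """Overlap between two interaction pair sets and its Fisher significance.

    The 2x2 table classifies every pair in the union of the two observed sets
    and the background by membership in each set; the p-value is a two-sided
    Fisher exact test.  Returns ``(shared, p)``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background pair set is empty")
    universe = cell_pairs | patient_pairs | bg
    in_both = len(cell_pairs & patient_pairs)
    only_cell = len(cell_pairs - patient_pairs)
    only_patient = len(patient_pairs - cell_pairs)
    neither = len(universe) - in_both - only_cell - only_patient
    _, p = stats.fisher_exact(
        [[in_both, only_cell], [only_patient, neither]], alternative="two-sided"
    )
    return in_both, float(p)


def network_summary(net: SuppressionNetwork) -> dict:
    """Descriptive statistics bundle for a curated network."""
    pairs = unique_interactions(net)
    cell = unique_interactions(net.by_study_type(StudyType.CELL))
    patient = unique_interactions(net.by_study_type(StudyType.PATIENT))
    supp_deg = degree_distribution(net, "suppressor")
    query_deg = degree_distribution(net, "query")
    n_supp = sum(supp_deg.values())
    n_query = sum(query_deg.values())
    return {
        "n_records": len(net),
        "n_unique_pairs": len(pairs),
        "n_genes": len(net.genes),
        "n_queries": len(net.queries),
        "n_suppressors": len(net.suppressors),
        "n_cell_pairs": len(cell),
        "n_patient_pairs": len(patient),
        "n_shared_cell_patient": len(cell & patient),
        "frac_suppressors_degree_1": (supp_deg.get(1, 0) / n_supp) if n_supp else 0.0,
        "frac_queries_degree_gt_1": (
            sum(c for d, c in query_deg.items() if d > 1) / n_query if n_query else 0.0
        ),
        "suppressor_degree_distribution": supp_deg,
        "query_degree_distribution": query_deg,
    }
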