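"""Seeded synthetic-data generators for every input class of the analysis.

The generators emulate the structure of the real inputs — a gene universe
with overlapping functional annotations, a literature-style suppression
network with a configurable mix of mechanistic classes, damaging-mutation
matrices with planted query-suppressor co-mutation excess, and negative-
binomial screen count matrices with planted positively selected genes —
so that every analysis stage can be exercised and validated against planted
truth without any external downloads.

Mechanism planting is constructive: each planted pair is built to satisfy
its assigned class given the generated annotations (e.g. same-complex pairs
are drawn within a complex, general-class pairs across processes), so the
mechanistic classifier is expected to recover planted labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .comutation import MutationMatrix, MutationSource
from .genesets import GeneSetCollection
from .mechanisms import GENERAL_CLASS_BY_PROCESS, MechanismClass
from .network import (
    EffectDirection,
    EffectSize,
    StudyType,
    SuppressionNetwork,
    SuppressionRecord,
)
from .screen import ScreenCountMatrix

__all__ = [
    "SimConfig",
    "Universe",
    "gen_annotation_universe",
    "gen_suppression_network",
    "gen_property_table",
    "gen_fitness_matrix",
    "gen_mutation_matrix",
    "gen_screen_counts",
    "DEFAULT_MECHANISM_MIX",
]

#: Non-general broad process categories used for query genes.
CORE_PROCESSES = (
    "Metabolism",
    "DNA replication & repair",
    "Cell cycle",
    "Transport & trafficking",
)
GENERAL_PROCESSES = tuple(GENERAL_CLASS_BY_PROCESS)

#: Default planted mechanism mix, mirroring the class prevalences observed in
#: literature-curated human suppression networks (~33% functional, ~38%
#: general of which half signaling/stress, ~29% unassigned).
DEFAULT_MECHANISM_MIX: dict[MechanismClass, float] = {
    MechanismClass.SAME_COMPLEX: 0.06,
    MechanismClass.SAME_PATHWAY: 0.13,
    MechanismClass.ALTERNATIVE_PATHWAY: 0.07,
    MechanismClass.UNCHAR_FUNCTIONAL: 0.07,
    MechanismClass.GEN_TRANSCRIPTION: 0.10,
    MechanismClass.GEN_TRANSLATION_RNA: 0.04,
    MechanismClass.GEN_DEGRADATION: 0.05,
    MechanismClass.GEN_SIGNALING_STRESS: 0.19,
    MechanismClass.OTHER_UNKNOWN: 0.29,
}


@dataclass
class SimConfig:
    """Configuration for all synthetic generators; same seed -> same outputs."""

    seed: int = 0
    # gene universe
    n_genes: int = 1200
    n_complexes: int = 80
    complex_size_range: tuple[int, int] = (3, 8)
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (5, 15)
    n_compartments: int = 10
    compartments_per_gene: tuple[int, int] = (1, 3)
    n_expression_clusters: int = 40
    pathway_annotated_fraction: float = 0.7
    process_labeled_fraction: float = 0.85
    # suppression network
    n_queries: int = 93
    suppressor_geometric_p: float = 0.35
    max_suppressors_per_query: int = 10
    mechanism_mix: dict = field(default_factory=lambda: dict(DEFAULT_MECHANISM_MIX))
    cell_study_fraction: float = 0.63
    both_types_fraction: float = 0.015
    mean_extra_reports: float = 1.0
    flagged_extra_records: int = 20
    # property table group shifts
    query_pli_shift: float = 0.15
    suppressor_pli_shift: float = 0.10
    query_fitness_shift: float = -0.2
    suppressor_fitness_shift: float = -0.15
    # mutation matrix
    n_samples: int = 500
    base_mutation_rate: float = 0.05
    comutation_boost: float = 5.0
    # screen
    n_screen_genes: int = 300
    guides_per_gene: int = 4
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    planted_screen_genes: int = 3
    selection_fold: float = 32.0
    screen_drift_sd: float = 0.2
    n_ko_lines: int = 2
    n_replicates: int = 2

    def __post_init__(self) -> None:
        self.mechanism_mix = {
            MechanismClass(k): float(v) for k, v in self.mechanism_mix.items()
        }
        total = sum(self.mechanism_mix.values())
        if self.mechanism_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"mechanism_mix fractions must sum to 1, got {total}")
        for name in ("n_genes", "n_queries", "n_samples", "guides_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent, reproducible generator per logical stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class Universe:
    """A synthetic gene universe with overlapping functional annotations."""

    genes: list[str]
    process: dict[str, str]
    complexes: GeneSetCollection
    pathways: GeneSetCollection
    compartments: GeneSetCollection
    clusters: GeneSetCollection
    properties: pd.DataFrame

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)


def _sample_sets(
    rng: np.random.Generator,
    prefix: str,
    n_sets: int,
    size_range: tuple[int, int],
    pools: Mapping[str, list[str]],
) -> dict[str, frozenset[str]]:
    """Sample sets nested within process categories from per-process pools."""
    categories = sorted(pools)
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        cat = categories[int(rng.integers(0, len(categories)))]
        pool = pools[cat]
        lo, hi = size_range
        size = int(rng.integers(lo, hi + 1))
        if size > len(pool):
            raise ValueError(
                f"cannot draw a set of size {size} from the {len(pool)} "
                f"{cat!r} genes; reduce set sizes or raise n_genes"
            )
        members = rng.choice(len(pool), size=size, replace=False)
        sets[f"{prefix}{i + 1:04d}"] = frozenset(pool[j] for j in members)
    return sets


def gen_annotation_universe(cfg: SimConfig) -> Universe:
    """Generate the annotation universe: processes, complexes, pathways,
    compartments, expression clusters, and baseline per-gene properties."""
    rng = cfg.rng(1)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    # broad process categories; a fraction of genes stays unlabeled
    vocab = CORE_PROCESSES + GENERAL_PROCESSES
    process: dict[str, str] = {}
    for g in genes:
        if rng.random() < cfg.process_labeled_fraction:
            process[g] = vocab[int(rng.integers(0, len(vocab)))]

    # per-process pools; only "pathway-annotatable" genes enter complexes and
    # pathways, the remainder supports planting of uncharacterized-functional
    # pairs (same process, no pathway data)
    annot_pool: dict[str, list[str]] = {c: [] for c in vocab}
    for g in genes:
        cat = process.get(g)
        if cat is not None and rng.random() < cfg.pathway_annotated_fraction:
            annot_pool[cat].append(g)
    for cat, pool in annot_pool.items():
        if cfg.n_complexes and len(pool) < max(cfg.complex_size_range[1], cfg.pathway_size_range[1]):
            raise ValueError(f"process {cat!r} has too few annotatable genes ({len(pool)})")

    complexes = GeneSetCollection(
        "complexes",
        _sample_sets(rng, "CPX", cfg.n_complexes, cfg.complex_size_range, annot_pool)
        if cfg.n_complexes
        else {},
    )
    pathways = GeneSetCollection(
        "pathways",
        _sample_sets(rng, "PW", cfg.n_pathways, cfg.pathway_size_range, annot_pool)
        if cfg.n_pathways
        else {},
    )

    comp_sets: dict[str, set[str]] = {f"COMP{i + 1:02d}": set() for i in range(cfg.n_compartments)}
    comp_ids = sorted(comp_sets)
    for g in genes:
        k = int(rng.integers(cfg.compartments_per_gene[0], cfg.compartments_per_gene[1] + 1))
        for j in rng.choice(cfg.n_compartments, size=k, replace=False):
            comp_sets[comp_ids[j]].add(g)
    compartments = GeneSetCollection(
        "compartments", {k: frozenset(v) for k, v in comp_sets.items() if v}
    )

    labels = rng.integers(0, cfg.n_expression_clusters, size=cfg.n_genes)
    clus_sets: dict[str, set[str]] = {}
    for g, lbl in zip(genes, labels):
        clus_sets.setdefault(f"CLU{int(lbl) + 1:03d}", set()).add(g)
    clusters = GeneSetCollection(
        "expression_clusters", {k: frozenset(v) for k, v in clus_sets.items()}
    )

    properties = pd.DataFrame(
        {
            "pli": np.clip(rng.beta(1.2, 2.0, size=cfg.n_genes), 0, 1),
            "fitness_median": rng.normal(-0.3, 0.35, size=cfg.n_genes),
            "ortholog_species": rng.poisson(8, size=cfg.n_genes),
            "disease_count": rng.poisson(1.0, size=cfg.n_genes),
        },
        index=pd.Index(genes, name="gene"),
    )
    return Universe(genes, process, complexes, pathways, compartments, clusters, properties)


def _candidate_suppressors(
    cls: MechanismClass,
    query: str,
    universe: Universe,
) -> list[str]:
    """Genes that, paired with ``query``, satisfy mechanism class ``cls``."""
    proc = universe.process
    cpx, pw = universe.complexes, universe.pathways
    q_cat = proc[query]
    q_cpx, q_pw = cpx.sets_of(query), pw.sets_of(query)

    def shares_cpx(g):
        return bool(cpx.sets_of(g) & q_cpx)

    def shares_pw(g):
        return bool(pw.sets_of(g) & q_pw)

    if cls is MechanismClass.SAME_COMPLEX:
        out = {g for cid in q_cpx for g in cpx.sets[cid]}
        return sorted(out - {query})
    if cls is MechanismClass.SAME_PATHWAY:
        out = {g for pid in q_pw for g in pw.sets[pid]}
        return sorted(g for g in out - {query} if not shares_cpx(g))
    if cls is MechanismClass.ALTERNATIVE_PATHWAY:
        return sorted(
            g
            for g in universe.genes
            if g != query
            and proc.get(g) == q_cat
            and pw.annotated(g)
            and not shares_pw(g)
            and not shares_cpx(g)
        )
    if cls is MechanismClass.UNCHAR_FUNCTIONAL:
        return sorted(
            g
            for g in universe.genes
            if g != query
            and proc.get(g) == q_cat
            and not pw.annotated(g)
            and not shares_cpx(g)
        )
    if cls in set(GENERAL_CLASS_BY_PROCESS.values()):
        target_cat = next(
            cat for cat, c in GENERAL_CLASS_BY_PROCESS.items() if c is cls
        )
        if target_cat == q_cat:
            return []
        return sorted(g for g in universe.genes if proc.get(g) == target_cat)
    # OTHER_UNKNOWN: no functional relation, suppressor not in a general class
    return sorted(
        g
        for g in universe.genes
        if g != query
        and proc.get(g) != q_cat
        and proc.get(g) not in GENERAL_CLASS_BY_PROCESS
        and not shares_cpx(g)
        and not shares_pw(g)
    )


def gen_suppression_network(
    cfg: SimConfig, universe: Universe
) -> tuple[SuppressionNetwork, pd.DataFrame]:
    """Generate a literature-style network with planted mechanistic classes.

    Returns the record-level network and a truth table (query, suppressor,
    planted class).  Query genes are drawn from process-labeled genes with
    both complex and pathway annotations in the non-general categories, which
    makes every mechanism class constructible.
    """
    rng = cfg.rng(2)
    mix_classes = [c for c, f in sorted(cfg.mechanism_mix.items(), key=lambda kv: kv[0].value) if f > 0]
    mix_probs = np.array([cfg.mechanism_mix[c] for c in mix_classes], dtype=float)
    if len(mix_classes) == 0:
        raise ValueError("mechanism_mix has no positive entries")
    mix_probs = mix_probs / mix_probs.sum()

    eligible_queries = [
        g
        for g in universe.genes
        if universe.process.get(g) in CORE_PROCESSES
        and universe.complexes.annotated(g)
        and universe.pathways.annotated(g)
    ]
    if len(eligible_queries) < cfg.n_queries:
        raise ValueError(
            f"only {len(eligible_queries)} eligible query genes for "
            f"n_queries={cfg.n_queries}; enlarge the universe"
        )
    q_idx = rng.choice(len(eligible_queries), size=cfg.n_queries, replace=False)
    queries = [eligible_queries[i] for i in q_idx]

    truth_rows = []
    planted: set[tuple[str, str]] = set()
    for q in queries:
        k = min(int(rng.geometric(cfg.suppressor_geometric_p)), cfg.max_suppressors_per_query)
        for _ in range(k):
            for _attempt in range(20):
                cls = mix_classes[int(rng.choice(len(mix_classes), p=mix_probs))]
                cands = [
                    s for s in _candidate_suppressors(cls, q, universe)
                    if (q, s) not in planted
                ]
                if cands:
                    s = cands[int(rng.integers(0, len(cands)))]
                    planted.add((q, s))
                    truth_rows.append({"query": q, "suppressor": s, "planted_class": cls.value})
                    break
            else:
                raise ValueError(
                    f"could not plant a suppressor for query {q}; "
                    "mechanism mix infeasible in this universe"
                )
    truth = pd.DataFrame(truth_rows)

    pmid_counter = [0]

    def next_pmid() -> str:
        pmid_counter[0] += 1
        return f"PM{pmid_counter[0]:06d}"

    def draw_effect(probs) -> EffectDirection:
        r = rng.random()
        if r < probs[0]:
            return EffectDirection.LOF
        if r < probs[0] + probs[1]:
            return EffectDirection.GOF
        return EffectDirection.UNKNOWN

    records: list[SuppressionRecord] = []
    for q, s in sorted(planted):
        base_type = (
            StudyType.CELL if rng.random() < cfg.cell_study_fraction else StudyType.PATIENT
        )
        n_reports = 1 + int(rng.poisson(cfg.mean_extra_reports))
        types = [base_type] * n_reports
        if rng.random() < cfg.both_types_fraction:
            other = StudyType.PATIENT if base_type is StudyType.CELL else StudyType.CELL
            types.append(other)
        for st in types:
            records.append(
                SuppressionRecord(
                    pmid=next_pmid(),
                    query=q,
                    suppressor=s,
                    study_type=st,
                    query_effect=draw_effect((0.8, 0.15)),
                    suppressor_effect=draw_effect((0.6, 0.25)),
                    context="synthetic cell line" if st is StudyType.CELL else None,
                    effect_size=EffectSize.PARTIAL if rng.random() < 0.5 else EffectSize.STRONG,
                    disease=None if st is StudyType.CELL else f"disease_{int(rng.integers(1, 40))}",
                )
            )

    # extra flagged records that the curation filters are expected to remove
    flags = ("intragenic", "multi_gene", "major_allele", "from_large_screen")
    for _ in range(cfg.flagged_extra_records):
        flag = flags[int(rng.integers(0, len(flags)))]
        q = universe.genes[int(rng.integers(0, len(universe.genes)))]
        if flag == "intragenic":
            s = q
        else:
            while True:
                s = universe.genes[int(rng.integers(0, len(universe.genes)))]
                if s != q:
                    break
        records.append(
            SuppressionRecord(
                pmid=next_pmid(),
                query=q,
                suppressor=s,
                study_type=StudyType.CELL,
                **{flag: True},
            )
        )
    rng.shuffle(records)  # records arrive in no particular order
    return SuppressionNetwork(records), truth


def gen_property_table(
    cfg: SimConfig,
    universe: Universe,
    net: SuppressionNetwork | None = None,
) -> pd.DataFrame:
    """Property table with configurable group shifts for query/suppressor genes.

    Starting from the universe's baseline properties, query and suppressor
    genes receive additive shifts emulating the empirical pattern that both
    groups are more intolerant to loss of function and more fitness-relevant
    than other genes.
    """
    table = universe.properties.copy()
    if net is None:
        return table
    for genes, pli_shift, fit_shift in (
        (net.queries, cfg.query_pli_shift, cfg.query_fitness_shift),
        (net.suppressors, cfg.suppressor_pli_shift, cfg.suppressor_fitness_shift),
    ):
        idx = table.index.intersection(sorted(genes))
        table.loc[idx, "pli"] = np.clip(table.loc[idx, "pli"] + pli_shift, 0, 1)
        table.loc[idx, "fitness_median"] += fit_shift
        table.loc[idx, "ortholog_species"] += 2
        table.loc[idx, "disease_count"] += 1
    return table


def gen_fitness_matrix(
    cfg: SimConfig,
    genes: Iterable[str],
    n_cell_lines: int = 50,
    n_excess: int = 0,
    excess_factor: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x cell-line knockout fitness matrix with a quadratic mean-variance law.

    Per-gene variance follows ``0.05*mean^2 + 0.02`` plus noise; the first
    ``n_excess`` genes get ``excess_factor`` times the expected variance
    (planted background-dependent genes).  Returns (matrix, excess_genes).
    """
    rng = cfg.rng(3)
    genes = list(genes)
    means = rng.normal(-0.5, 0.5, size=len(genes))
    base_var = 0.05 * means**2 + 0.02
    excess_genes = genes[:n_excess]
    var = base_var.copy()
    var[:n_excess] *= excess_factor
    values = rng.normal(
        loc=means[:, None], scale=np.sqrt(var)[:, None], size=(len(genes), n_cell_lines)
    )
    return (
        pd.DataFrame(values, index=pd.Index(genes, name="gene")),
        excess_genes,
    )


def gen_mutation_matrix(
    cfg: SimConfig,
    pairs: Iterable[tuple[str, str]],
    genes: Iterable[str],
    source: MutationSource = MutationSource.CELL_LINES,
) -> MutationMatrix:
    """Boolean mutation matrix with planted co-mutation excess for given pairs.

    Genes mutate independently per sample at ``base_mutation_rate``; for each
    planted pair an additional joint event occurs at rate
    ``(comutation_boost - 1) * rate^2``, bringing the pair's joint mutation
    probability to about ``comutation_boost`` times the independent
    expectation.
    """
    rng = cfg.rng(4)
    genes = sorted(set(genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    p = cfg.base_mutation_rate
    data = rng.random((len(genes), cfg.n_samples)) < p
    joint_rate = max(cfg.comutation_boost - 1.0, 0.0) * p * p
    for q, s in sorted(set(tuple(x) for x in pairs)):
        if q not in gene_idx or s not in gene_idx:
            continue
        joint = rng.random(cfg.n_samples) < joint_rate
        data[gene_idx[q]] |= joint
        data[gene_idx[s]] |= joint
    df = pd.DataFrame(
        data,
        index=pd.Index(genes, name="gene"),
        columns=[f"S{i + 1:04d}" for i in range(cfg.n_samples)],
    )
    return MutationMatrix(df, source)


def gen_screen_counts(cfg: SimConfig) -> tuple[ScreenCountMatrix, list[str]]:
    """Negative-binomial screen counts with planted positively selected genes.

    Day-0 counts are negative binomial around per-guide abundances; day-18
    counts follow the same guide's day-0 count scaled by multiplicative drift
    noise, with guides of planted genes additionally multiplied by
    ``selection_fold`` in knockout lines only.  Returns (matrix, planted genes).
    """
    rng = cfg.rng(5)
    genes = [f"SG{i + 1:05d}" for i in range(cfg.n_screen_genes)]
    n_planted = min(cfg.planted_screen_genes, cfg.n_screen_genes)
    planted = sorted(
        genes[i] for i in rng.choice(cfg.n_screen_genes, size=n_planted, replace=False)
    )
    guides = []
    guide_gene = []
    for g in genes:
        for j in range(cfg.guides_per_gene):
            guides.append(f"{g}_g{j + 1}")
            guide_gene.append(g)
    n_guides = len(guides)

    lines = [ "WT" ] + [f"KO{i + 1}" for i in range(cfg.n_ko_lines)]
    design_rows = []
    for line in lines:
        for day in (0, 18):
            for rep in range(1, cfg.n_replicates + 1):
                design_rows.append(
                    {"sample": f"{line}_d{day}_r{rep}", "line": line, "day": day, "replicate": rep}
                )
    design = pd.DataFrame(design_rows).set_index("sample")

    # per-guide baseline abundance (library composition)
    mu_guide = rng.lognormal(mean=np.log(cfg.nb_mean), sigma=0.4, size=n_guides)
    alpha = cfg.nb_dispersion
    nb_n = 1.0 / alpha

    counts = pd.DataFrame(index=pd.Index(guides, name="gRNA"), columns=design.index, dtype=float)
    planted_set = set(planted)
    is_planted = np.array([g in planted_set for g in guide_gene])
    for line in lines:
        for rep in range(1, cfg.n_replicates + 1):
            depth0 = rng.uniform(0.8, 1.2)
            mu0 = mu_guide * depth0
            d0 = rng.negative_binomial(nb_n, nb_n / (nb_n + mu0))
            counts[f"{line}_d0_r{rep}"] = d0
            drift = rng.lognormal(mean=0.0, sigma=cfg.screen_drift_sd, size=n_guides)
            fold = np.where(
                is_planted & (line != "WT"), cfg.selection_fold, 1.0
            )
            depth18 = rng.uniform(0.8, 1.2)
            mu18 = d0 * drift * fold * depth18
            counts[f"{line}_d18_r{rep}"] = rng.poisson(mu18)
    counts = counts.astype(float)
    return (
        ScreenCountMatrix(counts, pd.Series(guide_gene, index=counts.index, name="gene"), design),
        planted,
    )
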