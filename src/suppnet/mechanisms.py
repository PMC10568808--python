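"""Mechanistic classification of suppression interactions.

Each (query, suppressor) pair is assigned to exactly one of nine mechanistic
classes.  Pairs with a close functional relationship — shared complex, shared
pathway, same broad biological process — fall into four *functional*
subclasses; the remainder are subdivided by the suppressor gene's broad
process into four *general* compensation subclasses (transcription,
translation/RNA, protein degradation, signaling/stress) or, failing that,
Other/unknown.

The decision procedure is a strict priority cascade; the first matching rule
wins, so a pair sharing both a complex and a pathway is always "same
complex".
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Mapping

from scipy import stats

from .genesets import GeneSetCollection

__all__ = [
    "MechanismClass",
    "MechanismFamily",
    "GENERAL_CLASS_BY_PROCESS",
    "classify",
    "class_distribution",
    "compare_class_distributions",
    "read_process_annotation",
]


class MechanismFamily(str, enum.Enum):
    FUNCTIONAL = "functional"
    GENERAL = "general"
    OTHER = "other"


class MechanismClass(str, enum.Enum):
    SAME_COMPLEX = "SAME_COMPLEX"
    SAME_PATHWAY = "SAME_PATHWAY"
    ALTERNATIVE_PATHWAY = "ALTERNATIVE_PATHWAY"
    UNCHAR_FUNCTIONAL = "UNCHAR_FUNCTIONAL"
    GEN_TRANSCRIPTION = "GEN_TRANSCRIPTION"
    GEN_TRANSLATION_RNA = "GEN_TRANSLATION_RNA"
    GEN_DEGRADATION = "GEN_DEGRADATION"
    GEN_SIGNALING_STRESS = "GEN_SIGNALING_STRESS"
    OTHER_UNKNOWN = "OTHER_UNKNOWN"

    @property
    def family(self) -> MechanismFamily:
        if self in (
            MechanismClass.SAME_COMPLEX,
            MechanismClass.SAME_PATHWAY,
            MechanismClass.ALTERNATIVE_PATHWAY,
            MechanismClass.UNCHAR_FUNCTIONAL,
        ):
            return MechanismFamily.FUNCTIONAL
        if self is MechanismClass.OTHER_UNKNOWN:
            return MechanismFamily.OTHER
        return MechanismFamily.GENERAL


#: Broad process categories that map to a general compensation subclass when
#: carried by the suppressor of a functionally unrelated pair.
GENERAL_CLASS_BY_PROCESS: dict[str, MechanismClass] = {
    "Transcription & chromatin organization": MechanismClass.GEN_TRANSCRIPTION,
    "Translation & RNA processing": MechanismClass.GEN_TRANSLATION_RNA,
    "Protein degradation": MechanismClass.GEN_DEGRADATION,
    "Signaling & stress response": MechanismClass.GEN_SIGNALING_STRESS,
}


def read_process_annotation(path) -> dict[str, str]:
    """Read a 2-column TSV of gene -> broad process category (one per gene)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (gene, category)")
    gene_col, cat_col = df.columns[:2]
    annotation: dict[str, str] = {}
    for gene, cat in zip(df[gene_col], df[cat_col]):
        if gene in annotation and annotation[gene] != cat:
            raise ValueError(f"gene {gene!r} has conflicting process categories")
        annotation[str(gene)] = str(cat)
    return annotation


def classify(
    pair: tuple[str, str],
    process: Mapping[str, str],
    complexes: GeneSetCollection,
    pathways: GeneSetCollection,
) -> MechanismClass:
    """Assign one mechanistic class to an ordered (query, suppressor) pair.

    Priority cascade (first match wins):

    1. shared protein complex            -> SAME_COMPLEX
    2. shared pathway                    -> SAME_PATHWAY
    3. same process category, both genes
       pathway-annotated, none shared    -> ALTERNATIVE_PATHWAY
    4. same process category otherwise   -> UNCHAR_FUNCTIONAL
    5. unrelated pair whose suppressor's
       process is a general category     -> that general class
    6. anything else                     -> OTHER_UNKNOWN

    Genes missing from an annotation source are simply not matched by the
    rules that need it; classification never fails for unannotated genes.
    """
    query, suppressor = pair
    if complexes.share_set(query, suppressor):
        return MechanismClass.SAME_COMPLEX
    if pathways.share_set(query, suppressor):
        return MechanismClass.SAME_PATHWAY
    q_cat, s_cat = process.get(query), process.get(suppressor)
    same_process = q_cat is not None and q_cat == s_cat
    if same_process:
        if pathways.annotated(query) and pathways.annotated(suppressor):
            return MechanismClass.ALTERNATIVE_PATHWAY
        return MechanismClass.UNCHAR_FUNCTIONAL
    general = GENERAL_CLASS_BY_PROCESS.get(s_cat) if s_cat is not None else None
    if general is not None:
        return general
    return MechanismClass.OTHER_UNKNOWN


def class_distribution(
    pairs: Iterable[tuple[str, str]],
    process: Mapping[str, str],
    complexes: GeneSetCollection,
    pathways: GeneSetCollection,
) -> dict:
    """Counts and fractions per mechanistic class for a deduplicated pair set.

    Also reports family-level aggregates (functional / general / other) and
    the fraction of pairs assigned to any mechanism (everything except
    OTHER_UNKNOWN).
    """
    pairs = sorted(set(tuple(p) for p in pairs))
    if not pairs:
        raise ValueError("empty pair set")
    labels = [classify(p, process, complexes, pathways) for p in pairs]
    counts = Counter(labels)
    n = len(pairs)
    per_class = {cls.value: counts.get(cls, 0) for cls in MechanismClass}
    fractions = {k: v / n for k, v in per_class.items()}
    family_counts: Counter = Counter(lbl.family for lbl in labels)
    families = {fam.value: family_counts.get(fam, 0) / n for fam in MechanismFamily}
    return {
        "n_pairs": n,
        "counts": per_class,
        "fractions": fractions,
        "family_fractions": families,
        "assigned_fraction": 1.0 - fractions[MechanismClass.OTHER_UNKNOWN.value],
        "labels": dict(zip(pairs, labels)),
    }


def compare_class_distributions(a: dict, b: dict) -> dict[str, float]:
    """Per-class two-sided Fisher exact tests between two class distributions.

    Each class contributes a 2x2 table (in-class vs not) x (network a vs b).
    Inputs are outputs of :func:`class_distribution` with counts retained.
    """
    na, nb = a["n_pairs"], b["n_pairs"]
    if na == 0 or nb == 0:
        raise ValueError("both distributions must come from non-empty pair sets")
    out: dict[str, float] = {}
    for cls in MechanismClass:
        ka = a["counts"][cls.value]
        kb = b["counts"][cls.value]
        _, p = stats.fisher_exact(
            [[ka, na - ka], [kb, nb - kb]], alternative="two-sided"
        )
        out[cls.value] = float(p)
    return out
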