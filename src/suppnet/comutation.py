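"""Co-occurrence of damaging mutations in query-suppressor gene pairs.

Given a boolean gene x sample matrix of damaging mutations (cancer cell
lines or patient tumor samples), these routines count per-pair co-mutated
samples and compare the suppression pairs' co-mutation profile with a
constructed background pair set.  The comparison is either a Fisher exact
test on the proportion of pairs co-mutated at least once, or a Mann-Whitney
U test on the per-pair co-mutation count distributions.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutationSource",
    "MutationMatrix",
    "read_mutation_matrix",
    "comutation_counts",
    "comutation_enrichment",
]


class MutationSource(str, enum.Enum):
    CELL_LINES = "cell_lines"
    PATIENTS = "patients"


@dataclass
class MutationMatrix:
    """Boolean gene x sample damaging-mutation matrix.

    Variant-impact filtering (damaging-only calls, exclusion of variants of
    unknown significance) is assumed to have happened upstream.
    """

    data: pd.DataFrame
    source: MutationSource = MutationSource.CELL_LINES

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("mutation matrix has duplicated gene identifiers")
        self.data = self.data.astype(bool)
        self.source = MutationSource(self.source)

    @property
    def genes(self) -> set[str]:
        return set(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_mutation_matrix(path, source: MutationSource | str = MutationSource.CELL_LINES) -> MutationMatrix:
    """Read a mutation matrix from wide (genes x samples of 0/1) or long (gene, sample) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 2 and set(c.lower() for c in df.columns) == {"gene", "sample"}:
        df.columns = [c.lower() for c in df.columns]
        wide = pd.crosstab(df["gene"], df["sample"]).astype(bool)
        return MutationMatrix(wide, source)
    wide = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(wide.astype(int).astype(bool), source)


def comutation_counts(
    pairs: Iterable[tuple[str, str]], mm: MutationMatrix
) -> pd.Series:
    """Number of samples in which both genes of each pair carry a damaging mutation.

    Pairs with either gene absent from the matrix are dropped with a warning.
    Returns a Series indexed by the ordered pair.
    """
    if mm.n_samples == 0 or mm.data.shape[0] == 0:
        raise ValueError("mutation matrix is empty")
    pairs = list(dict.fromkeys(tuple(p) for p in pairs))
    gene_index = {g: i for i, g in enumerate(mm.data.index)}
    kept, qi, si = [], [], []
    dropped = 0
    for q, s in pairs:
        if q in gene_index and s in gene_index:
            kept.append((q, s))
            qi.append(gene_index[q])
            si.append(gene_index[s])
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"dropped {dropped} pair(s) with gene(s) absent from the mutation matrix",
            RuntimeWarning,
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no pairs with both genes present in the mutation matrix")
    values = mm.data.to_numpy()
    counts = (values[qi] & values[si]).sum(axis=1)
    return pd.Series(counts, index=pd.MultiIndex.from_tuples(kept, names=["query", "suppressor"]))


class ComutationTest(str, enum.Enum):
    FISHER = "fisher"
    MANNWHITNEY = "mannwhitney"


def comutation_enrichment(
    pairs: Iterable[tuple[str, str]],
    background: Iterable[tuple[str, str]],
    mm: MutationMatrix,
    test: ComutationTest | str = ComutationTest.FISHER,
    max_k: int | None = None,
) -> dict:
    """Compare co-mutation of suppression pairs against background pairs.

    Returns the cumulative curves (% of pairs co-mutated in >= k samples for
    k = 1..K, per pair source) and a p-value: Fisher exact on the 2x2 of
    (co-mutated >= 1 vs not) x (suppression vs background), or Mann-Whitney U
    on the two per-pair count distributions.  K defaults to the largest
    observed co-mutation count.
    """
    test = ComutationTest(test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        obs = comutation_counts(pairs, mm)
        bg = comutation_counts(background, mm)
    k_max = max_k if max_k is not None else int(max(obs.max(), bg.max(), 1))
    ks = np.arange(1, k_max + 1)

    def curve(counts: pd.Series) -> list[float]:
        arr = counts.to_numpy()
        return [float((arr >= k).mean() * 100.0) for k in ks]

    if test is ComutationTest.FISHER:
        a = int((obs >= 1).sum())
        c = int((bg >= 1).sum())
        table = [[a, len(obs) - a], [c, len(bg) - c]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        _, p = stats.mannwhitneyu(
            obs.to_numpy(), bg.to_numpy(), alternative="two-sided", method="auto"
        )
    return {
        "k": ks.tolist(),
        "curve_suppression": curve(obs),
        "curve_background": curve(bg),
        "p_value": float(p),
        "test": test.value,
        "n_pairs": int(len(obs)),
        "n_background": int(len(bg)),
    }
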