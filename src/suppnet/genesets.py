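"""Named gene-set collections with GMT and gene->label TSV input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "read_label_table"]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (complexes, pathways, GO terms, ...).

    ``max_set_size`` is applied at construction: sets of that size or larger
    are dropped, mirroring the practice of excluding huge, unspecific
    annotation terms (e.g. GO biological-process terms with >= 500 genes).
    """

    name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    max_set_size: int | None = None

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for set_id, members in self.sets.items():
            fs = frozenset(members)
            if not fs:
                raise ValueError(f"gene set {set_id!r} in {self.name!r} is empty")
            if self.max_set_size is not None and len(fs) >= self.max_set_size:
                continue
            clean[set_id] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, gene: str) -> bool:
        return gene in self.membership

    @property
    def membership(self) -> dict[str, frozenset[str]]:
        """Mapping gene -> frozenset of set IDs it belongs to (cached)."""
        cached = getattr(self, "_membership", None)
        if cached is None:
            m: dict[str, set[str]] = {}
            for set_id, members in self.sets.items():
                for g in members:
                    m.setdefault(g, set()).add(set_id)
            cached = {g: frozenset(ids) for g, ids in m.items()}
            object.__setattr__(self, "_membership", cached)
        return cached

    @property
    def genes(self) -> set[str]:
        return set(self.membership)

    def sets_of(self, gene: str) -> frozenset[str]:
        return self.membership.get(gene, frozenset())

    def share_set(self, a: str, b: str) -> bool:
        return bool(self.sets_of(a) & self.sets_of(b))

    def annotated(self, gene: str) -> bool:
        return gene in self.membership


def read_gmt(path, name: str | None = None, max_set_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file (set ID, description, tab-separated members per line)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            set_id, _desc, *members = fields
            members = [m for m in members if m]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set ID {set_id!r}")
            sets[set_id] = frozenset(members)
    return GeneSetCollection(name or str(path), sets, max_set_size=max_set_size)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[set_id]))
            fh.write(f"{set_id}\t{collection.name}\t{members}\n")


def read_label_table(path, name: str | None = None) -> GeneSetCollection:
    """Read a 2-column gene -> label TSV into a collection keyed by label.

    Multi-label membership is expressed by repeated rows for the same gene.
    Used for subcellular compartments and co-expression clusters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (gene, label)")
    gene_col, label_col = df.columns[:2]
    sets: dict[str, set[str]] = {}
    for gene, label in zip(df[gene_col], df[label_col]):
        sets.setdefault(str(label), set()).add(str(gene))
    return GeneSetCollection(name or str(path), {k: frozenset(v) for k, v in sets.items()})
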