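"""Suppressor calling from a genome-wide CRISPR knockout rescue screen.

The screen design compares a wild-type line against knockout clones of a
query gene, each sampled at the start (day 0) and end (day 18) of selection
under a stressor, in replicate.  Guides targeting a suppressor gene are
positively selected in the knockout clones but not in wild type.

The decision rule for calling a gene a suppressor:

(i)   pooled day-18 normalized counts over all knockout clones, replicates,
      and guides are significantly higher than pooled wild-type day-18
      counts (one-sided Wilcoxon rank-sum, p < alpha);
(ii)  at least ``frac_threshold`` of (guide, replicate) observations have
      log2 fold change (day 18 vs day 0, pseudocount-stabilized) above
      ``lfc_threshold`` in *each* knockout clone;
(iii) that fraction stays below ``frac_threshold`` in wild type.

No multiple-testing correction is applied; the p < alpha rule is a screening
heuristic backed by the orthogonal fold-change requirements, and reports
flag this explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenCountMatrix",
    "SuppressorCall",
    "read_screen_counts",
    "normalize_counts",
    "filter_guides",
    "call_suppressors",
]

WT_LINE = "WT"


@dataclass
class ScreenCountMatrix:
    """gRNA x sample counts with a guide->gene map and a sample design table.

    ``design`` is indexed by sample name with columns ``line`` (WT or a
    knockout clone label), ``day`` (integer timepoint), and ``replicate``.
    """

    counts: pd.DataFrame
    guide_map: pd.Series  # index: gRNA, value: gene symbol
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gRNA identifiers")
        unmapped = self.counts.index.difference(self.guide_map.index)
        if len(unmapped):
            raise ValueError(f"{len(unmapped)} gRNA(s) missing from the guide map")
        missing = self.counts.columns.difference(self.design.index)
        if len(missing):
            raise ValueError(f"sample(s) missing from design: {list(missing)}")
        for col in ("line", "day", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design table missing column {col!r}")

    @property
    def lines(self) -> list[str]:
        return sorted(self.design["line"].unique())

    @property
    def ko_lines(self) -> list[str]:
        return [l for l in self.lines if l != WT_LINE]

    def samples_for(self, line: str | None = None, day: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if line is not None:
            mask &= self.design["line"] == line
        if day is not None:
            mask &= self.design["day"] == day
        return [s for s in self.counts.columns if mask.get(s, False)]

    def genes(self) -> list[str]:
        return sorted(self.guide_map.loc[self.counts.index].unique())


def read_screen_counts(counts_path, design_path, guides_path) -> ScreenCountMatrix:
    """Assemble a screen matrix from counts, design, and guide-map TSV files."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    guides = pd.read_csv(guides_path, sep="\t", index_col=0)
    if guides.shape[1] < 1:
        raise ValueError("guide map needs 2 columns (gRNA, gene)")
    return ScreenCountMatrix(counts, guides.iloc[:, 0], design)


def normalize_counts(raw: ScreenCountMatrix) -> ScreenCountMatrix:
    """Scale each sample to the mean library size (total-count normalization).

    Preserves within-sample proportions; every column ends with the same
    total, the mean of the raw per-sample totals.
    """
    totals = raw.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    target = float(totals.mean())
    scaled = raw.counts * (target / totals)
    return ScreenCountMatrix(scaled, raw.guide_map, raw.design)


def filter_guides(m: ScreenCountMatrix, max_absent_day0: int = 2) -> ScreenCountMatrix:
    """Drop guides with zero counts in ``max_absent_day0`` or more day-0 samples.

    Guides already absent at the start of the screen cannot inform selection
    and inflate fold-change noise.
    """
    day0 = m.samples_for(day=0)
    if not day0:
        raise ValueError("design contains no day-0 samples")
    n_absent = (m.counts[day0] == 0).sum(axis=1)
    keep = n_absent < max_absent_day0
    return ScreenCountMatrix(m.counts.loc[keep], m.guide_map, m.design)


@dataclass(frozen=True)
class SuppressorCall:
    gene: str
    p_value: float
    frac_passing: dict[str, float]  # per line incl. WT
    called: bool
    n_guides: int


def _pair_replicates(m: ScreenCountMatrix, line: str) -> list[tuple[str, str]]:
    """Match day-18 samples with the same line/replicate's day-0 sample."""
    sub = m.design[m.design["line"] == line]
    pairs = []
    for rep, grp in sub.groupby("replicate"):
        d0 = grp[grp["day"] == 0].index
        d18 = grp[grp["day"] != 0].index
        for s18 in d18:
            if len(d0) == 0:
                raise ValueError(f"line {line} replicate {rep} lacks a day-0 sample")
            pairs.append((str(d0[0]), str(s18)))
    return pairs


def call_suppressors(
    m: ScreenCountMatrix,
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
    frac_threshold: float = 0.5,
    pseudocount: float = 0.5,
    min_guides: int = 2,
) -> list[SuppressorCall]:
    """Apply the rank-sum + fold-change suppressor decision rule per gene.

    Expects a normalized and guide-filtered matrix whose design includes a WT
    line and at least two knockout clones at both timepoints.  Genes with
    fewer than ``min_guides`` surviving guides are excluded with a warning.
    """
    ko_lines = m.ko_lines
    if WT_LINE not in m.lines or len(ko_lines) < 1:
        raise ValueError("design must include a WT line and >= 1 knockout line")
    end_day = int(m.design["day"].max())
    wt_end = m.samples_for(WT_LINE, end_day)
    ko_end = [s for line in ko_lines for s in m.samples_for(line, end_day)]
    if not wt_end or not ko_end:
        raise ValueError("missing end-of-screen samples for WT or knockout lines")

    rep_pairs = {line: _pair_replicates(m, line) for line in m.lines}
    calls: list[SuppressorCall] = []
    genes = m.guide_map.loc[m.counts.index]
    skipped = 0
    for gene, guide_idx in genes.groupby(genes).groups.items():
        sub = m.counts.loc[guide_idx]
        if len(sub) < min_guides:
            skipped += 1
            continue
        ko_vals = sub[ko_end].to_numpy().ravel()
        wt_vals = sub[wt_end].to_numpy().ravel()
        _, p = stats.mannwhitneyu(ko_vals, wt_vals, alternative="greater", method="auto")

        frac: dict[str, float] = {}
        for line in m.lines:
            lfcs = []
            for s0, s18 in rep_pairs[line]:
                lfc = np.log2(
                    (sub[s18].to_numpy() + pseudocount)
                    / (sub[s0].to_numpy() + pseudocount)
                )
                lfcs.append(lfc)
            all_lfc = np.concatenate(lfcs)
            frac[line] = float((all_lfc > lfc_threshold).mean())

        ko_pass = all(frac[line] >= frac_threshold for line in ko_lines)
        wt_pass = frac[WT_LINE] < frac_threshold
        called = bool(p < alpha and ko_pass and wt_pass)
        calls.append(
            SuppressorCall(
                gene=str(gene),
                p_value=float(p),
                frac_passing=frac,
                called=called,
                n_guides=int(len(sub)),
            )
        )
    if skipped:
        warnings.warn(
            f"excluded {skipped} gene(s) with < {min_guides} guides after filtering",
            RuntimeWarning,
            stacklevel=2,
        )
    return sorted(calls, key=lambda c: c.gene)


def calls_to_frame(calls: Iterable[SuppressorCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene": c.gene, "p_value": c.p_value, "called": c.called, "n_guides": c.n_guides}
        for line, f in c.frac_passing.items():
            row[f"frac_lfc_pass_{line}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
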