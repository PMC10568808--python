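# Methods

This note documents the models, decision rules, and parameter choices behind
`suppnet`, and what the synthetic validation does and does not establish.

## Data model and curation semantics

A *record* is one literature report of a suppression interaction: PMID,
query and suppressor gene symbols, study type (cultured cells vs patients),
mutation modes (LOF/GOF/unknown per side), context, effect size, optional
drug and disease, and five curation flags. Records are reports, not edges:
the same ordered (query, suppressor) pair reported by several publications
yields several records, and deduplication to *unique interactions* is a
separate, explicit operation. A pair observed in both directions counts as
two interactions, because the two roles are asymmetric.

Curation flags (intragenic, multi-gene, major-allele, from a large screen,
individually validated) are inputs, not computed: the underlying judgments
are manual. `apply_curation_filters` removes flagged records; in addition, a
PMID contributing more than `max_screen_hits` (default 50) records is
treated as a large screen, so the threshold has operational meaning even
when the flag was not set by the curator. Screen-derived records survive
only if individually validated. Filtering is idempotent.

Exceptionally well-studied disease genes can dominate every downstream
statistic; `exclude_queries` removes a gene's records in the query role only
(it may still appear as a suppressor).

Fisher exact tests are two-sided throughout unless a direction is inherent
to the question (the screen caller, below).

## Functional standards and enrichment

A standard is a symmetric relation plus an availability mask. For
membership standards (complexes, pathways), *non*-relatedness is only
asserted when the two genes belong to distinct, non-overlapping sets —
otherwise the pair is unavailable; for presence standards (localization,
expression clusters, GO terms) availability just requires both genes in the
source. GO co-annotation uses terms below 500 genes; TF-target and pathway
lists in the transcription-overlap analysis are restricted to under 100
members to avoid unspecific annotations. Co-expression is abstracted to a
cluster-membership relation; the interface is identical to a
correlation-derived relation but the derivation is not reproduced here.

The background pair set contains every ordered (query, candidate) pair over
a candidate universe (the genome, or the dataset's suppressors for the
patient co-mutation analysis), minus self-pairs — suppression is defined
extragenic — and minus the true suppression pairs. Fold enrichment is the
ratio of related fractions over available pairs; the availability mask makes
the statistic invariant to padding the universe with unannotated genes.

Suppressor–suppressor relatedness considers only pairs of suppressors of the
same query reported in different publications, so within-study redundancy
cannot masquerade as functional coherence.

## Mechanistic classes

The nine-way classification is a strict priority cascade (first match wins):
shared complex, shared pathway, alternative pathway (same broad process,
both genes pathway-annotated, no shared pathway), uncharacterized functional
relation (same process otherwise); then, for unrelated pairs, the
suppressor's broad process maps to one of four general classes, else
Other/unknown. Three consequences worth noting: a pair sharing a pathway but
not a process category is still functional; a same-process pair missing
pathway annotation on either side is "uncharacterized" rather than
"alternative pathway"; and only the suppressor's process decides the general
classes — general compensation is a property of the rescuing gene. Each gene
carries at most one process category; pleiotropic or uncharacterized genes
are unlabeled and therefore never "functionally related" by category alone.

## Knockout-fitness variance model

Across cell-line panels, the variance of a gene's knockout fitness grows
with its mean effect, so raw variance cannot identify background-dependent
genes. We fit `variance = a·mean² + b·mean + c` by least squares over all
genes and flag genes whose residual exceeds the empirical `flag_quantile`
(default 0.95) of residuals — an intentionally threshold-free-looking rule
whose flagged fraction is ~5% by construction under the null. Exact fits
leave only rounding noise; a small absolute tolerance (1e-9 of the variance
scale) prevents flagging genes that lie on the curve. If all means coincide
the quadratic is degenerate and a constant model is used with a warning.

## Prediction models

The lexicographic prioritization encodes the four standard indicators as a
place-value number (thousands: co-complex; hundreds: co-pathway; tens:
co-expression; ones: co-localization), so numeric score order provably
equals lexicographic priority order; ties break by candidate symbol for
determinism, and the query is excluded from its own ranking.

The random forest (scikit-learn, 500 trees by default) is trained on curated
pairs as positives against a seeded uniform sample of background pairs at 10
negatives per positive (the published analysis does not state its negative
set; the ratio is configurable). Features: the four standard indicators,
positive/negative genetic-interaction indicators, a protein–protein
interaction indicator, and the co-mutation count in cancer cell lines, with
per-standard availability side-channels kept out of the model input.
Performance is the out-of-bag ROC AUC, computed from per-sample votes of the
trees that did not train on the sample; we compute OOB votes directly from
each tree's bootstrap sample rather than relying on the estimator's built-in
OOB array, which under weighted bootstraps can leave high-weight samples
without any out-of-bag trees. Samples never out of bag score the prior 0.5.

Rank evaluation reports, per query, the best rank over its validated
suppressors and counts queries within the top-10/top-100, alongside the
analytic chance expectation `Σ_q (1 − Π_s (1 − t/N_q))` under uniform random
ranking (verified by permutation in the tests).

Real-data prediction performance depends on external complex/pathway/
expression/interaction snapshots and is out of scope here; the evaluation
machinery is instead validated on separable and label-randomized synthetic
cases.

## Screen caller

Counts are normalized per sample to the mean library size, preserving
within-sample proportions. Guides absent (zero) in two or more day-0
samples are removed. A gene is called a suppressor iff:

1. pooled day-18 normalized counts over all knockout clones, replicates,
   and guides exceed pooled wild-type day-18 counts (one-sided Wilcoxon
   rank-sum, p < α = 0.05) — one-sided because the question is directional;
2. at least `frac_threshold` (0.5) of (guide, replicate) observations have
   `log2((day18 + 0.5)/(day0 + 0.5)) > 2` in *each* knockout clone, pairing
   day 18 with the same line and replicate's day 0;
3. that fraction stays below the threshold in wild type.

The pseudocount 0.5 stabilizes fold changes when extreme positive selection
drives competing guides to zero; genes with fewer than two surviving guides
are excluded with a warning. No multiple-testing correction is applied — the
p < α rule is a screening heuristic backed by the orthogonal fold-change
requirements — and reports state this. Pooling the rank-sum across clones
(rather than testing per clone) follows the "across clones, replicates, and
guides" reading; the per-clone fold-change rule supplies the clone-level
stringency.

## Synthetic data

The generators define the study conditions under which everything is
validated. Defaults: a 1,200-gene universe with eight broad process
categories (15% of genes unlabeled), 80 complexes (3–8 genes) and 100
pathways (5–15 genes) nested within categories (70% of labeled genes
pathway-annotatable), 10 compartments, 40 expression clusters; 93 query
genes with a geometric suppressor-count distribution (p = 0.35, capped at
10); a planted mechanism mix of 6/13/7/7% functional subclasses, 10/4/5/19%
general subclasses, and 29% other — the class prevalences reported for
literature-curated human suppression networks; ~63% cell-derived reports,
~1.5% of pairs reported in both study types, one extra report per pair on
average (Poisson), and 20 flagged records for the filters to remove.
Mutation matrices use 500 samples at a 5% per-gene damaging-mutation rate
with a 5× joint-probability boost for planted pairs. Screens use 300 genes ×
4 guides (desk-scale stand-in for a genome-wide library), negative-binomial
day-0 counts (mean 500, dispersion 0.1), lognormal drift (σ = 0.2), ±20%
library-size variation, 32-fold selection of 3 planted genes in two knockout
clones only, in duplicate.

Mechanism planting is constructive — pairs are built to satisfy their class
given the generated annotations — so classifier recovery of planted labels
is exactly 100% on consistent universes; this validates the decision cascade,
not robustness to annotation noise. Query genes are drawn from
complex- and pathway-annotated genes in the four non-general categories so
that every class is constructible for every query. More generally the
generators emulate structure, not the marginal statistics of real resources
(annotation coverage biases, mutation-rate heterogeneity across genes and
samples, guide-efficiency variation), so passing tests demonstrate
correctness of the procedures and their statistical behavior under the
stated model, not performance on real data.

## Reproducibility

Every generator takes an explicit seed and derives independent streams per
stage; the same seed yields byte-identical outputs. The pipeline report
embeds the seed and a configuration hash. `scripts/acceptance.py --seed S`
reruns the whole chain at the default (study-scale) configuration in a few
seconds and writes all headline quantities as JSON. Validation against the
originally published curated network and screen supplements requires placing
those third-party files under `data/`; the corresponding tests fail
otherwise rather than silently skipping.
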