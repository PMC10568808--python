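"""Per-gene phenotype property comparisons and knockout-fitness variance analysis.

Query and suppressor genes of a suppression network are compared to all other
genes on properties such as loss-of-function intolerance (pLI-style
probability), median knockout fitness across cell-line panels, ortholog
species counts, and disease associations.  Group differences are assessed
with two-sided Mann-Whitney U tests.

``variance_excess`` models the mean-variance relation of knockout fitness
across cell lines with a quadratic least-squares fit and flags genes whose
variance lies far above the fitted curve — candidates for background-
dependent (suppressible) fitness effects.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .network import SuppressionNetwork

__all__ = [
    "PROPERTY_COLUMNS",
    "read_property_table",
    "compare_property",
    "variance_excess",
    "effect_fractions",
]

PROPERTY_COLUMNS = ("pli", "fitness_median", "ortholog_species", "disease_count")


def read_property_table(path) -> pd.DataFrame:
    """Read a gene property TSV (gene + the four property columns), gene-indexed."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing column(s): {', '.join(missing)}")
    if not df.index.is_unique:
        raise ValueError("property table has duplicated gene identifiers")
    return df


def _group_values(table: pd.DataFrame, genes: set[str], prop: str, label: str) -> np.ndarray:
    vals = table.reindex(sorted(genes))[prop].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(
            f"group {label!r} has {len(vals)} non-missing values for {prop!r}; need >= 2"
        )
    return vals


def compare_property(
    queries: Iterable[str],
    suppressors: Iterable[str],
    universe: Iterable[str],
    table: pd.DataFrame,
    prop: str,
) -> dict:
    """Compare queries, suppressors, and all other genes on one property.

    "Other" is the universe minus queries minus suppressors.  Missing values
    are dropped per group.  Returns per-group medians and sizes plus
    two-sided Mann-Whitney U p-values for queries-vs-other and
    suppressors-vs-other (exact for small tie-free samples, normal
    approximation with tie correction otherwise).
    """
    if prop not in table.columns:
        raise ValueError(f"unknown property {prop!r}")
    queries, suppressors = set(queries), set(suppressors)
    universe = set(universe)
    other = universe - queries - suppressors
    groups = {
        "queries": _group_values(table, queries, prop, "queries"),
        "suppressors": _group_values(table, suppressors, prop, "suppressors"),
        "other": _group_values(table, other, prop, "other"),
    }
    out: dict = {"property": prop, "groups": {}}
    for name, vals in groups.items():
        out["groups"][name] = {
            "n": int(len(vals)),
            "median": float(np.median(vals)),
            "values": vals,
        }
    for name in ("queries", "suppressors"):
        u, p = stats.mannwhitneyu(
            groups[name], groups["other"], alternative="two-sided", method="auto"
        )
        out[f"p_{name}_vs_other"] = float(p)
        out[f"U_{name}_vs_other"] = float(u)
    return out


def variance_excess(
    fitness: pd.DataFrame, flag_quantile: float = 0.95
) -> pd.DataFrame:
    """Flag genes whose knockout-fitness variance across cell lines is in excess.

    Fits ``variance = a*mean^2 + b*mean + c`` by least squares over all genes,
    computes the per-gene residual (observed minus fitted variance), and flags
    genes whose residual exceeds the ``flag_quantile`` empirical quantile of
    residuals.  Columns of the result: mean, variance, expected_variance,
    residual, flagged.
    """
    if fitness.shape[0] < 10:
        raise ValueError("need >= 10 genes to fit the mean-variance model")
    if fitness.shape[1] < 2:
        raise ValueError("need >= 2 cell lines to compute variances")
    if not 0 < flag_quantile < 1:
        raise ValueError("flag_quantile must be in (0, 1)")
    values = fitness.to_numpy(dtype=float)
    means = values.mean(axis=1)
    variances = values.var(axis=1, ddof=1)
    if np.allclose(means, means[0]):
        warnings.warn(
            "all gene means are equal; falling back to a constant variance model",
            RuntimeWarning,
            stacklevel=2,
        )
        expected = np.full_like(variances, variances.mean())
    else:
        coeffs = np.polyfit(means, variances, deg=2)
        expected = np.polyval(coeffs, means)
    residual = variances - expected
    # exact fits leave only rounding noise; never flag those
    eps = 1e-9 * max(1.0, float(np.abs(variances).max()))
    cutoff = max(np.quantile(residual, flag_quantile), 0.0) + eps
    return pd.DataFrame(
        {
            "mean": means,
            "variance": variances,
            "expected_variance": expected,
            "residual": residual,
            "flagged": residual > cutoff,
        },
        index=fitness.index,
    )


def effect_fractions(net: SuppressionNetwork) -> dict[str, dict[str, float]]:
    """Fractions of LOF / GOF / unknown mutation modes per role, over records."""
    if len(net) == 0:
        raise ValueError("network has no records")
    out: dict[str, dict[str, float]] = {}
    n = len(net)
    for role, attr in (("query", "query_effect"), ("suppressor", "suppressor_effect")):
        counts: dict[str, int] = {}
        for r in net.records:
            counts[getattr(r, attr).value] = counts.get(getattr(r, attr).value, 0) + 1
        out[role] = {k: v / n for k, v in sorted(counts.items())}
    return out
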