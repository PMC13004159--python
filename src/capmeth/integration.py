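"""Cross-assay integration and gene-set enrichment.

Combines the m7G-IP % methylation table with the Cap-Tag % input table:
correlation across the shared gene universe, median-split high/low
classes per assay, high-confidence intersections (methylation-high AND
Cap-Tag-low, and vice versa), a 2-fold induction filter, and gene-set
overrepresentation by one-sided Fisher's exact test with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import InsufficientDataError

__all__ = [
    "correlate",
    "median_split",
    "high_confidence",
    "induced_subset",
    "fisher_overrep_p",
    "enrich",
    "classify",
]


def fisher_overrep_p(k: int, N: int, K: int, n: int) -> float:
    """One-sided (overrepresentation) Fisher exact p: P(X >= k | N, K, n).

    Upper tail of the hypergeometric distribution for drawing ``k`` or
    more term genes in a query of size ``n`` from a universe of ``N``
    genes of which ``K`` belong to the term.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def correlate(
    x: pd.Series, y: pd.Series, method: str = "pearson"
) -> tuple[float, int]:
    """Correlation over the intersection of finite-valued genes.

    Returns (coefficient, number of genes used). Requires at least 3
    shared finite values.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    joined = pd.concat([x, y], axis=1, join="inner")
    joined = joined[np.isfinite(joined).all(axis=1)]
    n = len(joined)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 shared finite genes, have {n}")
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = float(func(joined.iloc[:, 0], joined.iloc[:, 1])[0])
    return r, n


def median_split(values: pd.Series) -> pd.Series:
    """Label each gene ``high`` (value > median) or ``low`` (<= median).

    Ties at the median go to ``low``, so the two classes always
    partition the input.
    """
    if len(values) < 2:
        raise InsufficientDataError("median split needs >= 2 genes")
    med = float(values.median())
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def high_confidence(meth: pd.DataFrame, captag: pd.DataFrame) -> pd.DataFrame:
    """Median-split both assays and intersect into high-confidence classes.

    High methylation confidence = methylation-high AND Cap-Tag %-input
    low (little unmethylated cap pulled down); low confidence class is
    the converse. Only genes present in both tables are classified.
    """
    shared = meth.index.intersection(captag.index)
    if len(shared) == 0:
        raise InsufficientDataError("no genes shared between the two assays")
    ip_class = median_split(meth.loc[shared, "pct_methylation"])
    captag_class = median_split(captag.loc[shared, "pct_input_corrected"])
    return pd.DataFrame(
        {
            "ip_class": ip_class,
            "captag_class": captag_class,
            "high_confidence_high": (ip_class == "high") & (captag_class == "low"),
            "high_confidence_low": (ip_class == "low") & (captag_class == "high"),
        },
        index=shared,
    )


def induced_subset(
    input_min: pd.Series, input_rich: pd.Series, fold: float = 2.0
) -> pd.DataFrame:
    """Flag genes induced by >= ``fold`` (spike-normalized min/rich input).

    Genes with zero rich-condition input are flagged not evaluable
    (``evaluable=False``, induced NaN->False).
    """
    rich = input_rich.reindex(input_min.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = input_min / rich
    evaluable = np.isfinite(ratio)
    induced = (ratio >= fold) & evaluable
    return pd.DataFrame(
        {"fold_induction": ratio, "induced": induced, "evaluable": evaluable}
    )


def classify(
    meth: pd.DataFrame,
    captag: pd.DataFrame,
    input_min: pd.Series | None = None,
    input_rich: pd.Series | None = None,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Full ClassLabels table: high-confidence classes plus induction flags."""
    labels = high_confidence(meth, captag)
    if input_min is not None and input_rich is not None:
        ind = induced_subset(input_min, input_rich, fold).reindex(labels.index)
        labels["fold_induction"] = ind["fold_induction"]
        labels["induced"] = ind["induced"].fillna(False)
    return labels


def enrich(
    query: set[str] | pd.Index,
    annotations: dict[str, set[str]],
    universe: set[str] | pd.Index,
) -> pd.DataFrame:
    """Gene-set overrepresentation of ``query`` within ``universe``.

    Each term is intersected with the universe; the one-sided Fisher
    exact p-value is the upper hypergeometric tail
    P(X >= k | N, K, n), and q-values are Benjamini-Hochberg across all
    tested terms. Returns a DataFrame indexed by term id, sorted by
    p-value, with columns ``k``, ``K``, ``n``, ``N``, ``odds_ratio``,
    ``p_value``, ``q_value``.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty gene universe")
    query = set(map(str, query)) & universe
    N, n = len(universe), len(query)
    rows = {}
    for term, genes in annotations.items():
        term_genes = set(map(str, genes)) & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = fisher_overrep_p(k, N, K, n)
        a, b, c, d = k, n - k, K - k, N - K - n + k
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows[term] = dict(k=k, K=K, n=n, N=N, odds_ratio=odds, p_value=p)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "term_id"
    if len(out):
        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="mergesort")
    else:
        out["q_value"] = []
    return out
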