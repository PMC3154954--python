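"""Over-representation analysis of constrained gene lists.

Each annotation term is tested with an upper-tail hypergeometric p-value for
the overlap between the query list and the term's genes within the
universe; p-values are BH-adjusted within each ontology class (each
class/query stratum is an independent adjustment family).  Terms significant
in both the highly- and lowly-constrained lists can be excluded so that only
class-unique terms remain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .compare import bh_adjust
from .data_io import AnnotationMap

logger = logging.getLogger("varcon")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) drawing n genes from a universe of N with K annotated."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: list[str],
    annotations: AnnotationMap,
    universe: list[str],
    alpha: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term against a query list.

    The query must lie within the universe; term sizes (K) count annotated
    genes inside the universe, and terms with K < ``min_term_size`` are
    skipped.  BH adjustment runs within each ontology class.  Returns one
    row per tested term with k, K, n, N, p_value, adjusted_p, significant.
    """
    if not query:
        raise ValueError("empty query list")
    uni = set(universe)
    outside = set(query) - uni
    if outside:
        raise ValueError(f"query gene {sorted(outside)[0]!r} not in universe")
    q = set(query)
    N, n = len(uni), len(q)

    rows = []
    for ont in annotations.classes():
        sub = annotations.by_class(ont)
        sub = sub[sub["gene_id"].isin(uni)]
        for term, genes in sub.groupby("term_id")["gene_id"]:
            term_genes = set(genes)
            K = len(term_genes)
            if K < min_term_size:
                continue
            k = len(term_genes & q)
            rows.append(
                {
                    "term_id": term,
                    "ontology_class": ont,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_value": hypergeom_pvalue(k, K, n, N),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "ontology_class", "k", "K", "n", "N", "p_value", "adjusted_p", "significant"]
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = np.nan
    for ont in table["ontology_class"].unique():
        mask = table["ontology_class"] == ont
        table.loc[mask, "adjusted_p"] = bh_adjust(table.loc[mask, "p_value"].to_numpy())
    table["significant"] = table["adjusted_p"] < alpha
    return table.sort_values(["ontology_class", "adjusted_p", "term_id"]).reset_index(drop=True)


def unique_terms(
    high_results: pd.DataFrame,
    low_results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop terms significant in both constraint lists; flag the rest unique.

    A term significant (adjusted p < alpha) in both the highly- and
    lowly-constrained results is removed from both outputs; each output
    keeps only its remaining significant terms, flagged ``unique=True``.
    """

    def sig_terms(table: pd.DataFrame) -> set[tuple[str, str]]:
        s = table[table["adjusted_p"] < alpha]
        return set(zip(s["ontology_class"], s["term_id"]))

    shared = sig_terms(high_results) & sig_terms(low_results)

    def filtered(table: pd.DataFrame) -> pd.DataFrame:
        sig = table[table["adjusted_p"] < alpha].copy()
        keys = list(zip(sig["ontology_class"], sig["term_id"]))
        keep = [key not in shared for key in keys]
        out = sig[keep].copy()
        out["unique"] = True
        return out.reset_index(drop=True)

    return filtered(high_results), filtered(low_results)
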