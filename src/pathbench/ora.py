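"""Overrepresentation analysis and shared multiple-testing corrections.

The test is a one-sided Fisher's exact test for enrichment: the p-value is
the upper hypergeometric tail P(X >= overlap) of the 2x2 table crossing
query membership with pathway membership inside a fixed gene universe.
False-discovery control defaults to Benjamini-Yekutieli, which remains
valid under the arbitrary dependence induced by overlapping pathways;
Bonferroni and Benjamini-Hochberg are exposed for the procedures that use
them elsewhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

logger = logging.getLogger(__name__)

_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by"}


def adjust(p_values, method: str = "by") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``method`` is one of ``bonferroni``, ``bh`` (Benjamini-Hochberg) or
    ``by`` (Benjamini-Yekutieli).  Output is aligned to input order and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    return multipletests(p, method=_METHODS[method])[1]


def fisher_ora(
    query: set[str],
    gene_sets: list[GeneSet],
    universe: set[str],
    method: str = "by",
    odds_ratio: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation test for each gene set.

    Parameters
    ----------
    query
        Genes of interest (e.g. upstream-significant DE genes); must be a
        subset of ``universe``.
    gene_sets
        Pathway gene sets; each is intersected with the universe before
        testing, and sets with no gene in the universe are skipped.
    universe
        The measurable gene background (by default the genes of the scored
        table upstream).
    odds_ratio
        When set, also report the sample odds ratio with Haldane's 0.5
        correction.

    Returns a frame sorted by raw p with columns ``pathway_id, overlap,
    pathway_size, query_size, universe_size, p_raw, q_value`` (plus
    ``odds_ratio`` on request).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {missing}")

    M, n_query = len(universe), len(query)
    rows = []
    for gs in gene_sets:
        in_universe = gs.genes & universe
        if not in_universe:
            logger.warning("pathway %s has no gene in the universe; skipped", gs.pathway_id)
            continue
        K = len(in_universe)
        k = len(in_universe & query)
        # upper tail P(X >= k) for X ~ Hypergeom(M, K, n_query)
        p = float(hypergeom.sf(k - 1, M, K, n_query))
        row = {
            "pathway_id": gs.pathway_id,
            "overlap": k,
            "pathway_size": K,
            "query_size": n_query,
            "universe_size": M,
            "p_raw": min(p, 1.0),
        }
        if odds_ratio:
            a = k + 0.5
            b = (n_query - k) + 0.5
            c = (K - k) + 0.5
            d = (M - K - n_query + k) + 0.5
            row["odds_ratio"] = (a * d) / (b * c)
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["pathway_id", "overlap", "pathway_size", "query_size",
                     "universe_size", "p_raw", "q_value"]
        )
    frame = pd.DataFrame(rows)
    frame["q_value"] = adjust(frame["p_raw"].to_numpy(), method=method)
    frame = frame.sort_values(
        ["p_raw", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with ``q_value`` below ``alpha``, order preserved."""
    return results[results["q_value"] < alpha].reset_index(drop=True)
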