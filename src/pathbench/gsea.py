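"""Preranked gene-set enrichment and single-sample pathway activity.

The enrichment score (ES) of a gene set against a ranked gene list is the
maximum-magnitude deviation of a running sum that increases by the
normalized score weight ``|s|^w`` at each in-set gene ("hit") and
decreases by ``1/(N - N_h)`` at each out-of-set gene ("miss").  The
permutation null draws random same-size gene sets from the ranked list;
NES divides the observed ES by the mean magnitude of same-sign null ES
values, and the FDR follows the standard NES-pooling procedure.

ssGSEA scores a single sample by replacing the preranked scores with the
sample's within-sample expression ranks raised to ``alpha``, and summing
the running difference between the weighted in-set and uniform out-of-set
empirical distribution functions.  Scores depend on ranks only, so they
are invariant under any strictly monotone transform of the expression
values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSet, ScoredGeneTable

logger = logging.getLogger(__name__)


def _as_ranked(ranked) -> pd.Series:
    """Coerce input to a descending-sorted score series (ties: gene asc)."""
    if isinstance(ranked, ScoredGeneTable):
        return ranked.ranked()
    series = pd.Series(ranked, dtype=float)
    if series.index.has_duplicates:
        raise ValueError("duplicate gene symbols in ranked list")
    order = sorted(series.index, key=lambda g: (-series[g], g))
    return series.loc[order]


def enrichment_score(ranked, gene_set, weight: float = 1.0):
    """Running-sum enrichment score of ``gene_set`` against a ranked list.

    Parameters
    ----------
    ranked
        Mapping gene -> score; sorted descending internally.
    gene_set
        A :class:`~pathbench.io.GeneSet` or a plain set of gene symbols.
    weight
        Exponent on ``|score|`` for hit increments; 0 gives the unweighted
        Kolmogorov-Smirnov walk, 1 the conventional weighting.

    Returns ``(es, running_sum)`` with ``es`` in [-1, 1].
    """
    series = _as_ranked(ranked)
    members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    genes = series.index.to_numpy()
    scores = series.to_numpy()
    hit = np.fromiter((g in members for g in genes), bool, len(genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no gene in the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the entire ranked list; miss step undefined")
    w = np.abs(scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all in-set scores are zero: fall back to equal steps
        w_hit = hit.astype(float)
        total = float(n_hit)
    increments = w_hit / total - (~hit) / (len(genes) - n_hit)
    running = np.cumsum(increments)
    top, bottom = running.max(), running.min()
    # magnitude ties (within fp noise) resolve to the positive extremum
    es = float(np.clip(top if top >= -bottom - 1e-12 else bottom, -1.0, 1.0))
    return es, running


def _null_es(positions: np.ndarray, w_abs: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorized ES for many same-size gene sets given by sorted positions.

    Between hits the running sum falls linearly, so its extrema occur at
    hit positions (just after the hit), just before hits, or at the final
    position (where it is exactly 0).
    """
    k = positions.shape[1]
    weights = w_abs[positions]
    cum = np.cumsum(weights, axis=1)
    total = cum[:, -1:]
    degenerate = total[:, 0] == 0
    if degenerate.any():
        weights = np.where(degenerate[:, None], 1.0, weights)
        cum = np.cumsum(weights, axis=1)
        total = cum[:, -1:]
    misses = (positions - np.arange(k)) / (n_genes - k)
    after = cum / total - misses
    before = (cum - weights) / total - misses
    before[positions == np.arange(k)] = 0.0  # no running value before the start
    top = np.maximum(after.max(axis=1), 0.0)
    bottom = np.minimum(before.min(axis=1), 0.0)
    return np.clip(np.where(top >= -bottom - 1e-12, top, bottom), -1.0, 1.0)


def preranked_gsea(
    ranked,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 10,
    max_size: int = 3000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Set sizes are computed after intersecting with the ranked genes and
    filtered to ``[min_size, max_size]``.  The null draws ``n_perm``
    uniform same-size gene sets (without replacement) from the ranked
    list.  Raw p is the same-sign tail fraction of the null, floored at
    ``1/(n_perm + 1)`` so that zero is never reported.

    Returns a frame with ``pathway_id, es, nes, p_raw, fdr,
    set_size_used, direction`` (direction = sign of NES).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} is below the floor of 100 permutations")
    series = _as_ranked(ranked)
    genes = series.index.to_numpy()
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    w_abs = np.abs(series.to_numpy()) ** weight
    rng = np.random.default_rng(seed)

    surviving = []
    for gs in gene_sets:
        pos = np.array(sorted(gene_pos[g] for g in gs.genes if g in gene_pos), dtype=int)
        if min_size <= len(pos) <= max_size and len(pos) < n_genes:
            surviving.append((gs, pos))
        elif 0 < len(pos) < min_size or len(pos) > max_size:
            logger.debug("set %s (size %d) outside size window", gs.pathway_id, len(pos))
    if not surviving:
        logger.warning("no gene set survived the size filter")
        return pd.DataFrame(
            columns=["pathway_id", "es", "nes", "p_raw", "fdr", "set_size_used", "direction"]
        )

    rows = []
    null_nes_pool: list[np.ndarray] = []
    floor = 1.0 / (n_perm + 1)
    for gs, pos in surviving:
        es = float(_null_es(pos[None, :], w_abs, n_genes)[0])
        draws = np.argpartition(
            rng.random((n_perm, n_genes)), len(pos) - 1, axis=1
        )[:, : len(pos)]
        draws.sort(axis=1)
        null = _null_es(draws, w_abs, n_genes)

        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        null_nes = np.concatenate([
            pos_null / mean_pos if pos_null.size else pos_null,
            neg_null / mean_neg if neg_null.size else neg_null,
        ])
        null_nes_pool.append(null_nes)

        if es > 0:
            same = pos_null
            nes = es / mean_pos if pos_null.size else 0.0
        elif es < 0:
            same = np.abs(neg_null)
            nes = -abs(es) / mean_neg if neg_null.size else 0.0
        else:
            same = np.array([])
            nes = 0.0
        if es == 0:
            p_raw = 1.0
        elif same.size == 0:
            p_raw = floor
        else:
            hits = int((same >= abs(es)).sum())
            p_raw = max(hits / same.size, floor) if hits else floor
        rows.append(
            {
                "pathway_id": gs.pathway_id,
                "es": es,
                "nes": float(nes),
                "p_raw": min(p_raw, 1.0),
                "set_size_used": len(pos),
                "direction": int(np.sign(nes)),
            }
        )

    frame = pd.DataFrame(rows)
    frame["fdr"] = _gsea_fdr(frame["nes"].to_numpy(), np.concatenate(null_nes_pool))
    frame = frame.sort_values(["p_raw", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return frame[["pathway_id", "es", "nes", "p_raw", "fdr", "set_size_used", "direction"]]


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Standard pooled-NES FDR: tail fraction in the null over tail fraction observed."""
    fdr = np.ones_like(obs_nes, dtype=float)
    pos_null, neg_null = null_nes[null_nes >= 0], null_nes[null_nes < 0]
    pos_obs, neg_obs = obs_nes[obs_nes >= 0], obs_nes[obs_nes < 0]
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            num = (pos_null >= nes).mean() if pos_null.size else 1.0
            den = (pos_obs >= nes).mean() if pos_obs.size else 1.0
        else:
            num = (neg_null <= nes).mean() if neg_null.size else 1.0
            den = (neg_obs <= nes).mean() if neg_obs.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    return fdr


def ssgsea_sample(
    expression,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    min_size: int = 1,
) -> pd.Series:
    """ssGSEA pathway-activity scores for one sample.

    Genes are ranked within the sample (descending expression, average
    ranks for ties); the score of a set is the sum over the ranked walk
    of the difference between the rank-weighted in-set ECDF (exponent
    ``alpha``) and the uniform out-of-set ECDF.
    """
    values = pd.Series(expression, dtype=float)
    if values.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression column")
    n_genes = len(values)
    if values.nunique() == 1:
        logger.warning("all-constant expression column; ssGSEA scores are unstable")
    # rank 1 = lowest expression, so higher expression -> larger weight
    ranks = rankdata(values.to_numpy(), method="average")
    order = sorted(range(n_genes), key=lambda i: (-values.iloc[i], values.index[i]))
    walk_genes = values.index.to_numpy()[order]
    walk_weights = ranks[order] ** alpha
    gene_row = {g: i for i, g in enumerate(walk_genes)}

    scores = {}
    for gs in gene_sets:
        pos = [gene_row[g] for g in gs.genes if g in gene_row]
        if len(pos) < min_size or len(pos) == 0:
            logger.warning("set %s has <%d genes in the sample; skipped", gs.pathway_id, min_size)
            continue
        if len(pos) == n_genes:
            raise ValueError(f"set {gs.pathway_id} covers every measured gene")
        hit = np.zeros(n_genes, dtype=bool)
        hit[pos] = True
        w_in = np.where(hit, walk_weights, 0.0)
        ecdf_in = np.cumsum(w_in) / w_in.sum()
        ecdf_out = np.cumsum(~hit) / (n_genes - len(pos))
        scores[gs.pathway_id] = float(np.sum(ecdf_in - ecdf_out))
    return pd.Series(scores, name="activity")


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
    min_size: int = 1,
) -> pd.DataFrame:
    """Sample-by-pathway activity matrix from per-column ssGSEA.

    With ``normalize`` on, all scores are divided by the single global
    score range of the matrix, preserving cross-sample comparability.
    """
    if expression.empty:
        raise ValueError("empty expression matrix")
    columns = {
        sample: ssgsea_sample(expression[sample], gene_sets, alpha=alpha, min_size=min_size)
        for sample in expression.columns
    }
    activity = pd.DataFrame(columns).T  # samples x pathways
    if activity.isna().to_numpy().any():
        raise ValueError("inconsistent pathway coverage across samples")
    if normalize:
        span = float(activity.to_numpy().max() - activity.to_numpy().min())
        if span > 0:
            activity = activity / span
    activity.attrs["alpha"] = alpha
    activity.attrs["normalized"] = normalize
    return activity
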