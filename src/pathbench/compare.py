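"""Quantify cross-database disagreement between enrichment results.

For every pair of databases, the pathway analogs shared by both (via the
mapping catalog) are ranked by their raw enrichment p-values within the
paired subset, and the two rank lists are compared with a Wilcoxon
signed-rank test.  Ranking within the analog subset (rather than each
full result list) avoids biases from unequal database sizes; full-list
ranking is available for sensitivity analysis.  Where the method reports
a direction (NES sign for GSEA, activated/inhibited for the topology
analysis), directional concordance of each analog pair is tabulated.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .merge import MappingCatalog

logger = logging.getLogger(__name__)


@dataclass
class WilcoxonResult:
    """Two-sided signed-rank test outcome.

    ``statistic`` is W+, the sum of ranks of positive differences (so
    reversing every pair mirrors it onto W-).  ``degenerate`` flags the
    all-zero-differences case, where no test is possible and p = 1.
    """

    statistic: float
    p_value: float
    n_used: int
    n_zeros_dropped: int
    degenerate: bool = False


def wilcoxon_signed_rank(x, y=None, exact_limit: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (their count is reported).  Up to
    ``exact_limit`` non-zero differences the p-value is exact, from the
    full distribution of the positive rank sum over all 2^n sign
    assignments (tied absolute differences get average ranks); above it a
    normal approximation with continuity and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    diffs = x if y is None else x - np.asarray(y, dtype=float)
    n_zeros = int(np.sum(diffs == 0))
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return WilcoxonResult(math.nan, 1.0, 0, n_zeros, degenerate=True)
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= exact_limit:
        p = _exact_two_sided(ranks, w_plus)
    else:
        p = _approx_two_sided(diffs, ranks, w_plus)
    return WilcoxonResult(w_plus, p, n, n_zeros)


def _exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    # doubling makes tied (half-integer) average ranks integral
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2 * min(lower, upper)))


def _approx_two_sided(diffs, ranks, w_plus) -> float:
    n = len(diffs)
    mean = n * (n + 1) / 4
    variance = n * (n + 1) * (2 * n + 1) / 24
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    variance -= np.sum(tie_counts**3 - tie_counts) / 48
    if variance <= 0:
        return 1.0
    shift = w_plus - mean
    z = (shift - 0.5 * np.sign(shift)) / math.sqrt(variance)
    return float(min(1.0, 2 * norm.sf(abs(z))))


def _directions(results: pd.DataFrame) -> pd.Series | None:
    """Normalize a direction column to signs; None when the method has none."""
    if "status" in results.columns:
        return results.set_index("pathway_id")["status"].map(
            {"activated": 1, "inhibited": -1}
        )
    if "direction" in results.columns:
        return results.set_index("pathway_id")["direction"].astype(int)
    return None


def collect_analog_pairs(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    catalog: MappingCatalog,
    subset_ranking: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Pair up analog pathways present in both result tables.

    Both frames need ``pathway_id`` and ``p_raw`` columns.  Returns the
    pair table and the number of equivalence classes excluded because a
    result was missing on either side.  Ranks are average-tie ranks of
    raw p-values, computed within the paired subset by default or within
    each full result list with ``subset_ranking=False``.
    """
    p_a = results_a.set_index("pathway_id")["p_raw"]
    p_b = results_b.set_index("pathway_id")["p_raw"]
    dir_a, dir_b = _directions(results_a), _directions(results_b)

    rows, excluded = [], 0
    for cls in catalog.classes:
        ids_a = [p for p in sorted(cls) if p in p_a.index]
        ids_b = [p for p in sorted(cls) if p in p_b.index]
        if len(ids_a) != 1 or len(ids_b) != 1:
            excluded += 1
            continue
        id_a, id_b = ids_a[0], ids_b[0]
        rows.append(
            {
                "class_id": min(cls),
                "pathway_id_a": id_a,
                "pathway_id_b": id_b,
                "p_raw_a": float(p_a[id_a]),
                "p_raw_b": float(p_b[id_b]),
                "direction_a": int(dir_a[id_a]) if dir_a is not None else None,
                "direction_b": int(dir_b[id_b]) if dir_b is not None else None,
            }
        )
    if not rows:
        logger.warning("no equivalence class has results in both databases")
        return pd.DataFrame(
            columns=["class_id", "pathway_id_a", "pathway_id_b", "p_raw_a",
                     "p_raw_b", "direction_a", "direction_b", "rank_a", "rank_b"]
        ), excluded
    pairs = pd.DataFrame(rows)
    if subset_ranking:
        pairs["rank_a"] = rankdata(pairs["p_raw_a"])
        pairs["rank_b"] = rankdata(pairs["p_raw_b"])
    else:
        full_a = pd.Series(rankdata(p_a), index=p_a.index)
        full_b = pd.Series(rankdata(p_b), index=p_b.index)
        pairs["rank_a"] = pairs["pathway_id_a"].map(full_a)
        pairs["rank_b"] = pairs["pathway_id_b"].map(full_b)
    return pairs, excluded


def direction_concordance(pairs: pd.DataFrame) -> dict:
    """Count direction-concordant and -discordant analog pairs.

    Returns ``{"applicable": False}`` for methods without a direction
    (e.g. overrepresentation analysis).
    """
    if pairs.empty or pairs["direction_a"].isna().all() or pairs["direction_b"].isna().all():
        return {"applicable": False}
    discordant = pairs[
        np.sign(pairs["direction_a"].astype(float))
        != np.sign(pairs["direction_b"].astype(float))
    ]
    return {
        "applicable": True,
        "n_concordant": int(len(pairs) - len(discordant)),
        "n_discordant": int(len(discordant)),
        "discordant_ids": sorted(discordant["class_id"]),
    }


def compare_databases(
    results_by_db: dict[str, pd.DataFrame],
    catalog: MappingCatalog,
    method: str = "",
    subset_ranking: bool = True,
) -> pd.DataFrame:
    """Full pairwise comparison report over all database pairs.

    One row per unordered database pair: number of analog pairs, the
    signed-rank statistic and p-value on the p-value ranks, and the
    direction-discordance tally where applicable.
    """
    rows = []
    for db_a, db_b in itertools.combinations(sorted(results_by_db), 2):
        pairs, excluded = collect_analog_pairs(
            results_by_db[db_a], results_by_db[db_b], catalog,
            subset_ranking=subset_ranking,
        )
        if pairs.empty:
            continue
        test = wilcoxon_signed_rank(
            pairs["rank_a"].to_numpy(), pairs["rank_b"].to_numpy()
        )
        concordance = direction_concordance(pairs)
        rows.append(
            {
                "method": method,
                "database_a": db_a,
                "database_b": db_b,
                "n_pairs": len(pairs),
                "n_excluded_classes": excluded,
                "statistic": test.statistic,
                "p_value": test.p_value,
                "degenerate": test.degenerate or test.n_used == 0,
                "n_discordant": concordance.get("n_discordant"),
                "discordant_ids": "|".join(concordance.get("discordant_ids", []))
                if concordance["applicable"] else None,
            }
        )
    return pd.DataFrame(rows)
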