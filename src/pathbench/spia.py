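"""Topology-based pathway enrichment via signed perturbation propagation.

Each pathway network is encoded as a matrix B whose entry (u, g) sums the
signed weights of edges u -> g (activation +1, inhibition -1) divided by
the out-degree of u.  The perturbation factor of every gene solves

    PF(g) = dE(g) + sum_u B[u, g] * PF(u)

where dE holds the observed log fold changes of the upstream-significant
genes (zero elsewhere).  The net accumulated perturbation is
tA = sum_g (PF(g) - dE(g)); its sign gives the activated/inhibited call.
Two evidences are combined: pNDE, a hypergeometric test for
overrepresentation of DE genes on the pathway, and pPERT, a bootstrap
tail probability of tA under random reassignment of the observed fold
changes to pathway genes.  The global p is pG = c - c*ln(c) with
c = pNDE * pPERT, Bonferroni-corrected over the evaluable pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import PathwayNetwork

logger = logging.getLogger(__name__)

#: Signed weight per relation type; configurable for richer vocabularies.
DEFAULT_BETA = {"activation": 1.0, "inhibition": -1.0}

#: Condition-number threshold above which the linear system is deemed singular.
CONDITION_LIMIT = 1e12


class SingularNetworkError(ValueError):
    """The perturbation linear system is numerically singular."""


@dataclass
class BetaMatrix:
    """Signed, out-degree-normalized adjacency of one pathway network."""

    pathway_id: str
    genes: tuple[str, ...]
    matrix: np.ndarray  # entry [u, g] = sum of beta(u->g) / out_degree(u)


def build_beta(
    network: PathwayNetwork, beta: dict[str, float] | None = None
) -> BetaMatrix:
    """Encode a signed network; opposing parallel edges sum (and may cancel)."""
    if not network.nodes:
        raise ValueError(f"network {network.pathway_id} is empty")
    weights = DEFAULT_BETA if beta is None else beta
    genes = tuple(sorted(network.nodes))
    index = {g: i for i, g in enumerate(genes)}
    out_degree = np.zeros(len(genes))
    for source, _, _ in network.edges:
        out_degree[index[source]] += 1
    matrix = np.zeros((len(genes), len(genes)))
    for source, target, relation in network.edges:
        u = index[source]
        matrix[u, index[target]] += weights[relation] / out_degree[u]
    return BetaMatrix(pathway_id=network.pathway_id, genes=genes, matrix=matrix)


def perturbation_factors(beta: BetaMatrix, delta_e: np.ndarray) -> np.ndarray:
    """Solve PF = dE + B^T PF for the per-gene perturbation factors.

    Raises :class:`SingularNetworkError` when (I - B^T) is numerically
    singular (e.g. a cycle with unit gain).
    """
    n = len(beta.genes)
    system = np.eye(n) - beta.matrix.T
    if np.linalg.cond(system) > CONDITION_LIMIT:
        raise SingularNetworkError(
            f"pathway {beta.pathway_id}: perturbation system is singular"
        )
    return np.linalg.solve(system, np.asarray(delta_e, dtype=float))


def net_accumulation(beta: BetaMatrix, delta_e: np.ndarray) -> float:
    """Total net accumulated perturbation tA = sum(PF - dE)."""
    pf = perturbation_factors(beta, delta_e)
    return float(np.sum(pf - delta_e))


def _accumulation_vector(beta: BetaMatrix) -> np.ndarray:
    """Vector v with tA = v . dE, exploiting linearity of the solve."""
    n = len(beta.genes)
    system = np.eye(n) - beta.matrix.T
    if np.linalg.cond(system) > CONDITION_LIMIT:
        raise SingularNetworkError(
            f"pathway {beta.pathway_id}: perturbation system is singular"
        )
    inverse = np.linalg.inv(system)
    return inverse.sum(axis=0) - 1.0


def combine_p(p_nde: float, p_pert: float) -> float:
    """Fisher-product combination pG = c - c*ln(c), c = pNDE*pPERT, in (0, 1]."""
    c = p_nde * p_pert
    if c <= 0:
        raise ValueError("component p-values must be positive")
    if c >= 1:
        return 1.0
    return float(min(1.0, c - c * np.log(c)))


def spia_pathway(
    network: PathwayNetwork,
    de_table: pd.Series,
    all_genes: set[str],
    n_boot: int = 2000,
    seed: int | None = None,
    beta: dict[str, float] | None = None,
) -> dict:
    """Run the perturbation analysis for one pathway.

    Parameters
    ----------
    de_table
        Gene -> log fold change for the upstream-significant DE genes only.
    all_genes
        The measurable gene universe for the overrepresentation component.
    n_boot
        Bootstrap resamples for pPERT (minimum 200).

    Returns a result record; a pathway without DE genes yields tA = 0,
    pNDE = pPERT = 1.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot={n_boot} is below the floor of 200")
    rng = np.random.default_rng(seed)
    bmat = build_beta(network, beta=beta)
    genes = bmat.genes
    pathway_in_universe = [g for g in genes if g in all_genes]
    de_genes = [g for g in genes if g in de_table.index]
    n_de = len(de_genes)

    M = len(all_genes)
    K = len(set(de_table.index) & all_genes)
    n = len(pathway_in_universe)
    p_nde = float(hypergeom.sf(n_de - 1, M, K, n)) if n else 1.0

    if n_de == 0:
        return {
            "pathway_id": network.pathway_id,
            "n_de_on_pathway": 0,
            "t_a": 0.0,
            "p_nde": min(p_nde, 1.0),
            "p_pert": 1.0,
            "p_g": combine_p(min(p_nde, 1.0), 1.0),
            "status": "inhibited",
        }

    acc = _accumulation_vector(bmat)
    gene_index = {g: i for i, g in enumerate(genes)}
    delta_obs = np.zeros(len(genes))
    for g in de_genes:
        delta_obs[gene_index[g]] = de_table[g]
    t_obs = float(acc @ delta_obs)

    values = de_table.to_numpy(dtype=float)
    replace_values = values.size < n_de
    t_null = np.empty(n_boot)
    for b in range(n_boot):
        targets = rng.choice(len(genes), size=n_de, replace=False)
        drawn = rng.choice(values, size=n_de, replace=replace_values)
        t_null[b] = acc[targets] @ drawn
    center = float(np.median(t_null))
    tail = int(np.sum(np.abs(t_null - center) >= abs(t_obs - center)))
    p_pert = tail / n_boot if tail else 1.0 / (n_boot + 1)

    p_g = combine_p(min(p_nde, 1.0), min(p_pert, 1.0))
    return {
        "pathway_id": network.pathway_id,
        "n_de_on_pathway": n_de,
        "t_a": t_obs,
        "p_nde": min(p_nde, 1.0),
        "p_pert": min(p_pert, 1.0),
        "p_g": p_g,
        "status": "activated" if t_obs > 0 else "inhibited",
    }


def spia_all(
    networks: list[PathwayNetwork],
    de_table: pd.Series,
    all_genes: set[str],
    n_boot: int = 2000,
    seed: int | None = None,
    beta: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Run the analysis over many pathways with Bonferroni-corrected pG.

    Numerically singular networks are skipped with a warning and excluded
    from the Bonferroni multiplier.  Results are sorted by pG.
    """
    if not networks:
        raise ValueError("no pathway networks supplied")
    seeds = np.random.SeedSequence(seed).spawn(len(networks))
    rows = []
    for network, child in zip(networks, seeds):
        try:
            rows.append(
                spia_pathway(
                    network, de_table, all_genes,
                    n_boot=n_boot,
                    seed=np.random.default_rng(child),
                    beta=beta,
                )
            )
        except SingularNetworkError:
            logger.warning("pathway %s skipped: singular system", network.pathway_id)
    if not rows:
        raise ValueError("no pathway was evaluable")
    frame = pd.DataFrame(rows)
    frame["p_g_adjusted"] = np.minimum(1.0, frame["p_g"] * len(frame))
    frame = frame.sort_values(["p_g", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return frame
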