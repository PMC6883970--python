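"""Synthetic multi-database pathway resources with planted signal.

The generator emulates the statistical structure of the real inputs the
toolkit consumes: three pathway databases whose analog pathways share a
configurable fraction of genes (with some classes spanning all three
databases, i.e. super-pathway structure), random-DAG signed topologies
per pathway, a gene-by-sample expression matrix in which the genes of a
planted pathway are mean-shifted in the case group (with subtypes planted
as distinct additional pathway shifts), and exponential
proportional-hazards survival times driven by pathway activity with
independent exponential censoring calibrated to a target censoring rate.

Everything is deterministic under the configuration seed; the three
stages draw from independent child streams of it so adding samples never
reshuffles the databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import ttest_ind

from .io import GeneSet, PathwayNetwork, ScoredGeneTable
from .merge import MappingCatalog
from .ora import adjust

logger = logging.getLogger(__name__)

DATABASES = ("kegg", "reactome", "wikipathways")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``effect_size`` is the mean shift of planted-pathway genes in the case
    group, in units of the per-gene noise SD; ``gene_overlap_fraction`` is
    the fraction of genes analog pathways share.
    """

    seed: int = 0
    n_genes: int = 2000
    n_pathways_per_db: tuple[int, int, int] = (10, 14, 12)
    pathway_size_range: tuple[int, int] = (20, 60)
    n_analog_classes: int = 4
    n_super_classes: int = 2
    gene_overlap_fraction: float = 0.6
    n_samples_per_group: int = 100
    n_subtypes: int = 4
    effect_size: float = 2.0
    noise_sd: float = 1.0
    censoring_rate: float = 0.2
    edge_probability: float = 0.15
    activation_fraction: float = 0.7

    def __post_init__(self) -> None:
        if min(self.n_pathways_per_db) < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.gene_overlap_fraction <= 1:
            raise ValueError("gene_overlap_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.pathway_size_range[0] < 2:
            raise ValueError("pathways need at least 2 genes")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway size exceeds the gene pool")


@dataclass
class SyntheticResource:
    """Three databases, their topologies, the mapping catalog, and the plant."""

    gene_sets: dict[str, list[GeneSet]]
    networks: dict[str, list[PathwayNetwork]]
    catalog: MappingCatalog
    planted_ids: tuple[str, ...] = ()
    planted_genes: frozenset[str] = frozenset()
    subtype_ids: tuple[str, ...] = ()

    def all_gene_sets(self) -> list[GeneSet]:
        return [gs for db in DATABASES for gs in self.gene_sets[db]]

    def find(self, pathway_id: str) -> GeneSet:
        for gs in self.all_gene_sets():
            if gs.pathway_id == pathway_id:
                return gs
        raise KeyError(pathway_id)


def _random_dag(pathway_id, database, genes, rng, edge_probability, activation_fraction):
    order = list(genes)
    rng.shuffle(order)
    edges = set()
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            if rng.random() < edge_probability:
                relation = "activation" if rng.random() < activation_fraction else "inhibition"
                edges.add((order[i], order[j], relation))
    if not edges:
        edges.add((order[0], order[1], "activation"))
    return PathwayNetwork(
        pathway_id=pathway_id, database=database,
        nodes=frozenset(genes), edges=frozenset(edges),
    )


def make_databases(config: SimulationConfig) -> SyntheticResource:
    """Generate three toy databases with analog and super-pathway structure.

    Analog classes share ``gene_overlap_fraction`` of their genes and are
    linked in the catalog by chained pairs (so equivalence requires
    transitive closure); super classes span all three databases.  The
    planted pathway is the first super class (falling back to the first
    analog class, then the first pathway).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    lo, hi = config.pathway_size_range

    # which databases each equivalence class spans
    class_spans: list[tuple[str, ...]] = []
    for _ in range(config.n_super_classes):
        class_spans.append(DATABASES)
    for i in range(config.n_analog_classes):
        a, b = DATABASES[i % 3], DATABASES[(i + 1) % 3]
        class_spans.append(tuple(sorted((a, b))))
    demand = {db: sum(1 for span in class_spans if db in span) for db in DATABASES}
    for db, quota in zip(DATABASES, config.n_pathways_per_db):
        if demand[db] > quota:
            raise ValueError(
                f"infeasible config: {demand[db]} mapped pathways demanded from "
                f"{db} but only {quota} allotted"
            )

    counters = {db: 0 for db in DATABASES}
    gene_sets: dict[str, list[GeneSet]] = {db: [] for db in DATABASES}
    pairs: set[frozenset[str]] = set()
    class_members: list[tuple[str, ...]] = []

    def new_id(db: str) -> str:
        counters[db] += 1
        return f"{db}:P{counters[db]:03d}"

    for concept, span in enumerate(class_spans):
        size = int(rng.integers(lo, hi + 1))
        n_core = int(round(config.gene_overlap_fraction * size))
        core = set(rng.choice(genes, size=n_core, replace=False))
        members = []
        for db in span:
            fill_pool = np.array(sorted(set(genes) - core))
            fill = rng.choice(fill_pool, size=size - n_core, replace=False)
            pid = new_id(db)
            gene_sets[db].append(GeneSet(
                pathway_id=pid, name=f"concept {concept}", database=db,
                genes=frozenset(core) | frozenset(fill),
            ))
            members.append(pid)
        for a, b in zip(members, members[1:]):  # chained, closed transitively
            pairs.add(frozenset((a, b)))
        class_members.append(tuple(members))

    for db, quota in zip(DATABASES, config.n_pathways_per_db):
        while counters[db] < quota:
            size = int(rng.integers(lo, hi + 1))
            members_genes = rng.choice(genes, size=size, replace=False)
            pid = new_id(db)
            gene_sets[db].append(GeneSet(
                pathway_id=pid, name=f"{db} exclusive {counters[db]}", database=db,
                genes=frozenset(members_genes),
            ))

    networks = {
        db: [
            _random_dag(gs.pathway_id, db, sorted(gs.genes), rng,
                        config.edge_probability, config.activation_fraction)
            for gs in gene_sets[db]
        ]
        for db in DATABASES
    }
    catalog = MappingCatalog(pairs=frozenset(pairs))

    if class_members:
        planted = class_members[0]
    else:
        planted = (gene_sets[DATABASES[0]][0].pathway_id,)
    planted_genes = frozenset().union(*(
        next(gs.genes for gs in gene_sets[pid.split(":")[0]] if gs.pathway_id == pid)
        for pid in planted
    ))
    # subtype plants: exclusive pathways, disjoint from the binary plant
    mapped = {pid for members in class_members for pid in members}
    exclusives = [gs.pathway_id for db in DATABASES for gs in gene_sets[db]
                  if gs.pathway_id not in mapped]
    subtype_ids = tuple(exclusives[: config.n_subtypes])
    if len(subtype_ids) < config.n_subtypes:
        raise ValueError("infeasible config: not enough exclusive pathways for subtypes")

    return SyntheticResource(
        gene_sets=gene_sets, networks=networks, catalog=catalog,
        planted_ids=planted, planted_genes=planted_genes, subtype_ids=subtype_ids,
    )


def simulate_expression(
    config: SimulationConfig,
    resource: SyntheticResource,
    planted_genes=None,
):
    """Expression matrix with a planted group difference and subtypes.

    Baseline expression is log-normal: per-gene means uniform on [3, 8]
    in log2 space with Gaussian noise of SD ``noise_sd``; the case group
    shifts planted-pathway genes by ``effect_size * noise_sd`` in log2
    space.  Case samples are cycled through ``n_subtypes`` subtypes, each
    adding the same shift to its own (exclusive) pathway's genes.

    Returns ``(expression, labels, subtypes)``: genes x samples matrix of
    positive values, a 0/1 series over all samples, and a subtype series
    over the case samples only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if planted_genes is None:
        planted_genes = resource.planted_genes
    genes = sorted({g for gs in resource.all_gene_sets() for g in gs.genes})
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = set(planted_genes) - set(genes)
    if missing:
        raise ValueError(f"planted genes absent from the databases: {sorted(missing)[:5]}")

    n = config.n_samples_per_group
    samples = [f"normal_{i:04d}" for i in range(n)] + [f"tumor_{i:04d}" for i in range(n)]
    labels = pd.Series([0] * n + [1] * n, index=samples, name="label")

    mu = rng.uniform(3.0, 8.0, size=len(genes))
    log_expr = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n))

    shift = config.effect_size * config.noise_sd
    planted_rows = [gene_index[g] for g in sorted(planted_genes)]
    log_expr[np.ix_(planted_rows, range(n, 2 * n))] += shift

    subtype_labels = pd.Series(
        [f"S{i % config.n_subtypes}" for i in range(n)],
        index=samples[n:], name="subtype",
    )
    for k, pid in enumerate(resource.subtype_ids):
        rows = [gene_index[g] for g in sorted(resource.find(pid).genes)]
        cols = [n + i for i in range(n) if i % config.n_subtypes == k]
        log_expr[np.ix_(rows, cols)] += shift

    expression = pd.DataFrame(2.0 ** log_expr, index=genes, columns=samples)
    expression.index.name = "gene"
    return expression, labels, subtype_labels


def group_difference_scores(
    expression: pd.DataFrame,
    labels: pd.Series,
    flag_alpha: float = 0.05,
) -> ScoredGeneTable:
    """Score genes by the standardized mean difference between groups.

    Scores are per-gene standardized mean differences of log2 expression
    (case minus control over the pooled SD); the significance flag marks
    genes whose Welch t-test passes ``flag_alpha`` after BH correction.
    This stands in for an upstream differential-expression analysis.
    """
    log_expr = np.log2(expression.to_numpy(dtype=float) + 1e-9)
    mask = labels.loc[expression.columns].to_numpy() == 1
    case, control = log_expr[:, mask], log_expr[:, ~mask]
    pooled = np.sqrt((case.var(axis=1, ddof=1) + control.var(axis=1, ddof=1)) / 2)
    pooled[pooled == 0] = np.nan
    smd = (case.mean(axis=1) - control.mean(axis=1)) / pooled
    smd = np.nan_to_num(smd, nan=0.0)
    p = ttest_ind(case, control, axis=1, equal_var=False).pvalue
    p = np.nan_to_num(p, nan=1.0)
    q = adjust(p, method="bh")
    scores = pd.Series(smd, index=expression.index, name="score")
    flags = pd.Series(q < flag_alpha, index=expression.index, name="significant")
    return ScoredGeneTable(scores=scores, significant=flags)


def simulate_survival(
    config: SimulationConfig,
    activity: pd.DataFrame,
    coefficients: dict[str, float],
    baseline_rate: float = 0.1,
) -> pd.DataFrame:
    """Survival times from an exponential proportional-hazards model.

    The linear predictor is the sum of the given coefficients times the
    z-scored activity columns; event times are exponential with rate
    ``baseline_rate * exp(eta)``.  Independent exponential censoring is
    calibrated so the expected censored fraction equals
    ``config.censoring_rate``.

    Returns a frame indexed like ``activity`` with columns ``time``,
    ``event`` and ``true_risk`` (the generative linear predictor, for
    oracle checks).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    unknown = sorted(set(coefficients) - set(activity.columns))
    if unknown:
        raise ValueError(f"coefficients reference unknown pathways: {unknown}")
    eta = np.zeros(len(activity))
    for pathway, beta in coefficients.items():
        column = activity[pathway].to_numpy(dtype=float)
        sd = column.std(ddof=0)
        z = (column - column.mean()) / sd if sd > 0 else np.zeros_like(column)
        eta = eta + beta * z

    rates = baseline_rate * np.exp(eta)
    event_times = rng.exponential(1.0 / rates)
    if config.censoring_rate == 0:
        times, events = event_times, np.ones(len(eta), dtype=int)
    else:
        target = config.censoring_rate

        def censored_fraction(rate_c):
            return float(np.mean(rate_c / (rate_c + rates))) - target

        rate_c = brentq(censored_fraction, 1e-12 * baseline_rate, 1e12 * baseline_rate)
        censor_times = rng.exponential(1.0 / rate_c, size=len(eta))
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    return pd.DataFrame(
        {"time": times, "event": events, "true_risk": eta}, index=activity.index
    )
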