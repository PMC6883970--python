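# Methods

This note documents the statistical models implemented in `pathbench`,
the defaults and numerical choices that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where more than one reasonable convention exists.

## Merged pathway resource

A mapping catalog supplies unordered pairs of equivalent pathway
identifiers from *different* databases. Equivalence classes are the
connected components of the pair graph (transitive closure): a chain
KEGG↔Reactome↔WikiPathways is one class even though the KEGG–WikiPathways
pair is never stated. A class containing two pathways of the same
database is rejected as ambiguous curation.

Each class becomes one merged pathway: its gene set is the exact union
of the member gene sets, and its network the graph union of member
networks. Edges are typed by sign, so an activation and an inhibition
between the same gene pair both survive the union; such conflicting-sign
pairs are logged for curator audit (their contributions to the
perturbation analysis cancel). Unmapped pathways pass through unchanged.

Tiers: a single-member pathway is *exclusive*; a class spanning every
configured database — and at least three of them — is a *super pathway*;
any other multi-database class is an *analog*. Requiring three databases
for the super tier keeps the term aligned with its definition as a
pathway represented in all three source resources even when a user loads
only two.

Deterministic conventions: `mpath_id` is `mpath:` plus the sorted member
ids joined with `|`; the merged name is taken from the member of the
highest-priority database (default KEGG > Reactome > WikiPathways).
The output size always satisfies |merged| = Σ|db| − Σ_classes(|class|−1),
which the tests verify on randomized catalogs.

## Overrepresentation analysis

For query Q, pathway P (intersected with the universe U before testing)
and universe U, the one-sided Fisher p-value is the upper hypergeometric
tail P(X ≥ |Q∩P|) with X ~ Hypergeom(|U|, |P|, |Q|). The universe
defaults to the genes of the upstream scored table — the measurable
universe defined by the expression platform — rather than the union of
pathway genes; callers can pass any universe explicitly.

Multiple-testing corrections are delegated to statsmodels:
Benjamini–Yekutieli by default (pathway gene sets overlap heavily, so
the dependence-robust control is the appropriate one), with
Benjamini–Hochberg and Bonferroni available for the procedures that use
them. Odds ratios are not reported by default; on request the sample
odds ratio with Haldane's 0.5 correction is emitted.

## Preranked GSEA

Genes are ranked by score (descending; ties broken by gene symbol so the
walk is deterministic). The running sum steps up by |s|^w normalized
over in-set genes at hits and down by 1/(N − N_h) at misses; the
enrichment score is the extremum of largest magnitude, with magnitude
ties inside floating-point noise (1e−12) resolved to the positive
extremum. If all in-set scores are exactly zero the hit steps fall back
to equal increments. ES is clipped to [−1, 1] against round-off.

The null distribution draws `n_perm` uniform same-size gene sets from
the ranked list without replacement (gene-set permutation; phenotype
permutation is impossible for a preranked input). The raw p-value is
the same-sign tail fraction of the null and is floored at
1/(n_perm + 1) so zero is never reported. NES divides ES by the mean
magnitude of same-sign null ES values; the FDR follows the standard
pooled-NES procedure (null tail fraction over observed tail fraction,
clipped to [0, 1]). Defaults: weight w = 1, n_perm = 1000 (minimum
enforced: 100), set-size window [10, 3000] applied after intersection
with the ranked genes.

## ssGSEA

One sample is scored from its within-sample expression ranks (average
ranks for ties; an all-constant column is flagged). Walking genes in
descending expression order, the score of a set is the summed difference
between the rank-weighted in-set ECDF (weights = rank^α, α = 0.25) and
the uniform out-of-set ECDF. Scores therefore depend on ranks only and
are invariant under any strictly monotone transform of a sample's
values. Matrix-level normalization divides every score by the single
global score range, preserving cross-sample comparability.

## Topology-based perturbation analysis

Each signed network is encoded as B[u, g] = Σ_{edges u→g} β(rel)/N_ds(u)
with β(activation) = +1, β(inhibition) = −1 (the edge-list exchange
format carries only these two signs; the β table is configurable).
Perturbation factors solve the linear system PF = ΔE + Bᵀ PF, where ΔE
holds the log fold changes of upstream-significant genes and zero
elsewhere. The solve is attempted for cyclic networks too; only systems
whose condition number exceeds 1e12 (e.g. unit-gain cycles) are skipped
and excluded from the Bonferroni multiplier. t_A = Σ(PF − ΔE) is linear
in ΔE, which the bootstrap exploits: t_A = v·ΔE for a precomputed
vector v, so each resample is a dot product.

Evidence combination: p_NDE is the hypergeometric upper tail for DE-gene
overrepresentation on the pathway; p_PERT is the two-sided bootstrap
tail probability of |t_A − median(null)| under re-assignment of the
observed number of DE fold-change values (drawn from the global DE
table, without replacement when enough values exist) to uniformly chosen
pathway genes, floored at 1/(n_boot + 1); p_G = c − c·ln c with
c = p_NDE·p_PERT, clamped to (0, 1]. Default n_boot = 2000 (floor 200).
Status is *activated* iff t_A > 0.

## Analog comparison

For a database pair, every equivalence class with exactly one result on
each side yields an analog pair; classes with a missing result are
excluded and counted. Raw p-values are ranked (average ranks for ties)
within the paired subset by default — ranking within the full result
lists would reintroduce the database-size bias the analog restriction is
meant to remove — with full-list ranking available for sensitivity
analysis. The rank lists are compared with a two-sided Wilcoxon
signed-rank test: zero differences are dropped and counted; up to 25
non-zero differences the p-value is exact, computed by dynamic
programming over the distribution of the positive rank sum across all
2^n sign assignments (tied ranks handled by doubling to integers);
beyond that a normal approximation with continuity and tie correction is
used. The reported statistic is W+, so reversing every pair mirrors it.
An all-zero comparison (identical gene sets on both sides) is flagged as
degenerate with p = 1.

## Predictive tasks

All three tasks share the nested design: an outer repeated stratified
k-fold loop (default 10 repeats × 10 folds) scores held-out folds only;
hyperparameters are selected by an inner 5-fold CV on the training
folds; feature standardization is fitted on training folds only.
Degenerate folds (single-class, event-free, or no comparable survival
pair) are skipped with a warning rather than failing the run.

- **Binary**: elastic-net logistic regression (saga solver), grid
  l1-ratio ∈ {0.1, 0.3, 0.5, 0.7, 0.9} × C ∈ 10^{−2..2} (5 points),
  inner scoring by AUC; held-out AUC and average precision reported.
- **Subtype**: linear SVM with native one-vs-one pair voting, grid
  C ∈ {0.01, 0.1, 1, 10, 100}, inner scoring by accuracy; held-out
  accuracy and macro-averaged precision/recall (macro because the paper
  leaves the averaging unspecified and subtype classes are imbalanced).
- **Survival**: elastic-net Cox model (coordinate-descent Coxnet), grid
  l1-ratio as above × penalty strength 10^{−3..0} (5 points); outer and
  inner folds stratified on the event flag; held-out Harrell c-index.

Harrell's c-index is computed by direct pair counting: a pair is
comparable iff the earlier time carries an observed event (equal times
are never comparable); the earlier-failing sample should have the higher
risk; risk ties count 0.5. The grids are package choices — the elastic
nets' original description names only the penalty pair without values.

Database impact: the per-fold metrics feed the two-way fixed-effects
ANOVA `performance ~ C(database) * C(dataset)` (statsmodels OLS, type-II
table; the designs are balanced, where type I and II coincide), with the
F-test on the database main effect, plus pairwise Mann–Whitney rank-sum
tests between databases (unpaired, since fold compositions differ) with
BH correction.

## Synthetic data

The generator emulates the statistical structure of the real inputs:

- **Databases**: three resources ("kegg", "reactome", "wikipathways")
  with configurable pathway counts (default 10/14/12 — the real
  resources differ in size) and pathway sizes uniform on [20, 60].
  Analog classes share a configurable fraction of genes (default 0.6)
  and are linked by chained catalog pairs so closure is exercised;
  super classes span all three databases. Topologies are random DAGs
  over each pathway's genes (edge probability 0.15, 70% activations).
- **Expression**: per-gene log2 means uniform on [3, 8] with Gaussian
  noise (SD 1.0); the case group shifts the planted pathway's genes by
  `effect_size` × noise SD (default 2.0 — a strong, clearly detectable
  signal appropriate for a recovery benchmark); four planted subtypes
  (mirroring the four agreed-upon breast-cancer intrinsic subtypes in
  shape only) each shift one additional exclusive pathway within the
  case group. Values are exponentiated to positive scale; downstream
  scoring is rank-based, so only the order matters.
- **Scored genes**: standardized mean differences of log2 expression
  between groups, flagged by Welch t-test with BH at 0.05 — a
  deliberate stand-in for an upstream differential-expression pipeline,
  which is out of scope.
- **Survival**: exponential proportional hazards with rate
  0.1·exp(β·z-scored activity); independent exponential censoring with
  its rate solved numerically (Brent) so the expected censored fraction
  equals the configured rate (default 0.2).

The three stages draw from independent child streams of the single
configuration seed, so enlarging the sample never reshuffles the
databases. Everything is bit-reproducible under a fixed seed.

What the generator does **not** emulate: real marginal expression
distributions, library-size or batch effects, gene–gene correlation
beyond the planted pathway structure, biologically curated topologies,
or hierarchical (parent/child) pathway relations. Passing tests
demonstrate that the machinery is correct and recovers planted signal
under the stated generative model — not that any particular biological
conclusion transfers to real cohorts.

## Problem sizes used in tests and the acceptance run

Unit and property tests run on small fixtures (universes ≤ 25 for the
exact Fisher sweep, ranked lists ≤ 20 for the ES oracle, ≤ 12 pairs for
the Wilcoxon enumeration, DAGs ≤ 10 nodes for the solver oracle). The
end-to-end recovery checks use effect size 2 with 200 samples (300 for
survival) and 3×5 repeated CV; the acceptance script uses the default
2000-gene, 36-pathway configuration with 1000 GSEA permutations, 2000
perturbation bootstraps and 2×5 repeated CV over two simulated datasets
and four resources (three databases plus the merged one). These sizes
were chosen to make every stochastic criterion stable across seeds while
keeping a full run on a single CPU in the minutes range.

## Known limitations

- The Fisher test is enrichment-only; depletion is deliberately not
  offered.
- GSEA reports no leading-edge subsets and draws its null from gene-set
  permutation only.
- The perturbation analysis collapses all relation vocabularies to the
  two signs the edge-list format carries.
- The merged resource supports equivalence mappings only — no
  similarity-inferred or hierarchical mappings.
- Identifier remapping is out of scope: gene symbols are opaque,
  case-sensitive strings assumed harmonized upstream.
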