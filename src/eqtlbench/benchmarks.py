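"""Knowledge-driven benchmarks for eQTL score profiles.

Rather than asking whether individual loci reach significance, these
benchmarks ask whether a method's high-scoring loci (the fixed-size
99th-percentile sets) systematically recover independently known biology:

* cis proportion — fraction of traits with a top-set marker near the target
  gene's own location;
* pathway enrichment — hypergeometric enrichment of top-set markers for
  markers near genes sharing a pathway with the target (or with the target's
  transcription factors), corrected against an empirical null built from
  random Gaussian score profiles, and summarized by a one-sided
  Kolmogorov-Smirnov statistic against the uniform distribution;
* mutant enrichment — whether genes near top-set markers, when experimentally
  deleted, produce large expression changes in the target (one-sided
  two-sample KS against a score-randomized null);
* method overlap — pairwise agreement of the top sets between methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seeds import derive_seed
from .io import ExpressionMatrix, GenotypeMatrix, MarkerMap
from .profiles import ScoreProfile, top_percentile, top_percentile_indices


# ---------------------------------------------------------------------------
# cis proportion

@dataclass
class CisReport:
    cis_flag: dict            # trait id -> bool
    proportion: float
    window_bp: int
    n_excluded: int = 0       # traits whose gene lacks an annotation


def cis_proportion(profiles, expression: ExpressionMatrix, genes,
                   markers: MarkerMap, window_bp: int,
                   percentile: float = 99.0) -> CisReport:
    """Fraction of traits with a top-percentile marker within ``window_bp`` of
    the target gene's midpoint (500 kb is the mouse setting, 50 kb yeast)."""
    gene_loc = {g.gene_id: (g.chromosome, g.midpoint_bp) for g in genes}
    pos_of = {m: (markers.chromosome[i], int(markers.position_bp[i]))
              for i, m in enumerate(markers.marker_id)}
    flags = {}
    excluded = 0
    for prof in profiles:
        gene = expression.gene_of_trait.get(prof.trait_id)
        if gene is None or gene not in gene_loc:
            excluded += 1
            continue
        chrom, mid = gene_loc[gene]
        hit = False
        for mk in top_percentile(prof, percentile):
            mchrom, mpos = pos_of[mk]
            if mchrom == chrom and abs(mpos - mid) <= window_bp:
                hit = True
                break
        flags[prof.trait_id] = hit
    prop = float(np.mean(list(flags.values()))) if flags else float("nan")
    return CisReport(cis_flag=flags, proportion=prop, window_bp=window_bp,
                     n_excluded=excluded)


# ---------------------------------------------------------------------------
# hypergeometric pathway enrichment

def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes this accurately
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


@dataclass
class EnrichmentContext:
    """Shared structures for the pathway enrichment test."""

    markers: MarkerMap
    pathways: dict            # pathway id -> set of gene ids
    gene2marker: dict         # gene id -> marker id (5 Mb nearest-marker rule)
    percentile: float = 99.0
    exclude_trait_gene: bool = True

    _marker_index: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self):
        self._marker_index = {m: i for i, m in enumerate(self.markers.marker_id)}

    def pathway_marker_indices(self, pathway_id: str, trait_gene: str) -> set:
        """Distinct marker indices mapped-to by a pathway's genes (the trait's
        own gene excluded, so cis hits cannot masquerade as pathway hits)."""
        out = set()
        for g in self.pathways[pathway_id]:
            if self.exclude_trait_gene and g == trait_gene:
                continue
            mk = self.gene2marker.get(g)
            if mk is not None:
                out.add(self._marker_index[mk])
        return out

    def min_p_over_pathways(self, score_idx: np.ndarray, trait_gene: str,
                            pathway_ids) -> float | None:
        """Min hypergeometric upper-tail P over the given pathways; None when
        every pathway maps to zero markers (trait skipped)."""
        N = len(self.markers)
        sel = set(int(i) for i in score_idx)
        n = len(sel)
        best = None
        for pw in pathway_ids:
            pw_idx = self.pathway_marker_indices(pw, trait_gene)
            K = len(pw_idx)
            if K == 0:
                continue
            k = len(sel & pw_idx)
            p = hypergeom_upper_p(k, K, n, N)
            if best is None or p < best:
                best = p
        return best

    def pathways_of_gene(self, gene: str) -> list:
        return [pw for pw, members in self.pathways.items() if gene in members]


def pathway_enrichment_per_trait(profile: ScoreProfile, trait_gene: str,
                                 context: EnrichmentContext) -> float | None:
    """Raw enrichment P for one trait: min over the pathways containing the
    trait's gene of the hypergeometric upper tail of top-set/pathway-marker
    overlap.  None if the gene is in no (marker-mapped) pathway."""
    pws = context.pathways_of_gene(trait_gene)
    if not pws:
        return None
    idx = top_percentile_indices(profile.scores, context.percentile)
    return context.min_p_over_pathways(idx, trait_gene, pws)


def tf_pathway_enrichment_per_trait(profile: ScoreProfile, trait_gene: str,
                                    tf_map: dict,
                                    context: EnrichmentContext) -> float | None:
    """TF-centric variant: the pathways tested are those containing any known
    transcription factor of the trait's gene."""
    tfs = tf_map.get(trait_gene)
    if not tfs:
        return None
    pws = sorted({pw for tf in tfs for pw in context.pathways_of_gene(tf)})
    if not pws:
        return None
    idx = top_percentile_indices(profile.scores, context.percentile)
    return context.min_p_over_pathways(idx, trait_gene, pws)


def null_enrichment_ps(trait_genes, context: EnrichmentContext,
                       n_null_per_trait: int = 1, seed: int = 0,
                       tf_map: dict | None = None) -> np.ndarray:
    """Null P values: random Gaussian scores over the markers, identical
    top-percentile + min-over-pathways test, per trait context."""
    p = len(context.markers)
    out = []
    for i, gene in enumerate(trait_genes):
        if tf_map is not None:
            tfs = tf_map.get(gene, set())
            pws = sorted({pw for tf in tfs for pw in context.pathways_of_gene(tf)})
        else:
            pws = context.pathways_of_gene(gene)
        if not pws:
            continue
        for r in range(n_null_per_trait):
            rng = np.random.default_rng(derive_seed(seed, "null-profile", i, r))
            scores = rng.standard_normal(p)
            idx = top_percentile_indices(scores, context.percentile)
            pval = context.min_p_over_pathways(idx, gene, pws)
            if pval is not None:
                out.append(pval)
    return np.asarray(out, dtype=float)


def empirical_null_correct(raw_ps, null_ps) -> np.ndarray:
    """Rank observed P values within the pooled empirical null:
    corrected_i = (1 + #{null <= raw_i}) / (1 + M)."""
    raw_ps = np.asarray(raw_ps, dtype=float)
    null_ps = np.sort(np.asarray(null_ps, dtype=float))
    M = null_ps.shape[0]
    if M == 0:
        raise ValueError("empty empirical null")
    counts = np.searchsorted(null_ps, raw_ps, side="right")
    return (1.0 + counts) / (1.0 + M)


def ks_uniform(values) -> tuple[float, float]:
    """One-sided KS against Uniform(0,1): D = sup_x (ECDF(x) - x), with the
    asymptotic tail p = exp(-2 n D^2)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 values")
    d_plus = np.arange(1, n + 1) / n - x
    D = float(max(0.0, d_plus.max()))
    ks_p = float(np.clip(np.exp(-2.0 * n * D * D), 0.0, 1.0))
    return D, ks_p


@dataclass
class EnrichmentSummary:
    trait_ids: list
    raw_p: np.ndarray
    corrected_p: np.ndarray
    D: float
    ks_p: float
    n_traits: int
    n_skipped: int = 0


def pathway_enrichment_summary(profiles, trait_genes, context: EnrichmentContext,
                               tf_map: dict | None = None,
                               n_null_per_trait: int = 1,
                               seed: int = 0) -> EnrichmentSummary:
    """Full pathway-enrichment benchmark over a set of traits.

    Raw min-over-pathways Ps are corrected against the pooled empirical null
    and the corrected distribution is summarized by the one-sided KS statistic
    against uniform (larger D = stronger systematic enrichment).
    """
    raw, kept_ids, kept_genes = [], [], []
    skipped = 0
    for prof, gene in zip(profiles, trait_genes):
        if tf_map is not None:
            pval = tf_pathway_enrichment_per_trait(prof, gene, tf_map, context)
        else:
            pval = pathway_enrichment_per_trait(prof, gene, context)
        if pval is None:
            skipped += 1
            continue
        raw.append(pval)
        kept_ids.append(prof.trait_id)
        kept_genes.append(gene)
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("no traits usable for the enrichment test")
    null_ps = null_enrichment_ps(kept_genes, context, n_null_per_trait, seed,
                                 tf_map=tf_map)
    corrected = empirical_null_correct(raw, null_ps)
    D, ks_p = ks_uniform(corrected)
    return EnrichmentSummary(trait_ids=kept_ids, raw_p=raw,
                             corrected_p=corrected, D=D, ks_p=ks_p,
                             n_traits=raw.size, n_skipped=skipped)


# ---------------------------------------------------------------------------
# mutant loss-of-function enrichment

@dataclass
class MutantEnrichmentResult:
    observed: np.ndarray
    null: np.ndarray
    D: float
    ks_p: float


def _mutant_values(score_idx_per_trait, trait_genes, regulators_of_marker,
                   mutant_table) -> list:
    values = []
    for idx, gene in zip(score_idx_per_trait, trait_genes):
        best = None
        for mi in idx:
            for reg in regulators_of_marker.get(int(mi), ()):
                ratio = mutant_table.get((reg, gene))
                if ratio is not None:
                    mag = abs(ratio)
                    if best is None or mag > best:
                        best = mag
        if best is not None:
            values.append(best)
    return values


def mutant_enrichment(profiles, expression: ExpressionMatrix, mutant_table,
                      gene2marker: dict, n_null: int = 1, seed: int = 0,
                      percentile: float = 99.0) -> MutantEnrichmentResult:
    """Do top-set markers sit near regulators whose deletion perturbs the target?

    Observed: per trait, over top-percentile markers that are the mapped
    marker of at least one mutated regulator, the max |log2 ratio| of that
    regulator's effect on the trait's gene.  Null: same aggregation with each
    trait's scores randomly permuted across markers, ``n_null`` times, pooled.
    One-sided two-sample KS (alternative: observed accumulates slower, i.e.
    tends to larger values): D = sup_x (F_null(x) - F_obs(x)).
    """
    if not mutant_table:
        raise ValueError("mutant effect table is empty")
    markers = profiles[0].markers
    midx = {m: i for i, m in enumerate(markers.marker_id)}
    regulators_of_marker: dict[int, list] = {}
    for reg in {r for r, _ in mutant_table}:
        mk = gene2marker.get(reg)
        if mk is not None:
            regulators_of_marker.setdefault(midx[mk], []).append(reg)

    trait_genes = [expression.gene_of_trait[p.trait_id] for p in profiles]
    obs_idx = [top_percentile_indices(p.scores, percentile) for p in profiles]
    observed = _mutant_values(obs_idx, trait_genes, regulators_of_marker,
                              mutant_table)

    p = len(markers)
    null_values: list[float] = []
    for r in range(n_null):
        perm_idx = []
        for t, prof in enumerate(profiles):
            rng = np.random.default_rng(derive_seed(seed, "mutant-null", t, r))
            perm_scores = prof.scores[rng.permutation(p)]
            perm_idx.append(top_percentile_indices(perm_scores, percentile))
        null_values.extend(_mutant_values(perm_idx, trait_genes,
                                          regulators_of_marker, mutant_table))

    if not observed or not null_values:
        raise ValueError(
            f"mutant enrichment undefined: {len(observed)} observed and "
            f"{len(null_values)} null values (need both non-empty; "
            f"{len(regulators_of_marker)} regulator markers)"
        )
    obs = np.sort(np.asarray(observed, float))
    nul = np.sort(np.asarray(null_values, float))
    grid = np.concatenate([obs, nul])
    f_obs = np.searchsorted(obs, grid, side="right") / obs.size
    f_nul = np.searchsorted(nul, grid, side="right") / nul.size
    D = float(max(0.0, (f_nul - f_obs).max()))
    ne = obs.size * nul.size / (obs.size + nul.size)
    ks_p = float(np.clip(np.exp(-2.0 * D * D * ne), 0.0, 1.0))
    return MutantEnrichmentResult(observed=obs, null=nul, D=D, ks_p=ks_p)


# ---------------------------------------------------------------------------
# method overlap

def method_overlap(profile_sets: dict) -> tuple[list, np.ndarray]:
    """Pairwise top-set agreement between methods, as a percentage.

    ``profile_sets`` maps method name -> list of per-trait top sets (same
    traits in the same order).  Per trait, overlap(A, B) =
    |A ∩ B| / ((|A| + |B|) / 2); reported averaged over traits, x100.
    """
    methods = list(profile_sets)
    n_methods = len(methods)
    mat = np.full((n_methods, n_methods), np.nan)
    for i, a in enumerate(methods):
        for j, b in enumerate(methods):
            vals = []
            for sa, sb in zip(profile_sets[a], profile_sets[b]):
                sa, sb = set(sa), set(sb)
                if not sa or not sb:
                    continue
                vals.append(len(sa & sb) / ((len(sa) + len(sb)) / 2.0))
            if vals:
                mat[i, j] = 100.0 * float(np.mean(vals))
    return methods, mat


# ---------------------------------------------------------------------------
# tree-depth and subsample studies

def tree_depth_study(expression: ExpressionMatrix, genotypes: GenotypeMatrix,
                     nodesizes, evaluate, n_trees: int = 5000,
                     null_forests: int = 500, trees_per_forest: int = 10,
                     seed: int = 0) -> dict:
    """Refit forests over a ladder of nodesizes and re-run a benchmark.

    For each nodesize the selection-frequency bias is re-estimated with a
    matching-nodesize null, every trait is mapped, and ``evaluate(profiles)``
    is called per importance measure.  Returns
    {nodesize: {measure: evaluate(...)}}; improvements are conventionally read
    against the shallowest forest (nodesize = number of strains, stump trees).
    """
    from .forest import RFConfig
    from .mapping import RandomForestMapper, estimate_sf_bias

    n = genotypes.n_strains
    results: dict = {}
    for ns in nodesizes:
        if ns > n:
            raise ValueError(f"nodesize {ns} exceeds strain count {n}")
        config = RFConfig(n_trees=n_trees, nodesize=ns)
        null_model = estimate_sf_bias(genotypes, n_forests=null_forests,
                                      trees_per_forest=trees_per_forest,
                                      config=config,
                                      seed=derive_seed(seed, "depth-null", ns))
        profiles = {"RFPI": [], "RFRSS": [], "RFSF": []}
        for t, trait_id in enumerate(expression.traits):
            est = RandomForestMapper(
                n_trees=n_trees, nodesize=ns,
                seed=derive_seed(seed, "depth-fit", ns, trait_id),
                null_model=null_model,
            ).fit(genotypes.values, expression.values[:, t])
            for measure in profiles:
                profiles[measure].append(
                    est.score_profile(trait_id, genotypes.markers, measure))
        results[ns] = {m: evaluate(profs) for m, profs in profiles.items()}
    return results


def subsample_study(genotypes: GenotypeMatrix, expression: ExpressionMatrix,
                    sizes, evaluate, seed: int = 0) -> dict:
    """Re-run mapping + benchmarks on nested strain subsets of decreasing size.

    ``evaluate(sub_genotypes, sub_expression, size)`` computes whatever
    benchmark table the caller wants; subsets are nested (each smaller subset
    is contained in the larger) and keep the original strain order, so the
    full-size subset is the original data.
    """
    n = genotypes.n_strains
    sizes = list(sizes)
    if any(s < 5 for s in sizes):
        raise ValueError("subsample sizes must be >= 5")
    if any(s > n for s in sizes):
        raise ValueError("subsample size exceeds strain count")
    if sorted(sizes, reverse=True) != sizes:
        raise ValueError("sizes must be in descending order")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    results = {}
    for size in sizes:
        idx = np.sort(perm[:size])
        sub_g = GenotypeMatrix(
            strains=[genotypes.strains[i] for i in idx],
            markers=genotypes.markers,
            values=genotypes.values[idx],
        )
        sub_e = ExpressionMatrix(
            strains=[expression.strains[i] for i in idx],
            traits=list(expression.traits),
            gene_of_trait=dict(expression.gene_of_trait),
            values=expression.values[idx],
        )
        results[size] = evaluate(sub_g, sub_e, size)
    return results
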