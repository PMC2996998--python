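"""Canonical study conditions for the benchmark battery at desk scale.

The full-size studies ran on real RI panels (thousands of markers, 22-114
strains).  These helpers pin the scaled-down synthetic conditions that the
bundled tests and the reproduction script share, so every consumer measures
the same thing:

* ``dense_panel`` — 90 strains, 500 markers at ~1 Mb spacing with tight
  linkage (adjacent-marker correlation ~0.95), emulating a dense RI marker
  map where LD blocks span many markers.  Used where LD behaviour is the
  phenomenon: the selection-frequency bias correction and the epistatic
  model comparison (broad LOD peaks crowd the fixed-size top set there).
* ``sparse_panel`` — 90 strains, 500 markers at ~2 Mb spacing and higher
  per-bp recombination (adjacent correlation ~0.6), a sparser framework map.
  Used for locus-recovery studies where each marker tags its own region.
* ``bias_panel`` — 120 strains x 600 markers, dense spacing, for the
  null-forest bias flattening study.
* ``depth_fixture_spec`` — the weak-effect fixture variant for the tree-depth
  study: trans traits are driven by a strong unannotated hub locus plus weak
  same-pathway regulators and a weak local (cis) term, so shallow forests see
  only the hub and the depth benefit is measurable.
"""

from __future__ import annotations

import numpy as np

from ._seeds import derive_seed
from .benchmarks import (
    EnrichmentContext, cis_proportion, mutant_enrichment,
    pathway_enrichment_summary, tree_depth_study,
)
from .fixtures import FixtureSpec, generate_fixture
from .forest import RFConfig
from .io import GenotypeMatrix, map_genes_to_markers
from .mapping import (
    CompositeIntervalMapper, HaleyKnottMapper, PenalizedMapper, estimate_sf_bias,
    fit_rf, map_hk, rf_importances,
)
from .profiles import ScoreProfile, top_percentile_indices
from .simulate import (
    draw_causal_loci, model_spec, run_simulation_study, simulate_ri_genotypes,
    simulate_trait,
)

DENSE_SEED = 11
SPARSE_SEED = 12
BIAS_SEED = 21


def dense_panel(seed: int = DENSE_SEED) -> GenotypeMatrix:
    return simulate_ri_genotypes(90, [(100, 100_000_000)] * 5, 1e-8, seed=seed)


def sparse_panel(seed: int = SPARSE_SEED) -> GenotypeMatrix:
    return simulate_ri_genotypes(90, [(100, 200_000_000)] * 5, 5e-8, seed=seed)


def bias_panel(seed: int = BIAS_SEED) -> GenotypeMatrix:
    return simulate_ri_genotypes(120, [(100, 100_000_000)] * 6, 1e-8, seed=seed)


def depth_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Weak-effect fixture for the tree-depth study (see module docstring)."""
    return FixtureSpec(
        seed=seed, n_genes=40, fraction_cis=0.3,
        cis_effect=0.35, hub_effect=0.8,
        weak_trans_effect=0.25, n_weak_trans=2,
        secondary_cis_effect=0.25, fraction_epistatic=0.0,
        n_regulators=8, noise_pct=2.5,
    )


def flattening_ratio(panel: GenotypeMatrix, seed: int,
                     n_forests: int = 500, trees_per_forest: int = 10) -> float:
    """Across-marker variance of a fresh null run's selection frequencies,
    raw vs bias-corrected (larger ratio = flatter corrected profile)."""
    est = estimate_sf_bias(panel, n_forests=n_forests,
                           trees_per_forest=trees_per_forest,
                           seed=derive_seed(seed, "flatten-est"))
    fresh = estimate_sf_bias(panel, n_forests=n_forests,
                             trees_per_forest=trees_per_forest,
                             seed=derive_seed(seed, "flatten-fresh"))
    raw_var = float(fresh.null_freq.var())
    corrected_var = float((fresh.null_freq - est.correction).var())
    return raw_var / corrected_var


def single_locus_recovery(panel: GenotypeMatrix, n_reps: int = 20,
                          noise_pct: float = 5.0, n_trees: int = 500,
                          seed: int = 0, null_model=None) -> dict:
    """Fraction of replicates in which each method places the causal marker
    of a single-locus trait inside the top-1% set."""
    X = panel.values
    p = panel.n_markers
    if null_model is None:
        null_model = estimate_sf_bias(panel, config=RFConfig(n_trees=n_trees),
                                      seed=derive_seed(seed, "null"))
    hits = {m: 0 for m in ("HK", "CIM", "LASSO", "ENET", "RFSF")}
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, "loci", rep))
        locus = draw_causal_loci(1, p, rng)[0]
        y = simulate_trait(model_spec("single", [locus], noise_pct), panel,
                           seed=derive_seed(seed, "trait", rep))
        def in_top(scores):
            return locus in top_percentile_indices(np.asarray(scores))
        hits["HK"] += in_top(HaleyKnottMapper().fit(X, y).scores_)
        hits["CIM"] += in_top(CompositeIntervalMapper(
            marker_map=panel.markers).fit(X, y).scores_)
        hits["LASSO"] += in_top(PenalizedMapper(
            lambda2=0.0, seed=derive_seed(seed, "cv", rep)).fit(X, y).scores_)
        hits["ENET"] += in_top(PenalizedMapper(
            lambda2=1.0, seed=derive_seed(seed, "cv", rep)).fit(X, y).scores_)
        forest = fit_rf(y, panel, RFConfig(n_trees=n_trees,
                                           seed=derive_seed(seed, "rf", rep)))
        _, _, sf_raw = rf_importances(forest, y, panel,
                                      derive_seed(seed, "perm", rep))
        hits["RFSF"] += in_top(sf_raw - null_model.correction)
    return {m: v / n_reps for m, v in hits.items()}


def epistatic_comparison(panel: GenotypeMatrix, seed: int,
                         noise_levels=(2.5, 5.0, 7.5), n_reps: int = 20,
                         n_trees: int = 500, null_model=None) -> dict:
    """Two-locus epistatic model: per noise level, do HK and bias-corrected
    RFSF place both causal loci inside the top-1% set (median criterion)?"""
    res = run_simulation_study(
        ["two_epistatic"], panel, ["HK", "RFSF"],
        noise_levels=list(noise_levels), n_reps=n_reps, seed=seed,
        rf_config=RFConfig(n_trees=n_trees), null_model=null_model)
    out = {"HK": {}, "RFSF": {}}
    for (model, method, noise), ok in res.success.items():
        out[method][noise] = bool(ok)
    out["rfsf_wins_somewhere"] = any(
        out["RFSF"][nl] and not out["HK"][nl] for nl in out["HK"])
    return out


def weak_locus_recovery(panel: GenotypeMatrix, n_reps: int = 25,
                        noise_pct: float = 5.0, n_trees: int = 500,
                        seed: int = 0, null_model=None) -> dict:
    """Eight-locus model (2 strong + 6 weak additive): fraction of weak causal
    loci scored inside the top-1% set, for RFSF vs RFPI (deep trees)."""
    p = panel.n_markers
    if null_model is None:
        null_model = estimate_sf_bias(panel, config=RFConfig(n_trees=n_trees),
                                      seed=derive_seed(seed, "null"))
    hits = {"RFSF": 0, "RFPI": 0}
    total = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, "loci", rep))
        loci = draw_causal_loci(8, p, rng)
        y = simulate_trait(model_spec("eight_locus", loci, noise_pct), panel,
                           seed=derive_seed(seed, "trait", rep))
        forest = fit_rf(y, panel, RFConfig(n_trees=n_trees, nodesize=5,
                                           seed=derive_seed(seed, "rf", rep)))
        rfpi, _, sf_raw = rf_importances(forest, y, panel,
                                         derive_seed(seed, "perm", rep))
        weak = set(loci[2:])
        hits["RFSF"] += len(weak & set(
            top_percentile_indices(sf_raw - null_model.correction).tolist()))
        hits["RFPI"] += len(weak & set(top_percentile_indices(rfpi).tolist()))
        total += len(weak)
    return {m: v / total for m, v in hits.items()}


def fixture_context(fx):
    g2m = map_genes_to_markers(fx.genes, fx.genotypes.markers)
    return EnrichmentContext(markers=fx.genotypes.markers,
                             pathways=fx.pathways, gene2marker=g2m)


def hk_profiles(fx):
    return [map_hk(fx.expression.values[:, t], fx.genotypes, trait_id=tid)
            for t, tid in enumerate(fx.expression.traits)]


def random_profiles(fx, seed: int):
    rng = np.random.default_rng(seed)
    p = fx.genotypes.n_markers
    return [ScoreProfile(tid, "EXTERNAL", rng.standard_normal(p),
                         fx.genotypes.markers) for tid in fx.expression.traits]


def enrichment_sensitivity(seed: int, n_null_per_trait: int = 5,
                           mutant_n_null: int = 20) -> dict:
    """Pathway D and mutant-enrichment D on the planted fixture: profiles
    from a correct mapper (single-marker LOD) vs random Gaussian profiles."""
    fx = generate_fixture(FixtureSpec(seed=derive_seed(seed, "fixture")))
    ctx = fixture_context(fx)
    genes = [fx.expression.gene_of_trait[t] for t in fx.expression.traits]
    out = {}
    for label, profs in (("mapped", hk_profiles(fx)),
                         ("random", random_profiles(fx, derive_seed(seed, "rand")))):
        summ = pathway_enrichment_summary(
            profs, genes, ctx, n_null_per_trait=n_null_per_trait,
            seed=derive_seed(seed, "nullp", label))
        mres = mutant_enrichment(
            profs, fx.expression, fx.mutant_table, ctx.gene2marker,
            n_null=mutant_n_null, seed=derive_seed(seed, "mut", label))
        out[label] = {"pathway_D": summ.D, "pathway_ks_p": summ.ks_p,
                      "mutant_D": mres.D, "mutant_ks_p": mres.ks_p}
    return out


def calibration_corrected_ps(n_traits: int = 500, seed: int = 0) -> np.ndarray:
    """Empirically corrected pathway-enrichment P values for random Gaussian
    score profiles (should be uniform)."""
    from .benchmarks import (empirical_null_correct, null_enrichment_ps,
                             pathway_enrichment_per_trait)

    fx = generate_fixture(FixtureSpec(
        seed=derive_seed(seed, "calib-fixture"), n_genes=400,
        n_pathways=30, pathway_size=20, n_regulators=10))
    ctx = fixture_context(fx)
    genes = [fx.expression.gene_of_trait[t] for t in fx.expression.traits]
    genes = [genes[i % len(genes)] for i in range(n_traits)]
    rng = np.random.default_rng(derive_seed(seed, "calib-scores"))
    p = fx.genotypes.n_markers
    raw, kept = [], []
    for i, gene in enumerate(genes):
        prof = ScoreProfile(f"t{i}", "EXTERNAL", rng.standard_normal(p),
                            fx.genotypes.markers)
        pv = pathway_enrichment_per_trait(prof, gene, ctx)
        if pv is not None:
            raw.append(pv)
            kept.append(gene)
    null = null_enrichment_ps(kept, ctx, n_null_per_trait=1,
                              seed=derive_seed(seed, "calib-null"))
    return empirical_null_correct(raw, null)


def depth_improvements(seed: int, n_trees: int = 500, null_forests: int = 500,
                       n_null_per_trait: int = 10) -> dict:
    """Deep (nodesize 5) minus stump (nodesize = n) benchmark values for
    RFSF and RFPI on the weak-effect fixture."""
    fx = generate_fixture(depth_fixture_spec(seed=derive_seed(seed, "fixture")))
    ctx = fixture_context(fx)
    n = fx.genotypes.n_strains

    def evaluate(profs):
        genes = [fx.expression.gene_of_trait[p.trait_id] for p in profs]
        summ = pathway_enrichment_summary(
            profs, genes, ctx, n_null_per_trait=n_null_per_trait,
            seed=derive_seed(seed, "depth-nullp"))
        cis = cis_proportion(profs, fx.expression, fx.genes,
                             fx.genotypes.markers, 500_000).proportion
        return {"cis": cis, "pathway_D": summ.D}

    res = tree_depth_study(fx.expression, fx.genotypes, [5, n], evaluate,
                           n_trees=n_trees, null_forests=null_forests,
                           trees_per_forest=10, seed=derive_seed(seed, "depth"))
    return {measure: {key: res[5][measure][key] - res[n][measure][key]
                      for key in ("cis", "pathway_D")}
            for measure in ("RFSF", "RFPI")}
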