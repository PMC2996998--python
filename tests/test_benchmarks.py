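import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eqtlbench.benchmarks import (
    EnrichmentContext, cis_proportion, empirical_null_correct,
    hypergeom_upper_p, ks_uniform, method_overlap, mutant_enrichment,
    null_enrichment_ps, pathway_enrichment_per_trait, subsample_study,
    tf_pathway_enrichment_per_trait,
)
from eqtlbench.io import ExpressionMatrix, GeneAnnotation, MarkerMap
from eqtlbench.profiles import ScoreProfile


def _markers(p, spacing=1_000_000):
    return MarkerMap(
        marker_id=np.array([f"m{i}" for i in range(p)], dtype=object),
        chromosome=np.array(["chr1"] * p, dtype=object),
        position_bp=np.arange(1, p + 1) * spacing,
    )


class TestHypergeom:
    def test_zero_successes_is_one(self):
        assert hypergeom_upper_p(0, 5, 5, 10) == 1.0

    def test_full_overlap_small_case(self):
        assert hypergeom_upper_p(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_exhaustive_enumeration(self):
        # P(X >= k) by summing the pmf written out with binomial coefficients
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        want = sum(
                            math.comb(K, i) * math.comb(N - K, n - i)
                            for i in range(k, min(n, K) + 1)
                        ) / math.comb(N, n)
                        got = hypergeom_upper_p(k, K, n, N)
                        assert got == pytest.approx(want, rel=1e-9), (k, K, n, N)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            hypergeom_upper_p(6, 5, 5, 10)


class TestKSUniform:
    def test_point_mass_near_zero(self):
        D, _ = ks_uniform(np.full(100, 0.001))
        assert D == pytest.approx(0.999)

    def test_exact_uniform_grid(self):
        n = 40
        x = (np.arange(1, n + 1) - 0.5) / n
        D, p = ks_uniform(x)
        assert D == pytest.approx(0.5 / n, abs=1e-12)
        assert p == pytest.approx(np.exp(-2 * n * D * D))

    def test_calibrated_on_uniform_samples(self):
        low = 0
        for seed in range(40):
            x = np.random.default_rng(seed).random(1000)
            _, p = ks_uniform(x)
            low += p < 0.01
        assert low <= 2  # >= 95% of draws pass

    @given(st.integers(0, 2000), st.integers(5, 100))
    def test_d_matches_bruteforce_sup(self, seed, n):
        x = np.random.default_rng(seed).random(n)
        D, _ = ks_uniform(x)
        xs = np.sort(x)
        brute = max(max((i + 1) / n - xs[i] for i in range(n)), 0.0)
        assert abs(D - brute) < 1e-12

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ks_uniform([0.5, 0.5])


class TestEmpiricalNull:
    def test_rank_formula_edges(self):
        null = np.linspace(0.01, 1.0, 99)
        got = empirical_null_correct([0.001, 1.0], null)
        assert got[0] == pytest.approx(1 / 100)
        assert got[1] == pytest.approx(1.0)

    def test_empty_null_fatal(self):
        with pytest.raises(ValueError):
            empirical_null_correct([0.5], [])

    def test_self_null_calibration(self, default_fixture):
        """Random-score 'observed' profiles corrected against the same null
        process give uniform corrected P values."""
        from eqtlbench.io import map_genes_to_markers

        fx = default_fixture
        g2m = map_genes_to_markers(fx.genes, fx.genotypes.markers)
        ctx = EnrichmentContext(markers=fx.genotypes.markers,
                                pathways=fx.pathways, gene2marker=g2m)
        genes = [fx.expression.gene_of_trait[t] for t in fx.expression.traits]
        genes = list(itertools.islice(itertools.cycle(genes), 500))
        rng = np.random.default_rng(0)
        raw = []
        kept = []
        for i, gene in enumerate(genes):
            prof = ScoreProfile(f"t{i}", "EXTERNAL",
                                rng.standard_normal(len(ctx.markers)),
                                fx.genotypes.markers)
            pv = pathway_enrichment_per_trait(prof, gene, ctx)
            if pv is not None:
                raw.append(pv)
                kept.append(gene)
        null = null_enrichment_ps(kept, ctx, n_null_per_trait=1, seed=123)
        corrected = empirical_null_correct(raw, null)
        _, p = ks_uniform(corrected)
        assert p > 0.01


class TestPathwayEnrichment:
    @staticmethod
    def _context(p=40):
        markers = _markers(p)
        # genes g0..g9 mapped to markers m0..m9; trait gene = g0
        genes = {f"g{i}": f"m{i}" for i in range(10)}
        pathways = {"PW": {"g0", "g1", "g2", "g3"}, "other": {"g9"}}
        return EnrichmentContext(markers=markers, pathways=pathways,
                                 gene2marker=genes)

    def test_disjoint_selection_gives_one(self):
        ctx = self._context()
        scores = np.zeros(40)
        scores[[30, 31, 32, 33]] = 1.0  # top-4 away from pathway markers
        prof = ScoreProfile("t", "EXTERNAL", scores, ctx.markers)
        assert pathway_enrichment_per_trait(prof, "g0", ctx) == 1.0

    def test_full_overlap_matches_formula(self):
        ctx = self._context()
        scores = np.zeros(40)
        scores[[1, 2, 3]] = 1.0  # pathway markers of g1..g3 (g0 excluded)
        scores[20] = 0.5
        prof = ScoreProfile("t", "EXTERNAL", scores, ctx.markers)
        # selected top-k: k = ceil(0.01*40) = 1 at pct 99; use pct 90 -> k = 4
        ctx.percentile = 90.0
        want = hypergeom_upper_p(3, 3, 4, 40)
        assert pathway_enrichment_per_trait(prof, "g0", ctx) == pytest.approx(want)

    def test_trait_gene_not_in_pathway_skipped(self):
        ctx = self._context()
        prof = ScoreProfile("t", "EXTERNAL", np.arange(40.0), ctx.markers)
        assert pathway_enrichment_per_trait(prof, "g5", ctx) is None

    def test_unmapped_pathway_skipped(self):
        markers = _markers(40)
        ctx = EnrichmentContext(markers=markers, pathways={"PW": {"g0", "gx"}},
                                gene2marker={"g0": "m0"})
        prof = ScoreProfile("t", "EXTERNAL", np.arange(40.0), markers)
        # only pathway gene besides g0 is unmapped -> K = 0 -> trait skipped
        assert pathway_enrichment_per_trait(prof, "g0", ctx) is None

    def test_tf_variant_unions_tf_pathways(self):
        ctx = self._context()
        ctx.percentile = 90.0
        # top-4 = m9 plus the three highest background markers (m37..m39),
        # which avoid both pathways' marker sets
        scores = np.linspace(0.0, 0.5, 40)
        scores[9] = 5.0
        prof = ScoreProfile("t", "EXTERNAL", scores, ctx.markers)
        # g5's TFs are g9 (in 'other') -> tests pathway 'other' only
        tf_map = {"g5": {"g9"}}
        got = tf_pathway_enrichment_per_trait(prof, "g5", tf_map, ctx)
        want = hypergeom_upper_p(1, 1, 4, 40)
        assert got == pytest.approx(want)
        # adding a TF from 'PW' (overlap 0 there -> P = 1) keeps the min;
        # TFs sharing a pathway would test it only once (set semantics)
        tf_map2 = {"g5": {"g9", "g1"}}
        got2 = tf_pathway_enrichment_per_trait(prof, "g5", tf_map2, ctx)
        assert got2 == pytest.approx(want)

    def test_no_tf_skipped(self):
        ctx = self._context()
        prof = ScoreProfile("t", "EXTERNAL", np.arange(40.0), ctx.markers)
        assert tf_pathway_enrichment_per_trait(prof, "g0", {}, ctx) is None


class TestCisProportion:
    def test_hand_enumeration(self):
        p = 200
        markers = _markers(p, spacing=100_000)
        rng = np.random.default_rng(1)
        genes, profiles, gene_of = [], [], {}
        planted = set(range(4))
        for t in range(10):
            gid = f"g{t}"
            anchor = 20 * t
            mid = int(markers.position_bp[anchor])
            genes.append(GeneAnnotation(gid, "chr1", mid, mid))
            scores = np.zeros(p)
            if t in planted:
                scores[anchor] = 5.0  # top-k contains the cis marker
            else:
                scores[(anchor + 100) % p] = 5.0
            profiles.append(ScoreProfile(f"t{t}", "EXTERNAL", scores, markers))
            gene_of[f"t{t}"] = gid
        expr = ExpressionMatrix(strains=["a", "b"], traits=[f"t{t}" for t in range(10)],
                                gene_of_trait=gene_of, values=np.zeros((2, 10)))
        rep = cis_proportion(profiles, expr, genes, markers, window_bp=500_000)
        assert rep.proportion == pytest.approx(0.4)
        assert [rep.cis_flag[f"t{t}"] for t in range(4)] == [True] * 4

    def test_window_is_strict(self):
        markers = _markers(100, spacing=100_000)
        scores = np.zeros(100)
        scores[50] = 1.0
        prof = ScoreProfile("t0", "EXTERNAL", scores, markers)
        expr = ExpressionMatrix(strains=["a", "b"], traits=["t0"],
                                gene_of_trait={"t0": "g"},
                                values=np.zeros((2, 1)))
        mpos = int(markers.position_bp[50])
        inside = [GeneAnnotation("g", "chr1", mpos + 500_000, mpos + 500_000)]
        outside = [GeneAnnotation("g", "chr1", mpos + 500_001, mpos + 500_001)]
        assert cis_proportion([prof], expr, inside, markers, 500_000).proportion == 1.0
        assert cis_proportion([prof], expr, outside, markers, 500_000).proportion == 0.0

    def test_unannotated_gene_excluded(self):
        markers = _markers(100)
        prof = ScoreProfile("t0", "EXTERNAL", np.arange(100.0), markers)
        expr = ExpressionMatrix(strains=["a", "b"], traits=["t0"],
                                gene_of_trait={"t0": "gX"},
                                values=np.zeros((2, 1)))
        rep = cis_proportion([prof], expr, [], markers, 500_000)
        assert rep.n_excluded == 1 and math.isnan(rep.proportion)


class TestMutantEnrichment:
    def _setup(self, planted=True, seed=0):
        p = 100
        markers = _markers(p)
        rng = np.random.default_rng(seed)
        gene2marker = {f"r{i}": f"m{i * 10}" for i in range(5)}
        traits = [f"t{i}" for i in range(30)]
        gene_of = {t: f"tgt{i}" for i, t in enumerate(traits)}
        mutant = {}
        for i in range(5):
            for j in range(30):
                mag = 3.0 if planted and i == j % 5 else 0.1
                mutant[(f"r{i}", f"tgt{j}")] = mag * (1 if (i + j) % 2 else -1)
        profiles = []
        for j, t in enumerate(traits):
            scores = rng.standard_normal(p) * 0.01
            if planted:
                scores[(j % 5) * 10] = 5.0  # planted regulator marker on top
            profiles.append(ScoreProfile(t, "EXTERNAL", scores, markers))
        expr = ExpressionMatrix(strains=["a", "b"], traits=traits,
                                gene_of_trait=gene_of,
                                values=np.zeros((2, 30)))
        return profiles, expr, mutant, gene2marker

    def test_empty_table_fatal(self):
        profiles, expr, _, g2m = self._setup()
        with pytest.raises(ValueError, match="empty"):
            mutant_enrichment(profiles, expr, {}, g2m)

    def test_planted_signal_detected(self):
        profiles, expr, mutant, g2m = self._setup(planted=True)
        res = mutant_enrichment(profiles, expr, mutant, g2m, n_null=20, seed=1)
        assert res.ks_p < 0.01
        assert np.median(res.observed) > np.median(res.null)

    def test_random_scores_not_significant_on_average(self):
        ps = []
        for seed in range(10):
            profiles, expr, mutant, g2m = self._setup(planted=False, seed=seed)
            # wider top sets (k = 5) keep the observed side non-empty
            res = mutant_enrichment(profiles, expr, mutant, g2m,
                                    n_null=20, seed=seed, percentile=95.0)
            ps.append(res.ks_p)
        assert np.mean(ps) > 0.05


class TestMethodOverlap:
    def test_identities(self):
        sets = {"A": [{1, 2, 3}], "B": [{1, 2, 3}], "C": [{7, 8, 9}]}
        names, mat = method_overlap(sets)
        i, j, k = names.index("A"), names.index("B"), names.index("C")
        assert mat[i, j] == pytest.approx(100.0)
        assert mat[i, k] == pytest.approx(0.0)

    def test_half_overlap_formula(self):
        a = set(range(38))
        b = set(range(19, 19 + 38))  # |intersection| = 19, sizes 38/38
        _, mat = method_overlap({"A": [a], "B": [b]})
        assert mat[0, 1] == pytest.approx(50.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        sets = {m: [set(rng.choice(50, 10, replace=False)) for _ in range(5)]
                for m in "ABCD"}
        _, mat = method_overlap(sets)
        assert np.allclose(mat, mat.T)
        assert np.nanmin(mat) >= 0 and np.nanmax(mat) <= 100

    def test_empty_sets_skipped(self):
        _, mat = method_overlap({"A": [set(), {1}], "B": [{1}, {1}]})
        assert mat[0, 1] == pytest.approx(100.0)  # only the second trait counts


class TestSubsample:
    def test_nested_and_full_size_identity(self, default_fixture):
        fx = default_fixture
        seen = {}

        def evaluate(g, e, size):
            seen[size] = list(g.strains)
            return g.values.sum()

        res = subsample_study(fx.genotypes, fx.expression, [100, 50, 20],
                              evaluate, seed=3)
        assert seen[100] == fx.genotypes.strains  # full size = original data
        assert res[100] == fx.genotypes.values.sum()
        assert set(seen[20]) <= set(seen[50]) <= set(seen[100])

    def test_size_bounds(self, default_fixture):
        fx = default_fixture
        with pytest.raises(ValueError, match=">= 5"):
            subsample_study(fx.genotypes, fx.expression, [50, 4],
                            lambda *a: None, seed=0)
        with pytest.raises(ValueError, match="descending"):
            subsample_study(fx.genotypes, fx.expression, [20, 50],
                            lambda *a: None, seed=0)
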