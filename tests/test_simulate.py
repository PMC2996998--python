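import numpy as np
import pytest

from eqtlbench.forest import RFConfig
from eqtlbench.simulate import (
    NOISE_LEVELS, TraitModelSpec, draw_causal_loci, model_spec,
    run_simulation_study, simulate_ri_genotypes, simulate_trait,
)


class TestRIPanel:
    def test_zero_recombination_gives_constant_chromosomes(self):
        g = simulate_ri_genotypes(20, [(30, 1_000_000)], 0.0, seed=1)
        assert np.all((g.values.sum(axis=1) == 0) | (g.values.sum(axis=1) == 30))

    def test_high_recombination_decorrelates_adjacent_markers(self):
        g = simulate_ri_genotypes(500, [(40, 40_000_000)], 1e-5, seed=2)
        X = g.values.astype(float)
        rs = [np.corrcoef(X[:, i], X[:, i + 1])[0, 1] for i in range(39)]
        assert np.max(np.abs(rs)) < 0.15

    def test_allele_frequency_near_half(self):
        g = simulate_ri_genotypes(400, [(50, 50_000_000)] * 2, 1e-8, seed=3)
        freqs = g.values.mean(axis=0)
        # binomial error at n=400 is ~0.025; LD makes markers non-independent
        assert 0.4 < freqs.mean() < 0.6
        assert np.all((freqs > 0.3) & (freqs < 0.7))

    def test_deterministic_and_sorted(self):
        a = simulate_ri_genotypes(10, [(20, 5_000_000)] * 2, 1e-8, seed=4)
        b = simulate_ri_genotypes(10, [(20, 5_000_000)] * 2, 1e-8, seed=4)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.markers.position_bp, b.markers.position_bp)


class TestTraitModels:
    @pytest.fixture(scope="class")
    def panel(self):
        return simulate_ri_genotypes(30, [(40, 40_000_000)], 1e-8, seed=5)

    def test_single_locus_noiseless_values(self, panel):
        spec = TraitModelSpec(additive_terms=[(7, 1.0)], noise_pct=0)
        y = simulate_trait(spec, panel, seed=0)
        x = panel.values[:, 7]
        assert np.all(y[x == 1] == 10.0) and np.all(y[x == 0] == 9.0)

    def test_two_locus_epistatic_noiseless_values(self, panel):
        spec = TraitModelSpec(
            additive_terms=[(3, 0.25), (25, 0.25)],
            epistatic_terms=[((3, 25), 1.0)], noise_pct=0)
        y = simulate_trait(spec, panel, seed=0)
        a, b = panel.values[:, 3], panel.values[:, 25]
        assert np.all(y[(a == 1) & (b == 1)] == 10.5)
        assert np.all(y[(a == 1) & (b == 0)] == 9.25)
        assert np.all(y[(a == 0) & (b == 0)] == 9.0)

    def test_noise_sd_is_fraction_of_trait_mean(self, panel):
        spec = TraitModelSpec(baseline=10.0, additive_terms=[(0, 0.0)],
                              noise_pct=10.0)
        resid = np.concatenate([
            simulate_trait(spec, panel, seed=s) - 10.0 for s in range(40)
        ])
        assert resid.std() == pytest.approx(1.0, rel=0.1)

    def test_nonpositive_mean_fatal(self, panel):
        spec = TraitModelSpec(baseline=-9.0, additive_terms=[(0, 0.0)],
                              noise_pct=5.0)
        with pytest.raises(ValueError, match="noise scale"):
            simulate_trait(spec, panel, seed=0)

    def test_bad_marker_index_fatal(self, panel):
        with pytest.raises(ValueError, match="out of range"):
            simulate_trait(TraitModelSpec(additive_terms=[(999, 1.0)]), panel, 0)


def test_draw_causal_loci_spacing():
    rng = np.random.default_rng(6)
    for _ in range(50):
        loci = draw_causal_loci(3, 200, rng, min_spacing=10)
        assert len(set(loci)) == 3
        s = sorted(loci)
        assert min(b - a for a, b in zip(s, s[1:])) > 10


def test_named_models_match_recipes():
    spec = model_spec("two_epistatic", [5, 40], noise_pct=7.5)
    assert spec.additive_terms == [(5, 0.25), (40, 0.25)]
    assert spec.epistatic_terms == [((5, 40), 1.0)]
    assert spec.causal_indices() == [5, 40]
    eight = model_spec("eight_locus", list(range(0, 160, 20)), 5.0)
    assert [c for _, c in eight.additive_terms] == [1.0, 1.0] + [0.25] * 6
    assert len(NOISE_LEVELS) == 8 and NOISE_LEVELS[0] == 2.5 and NOISE_LEVELS[-1] == 20.0


class TestSimulationStudy:
    @pytest.fixture(scope="class")
    def panel(self):
        return simulate_ri_genotypes(40, [(40, 80_000_000)] * 2, 5e-8, seed=7)

    def test_deterministic(self, panel):
        kw = dict(noise_levels=[5.0], n_reps=3, seed=9)
        a = run_simulation_study(["single"], panel, ["HK"], **kw)
        b = run_simulation_study(["single"], panel, ["HK"], **kw)
        assert a.median_worst_rank == b.median_worst_rank

    def test_zero_noise_single_locus_all_methods_rank_one(self):
        # loosely linked panel: no marker duplicates the causal column, so a
        # noiseless trait pins rank 1 exactly for every method
        panel = simulate_ri_genotypes(40, [(40, 80_000_000)] * 2, 1e-5, seed=8)
        res = run_simulation_study(
            ["single"], panel, ["HK", "CIM", "LASSO", "ENET", "RFSF"],
            noise_levels=[0.0], n_reps=2, seed=10,
            rf_config=RFConfig(n_trees=100))
        for key, med in res.median_worst_rank.items():
            assert med == 1, key
            assert res.success[key]

    def test_unknown_method_fatal(self, panel):
        with pytest.raises(ValueError, match="unknown method"):
            run_simulation_study(["single"], panel, ["NOPE"],
                                 noise_levels=[5.0], n_reps=1, seed=0)

    def test_median_rank_nondecreasing_in_noise(self, panel):
        res = run_simulation_study(["single"], panel, ["HK"],
                                   noise_levels=[2.5, 10.0, 20.0],
                                   n_reps=30, seed=11)
        meds = [res.median_worst_rank[("single", "HK", nl)]
                for nl in (2.5, 10.0, 20.0)]
        # allow one adjacent Monte-Carlo inversion
        inversions = sum(b < a for a, b in zip(meds, meds[1:]))
        assert inversions <= 1
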