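"""Synthetic RI genotype panels and simulated expression traits.

The trait models mirror the simulation study: every trait starts at a baseline
of 9, additive terms add coefficient x genotype, and epistatic terms add a
coefficient times the logical AND of the binary genotypes of a marker set.
Gaussian noise is then added with standard deviation expressed as a percentage
of the noiseless trait mean (the "noise level"), over the ladder
2.5, 5, ..., 20%.

The study protocol: for each genetic model, causal markers are drawn fresh for
each of the replicates, every mapping method scores the same simulated data,
the worst (maximum) rank among the causal markers is recorded, and the median
worst rank over replicates summarizes a (model, method, noise) cell.  A cell
"succeeds" when that median fits inside the top-percentile set size
k = ceil(0.01 * p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .forest import RFConfig
from .io import GenotypeMatrix, MarkerMap
from .mapping import (
    HaleyKnottMapper, CompositeIntervalMapper, PenalizedMapper,
    RandomForestMapper, estimate_sf_bias,
)
from .profiles import ScoreProfile, top_k_of, worst_rank

NOISE_LEVELS = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)

# default genetic models: (additive coefficient per locus, epistatic AND terms)
MODELS = {
    "single": {"n_loci": 1, "additive": (1.0,), "epistatic": ()},
    "two_epistatic": {"n_loci": 2, "additive": (0.25, 0.25),
                      "epistatic": (((0, 1), 1.0),)},
    "three_additive": {"n_loci": 3, "additive": (0.25, 0.25, 0.25),
                       "epistatic": ()},
    "three_epistatic": {"n_loci": 3, "additive": (0.25, 0.25, 0.25),
                        "epistatic": (((0, 1, 2), 1.0),)},
    # depth-study variant: 2 strong + 6 weak additive loci
    "eight_locus": {"n_loci": 8,
                    "additive": (1.0, 1.0, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25),
                    "epistatic": ()},
}


@dataclass
class TraitModelSpec:
    """One simulated trait: baseline + additive terms + AND-epistatic terms + noise."""

    baseline: float = 9.0
    additive_terms: list = field(default_factory=list)   # (marker index, coef)
    epistatic_terms: list = field(default_factory=list)  # (tuple of indices, coef)
    noise_pct: float = 0.0

    def causal_indices(self) -> list:
        loci = [m for m, _ in self.additive_terms]
        for idx_set, _ in self.epistatic_terms:
            loci.extend(idx_set)
        out = sorted(set(loci))
        if not out:
            raise ValueError("trait model has no causal loci")
        return out


def simulate_ri_genotypes(n_strains: int, chromosomes, recomb_per_bp: float,
                          seed: int = 0,
                          placement: str = "random") -> GenotypeMatrix:
    """A synthetic RI genotype panel with chromosome-wise linkage.

    ``chromosomes`` is a list of (n_markers, length_bp).  Marker positions are
    drawn at random along each chromosome (``placement="random"``, the
    default — real marker maps are irregular, which also makes the
    local-LD landscape heterogeneous) or evenly spaced (``"even"``).  Each
    strain's chromosome is a two-state Markov chain along the marker
    positions: the first marker is Bernoulli(0.5) and the probability of
    switching alleles between adjacent markers is the RI map-expanded
    recombination fraction min(0.5, 2 * (1 - exp(-recomb_per_bp * distance))).
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if placement not in ("random", "even"):
        raise ValueError("placement must be 'random' or 'even'")
    rng = np.random.default_rng(seed)
    ids, chroms, positions = [], [], []
    cols = []
    for ci, (n_markers, length_bp) in enumerate(chromosomes, start=1):
        if n_markers < 1:
            raise ValueError("each chromosome needs at least 1 marker")
        if placement == "even":
            pos = np.linspace(1, length_bp, n_markers).astype(np.int64)
        else:
            # distinct positions on a 1 kb grid, sorted
            grid = max(1, length_bp // max(1000, 2 * n_markers))
            pos = np.sort(rng.choice(
                np.arange(1, length_bp // grid, dtype=np.int64),
                size=n_markers, replace=False)) * grid
        ids.extend(f"c{ci}m{j + 1}" for j in range(n_markers))
        chroms.extend([f"chr{ci}"] * n_markers)
        positions.append(pos)

        states = np.empty((n_strains, n_markers), dtype=np.int8)
        states[:, 0] = rng.integers(0, 2, n_strains)
        if n_markers > 1:
            d = np.diff(pos).astype(float)
            switch = np.minimum(0.5, 2.0 * (1.0 - np.exp(-recomb_per_bp * d)))
            flips = rng.random((n_strains, n_markers - 1)) < switch
            for j in range(1, n_markers):
                states[:, j] = states[:, j - 1] ^ flips[:, j - 1]
        cols.append(states)

    markers = MarkerMap(
        marker_id=np.array(ids, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        position_bp=np.concatenate(positions),
    )
    return GenotypeMatrix(strains=[f"S{i + 1:03d}" for i in range(n_strains)],
                          markers=markers, values=np.hstack(cols))


def simulate_trait(spec: TraitModelSpec, genotypes: GenotypeMatrix,
                   seed: int = 0) -> np.ndarray:
    """Evaluate a trait model on a genotype panel and add scaled Gaussian noise."""
    X = genotypes.values
    p = X.shape[1]
    for m, _ in spec.additive_terms:
        if not 0 <= m < p:
            raise ValueError(f"additive marker index {m} out of range")
    y0 = np.full(X.shape[0], spec.baseline, dtype=np.float64)
    for m, coef in spec.additive_terms:
        y0 += coef * X[:, m]
    for idx_set, coef in spec.epistatic_terms:
        idx = list(idx_set)
        if any(not 0 <= m < p for m in idx):
            raise ValueError("epistatic marker index out of range")
        y0 += coef * np.all(X[:, idx] == 1, axis=1)
    if spec.noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    if spec.noise_pct == 0:
        return y0
    mean0 = float(y0.mean())
    if mean0 <= 0:
        raise ValueError("noiseless trait mean <= 0: noise scale undefined")
    sigma = (spec.noise_pct / 100.0) * mean0
    rng = np.random.default_rng(seed)
    return y0 + rng.normal(0.0, sigma, y0.shape[0])


def draw_causal_loci(n_loci: int, p: int, rng, min_spacing: int = 10) -> list:
    """Draw causal marker indices without replacement, no two within
    ``min_spacing`` markers of each other (avoids unidentifiable models)."""
    loci: list[int] = []
    for _ in range(10_000):
        cand = int(rng.integers(0, p))
        if all(abs(cand - x) > min_spacing for x in loci):
            loci.append(cand)
            if len(loci) == n_loci:
                return loci
    raise RuntimeError("could not place causal loci with the requested spacing")


def model_spec(model: str, loci, noise_pct: float,
               baseline: float = 9.0) -> TraitModelSpec:
    """Instantiate a named genetic model on concrete marker indices."""
    recipe = MODELS[model]
    if len(loci) != recipe["n_loci"]:
        raise ValueError(f"model {model} needs {recipe['n_loci']} loci")
    additive = [(loci[i], c) for i, c in enumerate(recipe["additive"])]
    epistatic = [
        (tuple(loci[i] for i in idx), c) for idx, c in recipe["epistatic"]
    ]
    return TraitModelSpec(baseline=baseline, additive_terms=additive,
                          epistatic_terms=epistatic, noise_pct=noise_pct)


def _make_mappers(methods, genotypes, rf_config: RFConfig, null_model, seed):
    out = {}
    for name in methods:
        key = name.upper()
        if key == "HK":
            out[name] = lambda X, y, s: HaleyKnottMapper().fit(X, y).scores_
        elif key == "CIM":
            mm = genotypes.markers
            out[name] = (lambda mm: lambda X, y, s: CompositeIntervalMapper(
                marker_map=mm).fit(X, y).scores_)(mm)
        elif key in ("LASSO", "ENET"):
            lam = 0.0 if key == "LASSO" else 1.0
            out[name] = (lambda lam: lambda X, y, s: PenalizedMapper(
                lambda2=lam, seed=s).fit(X, y).scores_)(lam)
        elif key in ("RFSF", "RFPI", "RFRSS", "RF"):
            def rf_scores(X, y, s, key=key):
                est = RandomForestMapper(
                    n_trees=rf_config.n_trees, mtry=rf_config.mtry,
                    nodesize=rf_config.nodesize, seed=s,
                    null_model=null_model if key in ("RFSF", "RF") else None,
                ).fit(X, y)
                return {"RFSF": est.rfsf_, "RF": est.rfsf_, "RFPI": est.rfpi_,
                        "RFRSS": est.rfrss_}[key]
            out[name] = rf_scores
        else:
            raise ValueError(f"unknown method {name!r}")
    return out


@dataclass
class SimulationStudyResult:
    """Median worst ranks of causal loci per (model, method, noise level)."""

    median_worst_rank: dict  # (model, method, noise) -> float
    success: dict            # (model, method, noise) -> bool
    n_reps: int
    k_top: int               # top-percentile set size
    causal_loci: dict | None = None  # (model, rep) -> list of marker ids

    def to_rows(self):
        for key in sorted(self.median_worst_rank):
            model, method, noise = key
            yield {"model": model, "method": method, "noise_pct": noise,
                   "median_worst_rank": self.median_worst_rank[key],
                   "success": self.success[key]}


def run_simulation_study(models, genotypes: GenotypeMatrix, methods,
                         noise_levels=NOISE_LEVELS, n_reps: int = 50,
                         seed: int = 0, rf_config: RFConfig | None = None,
                         null_model=None, percentile: float = 99.0,
                         min_spacing: int = 10) -> SimulationStudyResult:
    """Simulate traits under each genetic model and rank-score every method.

    Causal loci are redrawn for every replicate; within a replicate the same
    noiseless trait underlies every noise level, and every method scores the
    same noisy data.  If an RF measure is requested and no ``null_model`` is
    given, the selection-frequency bias is estimated once on the panel.
    """
    X = genotypes.values
    p = X.shape[1]
    k_top = top_k_of(p, percentile)
    if rf_config is None:
        rf_config = RFConfig()
    wants_rf = any(m.upper() in ("RFSF", "RF") for m in methods)
    if wants_rf and null_model is None:
        null_model = estimate_sf_bias(genotypes, config=rf_config,
                                      seed=derive_seed(seed, "sf-bias"))
    mappers = _make_mappers(methods, genotypes, rf_config, null_model, seed)

    ranks: dict = {}
    causal_record: dict = {}
    for model in models:
        for rep in range(n_reps):
            rng = np.random.default_rng(derive_seed(seed, "loci", model, rep))
            loci = draw_causal_loci(MODELS[model]["n_loci"], p, rng, min_spacing)
            causal_ids = list(genotypes.markers.marker_id[loci])
            causal_record[(model, rep)] = causal_ids
            for noise in noise_levels:
                spec = model_spec(model, loci, noise)
                y = simulate_trait(spec, genotypes,
                                   seed=derive_seed(seed, "noise", model, rep, noise))
                for method, fn in mappers.items():
                    scores = fn(X, y, derive_seed(seed, "map", model, rep,
                                                  noise, method))
                    prof = ScoreProfile("sim", "EXTERNAL", scores,
                                        genotypes.markers)
                    ranks.setdefault((model, method, noise), []).append(
                        worst_rank(prof, causal_ids))

    med = {key: float(np.median(vals)) for key, vals in ranks.items()}
    succ = {key: bool(med[key] <= k_top) for key in med}
    return SimulationStudyResult(median_worst_rank=med, success=succ,
                                 n_reps=n_reps, k_top=k_top,
                                 causal_loci=causal_record)
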