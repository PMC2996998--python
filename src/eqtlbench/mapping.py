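"""Per-trait marker scorers: single-marker LOD, composite-marker LOD,
penalized regression, and Random-Forest importances with the bias-corrected
selection frequency.

Each mapper is a scikit-learn style estimator: hyperparameters in the
constructor, ``fit(X, y)`` with X the (strains x markers) binary genotype
matrix and y the expression trait, fitted score vectors in trailing-underscore
attributes.  ``score_profile`` wraps the scores into a ScoreProfile aligned to
a MarkerMap.  The module-level ``map_*`` functions are thin wrappers.

Scores by method
----------------
HK      LOD of the one-marker regression at each marker location.
CIM     LOD of the test marker given forward-selected cofactor markers,
        excluding cofactors within a window of the test position.
LASSO   |coefficient| along the L1 path at a cross-validated fraction s of the
        maximal L1 norm (s floored at 0.5).
ENET    same with an added ridge penalty (naive elastic net, lambda2 = 1).
RFPI    unscaled out-of-bag permutation importance.
RFRSS   total split RSS decrease per marker, per tree.
RFSF    split selection frequency per marker, per tree, minus a null-forest
        bias correction (markers in linkage disequilibrium are under-selected
        under the null; the correction removes that bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import lars_path

from ._seeds import derive_seed
from .forest import RFConfig, RegressionForest, grow_forest, oob_permutation_importance
from .io import GenotypeMatrix, MarkerMap
from .profiles import ScoreProfile

# Relative floor on the fitted-model RSS, keeping LOD finite on perfect fits:
# LOD is capped at (n/2) * 10.
LOD_RSS_FLOOR = 1e-10


def _as_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_strains, n_markers) matching y")
    return X, y


def _hk_lods(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form single-marker LOD at every marker (vectorized)."""
    n = y.shape[0]
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        warnings.warn("zero-variance trait: all LOD scores are 0")
        return np.zeros(X.shape[1])
    xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    with np.errstate(invalid="ignore", divide="ignore"):
        explained = np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = np.maximum(rss0 - explained, LOD_RSS_FLOOR * rss0)
    return (n / 2.0) * np.log10(rss0 / rss1)


class HaleyKnottMapper(BaseEstimator):
    """Single-marker regression LOD scores at the marker locations.

    For RI strains with genotypes observed at the markers themselves, the
    interval-mapping regression reduces to ordinary one-marker least squares:
    LOD_m = (n/2) * log10(RSS0 / RSS1).
    """

    method = "HK"

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 strains")
        self.scores_ = _hk_lods(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def score_profile(self, trait_id: str, markers: MarkerMap) -> ScoreProfile:
        return ScoreProfile(trait_id, self.method, self.scores_, markers)


class CompositeIntervalMapper(BaseEstimator):
    """Marker-based composite mapping: test-marker LOD given background cofactors.

    Cofactor markers are chosen by greedy forward selection on the trait (each
    step adds the marker with the largest RSS reduction).  When scoring a test
    marker, cofactors on the same chromosome within ``window_bp`` of it (which
    includes the test marker itself) are dropped from both the full and the
    reduced model, so linked cofactors cannot absorb the tested effect.
    """

    method = "CIM"

    def __init__(self, marker_map=None, n_cofactors: int = 3,
                 window_bp: int = 10_000_000):
        self.marker_map = marker_map
        self.n_cofactors = n_cofactors
        self.window_bp = window_bp

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 strains")
        if self.n_cofactors >= n - 2:
            raise ValueError("n_cofactors must be < n - 2")
        if self.n_cofactors > 0 and self.marker_map is None:
            raise ValueError("marker_map is required when n_cofactors > 0")

        self.cofactors_ = self._forward_select(X, y)
        if not self.cofactors_:
            self.scores_ = _hk_lods(X, y)
            self.n_features_in_ = p
            return self

        chrom = self.marker_map.chromosome
        pos = self.marker_map.position_bp
        cof = np.array(self.cofactors_, dtype=int)
        lods = np.empty(p)
        ones = np.ones((n, 1))
        yc = y - y.mean()
        rss0 = float(yc @ yc)
        plain = None  # markers scored with no cofactors share the HK path
        for m in range(p):
            same = chrom[cof] == chrom[m]
            near = same & (np.abs(pos[cof] - pos[m]) <= self.window_bp)
            kept = cof[~near]
            if kept.size == 0:
                if plain is None:
                    plain = _hk_lods(X, y)
                lods[m] = plain[m]
                continue
            reduced = np.hstack([ones, X[:, kept]])
            full = np.hstack([reduced, X[:, [m]]])
            rss_r = _rss(reduced, y)
            if rss_r <= 1e-12 * rss0:
                # cofactors already fit perfectly: no evidence left to test
                lods[m] = 0.0
                continue
            rss_f = max(_rss(full, y), LOD_RSS_FLOOR * rss_r)
            lods[m] = (n / 2.0) * np.log10(rss_r / rss_f)
        self.scores_ = lods
        self.n_features_in_ = p
        return self

    def _forward_select(self, X, y):
        """Greedy forward selection by residual correlation (Gram-Schmidt)."""
        n, p = X.shape
        r = y - y.mean()
        Xr = X - X.mean(axis=0)
        norm0 = np.einsum("ij,ij->j", Xr, Xr)
        selected: list[int] = []
        for _ in range(self.n_cofactors):
            norms = np.einsum("ij,ij->j", Xr, Xr)
            valid = norms > 1e-10 * np.maximum(norm0, 1e-30)
            if selected:
                valid[np.array(selected)] = False
            with np.errstate(invalid="ignore", divide="ignore"):
                gains = np.where(valid, (r @ Xr) ** 2 / np.where(valid, norms, 1.0), 0.0)
            best = int(np.argmax(gains))
            if gains[best] <= 1e-12:
                if (~valid).sum() > len(selected):
                    warnings.warn("collinear cofactor candidates dropped during "
                                  "forward selection")
                break
            u = Xr[:, best] / np.sqrt(norms[best])
            r = r - (u @ r) * u
            Xr = Xr - np.outer(u, u @ Xr)
            selected.append(best)
        return selected

    def score_profile(self, trait_id: str, markers: MarkerMap) -> ScoreProfile:
        return ScoreProfile(trait_id, self.method, self.scores_, markers,
                            meta={"cofactors": list(self.cofactors_)})


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    res = y - design @ beta
    return float(res @ res)


class PenalizedMapper(BaseEstimator):
    """Lasso / naive elastic-net coefficient scores along the L1 path.

    Solves min ||y - Xb||^2 + lambda2 ||b||^2 + lambda1 ||b||_1 on
    internally standardized predictors via the LARS path (the ridge term is
    absorbed by data augmentation), then picks the L1 fraction
    s = ||b||_1 / max ||b||_1 from the grid {s_min, s_min+0.05, ..., 1.0}
    minimizing K-fold cross-validated MSE.  Scores are |b(s)| on the
    standardized scale.  lambda2 = 0 is the lasso; lambda2 = 1 the elastic
    net used in the study.
    """

    def __init__(self, lambda2: float = 0.0, cv_folds: int = 10,
                 s_min: float = 0.5, seed: int = 0):
        self.lambda2 = lambda2
        self.cv_folds = cv_folds
        self.s_min = s_min
        self.seed = seed

    @property
    def method(self) -> str:
        return "LASSO" if self.lambda2 == 0 else "ENET"

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        n, p = X.shape
        if n < self.cv_folds:
            raise ValueError("need n >= cv_folds")
        self.s_grid_ = np.round(np.arange(self.s_min, 1.0 + 1e-9, 0.05), 10)
        yc = y - y.mean()
        if float(yc @ yc) == 0.0:
            warnings.warn("constant trait: all penalized scores are 0")
            self.scores_ = np.zeros(p)
            self.s_ = 1.0
            self.n_features_in_ = p
            return self

        # seeded round-robin fold assignment
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = np.arange(n) % self.cv_folds

        cv_mse = np.zeros(len(self.s_grid_))
        for kf in range(self.cv_folds):
            test = folds == kf
            betas = self._path_betas(X[~test], y[~test])
            mu_x = X[~test].mean(axis=0)
            sd_x = X[~test].std(axis=0)
            sd_x[sd_x == 0] = 1.0
            mu_y = y[~test].mean()
            Xt = (X[test] - mu_x) / sd_x
            pred = Xt @ betas  # (n_test, n_grid)
            cv_mse += ((y[test, None] - mu_y - pred) ** 2).sum(axis=0)
        cv_mse /= n
        self.cv_mse_ = cv_mse
        self.s_ = float(self.s_grid_[int(np.argmin(cv_mse))])

        betas = self._path_betas(X, y)
        self.coef_ = betas[:, int(np.argmin(cv_mse))]
        self.scores_ = np.abs(self.coef_)
        self.n_features_in_ = p
        return self

    def _path_betas(self, X, y):
        """Coefficients at every grid fraction s, on the standardized scale."""
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        Xs = (X[:, keep] - mu[keep]) / sd[keep]
        yc = y - y.mean()
        pk = Xs.shape[1]
        if self.lambda2 > 0:
            Xa = np.vstack([Xs, np.sqrt(self.lambda2) * np.eye(pk)])
            ya = np.concatenate([yc, np.zeros(pk)])
        else:
            Xa, ya = Xs, yc
        with warnings.catch_warnings():
            # near-duplicate genotype columns routinely degenerate the LARS
            # active set; the truncated path is the correct solution here
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                _, _, coefs = lars_path(Xa, ya, method="lasso")
            except ValueError:
                # duplicate columns can break LARS outright; coordinate
                # descent over a dense penalty grid is a robust stand-in
                from sklearn.linear_model import lasso_path
                _, coefs, _ = lasso_path(Xa, ya, n_alphas=200, eps=1e-4)
        l1 = np.abs(coefs).sum(axis=0)
        l1max = l1[-1]
        out = np.zeros((X.shape[1], len(self.s_grid_)))
        if l1max == 0:
            return out
        frac = np.maximum.accumulate(l1 / l1max)  # knot fractions, monotone
        for j in range(coefs.shape[0]):
            out[np.where(keep)[0][j]] = np.interp(self.s_grid_, frac, coefs[j])
        return out

    def score_profile(self, trait_id: str, markers: MarkerMap) -> ScoreProfile:
        return ScoreProfile(trait_id, self.method, self.scores_, markers,
                            meta={"s": self.s_, "lambda2": self.lambda2})


@dataclass
class NullSelectionModel:
    """Per-marker selection frequencies of null forests and the derived correction.

    Null forests are grown on the actual genotype matrix with traits that are
    independent standard-Gaussian draws, so any structure in ``null_freq``
    reflects selection bias (linkage-disequilibrium-driven under-selection),
    not signal.  ``correction = null_freq - mean(null_freq)`` is subtracted
    from observed selection frequencies.
    """

    null_freq: np.ndarray
    mean_null: float
    correction: np.ndarray
    provenance: dict

    def __post_init__(self):
        if (self.null_freq < 0).any():
            raise ValueError("null frequencies must be >= 0")
        if abs(float(self.correction.mean())) > 1e-12:
            raise ValueError("correction must be centered")


class RandomForestMapper(BaseEstimator):
    """Forest-based importances: RFPI, RFRSS, and (bias-corrected) RFSF.

    Fitting grows one regression forest and extracts all three importance
    vectors; if a ``null_model`` is supplied, ``rfsf_`` is the bias-corrected
    selection frequency, otherwise it equals the raw frequency.
    """

    def __init__(self, n_trees: int = 5000, mtry: int | None = None,
                 nodesize: int = 5, seed: int = 0, perm_seed: int | None = None,
                 null_model: NullSelectionModel | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.nodesize = nodesize
        self.seed = seed
        self.perm_seed = perm_seed
        self.null_model = null_model

    method = "RFSF"

    def _config(self) -> RFConfig:
        return RFConfig(n_trees=self.n_trees, mtry=self.mtry,
                        nodesize=self.nodesize, seed=self.seed)

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64).ravel()
        self.forest_ = grow_forest(np.asarray(X), y, self._config())
        rfpi, rfrss, rfsf_raw = rf_importances(
            self.forest_, y, np.asarray(X),
            self.perm_seed if self.perm_seed is not None else self.seed + 1,
        )
        self.rfpi_ = rfpi
        self.rfrss_ = rfrss
        self.rfsf_raw_ = rfsf_raw
        if self.null_model is not None:
            if len(self.null_model.correction) != rfsf_raw.shape[0]:
                raise ValueError("null model length does not match marker count")
            self.rfsf_ = rfsf_raw - self.null_model.correction
        else:
            self.rfsf_ = rfsf_raw.copy()
        self.scores_ = self.rfsf_
        self.n_features_in_ = self.forest_.n_markers
        return self

    def score_profile(self, trait_id: str, markers: MarkerMap,
                      measure: str = "RFSF") -> ScoreProfile:
        scores = {"RFPI": self.rfpi_, "RFRSS": self.rfrss_,
                  "RFSF": self.rfsf_}[measure]
        return ScoreProfile(trait_id, measure, scores, markers,
                            meta={"n_trees": self.n_trees,
                                  "nodesize": self.nodesize,
                                  "bias_corrected": self.null_model is not None})


def rf_importances(forest: RegressionForest, trait, genotypes,
                   perm_seed: int):
    """(RFPI, RFRSS, RFSF_raw) for a fitted forest.

    RFPI: mean over trees of the OOB-MSE increase after permuting a marker's
    OOB values (unscaled; trees not splitting on the marker contribute 0).
    RFRSS: summed split RSS decreases per marker, divided by the tree count.
    RFSF_raw: internal-node split count per marker, divided by the tree count.
    """
    X = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    y = np.asarray(trait, dtype=np.float64).ravel()
    rfpi = oob_permutation_importance(forest, X, y, perm_seed)
    rfrss = forest.rss_decrease_totals() / forest.n_trees
    rfsf_raw = forest.split_counts() / forest.n_trees
    return rfpi, rfrss, rfsf_raw


def estimate_sf_bias(genotypes, n_forests: int = 500, trees_per_forest: int = 10,
                     config: RFConfig | None = None, seed: int = 0) -> NullSelectionModel:
    """Selection-frequency bias of the genotype matrix under the null.

    Grows ``n_forests`` forests of ``trees_per_forest`` trees each, every
    forest fit to an independent standard-Gaussian trait on the actual
    genotypes (defaults pool 500 x 10 = 5,000 trees, the size of the study
    forests).  Split counts are pooled over all trees; the per-marker
    deviation of the pooled selection frequency from its mean is the
    correction vector.
    """
    X = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    n, p = X.shape
    if config is None:
        config = RFConfig()
    total_trees = n_forests * trees_per_forest
    if total_trees < 100:
        warnings.warn("fewer than 100 null trees: bias correction may be unstable")
    counts = np.zeros(p, dtype=np.int64)
    for f in range(n_forests):
        rng = np.random.default_rng(derive_seed(seed, "null-trait", f))
        ynull = rng.standard_normal(n)
        fconf = RFConfig(n_trees=trees_per_forest, mtry=config.mtry,
                         nodesize=config.nodesize,
                         seed=derive_seed(seed, "null-forest", f))
        counts += grow_forest(X, ynull, fconf).split_counts()
    null_freq = counts / total_trees
    mean_null = float(null_freq.mean())
    return NullSelectionModel(
        null_freq=null_freq,
        mean_null=mean_null,
        correction=null_freq - mean_null,
        provenance={"n_forests": n_forests, "trees_per_forest": trees_per_forest,
                    "seed": seed, "nodesize": config.nodesize, "mtry": config.mtry},
    )


def rfsf_corrected(rfsf_raw: np.ndarray, null_model: NullSelectionModel,
                   markers: MarkerMap, trait_id: str = "trait") -> ScoreProfile:
    """Bias-corrected selection frequencies: raw minus the null correction."""
    rfsf_raw = np.asarray(rfsf_raw, dtype=float)
    if rfsf_raw.shape[0] != len(null_model.correction):
        raise ValueError("RFSF vector and null model have different lengths")
    return ScoreProfile(trait_id, "RFSF", rfsf_raw - null_model.correction, markers)


# ---------------------------------------------------------------------------
# thin functional wrappers

def map_hk(trait, genotypes: GenotypeMatrix, trait_id: str = "trait") -> ScoreProfile:
    est = HaleyKnottMapper().fit(genotypes.values, trait)
    return est.score_profile(trait_id, genotypes.markers)


def map_cim(trait, genotypes: GenotypeMatrix, n_cofactors: int = 3,
            window_bp: int = 10_000_000, trait_id: str = "trait") -> ScoreProfile:
    est = CompositeIntervalMapper(marker_map=genotypes.markers,
                                  n_cofactors=n_cofactors,
                                  window_bp=window_bp).fit(genotypes.values, trait)
    return est.score_profile(trait_id, genotypes.markers)


def map_penalized(trait, genotypes: GenotypeMatrix, lambda2: float,
                  cv_folds: int = 10, s_min: float = 0.5, seed: int = 0,
                  trait_id: str = "trait") -> ScoreProfile:
    est = PenalizedMapper(lambda2=lambda2, cv_folds=cv_folds, s_min=s_min,
                          seed=seed).fit(genotypes.values, trait)
    return est.score_profile(trait_id, genotypes.markers)


def fit_rf(trait, genotypes: GenotypeMatrix, config: RFConfig) -> RegressionForest:
    return grow_forest(genotypes.values, np.asarray(trait, float), config)
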