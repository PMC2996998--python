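"""Regression forests over binary RI genotypes, with split-level bookkeeping.

The forest here is a standard bagged CART regression forest (bootstrap of the
strains, random mtry-subset of markers scanned at each node, best
variance-reducing binary split), but unlike off-the-shelf implementations it
records everything the importance measures downstream need:

* every internal split (marker, RSS decrease) — for selection frequency (RFSF)
  and RSS importance (RFRSS);
* per-tree in-bag/out-of-bag membership — for the unscaled out-of-bag
  permutation importance (RFPI).

Splitting rule: the root is always eligible; any other node may be split only
if it holds more than ``nodesize`` bootstrap samples and the best candidate
split strictly reduces the residual sum of squares.  Setting ``nodesize`` to
the number of strains therefore yields stump forests that stop after the root
split — the shallow-tree end of the tree-depth ladder.

Genotypes are binary, so every split is "allele 0 left, allele 1 right";
thresholds are fixed at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

LEAF = -1


@dataclass
class RFConfig:
    """Forest hyperparameters.

    Defaults are the settings used throughout the study: 5,000 trees,
    mtry = floor(p/3) (the regression default), nodesize 5.
    """

    n_trees: int = 5000
    mtry: int | None = None  # None -> floor(p/3), at least 1
    nodesize: int = 5
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, p // 3)
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m

    def validate(self, p: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        self.resolve_mtry(p)


@njit(cache=True)
def _grow_forest(X, y, n_trees, mtry, nodesize, seed):  # pragma: no cover - numba
    n, p = X.shape
    max_nodes = 2 * n + 1
    feature = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    left = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    right = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    value = np.zeros((n_trees, max_nodes), dtype=np.float64)
    rss_dec = np.zeros((n_trees, max_nodes), dtype=np.float64)
    n_nodes = np.zeros(n_trees, dtype=np.int32)
    inbag = np.zeros((n_trees, n), dtype=np.int32)

    np.random.seed(seed)
    idx = np.empty(n, dtype=np.int64)
    perm = np.arange(p)
    # per-node work stack: node id, start, end (slice of idx), is_root flag
    stack_node = np.empty(max_nodes, dtype=np.int32)
    stack_start = np.empty(max_nodes, dtype=np.int32)
    stack_end = np.empty(max_nodes, dtype=np.int32)
    stack_root = np.empty(max_nodes, dtype=np.int32)

    for t in range(n_trees):
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inbag[t, j] += 1

        ncur = 1  # node 0 is the root
        top = 0
        stack_node[0] = 0
        stack_start[0] = 0
        stack_end[0] = n
        stack_root[0] = 1
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            start = stack_start[top]
            end = stack_end[top]
            is_root = stack_root[top]
            nS = end - start

            sumy = 0.0
            for ii in range(start, end):
                sumy += y[idx[ii]]
            ybar = sumy / nS
            value[t, node] = ybar

            if nS < 2 or (is_root == 0 and nS <= nodesize):
                continue  # terminal

            # scan a random mtry-subset of markers for the best split
            best_gain = 0.0
            best_f = -1
            best_n1 = 0
            best_s1 = 0.0
            for c in range(mtry):
                r = c + np.random.randint(0, p - c)
                tmp = perm[c]
                perm[c] = perm[r]
                perm[r] = tmp
                f = perm[c]
                n1 = 0
                s1 = 0.0
                for ii in range(start, end):
                    if X[idx[ii], f] == 1:
                        n1 += 1
                        s1 += y[idx[ii]]
                if n1 == 0 or n1 == nS:
                    continue
                n0 = nS - n1
                s0 = sumy - s1
                d = s1 / n1 - s0 / n0
                gain = d * d * n1 * n0 / nS
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_n1 = n1
                    best_s1 = s1
            if best_f < 0 or best_gain <= 1e-12:
                continue  # no RSS-reducing split among the candidates

            # partition idx[start:end]: allele 0 to the left, 1 to the right
            lo = start
            hi = end - 1
            while lo <= hi:
                if X[idx[lo], best_f] == 0:
                    lo += 1
                else:
                    tmp2 = idx[lo]
                    idx[lo] = idx[hi]
                    idx[hi] = tmp2
                    hi -= 1
            mid = lo  # first right-side element

            feature[t, node] = best_f
            rss_dec[t, node] = best_gain
            lchild = ncur
            rchild = ncur + 1
            ncur += 2
            left[t, node] = lchild
            right[t, node] = rchild

            stack_node[top] = lchild
            stack_start[top] = start
            stack_end[top] = mid
            stack_root[top] = 0
            top += 1
            stack_node[top] = rchild
            stack_start[top] = mid
            stack_end[top] = end
            stack_root[top] = 0
            top += 1
        n_nodes[t] = ncur
    return feature, left, right, value, rss_dec, n_nodes, inbag


@njit(cache=True)
def _predict_forest(X, feature, left, right, value, n_trees):  # pragma: no cover
    n = X.shape[0]
    out = np.zeros(n, dtype=np.float64)
    for i in range(n):
        acc = 0.0
        for t in range(n_trees):
            node = 0
            while feature[t, node] >= 0:
                if X[i, feature[t, node]] == 0:
                    node = left[t, node]
                else:
                    node = right[t, node]
            acc += value[t, node]
        out[i] = acc / n_trees
    return out


@njit(cache=True)
def _oob_predict(X, feature, left, right, value, inbag, n_trees):  # pragma: no cover
    n = X.shape[0]
    out = np.full(n, np.nan)
    cnt = np.zeros(n, dtype=np.int64)
    acc = np.zeros(n, dtype=np.float64)
    for t in range(n_trees):
        for i in range(n):
            if inbag[t, i] == 0:
                node = 0
                while feature[t, node] >= 0:
                    if X[i, feature[t, node]] == 0:
                        node = left[t, node]
                    else:
                        node = right[t, node]
                acc[i] += value[t, node]
                cnt[i] += 1
    for i in range(n):
        if cnt[i] > 0:
            out[i] = acc[i] / cnt[i]
    return out


@njit(cache=True)
def _oob_perm_importance(X, y, feature, left, right, value, n_nodes, inbag,
                         n_trees, seed):  # pragma: no cover - numba
    n, p = X.shape
    imp = np.zeros(p, dtype=np.float64)
    np.random.seed(seed)
    used = np.zeros(p, dtype=np.uint8)
    for t in range(n_trees):
        n_oob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                n_oob += 1
        if n_oob == 0:
            continue
        oob = np.empty(n_oob, dtype=np.int64)
        k = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob[k] = i
                k += 1

        base = 0.0
        for k in range(n_oob):
            i = oob[k]
            node = 0
            while feature[t, node] >= 0:
                if X[i, feature[t, node]] == 0:
                    node = left[t, node]
                else:
                    node = right[t, node]
            d = y[i] - value[t, node]
            base += d * d
        base /= n_oob

        # distinct markers split on in this tree
        for f in range(p):
            used[f] = 0
        for nd in range(n_nodes[t]):
            if feature[t, nd] >= 0:
                used[feature[t, nd]] = 1

        for f in range(p):
            if used[f] == 0:
                continue
            colperm = np.empty(n_oob, dtype=np.int8)
            for k in range(n_oob):
                colperm[k] = X[oob[k], f]
            # Fisher-Yates shuffle (one permutation per tree x marker)
            for k in range(n_oob - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = colperm[k]
                colperm[k] = colperm[j]
                colperm[j] = tmp
            mse = 0.0
            for k in range(n_oob):
                i = oob[k]
                node = 0
                while feature[t, node] >= 0:
                    ff = feature[t, node]
                    xv = colperm[k] if ff == f else X[i, ff]
                    if xv == 0:
                        node = left[t, node]
                    else:
                        node = right[t, node]
                d = y[i] - value[t, node]
                mse += d * d
            mse /= n_oob
            imp[f] += mse - base
    return imp / n_trees


@dataclass
class RegressionForest:
    """A fitted forest: tree structures plus in-bag bookkeeping."""

    config: RFConfig
    n_strains: int
    n_markers: int
    feature_: np.ndarray   # (n_trees, max_nodes) split marker, -1 for leaves
    left_: np.ndarray
    right_: np.ndarray
    value_: np.ndarray
    rss_dec_: np.ndarray
    n_nodes_: np.ndarray
    inbag_: np.ndarray     # (n_trees, n_strains) bootstrap multiplicities
    meta: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return self.config.n_trees

    def oob_indices(self, tree: int) -> np.ndarray:
        return np.where(self.inbag_[tree] == 0)[0]

    def split_counts(self) -> np.ndarray:
        """Number of internal-node splits using each marker, over the forest."""
        counts = np.zeros(self.n_markers, dtype=np.int64)
        feats = self.feature_[self.feature_ >= 0]
        np.add.at(counts, feats, 1)
        return counts

    def rss_decrease_totals(self) -> np.ndarray:
        """Sum of split RSS decreases per marker, over the forest."""
        totals = np.zeros(self.n_markers, dtype=np.float64)
        mask = self.feature_ >= 0
        np.add.at(totals, self.feature_[mask], self.rss_dec_[mask])
        return totals

    def total_internal_nodes(self) -> int:
        return int((self.feature_ >= 0).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.int8)
        return _predict_forest(X, self.feature_, self.left_, self.right_,
                               self.value_, self.config.n_trees)

    def oob_predict(self, X: np.ndarray) -> np.ndarray:
        """Per-strain prediction averaged over trees where the strain is OOB."""
        X = np.ascontiguousarray(X, dtype=np.int8)
        return _oob_predict(X, self.feature_, self.left_, self.right_,
                            self.value_, self.inbag_, self.config.n_trees)

    def oob_mse(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self.oob_predict(X)
        ok = np.isfinite(pred)
        return float(np.mean((np.asarray(y, float)[ok] - pred[ok]) ** 2))


def grow_forest(X: np.ndarray, y: np.ndarray, config: RFConfig) -> RegressionForest:
    """Fit a regression forest of binary-genotype CART trees.

    Deterministic given ``config.seed``.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 strains")
    if y.shape != (n,):
        raise ValueError("trait length does not match strain count")
    config.validate(p)
    mtry = config.resolve_mtry(p)
    feature, left, right, value, rss_dec, n_nodes, inbag = _grow_forest(
        X, y, config.n_trees, mtry, config.nodesize, config.seed % (2**31)
    )
    return RegressionForest(
        config=config, n_strains=n, n_markers=p,
        feature_=feature, left_=left, right_=right, value_=value,
        rss_dec_=rss_dec, n_nodes_=n_nodes, inbag_=inbag,
        meta={"mtry": mtry},
    )


def oob_permutation_importance(forest: RegressionForest, X: np.ndarray,
                               y: np.ndarray, perm_seed: int) -> np.ndarray:
    """Unscaled OOB permutation importance, averaged over all trees.

    For each tree and each marker the tree split on, the marker's out-of-bag
    values are permuted once and the increase in OOB MSE is recorded; trees
    that never split on a marker contribute zero for it.  No standard-error
    scaling is applied.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _oob_perm_importance(
        X, y, forest.feature_, forest.left_, forest.right_, forest.value_,
        forest.n_nodes_, forest.inbag_, forest.config.n_trees,
        perm_seed % (2**31),
    )
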