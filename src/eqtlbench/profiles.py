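"""Per-marker score profiles — the common currency between mapping and benchmarks.

Every mapping method reduces to a ScoreProfile: one real score per marker for
one trait, higher meaning more important.  Benchmarks consume profiles through
``top_percentile`` (the fixed-size top-k "high-scoring eQTL" set) and
``worst_rank`` (the max rank over a causal set, used by the simulation study).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerMap

METHODS = ("HK", "CIM", "LASSO", "ENET", "RFPI", "RFRSS", "RFSF", "EXTERNAL")


def top_k_of(p: int, pct: float = 99.0) -> int:
    """Size of the top-percentile set: ceil((100 - pct) * p / 100)."""
    return math.ceil((100.0 - pct) * p / 100.0)


@dataclass
class ScoreProfile:
    trait_id: str
    method: str
    scores: np.ndarray  # aligned to markers, higher = more important
    markers: MarkerMap
    meta: dict | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.markers),):
            raise ValueError("score length does not match marker count")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


def top_percentile(profile: ScoreProfile, pct: float = 99.0) -> list:
    """The k = ceil((1 - pct/100) * p) top-scoring marker ids.

    Ties are broken deterministically by genome order (the marker map is in
    genome order), so sparse profiles where many scores tie at zero still
    yield a well-defined set.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    p = len(profile.markers)
    k = top_k_of(p, pct)
    order = np.lexsort((np.arange(p), -profile.scores))
    idx = order[:k]
    if profile.scores[idx].min() <= 0 and (profile.scores > 0).sum() < k:
        warnings.warn(
            f"top-{k} set for trait {profile.trait_id!r} ({profile.method}) "
            "includes zero-score markers chosen by genome-order tie-break"
        )
    return list(profile.markers.marker_id[idx])


def top_percentile_indices(scores: np.ndarray, pct: float = 99.0) -> np.ndarray:
    """Index version of top_percentile for hot loops (same tie-break)."""
    p = scores.shape[0]
    order = np.lexsort((np.arange(p), -scores))
    return order[: top_k_of(p, pct)]


def worst_rank(profile: ScoreProfile, causal) -> int:
    """Max rank over the causal marker set; ties all get their group's worst rank."""
    causal = list(causal)
    if not causal:
        raise ValueError("causal set is empty")
    scores = profile.scores
    idx = profile.markers.index_of(causal)
    # rank with max-tie rule: rank(s) = number of markers with score >= s
    return int(max((scores >= scores[i]).sum() for i in idx))


def write_profile(profile: ScoreProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trait={profile.trait_id}\tmethod={profile.method}\n")
        for key, val in (profile.meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("marker_id\tchromosome\tposition_bp\tscore\n")
        m = profile.markers
        for i in range(len(m)):
            fh.write(f"{m.marker_id[i]}\t{m.chromosome[i]}\t"
                     f"{m.position_bp[i]}\t{float(profile.scores[i])!r}\n")


def read_profile(path) -> ScoreProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for part in line[1:].strip().split("\t"):
                if "=" in part:
                    key, val = part.split("=", 1)
                    meta[key.strip()] = val
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    markers = MarkerMap(
        marker_id=df["marker_id"].to_numpy(dtype=object),
        chromosome=df["chromosome"].astype(str).to_numpy(dtype=object),
        position_bp=df["position_bp"].to_numpy(dtype=np.int64),
    )
    return ScoreProfile(
        trait_id=meta.pop("trait", "unknown"),
        method=meta.pop("method", "EXTERNAL"),
        scores=df["score"].to_numpy(dtype=float),
        markers=markers,
        meta=meta or None,
    )
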