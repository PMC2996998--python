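"""End-to-end run orchestration: config, mapping all traits, benchmark reports.

A run is driven by a RunConfig (usually parsed from a TOML file): input paths,
the method list with per-method settings, the percentile and distance windows,
and one master seed from which every per-stage, per-trait stream is derived —
so a rerun with the same config is byte-reproducible and adding a trait never
reshuffles the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .benchmarks import (
    EnrichmentContext, cis_proportion, method_overlap, mutant_enrichment,
    pathway_enrichment_summary,
)
from .forest import RFConfig
from .io import (
    load_dataset, map_genes_to_markers, read_gene_annotations, read_gmt,
    read_mutant_table, read_tf_map,
)
from .mapping import (
    CompositeIntervalMapper, HaleyKnottMapper, PenalizedMapper,
    RandomForestMapper, estimate_sf_bias,
)
from .profiles import ScoreProfile, read_profile, top_percentile, write_profile

logger = logging.getLogger(__name__)

RF_MEASURES = ("RFPI", "RFRSS", "RFSF")


@dataclass
class RunConfig:
    genotypes: str
    expression: str
    outdir: str
    seed: int = 0
    genes: str | None = None
    pathways: str | None = None
    tf_map: str | None = None
    mutants: str | None = None
    external_scores: str | None = None   # directory of EXTERNAL profile TSVs
    methods: list = field(default_factory=lambda: ["HK", "LASSO", "ENET", "RFSF"])
    benchmarks: list = field(default_factory=lambda: ["cis", "overlap"])
    percentile: float = 99.0
    cis_window_bp: int = 500_000
    gene_marker_max_bp: int = 5_000_000
    rf_n_trees: int = 5000
    rf_nodesize: int = 5
    rf_mtry: int | None = None
    null_forests: int = 500
    trees_per_forest: int = 10
    cim_cofactors: int = 3
    cim_window_bp: int = 10_000_000
    cv_folds: int = 10
    s_min: float = 0.5
    n_null_per_trait: int = 1
    mutant_n_null: int = 1
    depth_nodesizes: list | None = None   # default [5, n]
    subsample_sizes: list | None = None   # default [n, n//2, n//4]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        return cls(**flat)

    def validate(self) -> None:
        for name in ("genotypes", "expression"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        needs = {"cis": ["genes"], "pathway": ["genes", "pathways"],
                 "tf_pathway": ["genes", "pathways", "tf_map"],
                 "mutant": ["genes", "mutants"], "overlap": [],
                 "depth": ["genes", "pathways"], "subsample": ["genes"]}
        for bench in self.benchmarks:
            if bench not in needs:
                raise ValueError(f"unknown benchmark {bench!r}")
            for req in needs[bench]:
                if getattr(self, req) is None:
                    raise ValueError(f"benchmark {bench!r} requires input {req!r}")
        for m in self.methods:
            if m.upper() == "EXTERNAL" and self.external_scores is None:
                raise ValueError("method EXTERNAL requires external_scores")

    def config_hash(self) -> str:
        # outdir is run metadata, not analysis configuration
        d = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _marker_map_hash(markers) -> str:
    blob = "\n".join(f"{m}\t{c}\t{p}" for m, c, p in
                     zip(markers.marker_id, markers.chromosome,
                         markers.position_bp))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def map_all_traits(genotypes, expression, config: RunConfig) -> dict:
    """Score every trait with every requested method.

    Returns {method: [ScoreProfile per trait]}.  RF measures share one forest
    per trait; RFSF is always paired with a null-forest bias estimation on the
    same genotypes.
    """
    methods = [m.upper() for m in config.methods]
    profiles: dict[str, list] = {m: [] for m in methods}
    rf_wanted = [m for m in methods if m in RF_MEASURES]
    null_model = None
    if "RFSF" in rf_wanted:
        logger.info("estimating selection-frequency bias "
                    "(%d x %d-tree null forests)",
                    config.null_forests, config.trees_per_forest)
        null_model = estimate_sf_bias(
            genotypes, n_forests=config.null_forests,
            trees_per_forest=config.trees_per_forest,
            config=RFConfig(nodesize=config.rf_nodesize, mtry=config.rf_mtry),
            seed=derive_seed(config.seed, "sf-bias"))

    external = {}
    if "EXTERNAL" in methods:
        for path in sorted(Path(config.external_scores).glob("*.tsv")):
            prof = read_profile(path)
            external[prof.trait_id] = prof

    X = genotypes.values
    markers = genotypes.markers
    for t, trait_id in enumerate(expression.traits):
        y = expression.values[:, t]
        rf_est = None
        for method in methods:
            try:
                if method == "HK":
                    prof = HaleyKnottMapper().fit(X, y).score_profile(trait_id, markers)
                elif method == "CIM":
                    prof = CompositeIntervalMapper(
                        marker_map=markers, n_cofactors=config.cim_cofactors,
                        window_bp=config.cim_window_bp,
                    ).fit(X, y).score_profile(trait_id, markers)
                elif method in ("LASSO", "ENET"):
                    prof = PenalizedMapper(
                        lambda2=0.0 if method == "LASSO" else 1.0,
                        cv_folds=config.cv_folds, s_min=config.s_min,
                        seed=derive_seed(config.seed, "penalized", method, trait_id),
                    ).fit(X, y).score_profile(trait_id, markers)
                elif method in RF_MEASURES:
                    if rf_est is None:
                        rf_est = RandomForestMapper(
                            n_trees=config.rf_n_trees, mtry=config.rf_mtry,
                            nodesize=config.rf_nodesize,
                            seed=derive_seed(config.seed, "rf", trait_id),
                            null_model=null_model,
                        ).fit(X, y)
                    prof = rf_est.score_profile(trait_id, markers, method)
                elif method == "EXTERNAL":
                    if trait_id not in external:
                        continue
                    prof = external[trait_id]
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:
                raise RuntimeError(
                    f"mapping stage {method!r} failed on trait {trait_id!r}: {exc}"
                ) from exc
            profiles[method].append(prof)
    return profiles


def run_pipeline(config: RunConfig) -> dict:
    """Map all traits with all requested methods and run the benchmark battery.

    Writes per-method score profiles, per-benchmark TSV/JSON reports and a
    summary JSON under ``config.outdir``; returns the summary dict.
    """
    config.validate()
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genotypes, expression, load_report = load_dataset(config.genotypes,
                                                      config.expression)
    markers = genotypes.markers
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "marker_map_hash": _marker_map_hash(markers),
    }

    profiles = map_all_traits(genotypes, expression, config)
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for method, profs in profiles.items():
        for prof in profs:
            prof.meta = {**(prof.meta or {}), **provenance}
            write_profile(prof, prof_dir / f"{method}_{prof.trait_id}.tsv")

    genes = read_gene_annotations(config.genes) if config.genes else None
    summary: dict = {
        "provenance": provenance,
        "load_report": load_report.__dict__,
        "n_traits": expression.n_traits,
        "methods": list(profiles),
        "benchmarks": {},
    }

    gene2marker = None
    if genes is not None:
        gene2marker = map_genes_to_markers(genes, markers,
                                           config.gene_marker_max_bp)

    for bench in config.benchmarks:
        res: dict = {}
        if bench == "cis":
            for method, profs in profiles.items():
                rep = cis_proportion(profs, expression, genes, markers,
                                     config.cis_window_bp, config.percentile)
                res[method] = {"proportion": rep.proportion,
                               "n_excluded": rep.n_excluded}
        elif bench in ("pathway", "tf_pathway"):
            pathways = read_gmt(config.pathways)
            tf_map = read_tf_map(config.tf_map) if bench == "tf_pathway" else None
            context = EnrichmentContext(markers=markers, pathways=pathways,
                                        gene2marker=gene2marker,
                                        percentile=config.percentile)
            for method, profs in profiles.items():
                trait_genes = [expression.gene_of_trait[p.trait_id] for p in profs]
                summ = pathway_enrichment_summary(
                    profs, trait_genes, context, tf_map=tf_map,
                    n_null_per_trait=config.n_null_per_trait,
                    seed=derive_seed(config.seed, bench, method))
                res[method] = {"D": summ.D, "ks_p": summ.ks_p,
                               "n_traits": summ.n_traits,
                               "n_skipped": summ.n_skipped}
        elif bench == "mutant":
            mutants = read_mutant_table(config.mutants)
            for method, profs in profiles.items():
                mres = mutant_enrichment(
                    profs, expression, mutants, gene2marker,
                    n_null=config.mutant_n_null,
                    seed=derive_seed(config.seed, "mutant", method),
                    percentile=config.percentile)
                res[method] = {"D": mres.D, "ks_p": mres.ks_p,
                               "n_observed": int(mres.observed.size),
                               "n_null": int(mres.null.size)}
        elif bench == "overlap":
            sets = {m: [top_percentile(p, config.percentile) for p in profs]
                    for m, profs in profiles.items()}
            names, mat = method_overlap(sets)
            res = {"methods": names, "matrix": mat.tolist()}
        elif bench == "depth":
            from .benchmarks import tree_depth_study

            pathways = read_gmt(config.pathways)
            context = EnrichmentContext(markers=markers, pathways=pathways,
                                        gene2marker=gene2marker,
                                        percentile=config.percentile)

            def evaluate(profs):
                trait_genes = [expression.gene_of_trait[p.trait_id] for p in profs]
                summ = pathway_enrichment_summary(
                    profs, trait_genes, context,
                    n_null_per_trait=config.n_null_per_trait,
                    seed=derive_seed(config.seed, "depth-null"))
                rep = cis_proportion(profs, expression, genes, markers,
                                     config.cis_window_bp, config.percentile)
                return {"cis": rep.proportion, "pathway_D": summ.D}

            nodesizes = config.depth_nodesizes or [config.rf_nodesize,
                                                   genotypes.n_strains]
            depth = tree_depth_study(
                expression, genotypes, nodesizes, evaluate,
                n_trees=config.rf_n_trees, null_forests=config.null_forests,
                trees_per_forest=config.trees_per_forest,
                seed=derive_seed(config.seed, "depth"))
            res = {str(ns): vals for ns, vals in depth.items()}
        elif bench == "subsample":
            from .benchmarks import subsample_study

            n = genotypes.n_strains
            sizes = config.subsample_sizes or [n, max(5, n // 2), max(5, n // 4)]

            def evaluate_sub(sub_g, sub_e, size):
                sub_profiles = map_all_traits(sub_g, sub_e, config)
                return {m: cis_proportion(ps, sub_e, genes, markers,
                                          config.cis_window_bp,
                                          config.percentile).proportion
                        for m, ps in sub_profiles.items()}

            res = {str(size): vals for size, vals in subsample_study(
                genotypes, expression, sizes, evaluate_sub,
                seed=derive_seed(config.seed, "subsample")).items()}
        summary["benchmarks"][bench] = res

    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    _write_benchmark_tsv(summary, outdir / "benchmarks.tsv", provenance)
    return summary


def _write_benchmark_tsv(summary: dict, path, provenance: dict) -> None:
    with open(path, "w") as fh:
        for key, val in provenance.items():
            fh.write(f"# {key}={val}\n")
        fh.write("benchmark\tmethod\tstatistic\tvalue\n")
        for bench, res in summary["benchmarks"].items():
            if bench == "overlap":
                names = res["methods"]
                mat = np.asarray(res["matrix"])
                for i, a in enumerate(names):
                    for j, b in enumerate(names):
                        fh.write(f"overlap\t{a}|{b}\tpct_overlap\t{mat[i, j]}\n")
                continue
            def emit(prefix, obj):
                if isinstance(obj, dict):
                    for key, val in obj.items():
                        emit(prefix + [str(key)], val)
                else:
                    fh.write(f"{bench}\t{prefix[0]}\t{'.'.join(prefix[1:])}\t{obj}\n")

            for method, stats_ in res.items():
                emit([method], stats_)
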