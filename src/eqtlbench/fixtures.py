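"""Synthetic input bundles: a self-contained eQTL study with planted truth.

The generator emulates the statistical structure every benchmark needs, with
no downloads: an RI genotype panel with chromosome-wise linkage, expression
traits planted as cis (driven by the marker nearest the gene's own location)
or trans (driven by a planted regulator gene's nearest marker, optionally with
an AND-epistatic partner), pathways in which each regulator co-occurs with its
targets, a TF->target map of the planted regulation, and a mutant table
assigning large |log2| expression ratios to (regulator, target) pairs and
small background ratios elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .io import (
    ExpressionMatrix, GeneAnnotation, GenotypeMatrix,
    write_expression, write_gene_annotations, write_genotypes, write_gmt,
    write_mutant_table, write_tf_map,
)
from .simulate import TraitModelSpec, simulate_ri_genotypes, simulate_trait


@dataclass
class FixtureSpec:
    """Shape and effect sizes of the synthetic study.

    Defaults give a compact RI panel (100 strains, 5 x 100 markers at 1 Mb
    spacing) with 60 expression traits, half cis-regulated with effect 1.0
    (the single-locus simulation coefficient), half trans-regulated by one of
    6 planted regulators with effect 0.8, a quarter of the trans traits
    carrying an extra AND-epistatic term, and 5% Gaussian noise.
    """

    n_strains: int = 100
    chromosomes: list = field(default_factory=lambda: [(100, 100_000_000)] * 5)
    recomb_per_bp: float = 1e-8
    n_genes: int = 60
    fraction_cis: float = 0.5
    n_regulators: int = 6
    n_pathways: int = 10
    pathway_size: int = 10
    cis_effect: float = 1.0
    trans_effect: float = 0.8
    # weak local regulation on top of the trans signal: every trans trait also
    # gets its own gene's nearest marker with this (small) coefficient, so
    # recovering those cis loci separates methods that see weak effects
    secondary_cis_effect: float = 0.25
    # weak extra regulators on trans traits (same-pathway, small coefficient):
    # only methods that see effects beyond the primary locus recover them
    weak_trans_effect: float = 0.25
    n_weak_trans: int = 1
    # optional unannotated hub loci: when hub_effect > 0, the strong trans
    # driver is a marker with no nearby gene (a regulatory variant outside any
    # annotated pathway), replacing the primary regulator; pathway signal then
    # rides entirely on the weak regulators
    hub_effect: float = 0.0
    n_hubs: int = 3
    epistatic_effect: float = 1.0
    fraction_epistatic: float = 0.25   # of trans traits
    noise_pct: float = 5.0
    baseline: float = 9.0
    mutant_log2_planted: float = 3.0
    mutant_log2_background: float = 0.1
    gene_jitter_bp: int = 200_000
    seed: int = 0


@dataclass
class Fixture:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    genes: list
    pathways: dict
    tf_map: dict
    mutant_table: dict
    truth: dict
    spec: FixtureSpec

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.tsv",
            "expression": outdir / "expression.tsv",
            "genes": outdir / "genes.bed",
            "pathways": outdir / "pathways.gmt",
            "tf_map": outdir / "tf_map.tsv",
            "mutants": outdir / "mutants.tsv",
            "truth": outdir / "ground_truth.json",
            "provenance": outdir / "provenance.json",
        }
        write_genotypes(self.genotypes, paths["genotypes"])
        write_expression(self.expression, paths["expression"])
        write_gene_annotations(self.genes, paths["genes"])
        write_gmt(self.pathways, paths["pathways"])
        write_tf_map(self.tf_map, paths["tf_map"])
        write_mutant_table(self.mutant_table, paths["mutants"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=list)
        with open(paths["provenance"], "w") as fh:
            json.dump({"seed": self.spec.seed, "spec": self.spec.__dict__},
                      fh, indent=1, default=str)
        return {k: str(v) for k, v in paths.items()}


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the full synthetic study bundle from a FixtureSpec."""
    if spec.n_regulators > spec.n_genes:
        raise ValueError("more regulators than genes")
    if not 0.0 <= spec.fraction_cis <= 1.0:
        raise ValueError("fraction_cis must be in [0, 1]")

    genotypes = simulate_ri_genotypes(spec.n_strains, spec.chromosomes,
                                      spec.recomb_per_bp,
                                      seed=derive_seed(spec.seed, "genotypes"))
    markers = genotypes.markers
    p = len(markers)
    rng = np.random.default_rng(derive_seed(spec.seed, "layout"))

    # anchor each gene to a distinct marker; the gene sits within jitter of it
    anchors = rng.choice(p, size=spec.n_genes, replace=False)
    genes = []
    for gi, mi in enumerate(anchors):
        mid = int(markers.position_bp[mi]) + int(
            rng.integers(-spec.gene_jitter_bp, spec.gene_jitter_bp + 1))
        mid = max(mid, 5_001)
        genes.append(GeneAnnotation(
            gene_id=f"G{gi + 1:04d}", chromosome=str(markers.chromosome[mi]),
            start_bp=mid - 5_000, end_bp=mid + 5_000))
    gene_ids = [g.gene_id for g in genes]
    anchor_of = dict(zip(gene_ids, (int(a) for a in anchors)))

    # planted regulators are always cis-regulated themselves
    regulators = sorted(rng.choice(gene_ids, size=spec.n_regulators,
                                   replace=False))
    reg_set = set(regulators)
    others = [g for g in gene_ids if g not in reg_set]
    n_cis_total = int(round(spec.fraction_cis * spec.n_genes))
    n_cis_extra = max(0, n_cis_total - len(regulators))
    shuffled = list(rng.permutation(others))
    cis_genes = set(regulators) | set(shuffled[:n_cis_extra])

    # hub markers: strong unannotated trans drivers, kept away from gene anchors
    hub_markers = np.array([], dtype=int)
    if spec.hub_effect > 0:
        free = np.setdiff1d(np.arange(p), anchors)
        hub_markers = rng.choice(free, size=min(spec.n_hubs, free.size),
                                 replace=False)

    traits, values, gene_of_trait = [], [], {}
    truth_traits = {}
    targets_of_reg: dict[str, list] = {r: [] for r in regulators}
    tf_map: dict[str, set] = {}
    for g in genes:
        trait_id = f"T_{g.gene_id}"
        if g.gene_id in cis_genes:
            causal = [anchor_of[g.gene_id]]
            model = TraitModelSpec(
                baseline=spec.baseline,
                additive_terms=[(causal[0], spec.cis_effect)],
                noise_pct=spec.noise_pct)
            kind = "cis"
        else:
            if spec.hub_effect > 0 and hub_markers.size:
                # strong driver is an unannotated hub locus
                hub = int(hub_markers[int(rng.integers(0, hub_markers.size))])
                reg = None
                causal = [hub]
                additive = [(hub, spec.hub_effect)]
            else:
                reg = regulators[int(rng.integers(0, len(regulators)))]
                targets_of_reg[reg].append(g.gene_id)
                tf_map.setdefault(g.gene_id, set()).add(reg)
                causal = [anchor_of[reg]]
                additive = [(anchor_of[reg], spec.trans_effect)]
            if spec.secondary_cis_effect > 0:
                additive.append((anchor_of[g.gene_id], spec.secondary_cis_effect))
                causal.append(anchor_of[g.gene_id])
            if spec.weak_trans_effect > 0 and len(regulators) > 1:
                n_extra = min(spec.n_weak_trans, len(regulators) - 1)
                pool = [r for r in regulators if r != reg]
                for reg2 in rng.choice(pool, size=n_extra, replace=False):
                    additive.append((anchor_of[reg2], spec.weak_trans_effect))
                    causal.append(anchor_of[reg2])
                    tf_map.setdefault(g.gene_id, set()).add(reg2)
                    targets_of_reg[reg2].append(g.gene_id)
            epistatic = []
            if (reg is not None and len(regulators) > 1
                    and rng.random() < spec.fraction_epistatic):
                partner = reg
                while partner == reg:
                    partner = regulators[int(rng.integers(0, len(regulators)))]
                epistatic = [((anchor_of[reg], anchor_of[partner]),
                              spec.epistatic_effect)]
                tf_map[g.gene_id].add(partner)
                targets_of_reg[partner].append(g.gene_id)
                causal.append(anchor_of[partner])
                kind = "trans_epistatic"
            else:
                kind = "trans"
            model = TraitModelSpec(baseline=spec.baseline,
                                   additive_terms=additive,
                                   epistatic_terms=epistatic,
                                   noise_pct=spec.noise_pct)
        y = simulate_trait(model, genotypes,
                           seed=derive_seed(spec.seed, "trait", trait_id))
        traits.append(trait_id)
        values.append(y)
        gene_of_trait[trait_id] = g.gene_id
        truth_traits[trait_id] = {
            "gene": g.gene_id, "kind": kind,
            "causal_markers": [str(markers.marker_id[c]) for c in causal],
        }

    expression = ExpressionMatrix(strains=list(genotypes.strains),
                                  traits=traits,
                                  gene_of_trait=gene_of_trait,
                                  values=np.column_stack(values))

    # pathways: one per regulator containing regulator + its targets + fillers;
    # remaining pathways are random fillers so every gene is in >= 1 pathway
    pathways: dict[str, set] = {}
    covered: set[str] = set()
    for ri, reg in enumerate(regulators):
        members = {reg, *targets_of_reg[reg]}
        fillers = [g for g in gene_ids if g not in members]
        extra = max(0, spec.pathway_size - len(members))
        if extra and fillers:
            members |= set(rng.choice(fillers,
                                      size=min(extra, len(fillers)),
                                      replace=False))
        pathways[f"PW_reg{ri + 1:02d}"] = members
        covered |= members
    uncovered = [g for g in gene_ids if g not in covered]
    extra_needed = max(spec.n_pathways - len(pathways),
                       1 if uncovered else 0)
    for k in range(extra_needed):
        members = set(uncovered[k::extra_needed]) if uncovered else set()
        pool = [g for g in gene_ids if g not in members]
        want = max(0, spec.pathway_size - len(members))
        if want and pool:
            members |= set(rng.choice(pool, size=min(want, len(pool)),
                                      replace=False))
        if members:
            pathways[f"PW_rand{k + 1:02d}"] = members

    # mutant table: every (regulator, gene) pair gets a ratio; planted pairs
    # large, everything else small background
    mutant_table: dict[tuple, float] = {}
    for reg in regulators:
        planted = set(targets_of_reg[reg])
        for g in gene_ids:
            if g == reg:
                continue
            rng_m = np.random.default_rng(derive_seed(spec.seed, "mutant", reg, g))
            mag = spec.mutant_log2_planted if g in planted else spec.mutant_log2_background
            sign = -1.0 if rng_m.random() < 0.5 else 1.0
            mutant_table[(reg, g)] = sign * mag * (0.8 + 0.4 * rng_m.random())

    truth = {
        "seed": spec.seed,
        "regulators": regulators,
        "regulator_markers": {r: str(markers.marker_id[anchor_of[r]])
                              for r in regulators},
        "traits": truth_traits,
    }
    return Fixture(genotypes=genotypes, expression=expression, genes=genes,
                   pathways=pathways, tf_map=tf_map,
                   mutant_table=mutant_table, truth=truth, spec=spec)
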