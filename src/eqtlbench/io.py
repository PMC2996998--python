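"""Domain containers and readers/writers for the file formats the toolkit consumes.

Genotypes are recombinant-inbred (RI) style: every strain is homozygous at
every marker, so after ingest a genotype is a single bit per (strain, marker)
— 1 for the "B" parental allele, 0 for the "D" allele.  Heterozygous and
unknown calls are imputed at load time with the per-marker mode (ties go to 1)
so that downstream tree splits and selection-frequency counting operate on a
strictly binary matrix.

Coordinates are 1-based inclusive internally; BED input (0-based, half-open)
is converted at ingest.  All distance cutoffs in the toolkit (cis windows,
the 5 Mb gene-to-marker rule) are physical base-pair distances.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Allele codes accepted in genotype TSVs.  B/D are the two RI parental
# alleles; H (heterozygous) and U (unknown) are treated as missing.
_ALLELE_CODES = {
    "B": 1, "D": 0, "1": 1, "0": 0,
    "H": -1, "U": -1, "NA": -1, "": -1,
}


@dataclass(frozen=True)
class MarkerMap:
    """Genomic locations of the genotyped markers, in genome order."""

    marker_id: np.ndarray      # str array, unique
    chromosome: np.ndarray     # str array
    position_bp: np.ndarray    # int64, 1-based
    position_cm: np.ndarray | None = None

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        if len(set(mid)) != len(mid):
            raise ValueError("marker ids must be unique")
        pos = np.asarray(self.position_bp)
        if (pos < 0).any():
            raise ValueError("negative marker positions")
        for chrom in pd.unique(self.chromosome):
            p = pos[self.chromosome == chrom]
            if not (np.diff(p) >= 0).all():
                raise ValueError(f"markers on chromosome {chrom} not sorted by position")

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def index_of(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_id)}
        return np.array([lookup[m] for m in marker_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "position_bp": self.position_bp,
        }
        if self.position_cm is not None:
            d["position_cm"] = self.position_cm
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            marker_id=df["marker_id"].to_numpy(dtype=object),
            chromosome=df["chromosome"].astype(str).to_numpy(dtype=object),
            position_bp=df["position_bp"].to_numpy(dtype=np.int64),
            position_cm=(
                df["position_cm"].to_numpy(dtype=float)
                if "position_cm" in df.columns else None
            ),
        )


@dataclass
class GenotypeMatrix:
    """Binary RI genotypes: strains x markers, 1 = B allele, 0 = D allele."""

    strains: list[str]
    markers: MarkerMap
    values: np.ndarray  # (n_strains, n_markers) int8 in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.strains), len(self.markers)):
            raise ValueError("genotype value shape does not match strains x markers")
        if len(self.strains) < 2:
            raise ValueError("need at least 2 strains")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("genotype values must be 0/1 after imputation")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class ExpressionMatrix:
    """Expression traits (strains x traits), each trait tied to a gene id."""

    strains: list[str]
    traits: list[str]
    gene_of_trait: dict[str, str]
    values: np.ndarray  # (n_strains, n_traits) float64

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.strains), len(self.traits)):
            raise ValueError("expression value shape does not match strains x traits")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        missing = [t for t in self.traits if t not in self.gene_of_trait]
        if missing:
            raise ValueError(f"traits without a gene id: {missing[:5]}")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def trait_vector(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.traits.index(trait_id)]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def midpoint_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


# PathwayCollection: pathway id -> set of gene ids
PathwayCollection = dict[str, set]
# TFTargetMap: target gene id -> set of transcription-factor gene ids
TFTargetMap = dict[str, set]
# MutantEffectTable: (regulator gene id, target gene id) -> log2 expression ratio
MutantEffectTable = dict[tuple, float]


@dataclass
class LoadReport:
    """Bookkeeping from load_dataset: what was dropped or imputed."""

    shared_strains: int = 0
    genotype_only_strains: int = 0
    expression_only_strains: int = 0
    imputed_calls: int = 0
    dropped_traits_no_gene: int = 0
    notes: list = field(default_factory=list)


def _read_tsv(path):
    # pandas infers gzip from the .gz suffix
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def load_dataset(genotype_path, expression_path) -> tuple[GenotypeMatrix, ExpressionMatrix, LoadReport]:
    """Read genotype and expression TSVs and align them on shared strains.

    Genotype TSV: columns ``marker_id, chromosome, position_bp`` then one
    column per strain with allele codes in {B, D, H, U, 0, 1, NA}.  Expression
    TSV: columns ``trait_id, gene_id`` then one column per strain.

    Heterozygous/unknown calls are imputed with the per-marker mode (ties
    resolved to 1); traits lacking a gene id are dropped.  Returns the aligned
    matrices plus a LoadReport of counts.
    """
    report = LoadReport()

    gdf = _read_tsv(genotype_path)
    required = ["marker_id", "chromosome", "position_bp"]
    if list(gdf.columns[:3]) != required:
        raise ValueError(f"genotype file must start with columns {required}")
    strain_cols = list(gdf.columns[3:])

    edf = _read_tsv(expression_path)
    if list(edf.columns[:2]) != ["trait_id", "gene_id"]:
        raise ValueError("expression file must start with columns trait_id, gene_id")
    expr_strains = list(edf.columns[2:])

    shared = [s for s in strain_cols if s in set(expr_strains)]
    if len(shared) < 2:
        raise ValueError(
            f"fewer than 2 strains shared between genotype and expression files "
            f"(got {len(shared)})"
        )
    report.shared_strains = len(shared)
    report.genotype_only_strains = len(strain_cols) - len(shared)
    report.expression_only_strains = len(expr_strains) - len(shared)

    # decode allele codes; -1 marks missing
    raw = np.empty((len(shared), len(gdf)), dtype=np.int8)
    for i, s in enumerate(shared):
        col = gdf[s].fillna("NA").str.strip().str.upper()
        for j, code in enumerate(col):
            try:
                raw[i, j] = _ALLELE_CODES[code]
            except KeyError:
                raise ValueError(
                    f"unknown allele code {code!r} at marker "
                    f"{gdf['marker_id'].iloc[j]!r}, strain {s!r}"
                ) from None

    # per-marker mode imputation, ties -> 1
    for j in range(raw.shape[1]):
        col = raw[:, j]
        miss = col == -1
        if miss.all():
            raise ValueError(f"marker {gdf['marker_id'].iloc[j]!r} entirely missing")
        if miss.any():
            obs = col[~miss]
            n1 = int((obs == 1).sum())
            mode = 1 if n1 * 2 >= obs.size else 0
            col[miss] = mode
            report.imputed_calls += int(miss.sum())

    gdf = gdf.copy()
    gdf["position_bp"] = gdf["position_bp"].astype(np.int64)
    # sort positions within each chromosome, keeping the file's chromosome
    # order (so "chr10" does not jump ahead of "chr2")
    chrom_rank = {c: i for i, c in enumerate(pd.unique(gdf["chromosome"]))}
    order = np.lexsort((gdf["position_bp"].to_numpy(),
                        gdf["chromosome"].map(chrom_rank).to_numpy()))
    gdf = gdf.iloc[order].reset_index(drop=True)
    raw = raw[:, order]

    markers = MarkerMap(
        marker_id=gdf["marker_id"].to_numpy(dtype=object),
        chromosome=gdf["chromosome"].to_numpy(dtype=object),
        position_bp=gdf["position_bp"].to_numpy(),
    )
    genotypes = GenotypeMatrix(strains=list(shared), markers=markers, values=raw)

    keep = edf["gene_id"].notna() & (edf["gene_id"].astype(str).str.len() > 0)
    report.dropped_traits_no_gene = int((~keep).sum())
    if report.dropped_traits_no_gene:
        logger.info("dropped %d traits without a gene id", report.dropped_traits_no_gene)
    edf = edf[keep]
    traits = list(edf["trait_id"])
    evalues = edf[shared].to_numpy(dtype=np.float64).T
    expression = ExpressionMatrix(
        strains=list(shared),
        traits=traits,
        gene_of_trait=dict(zip(traits, edf["gene_id"])),
        values=evalues,
    )
    return genotypes, expression, report


def write_genotypes(genotypes: GenotypeMatrix, path, codes: bool = True) -> None:
    """Write a genotype TSV (B/D codes by default, 0/1 if codes=False)."""
    df = genotypes.markers.to_frame()[["marker_id", "chromosome", "position_bp"]]
    for i, s in enumerate(genotypes.strains):
        col = genotypes.values[i]
        if codes:
            df[s] = np.where(col == 1, "B", "D")
        else:
            df[s] = col
    df.to_csv(path, sep="\t", index=False)


def write_expression(expression: ExpressionMatrix, path) -> None:
    df = pd.DataFrame({
        "trait_id": expression.traits,
        "gene_id": [expression.gene_of_trait[t] for t in expression.traits],
    })
    for i, s in enumerate(expression.strains):
        df[s] = expression.values[i]
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayCollection:
    """Read gene sets from a GMT file (name, description, member genes)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    pathways: PathwayCollection = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in pathways:
                raise ValueError(f"GMT line {lineno}: duplicate pathway id {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"GMT line {lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return pathways


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read gene locations from BED (0-based half-open; name column = gene id).

    Converted to 1-based inclusive: start = bed_start + 1, end = bed_end.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
                     dtype={"chrom": str, "name": str})
    genes = []
    seen = set()
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ValueError(f"gene {row.name!r}: BED end <= start")
        if row.name in seen:
            raise ValueError(f"duplicate gene id {row.name!r}")
        seen.add(row.name)
        genes.append(GeneAnnotation(gene_id=row.name, chromosome=row.chrom,
                                    start_bp=start + 1, end_bp=end))
    return genes


def write_gene_annotations(genes: list, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\n")


def read_tf_map(path) -> TFTargetMap:
    """Read a two-column TSV (target, tf) into target -> {TFs}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["target", "tf"]:
        raise ValueError("TF map file must have columns target, tf")
    out: TFTargetMap = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.target, set()).add(row.tf)
    return out


def write_tf_map(tf_map: TFTargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("target\ttf\n")
        for target in sorted(tf_map):
            for tf in sorted(tf_map[target]):
                fh.write(f"{target}\t{tf}\n")


def read_mutant_table(path) -> MutantEffectTable:
    """Read a regulator/target/log2_ratio TSV.

    Repeated (regulator, target) pairs are collapsed by keeping the value of
    largest absolute magnitude.
    """
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    if list(df.columns[:3]) != ["regulator", "target", "log2_ratio"]:
        raise ValueError("mutant table must have columns regulator, target, log2_ratio")
    if len(df) == 0:
        warnings.warn("mutant effect table is empty")
        return {}
    ratios = pd.to_numeric(df["log2_ratio"], errors="raise").to_numpy(dtype=float)
    if not np.isfinite(ratios).all():
        raise ValueError("non-finite log2 ratio in mutant table")
    table: MutantEffectTable = {}
    for (reg, tgt), ratio in zip(zip(df["regulator"], df["target"]), ratios):
        key = (reg, tgt)
        if key not in table or abs(ratio) > abs(table[key]):
            table[key] = float(ratio)
    return table


def write_mutant_table(table: MutantEffectTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tlog2_ratio\n")
        for (reg, tgt), ratio in sorted(table.items()):
            fh.write(f"{reg}\t{tgt}\t{ratio!r}\n")


def map_genes_to_markers(genes, markers: MarkerMap,
                         max_dist_bp: int = 5_000_000) -> dict:
    """Map each gene to its nearest same-chromosome marker (by midpoint).

    Genes farther than ``max_dist_bp`` from every marker on their chromosome
    (or on chromosomes with no markers) are omitted.  Equidistant markers are
    resolved toward the lower coordinate.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(markers.chromosome):
        sel = markers.chromosome == chrom
        by_chrom[chrom] = (markers.position_bp[sel],
                           markers.marker_id[sel])
    mapping = {}
    for g in genes:
        if g.chromosome not in by_chrom:
            continue
        pos, ids = by_chrom[g.chromosome]
        dist = np.abs(pos.astype(np.int64) - g.midpoint_bp)
        best = int(np.argmin(dist))  # argmin takes the first = lowest position
        if dist[best] > max_dist_bp:
            continue
        mapping[g.gene_id] = ids[best]
    return mapping


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=list)
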