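"""Synthetic fixtures for every input class the toolkit consumes.

These generators stand in for the real atlas inputs at desk scale: a
tripartite TF-region-gene regulatory network with a planted
disease-relevant module, LD-blocked GWAS summary statistics whose signal
SNPs fall on the planted nodes, clustered negative-binomial expression for
a droplet reference plus an independent ISS draw restricted to a
155-gene-style panel, and a toy annotated label raster with two parallel
structures for axis construction.  Every generator is a deterministic
function of its spec and seed, and each can write the exact on-disk format
its consumer reads, so end-to-end file-to-file runs need no downloads.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas import GwasSummary, LdBlock, write_ld_blocks
from .isspatch import CellMatrix, write_cell_matrix
from .netcore import (
    GeneAnnotation,
    NetworkNode,
    RegulatoryNetwork,
    parse_region_id,
    write_network,
)
from .organaxis import LabelImage, StructureDef, write_label_image

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs


@dataclass
class GrnSpec:
    n_tf: int = 8
    n_region: int = 60
    n_gene: int = 120
    mean_degree: float = 2.0
    module_size: int = 20

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_region, self.n_gene, self.module_size) < 1:
            raise ValueError("all GRN sizes must be >= 1")
        if self.module_size > self.n_tf + self.n_region + self.n_gene:
            raise ValueError("planted module larger than the network")


@dataclass
class GwasSpec:
    snps_per_node: int = 3
    n_background_snps: int = 200
    n_blocks: int = 20
    block_size: int = 5
    block_r2: float = 0.5
    signal_beta_a: float = 0.1  # Beta(a, 1) p-values on planted-node SNPs

    def __post_init__(self) -> None:
        if self.snps_per_node < 1 or self.block_size < 1:
            raise ValueError("snps_per_node and block_size must be >= 1")
        if not (0 <= self.block_r2 <= 1):
            raise ValueError("block_r2 must lie in [0, 1]")
        if self.signal_beta_a <= 0:
            raise ValueError("signal_beta_a must be > 0")


@dataclass
class ExpressionSpec:
    n_genes: int = 300
    n_clusters: int = 5
    cells_per_cluster: int = 60
    iss_cells_per_cluster: int = 40
    markers_per_cluster: int = 15
    nb_mean_low: float = 1.0
    nb_mean_high: float = 8.0
    nb_dispersion: float = 10.0  # NB theta: var = mu + mu^2/theta
    fold_change: float = 5.0
    #: sd of per-gene per-cluster log-fold variation, as a multiple of
    #: log(fold_change): cell types differ transcriptome-wide, not only in
    #: their designated markers; 0 at fold_change = 1 (no separation)
    celltype_lfc_sd: float = 0.8
    panel_size: int = 155  # ISS pool size

    def __post_init__(self) -> None:
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size cannot exceed n_genes")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_clusters < 2 or self.cells_per_cluster < 3:
            raise ValueError("need >= 2 clusters and >= 3 cells per cluster")
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("too many markers for the gene count")


@dataclass(frozen=True)
class BandShape:
    """Vertical band spanning the full image height, x in [x0, x1) pixels."""

    name: str
    level: int
    label: int
    x0: int
    x1: int


@dataclass(frozen=True)
class DiscShape:
    name: str
    level: int
    label: int
    cx: float
    cy: float
    radius: float


@dataclass
class ImageSpec:
    height: int = 80
    width: int = 100
    pixel_size_um: float = 1.0
    shapes: tuple = (
        BandShape("suture", 1, 1, 10, 20),
        BandShape("bone", 1, 2, 80, 90),
        DiscShape("condensation", 0, 3, 50.0, 25.0, 8.0),
    )


@dataclass
class SyntheticSpec:
    """Bundle of all generator parameters plus the master seed."""

    seed: int = 0
    grn: GrnSpec = field(default_factory=GrnSpec)
    gwas: GwasSpec = field(default_factory=GwasSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    image: ImageSpec = field(default_factory=ImageSpec)


# ---------------------------------------------------------------------------
# GRN with a planted module


def _region_id(i: int) -> str:
    start = 1000 + i * 2000
    return f"chr1:{start}-{start + 500}"


def gen_grn(spec: GrnSpec, seed: int = 0) -> tuple[RegulatoryNetwork, set[str]]:
    """Tripartite TF->region->gene network with a connected planted module.

    Background regions attach to TFs and genes to regions by preferential
    attachment; the planted module is a star of regions around one TF with
    genes hung off those regions, so it is connected by construction.
    Importances are uniform in (0.1, 1].
    """
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1}" for i in range(spec.n_tf)]
    regions = [_region_id(i) for i in range(spec.n_region)]
    genes = [f"G{i + 1:04d}" for i in range(spec.n_gene)]

    m = spec.module_size
    m_r = min(spec.n_region, max(1, (m - 1) // 3))
    m_g = min(spec.n_gene, max(1, m - 1 - m_r))
    planted = {tfs[0], *regions[:m_r], *genes[:m_g]}

    def imp() -> float:
        return float(rng.uniform(0.1, 1.0))

    edges: list[tuple[str, str, float, str]] = []
    # planted module emulates one eRegulon: the TF binds every module
    # region and each target gene is driven by several module regions, so
    # the module is densely interconnected (as a real regulatory program
    # is), not a fragile star
    for r in regions[:m_r]:
        edges.append((tfs[0], r, imp(), "tf-region"))
    for i, g in enumerate(genes[:m_g]):
        for off in range(min(3, m_r)):
            edges.append((regions[(i + off) % m_r], g, imp(), "region-gene"))

    # background: preferential attachment on current degrees
    tf_deg = np.ones(spec.n_tf)
    tf_deg[0] += m_r
    for r in regions[m_r:]:
        t = int(rng.choice(spec.n_tf, p=tf_deg / tf_deg.sum()))
        tf_deg[t] += 1
        edges.append((tfs[t], r, imp(), "tf-region"))
    region_deg = np.ones(spec.n_region)
    region_deg[:m_r] += 1
    for g in genes[m_g:]:
        n_parents = 1 + int(rng.poisson(max(spec.mean_degree - 1, 0)))
        parents = rng.choice(
            spec.n_region,
            size=min(n_parents, spec.n_region),
            replace=False,
            p=region_deg / region_deg.sum(),
        )
        for ridx in parents:
            region_deg[ridx] += 1
            edges.append((regions[int(ridx)], g, imp(), "region-gene"))
    # a sprinkle of direct TF->gene links (retained by default)
    for t in tfs:
        for g in rng.choice(genes, size=min(2, spec.n_gene), replace=False):
            if g != t:
                edges.append((t, str(g), imp(), "tf-gene"))

    nodes = (
        [NetworkNode(t, "TF") for t in tfs]
        + [NetworkNode(r, "region", parse_region_id(r)) for r in regions]
        + [NetworkNode(g, "gene") for g in genes]
    )
    return RegulatoryNetwork(nodes, edges), planted


# ---------------------------------------------------------------------------
# GWAS summary statistics + LD blocks + gene coordinates


@dataclass
class SyntheticGwas:
    summary: GwasSummary
    blocks: list[LdBlock]
    genes: list[GeneAnnotation]
    snp_nodes: dict[str, str]  # variant -> node it was placed in ("" = background)


def gene_annotations_for(net: RegulatoryNetwork) -> list[GeneAnnotation]:
    """Deterministic toy-genome layout: gene i sits on chr2 with a 800 bp
    body every 3 kb, so genes never overlap each other."""
    gene_ids = sorted(net.nodes_of_kind("gene")) + sorted(net.nodes_of_kind("TF"))
    anns = []
    for i, g in enumerate(gene_ids):
        start = 1000 + i * 3000
        anns.append(GeneAnnotation(g, "chr2", start, start + 800, "+"))
    return anns


def gen_gwas(
    spec: GwasSpec,
    net: RegulatoryNetwork,
    planted: set[str],
    seed: int = 0,
) -> SyntheticGwas:
    """Summary statistics with uniform background p-values and Beta(a, 1)
    (concentrated near 0) p-values for SNPs landing on planted nodes, plus
    constant-r² LD blocks over consecutive variants."""
    unknown = planted - set(net.nodes)
    if unknown:
        raise ValueError(f"planted nodes not in network: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    genes = gene_annotations_for(net)
    gene_by_id = {a.gene_id: a for a in genes}

    rows = []
    snp_nodes: dict[str, str] = {}
    counter = 0

    def add_snp(chrom: str, pos: int, node: str) -> None:
        nonlocal counter
        counter += 1
        vid = f"rs{counter:06d}"
        if node in planted:
            p = float(rng.beta(spec.signal_beta_a, 1.0))
        else:
            p = float(rng.uniform(0.0, 1.0))
        p = min(max(p, 1e-300), 1.0)
        rows.append((vid, chrom, pos, p))
        snp_nodes[vid] = node

    for node in net.nodes.values():
        if node.kind == "region":
            iv = node.interval
            chrom, start, end = iv.chrom, iv.start, iv.end
        else:
            ann = gene_by_id.get(node.id)
            if ann is None:
                continue
            chrom, start, end = ann.chrom, ann.start, ann.end
        for _ in range(spec.snps_per_node):
            pos = int(rng.integers(start + 1, end + 1))  # 1-based inside [start, end)
            add_snp(chrom, pos, node.id)

    span = 1000 + 3000 * (len(genes) + len(net.nodes_of_kind("region")))
    for _ in range(spec.n_background_snps):
        chrom = "chr3"
        add_snp(chrom, int(rng.integers(1, span)), "")

    summary = GwasSummary(pd.DataFrame(rows, columns=["variant", "chrom", "pos", "p"]))

    # LD blocks over consecutive (chrom, pos)-sorted variants
    ordered = summary.records["variant"].tolist()
    blocks: list[LdBlock] = []
    for b in range(spec.n_blocks):
        members = ordered[b * spec.block_size : (b + 1) * spec.block_size]
        if len(members) < 2:
            break
        n = len(members)
        r2 = np.full((n, n), spec.block_r2)
        np.fill_diagonal(r2, 1.0)
        blocks.append(LdBlock(members, r2, block_id=f"B{b + 1}"))
    return SyntheticGwas(summary, blocks, genes, snp_nodes)


# ---------------------------------------------------------------------------
# clustered negative-binomial expression


@dataclass
class SyntheticExpression:
    reference: CellMatrix  # labels attached
    iss: CellMatrix  # labels withheld
    iss_true_labels: list[str]
    iss_true_counts_full: np.ndarray  # ISS cells x all genes, one noisy draw
    iss_true_means_full: np.ndarray  # ISS cells x all genes, ground-truth NB means
    panel: list[str]
    markers: dict[str, list[str]]  # cluster -> marker gene ids


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def gen_expression(
    spec: ExpressionSpec,
    seed: int = 0,
    planted_genes: Sequence[str] | None = None,
) -> SyntheticExpression:
    """Clustered negative-binomial counts for a reference and an ISS draw.

    Each cluster up-regulates its own marker genes by ``fold_change``.
    The ISS matrix is an independent draw from the same per-cluster means
    restricted to the panel (never a copy of reference cells), with true
    labels returned separately.  When ``planted_genes`` is given those
    genes become (the first) markers of cluster C1, tying the expression
    fixture to a planted network module.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    gene_set = set(genes)
    clusters = [f"C{i + 1}" for i in range(spec.n_clusters)]

    markers: dict[str, list[str]] = {}
    used: set[str] = set()
    if planted_genes is not None:
        seeded = [g for g in planted_genes if g in gene_set][: spec.markers_per_cluster]
        markers[clusters[0]] = list(seeded)
        used.update(seeded)
    free = [g for g in genes if g not in used]
    rng.shuffle(free)
    cursor = 0
    for c in clusters:
        cur = markers.get(c, [])
        need = spec.markers_per_cluster - len(cur)
        cur.extend(free[cursor : cursor + need])
        cursor += need
        markers[c] = cur

    base_mean = rng.uniform(spec.nb_mean_low, spec.nb_mean_high, size=spec.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    lfc_sd = spec.celltype_lfc_sd * math.log(spec.fold_change)
    cluster_means = {}
    for c in clusters:
        # broad cell-type identity: every gene carries a lognormal
        # cluster-specific factor; markers get the full fold change on top
        mu = base_mean * np.exp(rng.normal(0.0, lfc_sd, size=spec.n_genes))
        mu[[gene_idx[g] for g in markers[c]]] = (
            base_mean[[gene_idx[g] for g in markers[c]]] * spec.fold_change
        )
        cluster_means[c] = mu

    def draw(cells_per: int, cols: np.ndarray) -> tuple[np.ndarray, list[str]]:
        mats, labs = [], []
        for c in clusters:
            mu = np.tile(cluster_means[c][cols], (cells_per, 1))
            mats.append(_nb_draw(rng, mu, spec.nb_dispersion))
            labs.extend([c] * cells_per)
        X = np.vstack(mats)
        # guarantee no zero-total cell (breaks loading); bump one count
        zero = X.sum(axis=1) == 0
        X[zero, 0] += 1
        return X, labs

    all_cols = np.arange(spec.n_genes)
    X_ref, ref_labels = draw(spec.cells_per_cluster, all_cols)
    ref = CellMatrix(
        X_ref,
        genes,
        [f"ref_{i}" for i in range(X_ref.shape[0])],
        labels=ref_labels,
        modality="reference",
    )

    # panel: all markers plus random filler, sorted for determinism
    panel = sorted({g for ms in markers.values() for g in ms})
    filler = [g for g in genes if g not in panel]
    rng.shuffle(filler)
    panel = sorted(panel + filler[: max(0, spec.panel_size - len(panel))])
    panel_cols = np.array([gene_idx[g] for g in panel])

    X_iss_full, iss_labels = draw(spec.iss_cells_per_cluster, all_cols)
    iss_means_full = np.vstack(
        [np.tile(cluster_means[c], (spec.iss_cells_per_cluster, 1)) for c in clusters]
    )
    X_iss = X_iss_full[:, panel_cols]
    zero = X_iss.sum(axis=1) == 0
    X_iss[zero, 0] += 1
    iss = CellMatrix(
        X_iss,
        panel,
        [f"iss_{i}" for i in range(X_iss.shape[0])],
        labels=None,
        modality="iss",
    )
    return SyntheticExpression(
        ref, iss, iss_labels, X_iss_full, iss_means_full, panel, markers
    )


# ---------------------------------------------------------------------------
# label image


def gen_label_image(spec: ImageSpec) -> LabelImage:
    """Render non-overlapping named structures onto an integer raster."""
    px = np.zeros((spec.height, spec.width), dtype=np.int64)
    legend: dict[int, StructureDef] = {}
    for shape in spec.shapes:
        mask = np.zeros_like(px, dtype=bool)
        if isinstance(shape, BandShape):
            mask[:, shape.x0 : shape.x1] = True
        elif isinstance(shape, DiscShape):
            jj, ii = np.mgrid[0 : spec.height, 0 : spec.width]
            mask = (ii + 0.5 - shape.cx) ** 2 + (jj + 0.5 - shape.cy) ** 2 <= shape.radius**2
        else:
            raise TypeError(f"unknown shape type {type(shape).__name__}")
        if not mask.any():
            raise ValueError(f"structure {shape.name!r} rasterizes to no pixel")
        if (px[mask] != 0).any():
            raise ValueError(f"structure {shape.name!r} overlaps an earlier structure")
        px[mask] = shape.label
        legend[shape.label] = StructureDef(shape.name, shape.level)
    return LabelImage(px, spec.pixel_size_um, legend)


def gen_visium_coords(
    spec: ImageSpec, n_spots: int = 80, seed: int = 0
) -> pd.DataFrame:
    """Random pseudo-Visium spot coordinates within the image frame (µm)."""
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0, spec.width * spec.pixel_size_um, size=n_spots)
    ys = rng.uniform(0, spec.height * spec.pixel_size_um, size=n_spots)
    return pd.DataFrame(
        {"barcode": [f"BC{i + 1:04d}" for i in range(n_spots)], "x_um": xs, "y_um": ys}
    )


# ---------------------------------------------------------------------------
# file emission for end-to-end runs


def simulate_to_dir(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate one full scene and write every consumer format.

    Child seeds are derived from the master seed by fixed offsets so each
    generator is independently reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = int(spec.seed)
    net, planted = gen_grn(spec.grn, seed=s)
    syn_gwas = gen_gwas(spec.gwas, net, planted, seed=s + 1)
    planted_genes = sorted(n for n in planted if net.nodes[n].kind == "gene")
    expr = gen_expression(spec.expression, seed=s + 2, planted_genes=planted_genes)
    img = gen_label_image(spec.image)
    visium = gen_visium_coords(spec.image, seed=s + 3)

    paths: dict[str, Path] = {}

    paths["network"] = outdir / "network.edges.tsv"
    write_network(net, paths["network"])
    paths["planted"] = outdir / "planted_nodes.txt"
    paths["planted"].write_text("\n".join(sorted(planted)) + "\n")

    paths["gwas"] = outdir / "gwas.tsv"
    syn_gwas.summary.records.to_csv(paths["gwas"], sep="\t", index=False)
    paths["ld"] = outdir / "ld_blocks.txt"
    write_ld_blocks(syn_gwas.blocks, paths["ld"])
    paths["genes"] = outdir / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for a in syn_gwas.genes:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene_id}\n")

    paths["ref_counts"] = outdir / "reference_counts.csv"
    write_cell_matrix(expr.reference, paths["ref_counts"])
    paths["ref_labels"] = outdir / "reference_labels.tsv"
    pd.DataFrame(
        {"cell": expr.reference.cell_ids, "label": expr.reference.labels}
    ).to_csv(paths["ref_labels"], sep="\t", index=False)
    paths["iss_counts"] = outdir / "iss_counts.csv"
    write_cell_matrix(expr.iss, paths["iss_counts"])
    paths["iss_true_labels"] = outdir / "iss_true_labels.tsv"
    pd.DataFrame(
        {"cell": expr.iss.cell_ids, "label": expr.iss_true_labels}
    ).to_csv(paths["iss_true_labels"], sep="\t", index=False)

    paths["image"] = outdir / "annotation.png"
    paths["legend"] = outdir / "legend.json"
    write_label_image(img, paths["image"], paths["legend"])
    paths["visium"] = outdir / "visium_coords.csv"
    visium.to_csv(paths["visium"], index=False)
    return paths
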