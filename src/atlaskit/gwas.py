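"""GWAS summary statistics to network-node seeds.

The pipeline is: read summary statistics, score each SNP as -log10(p),
smooth scores across linked variants within LD blocks (r²-weighted
within-block means), then map SNPs onto gene and region nodes of a
regulatory network by genomic overlap, aggregating per node.  The result
is a :class:`~atlaskit.netcore.NodeSeed` ready for propagation.

Position conventions: GWAS positions are 1-based (the convention of
summary-statistics files); all intervals are 0-based half-open, and the
overlap rule converts explicitly (a SNP at 1-based position p overlaps
[start, end) iff start <= p-1 < end).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netcore import (
    FormatError,
    GeneAnnotation,
    NodeSeed,
    RegulatoryNetwork,
)

logger = logging.getLogger(__name__)

#: symmetric pad applied to gene bodies when assigning SNPs, in bp
DEFAULT_GENE_WINDOW_BP = 10_000


class GwasSummary:
    """Validated per-variant summary statistics (variant, chrom, pos, p).

    Positions are 1-based; p-values must lie in (0, 1].  Duplicate variant
    ids keep the record with the smallest p (with a warning).
    """

    def __init__(self, records: pd.DataFrame) -> None:
        df = records[["variant", "chrom", "pos", "p"]].copy()
        df["variant"] = df["variant"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(int)
        df["p"] = df["p"].astype(float)
        if (df["pos"] < 1).any():
            raise ValueError("GWAS positions must be >= 1 (1-based)")
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if df["variant"].duplicated().any():
            n_dup = int(df["variant"].duplicated().sum())
            logger.warning("%d duplicate variant ids; keeping smallest p each", n_dup)
            df = df.sort_values("p", kind="stable").drop_duplicates("variant", keep="first")
        self.records = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def read_gwas(
    path: str | Path,
    column_map: Mapping[str, str],
    sep: str = "\t",
) -> GwasSummary:
    """Read summary statistics from delimited text.

    ``column_map`` names the file's columns for the keys variant, chrom,
    pos and p (extra keys such as beta or z are accepted and ignored).
    Rows with unparsable or out-of-domain p (outside (0, 1]) or positions
    are dropped with a logged count.
    """
    for key in ("variant", "chrom", "pos", "p"):
        if key not in column_map:
            raise FormatError(f"column_map must name a column for {key!r}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [column_map[k] for k in ("variant", "chrom", "pos", "p") if column_map[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: mapped column(s) absent: {missing}")
    sub = pd.DataFrame(
        {
            "variant": df[column_map["variant"]],
            "chrom": df[column_map["chrom"]],
            "pos": pd.to_numeric(df[column_map["pos"]], errors="coerce"),
            "p": pd.to_numeric(df[column_map["p"]], errors="coerce"),
        }
    )
    n_before = len(sub)
    ok = sub["pos"].notna() & sub["p"].notna() & (sub["p"] > 0) & (sub["p"] <= 1) & (sub["pos"] >= 1)
    dropped = n_before - int(ok.sum())
    if dropped:
        logger.warning("%s: dropped %d rows with invalid position or p-value", path, dropped)
    return GwasSummary(sub[ok])


@dataclass
class LdBlock:
    """One LD block: an ordered variant list with its pairwise r² matrix."""

    variants: list[str]
    r2: np.ndarray
    block_id: str = ""

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variants)
        if r2.shape != (n, n):
            raise ValueError(f"LD block {self.block_id!r}: r2 must be {n}x{n}")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError(f"LD block {self.block_id!r}: r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError(f"LD block {self.block_id!r}: r2 diagonal must be exactly 1")
        if r2.min() < 0 or r2.max() > 1 + 1e-12:
            raise ValueError(f"LD block {self.block_id!r}: r2 entries must lie in [0, 1]")
        self.r2 = r2


def validate_blocks(blocks: Sequence[LdBlock]) -> None:
    """Each variant may belong to at most one block."""
    seen: dict[str, str] = {}
    for b in blocks:
        for v in b.variants:
            if v in seen:
                raise ValueError(f"variant {v!r} appears in blocks {seen[v]!r} and {b.block_id!r}")
            seen[v] = b.block_id or "?"


class SnpScore:
    """Per-variant raw score s = -log10(p) and LD-weighted score s'."""

    def __init__(self, table: pd.DataFrame) -> None:
        req = {"variant", "s", "s_prime"}
        if not req <= set(table.columns):
            raise ValueError(f"SnpScore table requires columns {sorted(req)}")
        if not np.isfinite(table[["s", "s_prime"]].to_numpy()).all():
            raise ValueError("SNP scores must be finite")
        if (table[["s", "s_prime"]].to_numpy() < 0).any():
            raise ValueError("SNP scores must be >= 0")
        self.table = table.reset_index(drop=True)

    def as_series(self, column: str = "s_prime") -> pd.Series:
        return self.table.set_index("variant")[column]


def score_snps(g: GwasSummary) -> SnpScore:
    """s_i = -log10(p_i); the LD-weighted score starts equal to s."""
    s = -np.log10(g.records["p"].to_numpy())
    table = pd.DataFrame({"variant": g.records["variant"], "s": s, "s_prime": s})
    return SnpScore(table)


def apply_ld_weighting(scores: SnpScore, blocks: Sequence[LdBlock]) -> SnpScore:
    """Smooth SNP scores within LD blocks.

    For block member i, s'_i = sum_j r2_ij * s_j / sum_j r2_ij over the
    block members present in the score table (j includes i since
    r2_ii = 1).  Variants in no block keep s' = s.  The result is a convex
    combination, so every weighted score stays within the block's raw
    score range.
    """
    validate_blocks(blocks)
    table = scores.table.copy()
    idx = pd.Index(table["variant"])
    s = table["s"].to_numpy()
    s_prime = table["s_prime"].to_numpy().copy()
    for block in blocks:
        pos = idx.get_indexer(block.variants)
        present = pos >= 0
        if not present.all():
            missing = [v for v, ok in zip(block.variants, present) if not ok]
            logger.warning(
                "LD block %s: %d variant(s) absent from scores, ignored", block.block_id, len(missing)
            )
        if present.sum() == 0:
            continue
        sub = pos[present]
        r2 = block.r2[np.ix_(present.nonzero()[0], present.nonzero()[0])]
        weights_sum = r2.sum(axis=1)
        s_prime[sub] = r2 @ s[sub] / weights_sum
    table["s_prime"] = s_prime
    return SnpScore(table)


# ---------------------------------------------------------------------------
# LD block file I/O: a concatenated plain-text format.  Each block starts
# with a line "#block <id>", followed by one line per variant:
# "<variant_id> <r2 row, whitespace-separated>".


def write_ld_blocks(blocks: Sequence[LdBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"#block {b.block_id}\n")
            for v, row in zip(b.variants, b.r2):
                fh.write(v + " " + " ".join(f"{x:.6g}" for x in row) + "\n")


def read_ld_blocks(path: str | Path) -> list[LdBlock]:
    blocks: list[LdBlock] = []
    block_id = None
    variants: list[str] = []
    rows: list[list[float]] = []

    def flush() -> None:
        if block_id is not None:
            blocks.append(LdBlock(variants.copy(), np.array(rows, dtype=float), block_id))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#block"):
                flush()
                block_id = line.split(maxsplit=1)[1] if " " in line else ""
                variants, rows = [], []
            else:
                if block_id is None:
                    raise FormatError(f"{path}: data line before any '#block' header")
                parts = line.split()
                variants.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
    flush()
    return blocks


# ---------------------------------------------------------------------------
# mapping SNP scores to network nodes


def map_scores_to_nodes(
    scores: SnpScore,
    g: GwasSummary,
    net: RegulatoryNetwork,
    genes: Sequence[GeneAnnotation],
    window_bp: int = DEFAULT_GENE_WINDOW_BP,
    agg: str = "max",
    context: str = "",
) -> NodeSeed:
    """Assign LD-weighted SNP scores to gene and region nodes by overlap.

    Gene nodes collect SNPs overlapping their annotation padded by
    ``window_bp`` on both sides; region nodes collect SNPs overlapping
    their own interval.  Per-node aggregation is the max of the collected
    scores by default (avoiding length bias), configurable to sum or
    mean.  TF nodes receive a seed only if they also match a gene
    annotation.  Nodes collecting no SNP are absent from the seed.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if agg not in ("max", "sum", "mean"):
        raise ValueError(f"agg must be max, sum or mean, got {agg!r}")

    s_prime = scores.as_series("s_prime")
    recs = g.records[g.records["variant"].isin(s_prime.index)]
    gene_by_id = {a.gene_id: a for a in genes}

    # candidate (node_id, chrom, start, end) intervals
    node_intervals: list[tuple[str, str, int, int]] = []
    n_unmatched = 0
    for node in net.nodes.values():
        if node.kind == "region":
            iv = node.interval
            node_intervals.append((node.id, iv.chrom, iv.start, iv.end))
        else:  # gene or TF: needs a gene annotation
            ann = gene_by_id.get(node.id)
            if ann is None:
                if node.kind == "gene":
                    n_unmatched += 1
                continue
            node_intervals.append(
                (node.id, ann.chrom, max(0, ann.start - window_bp), ann.end + window_bp)
            )
    if n_unmatched:
        logger.warning("%d gene node(s) without annotation receive no seed", n_unmatched)

    # per-chromosome sorted SNP positions for fast range queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in recs.groupby("chrom"):
        pos0 = grp["pos"].to_numpy() - 1  # 0-based index occupied by the SNP
        order = np.argsort(pos0, kind="stable")
        by_chrom[str(chrom)] = (pos0[order], s_prime.loc[grp["variant"]].to_numpy()[order])

    seed: dict[str, float] = {}
    for node_id, chrom, start, end in node_intervals:
        if chrom not in by_chrom:
            continue
        pos0, vals = by_chrom[chrom]
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        if hi <= lo:
            continue
        hit = vals[lo:hi]
        if agg == "max":
            score = float(hit.max())
        elif agg == "sum":
            score = float(hit.sum())
        else:
            score = float(hit.mean())
        # a node may be reachable both as TF and gene id; keep the larger
        seed[node_id] = max(score, seed.get(node_id, 0.0))
    return NodeSeed(seed, context=context)
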