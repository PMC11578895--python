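"""Network propagation of seed scores with permutation statistics.

This is the scoring core: seed scores (GWAS-derived or cluster-marker
derived) are spread over the regulatory network by a random walk with
restart (personalized PageRank), q = r*s + (1-r)*T*q, on the symmetrized,
importance-weighted graph.  A permutation null — the same propagation run
with seed values shuffled uniformly across all nodes — yields per-node
z-scores and empirical p-values.  Trait and cell-cluster propagations are
combined by the per-node minimum of the two z-scores, thresholded, and the
connected components of the surviving nodes are reported as enriched
subnetworks.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .netcore import IntegrityError, NodeSeed, RegulatoryNetwork, connected_components

logger = logging.getLogger(__name__)

#: cap on -log10 adjusted p marker scores
MARKER_SCORE_CAP = 300.0


@dataclass
class PropagationConfig:
    """Knobs of the propagation and its permutation null.

    restart_prob is the probability of jumping back to the seed
    distribution at each step (PageRank damping 1 - restart_prob);
    n_perm and z_thresh default to the published operating point
    (1000 permutations, z > 2).
    """

    restart_prob: float = 0.15
    tol: float = 1e-8
    max_iter: int = 1000
    n_perm: int = 1000
    rng_seed: int = 0
    z_thresh: float = 2.0
    perm_mode: str = "all"  # "all" or "degree_binned"

    def __post_init__(self) -> None:
        if not (0 < self.restart_prob <= 1):
            raise ValueError("restart_prob must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.perm_mode not in ("all", "degree_binned"):
            raise ValueError("perm_mode must be 'all' or 'degree_binned'")


class TransitionMatrix:
    """Column-stochastic transition operator over a fixed node order."""

    def __init__(self, matrix: sp.spmatrix, nodes: Sequence[str]) -> None:
        self.matrix = sp.csr_matrix(matrix)
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)


def build_transition(net: RegulatoryNetwork) -> TransitionMatrix:
    """Symmetrized, degree-normalized transition matrix.

    Edges are treated as undirected and weighted by importance; column j
    holds w_ij / deg_j.  Nodes with no (positively weighted) incident edge
    get a uniform column over all nodes so the walk never loses mass.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    nodes = net.node_ids
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    edges = net.edges
    if len(edges):
        src = edges["source"].map(index).to_numpy()
        tgt = edges["target"].map(index).to_numpy()
        w = edges["importance"].to_numpy(dtype=float)
        W = sp.coo_matrix((w, (src, tgt)), shape=(n, n))
        W = (W + W.T).tocsc()
    else:
        W = sp.csc_matrix((n, n))
    deg = np.asarray(W.sum(axis=0)).ravel()
    isolated = deg <= 0
    if isolated.any():
        logger.warning("%d node(s) with no positive-weight edge; uniform columns", int(isolated.sum()))
    safe_deg = np.where(isolated, 1.0, deg)
    T = (W @ sp.diags(1.0 / safe_deg)).tolil()
    for j in np.flatnonzero(isolated):
        T[:, j] = 1.0 / n
    return TransitionMatrix(T.tocsr(), nodes)


def _seed_vector(T: TransitionMatrix, seed: NodeSeed) -> np.ndarray:
    s = np.zeros(T.n)
    unknown = [k for k in seed.scores if k not in T.index]
    if unknown:
        logger.warning("%d seed node(s) absent from the network, ignored", len(unknown))
    for node_id, val in seed.items():
        i = T.index.get(node_id)
        if i is not None:
            if val < 0:
                raise ValueError(f"propagation seed for {node_id!r} is negative")
            s[i] = val
    return s


def _propagate_many(
    T: TransitionMatrix, S: np.ndarray, cfg: PropagationConfig
) -> np.ndarray:
    """Power-iterate q = r*s + (1-r)*T*q for each column of S (each a
    normalized seed distribution); returns the fixed points column-wise."""
    r = cfg.restart_prob
    Q = S.copy()
    for _ in range(cfg.max_iter):
        Q_next = r * S + (1.0 - r) * (T.matrix @ Q)
        resid = np.abs(Q_next - Q).sum(axis=0).max()
        Q = Q_next
        if resid < cfg.tol:
            return Q
    raise RuntimeError(
        f"propagation did not converge in {cfg.max_iter} iterations "
        f"(final L1 residual {resid:.3e} >= tol {cfg.tol:.3e})"
    )


def propagate(
    T: TransitionMatrix, seed: NodeSeed, cfg: PropagationConfig | None = None
) -> np.ndarray:
    """Random walk with restart from a seed distribution.

    The raw seed is normalized to sum 1 over all nodes (absent nodes get
    0); the returned q is the fixed point of q = r*s + (1-r)*T*q and sums
    to 1 (seed mass is conserved).
    """
    cfg = cfg or PropagationConfig()
    s = _seed_vector(T, seed)
    total = s.sum()
    if total <= 0:
        raise ValueError("seed has no positive entry on the network")
    s = s / total
    return _propagate_many(T, s[:, None], cfg)[:, 0]


@dataclass
class PropagationResult:
    """Observed propagation with its permutation null, per node."""

    nodes: list[str]
    q: np.ndarray
    mu_perm: np.ndarray
    sd_perm: np.ndarray
    z: np.ndarray
    p_emp: np.ndarray
    context: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "q": self.q,
                "mu_perm": self.mu_perm,
                "sd_perm": self.sd_perm,
                "z": self.z,
                "p_emp": self.p_emp,
            }
        )

    def z_seed(self) -> NodeSeed:
        return NodeSeed(dict(zip(self.nodes, self.z)), context=self.context, allow_negative=True)


def _degree_bins(T: TransitionMatrix, n_bins: int = 10) -> np.ndarray:
    deg = np.asarray((T.matrix != 0).sum(axis=0)).ravel()
    ranks = pd.Series(deg).rank(method="first").to_numpy()
    return np.minimum((ranks - 1) * n_bins // T.n, n_bins - 1).astype(int)


def permutation_zscores(
    T: TransitionMatrix, seed: NodeSeed, cfg: PropagationConfig | None = None
) -> PropagationResult:
    """Propagate a seed and contrast it with shuffled-seed propagations.

    Each permutation shuffles the raw seed values uniformly across all
    network nodes (zeros included; or within degree bins when
    cfg.perm_mode == "degree_binned"), re-propagates, and the per-node
    mean and sd over permutations give z = (q - mu)/sd.  sd == 0 (a
    degenerate null, e.g. a constant seed) yields z = 0 rather than an
    infinity that would poison downstream min-combination.  Empirical
    p = (1 + #{perm q >= observed q}) / (1 + n_perm).  Fully reproducible
    from cfg.rng_seed.
    """
    cfg = cfg or PropagationConfig()
    s_raw = _seed_vector(T, seed)
    if s_raw.sum() <= 0:
        raise ValueError("seed has no positive entry on the network")
    q_obs = propagate(T, seed, cfg)

    rng = np.random.default_rng(cfg.rng_seed)
    n = T.n
    perms = np.empty((n, cfg.n_perm), dtype=float)
    if cfg.perm_mode == "all":
        for j in range(cfg.n_perm):
            perms[:, j] = s_raw[rng.permutation(n)]
    else:
        bins = _degree_bins(T)
        for j in range(cfg.n_perm):
            col = s_raw.copy()
            for b in np.unique(bins):
                idx = np.flatnonzero(bins == b)
                col[idx] = col[idx][rng.permutation(len(idx))]
            perms[:, j] = col
    perms /= perms.sum(axis=0, keepdims=True)

    # batch the permuted propagations; chunk to bound memory on big runs
    chunk = max(1, min(cfg.n_perm, 512))
    sum_q = np.zeros(n)
    sum_q2 = np.zeros(n)
    count_ge = np.zeros(n)
    for start in range(0, cfg.n_perm, chunk):
        Q = _propagate_many(T, perms[:, start : start + chunk], cfg)
        sum_q += Q.sum(axis=1)
        sum_q2 += (Q**2).sum(axis=1)
        count_ge += (Q >= q_obs[:, None]).sum(axis=1)

    mu = sum_q / cfg.n_perm
    var = np.maximum(sum_q2 / cfg.n_perm - mu**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (q_obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    p_emp = (1.0 + count_ge) / (1.0 + cfg.n_perm)
    return PropagationResult(
        nodes=list(T.nodes),
        q=q_obs,
        mu_perm=mu,
        sd_perm=sd,
        z=z,
        p_emp=p_emp,
        context=seed.context,
    )


# ---------------------------------------------------------------------------
# cluster marker scores


def compute_marker_scores(
    cells: "CellMatrix",
    net: RegulatoryNetwork | None = None,
    min_cells: int = 3,
    cap: float = MARKER_SCORE_CAP,
) -> dict[str, NodeSeed]:
    """Differential-expression marker scores per cluster, as seeds.

    Counts are library-normalized to the median total, log1p-transformed,
    then each gene is compared in-cluster vs rest with a two-sided
    rank-sum test; p-values are Benjamini-Hochberg adjusted across genes
    within the cluster.  Gene score = -log10(p_adj) when the in-cluster
    mean exceeds the rest mean, else 0, capped at ``cap``.  When a network
    is given, seeds are restricted to its gene nodes.  Clusters with fewer
    than ``min_cells`` cells are excluded with a warning.
    """
    from .isspatch import CellMatrix  # local import avoids a cycle

    assert isinstance(cells, CellMatrix)
    if cells.labels is None:
        raise ValueError("cell matrix carries no cluster labels")
    X = cells.dense().astype(float)
    totals = X.sum(axis=1)
    X_norm = np.log1p(X * (np.median(totals) / totals)[:, None])

    labels = np.asarray(cells.labels)
    clusters = sorted(set(labels))
    kept = [c for c in clusters if (labels == c).sum() >= min_cells]
    dropped = set(clusters) - set(kept)
    if dropped:
        logger.warning("excluding cluster(s) with < %d cells: %s", min_cells, sorted(dropped))
    if len(kept) < 2:
        raise ValueError("need at least 2 clusters with enough cells")

    gene_node_ids = set(net.nodes) if net is not None else None
    out: dict[str, NodeSeed] = {}
    for cluster in kept:
        mask = labels == cluster
        a, b = X_norm[mask], X_norm[~mask]
        res = mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        pvals = np.nan_to_num(pvals, nan=1.0)  # constant genes: no evidence
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        up = a.mean(axis=0) > b.mean(axis=0)
        score = np.where(up, np.minimum(-np.log10(np.maximum(p_adj, 1e-320)), cap), 0.0)
        seed = {
            g: float(s)
            for g, s in zip(cells.gene_ids, score)
            if s > 0 and (gene_node_ids is None or g in gene_node_ids)
        }
        out[str(cluster)] = NodeSeed(seed, context=str(cluster))
    return out


# ---------------------------------------------------------------------------
# combination and subnetwork extraction


def combine_min(trait: PropagationResult, cluster: PropagationResult) -> NodeSeed:
    """Per-node minimum of trait and cluster z-scores.

    A node is enriched for the trait-cluster pair only if it scores highly
    in both propagations, hence the elementwise minimum.
    """
    if trait.nodes != cluster.nodes:
        raise IntegrityError("trait and cluster results are on different node universes")
    combined = np.minimum(trait.z, cluster.z)
    return NodeSeed(
        dict(zip(trait.nodes, combined)),
        context=f"{trait.context}|{cluster.context}",
        allow_negative=True,
    )


@dataclass
class Subnetwork:
    nodes: set[str]
    mean_score: float

    def __len__(self) -> int:
        return len(self.nodes)


def extract_subnetworks(
    net: RegulatoryNetwork, combined: NodeSeed, cfg: PropagationConfig | None = None
) -> list[Subnetwork]:
    """Threshold combined scores and report enriched connected components.

    Nodes with combined score > cfg.z_thresh are kept; connected
    components of the induced (undirected) subgraph are returned with
    their mean combined score, ranked by mean score descending.
    """
    cfg = cfg or PropagationConfig()
    unknown = set(combined.scores) - set(net.nodes)
    if unknown:
        raise IntegrityError(f"combined scores reference unknown nodes: {sorted(unknown)[:5]}")
    keep = {n for n, s in combined.items() if s > cfg.z_thresh}
    if not keep:
        return []
    comps = connected_components(net, keep)
    subs = [
        Subnetwork(c, float(np.mean([combined[n] for n in c])))
        for c in comps
    ]
    subs.sort(key=lambda s: (-s.mean_score, -len(s.nodes), min(s.nodes)))
    return subs
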