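"""Peak-associated gene ranking: joint PCA co-embedding, cosine kNN, modules.

Genes (top highly variable) and peaks are co-embedded by PCA of the paired
observations-by-features matrix: each feature's coordinates are its loading
vector scaled by the singular values (principal-axis coordinates of
variables), so features that covary across space land close together. Each
peak is then linked to its ten nearest gene features by cosine distance,
and spinglass community detection over the resulting graph yields spatially
co-detected peak-gene modules.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import MultimodalDataset


@dataclass
class FeatureEmbedding:
    feature_ids: list[str]
    feature_types: list[str]  # "gene" or "peak", aligned with feature_ids
    coords: np.ndarray        # features x d

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.feature_ids) != self.coords.shape[0]:
            raise ValueError("feature_ids and coords disagree")
        if len(self.feature_types) != len(self.feature_ids):
            raise ValueError("feature_types and feature_ids disagree")
        if self.coords.shape[1] < 2:
            raise ValueError("embedding needs at least 2 dimensions")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")


@dataclass
class PeakGeneGraph:
    """Directed peak-to-gene cosine-kNN graph with optional community labels."""

    nodes: list[str]
    node_types: dict[str, str]
    edges: list[tuple[str, str, float, int]]  # (peak, gene, cosine_distance, rank)
    community: dict[str, int] = field(default_factory=dict)

    def peak_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.node_types[n] == "peak"]

    def gene_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.node_types[n] == "gene"]


def _zscore_features(x: np.ndarray, names: list[str]) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant feature cannot be z-scored: {names[dead[0]]}")
    return (x - mu) / sd


def joint_embedding(
    mm: MultimodalDataset, hvgs: list[str], cfg: PipelineConfig
) -> FeatureEmbedding:
    """PCA co-embedding of HVG expression and peak intensities.

    The observations x features matrix stacks z-scored log-normalized HVG
    expression with z-scored log1p peak intensities; PCA retains
    ``cfg.n_pcs`` components and each feature's embedding is its loading
    scaled by the singular values. Component signs are fixed by forcing the
    largest-magnitude loading of each component positive, so repeated runs
    are bit-identical.
    """
    gene_index = {str(g): i for i, g in enumerate(mm.gene_ids)}
    missing = [g for g in hvgs if g not in gene_index]
    if missing:
        raise ValueError(f"HVGs absent from dataset (first: {missing[0]})")
    d = min(cfg.n_pcs, len(hvgs) + len(mm.mz))
    if mm.n_obs < d:
        raise ValueError(f"{mm.n_obs} observations < {d} requested components")

    gene_block = mm.gene_norm[[gene_index[g] for g in hvgs]].T  # obs x genes
    peak_block = np.log1p(mm.peak_intensities).T                # obs x peaks
    peak_names = [f"{mz:.4f}" for mz in mm.mz]
    x = np.column_stack(
        [_zscore_features(gene_block, hvgs), _zscore_features(peak_block, peak_names)]
    )
    _, sv, vt = np.linalg.svd(x, full_matrices=False)
    vt = vt[:d]
    sv = sv[:d]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(d), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    coords = (vt * sv[:, None]).T  # features x d

    return FeatureEmbedding(
        feature_ids=list(hvgs) + peak_names,
        feature_types=["gene"] * len(hvgs) + ["peak"] * len(peak_names),
        coords=coords,
    )


def peak_knn(embedding: FeatureEmbedding, cfg: PipelineConfig) -> PeakGeneGraph:
    """Exact cosine-distance k nearest gene features for each peak.

    Edges are directed peak -> gene, ranked 1..k by ascending cosine
    distance, ties broken by gene id. The search is exhaustive, hence exact.
    """
    types = np.array(embedding.feature_types)
    gene_idx = np.flatnonzero(types == "gene")
    peak_idx = np.flatnonzero(types == "peak")
    if peak_idx.size == 0:
        raise ValueError("embedding contains no peaks")
    k = min(cfg.knn_peaks, gene_idx.size)
    if k == 0:
        raise ValueError("embedding contains no genes")

    norms = np.linalg.norm(embedding.coords, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValueError(f"zero-vector embedding: {embedding.feature_ids[dead[0]]}")
    unit = embedding.coords / norms[:, None]
    dist = 1.0 - unit[peak_idx] @ unit[gene_idx].T  # peaks x genes
    dist = np.clip(dist, 0.0, 2.0)

    gene_names = [embedding.feature_ids[i] for i in gene_idx]
    peak_names = [embedding.feature_ids[i] for i in peak_idx]
    edges = []
    for pi, pname in enumerate(peak_names):
        order = sorted(range(len(gene_names)), key=lambda j: (dist[pi, j], gene_names[j]))
        for rank, j in enumerate(order[:k], start=1):
            edges.append((pname, gene_names[j], float(dist[pi, j]), rank))

    nodes = gene_names + peak_names
    node_types = {n: "gene" for n in gene_names}
    node_types.update({n: "peak" for n in peak_names})
    return PeakGeneGraph(nodes=nodes, node_types=node_types, edges=edges)


def _weakly_connected_components(graph: PeakGeneGraph) -> list[list[str]]:
    adj: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for a, b, _, _ in graph.edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    components = []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        components.append(comp)
    return components


def detect_modules(
    graph: PeakGeneGraph,
    cfg: PipelineConfig,
    gamma: float = 0.5,
    n_restarts: int = 5,
) -> PeakGeneGraph:
    """Spinglass community detection over the peak-gene graph.

    Edge weights are cosine similarities (1 - distance) clipped at zero;
    zero-weight edges are dropped. igraph's spinglass implementation
    requires an undirected connected graph, so the directed kNN graph is
    symmetrized by maximum weight and detection runs independently per
    weakly-connected component (isolated nodes form singleton communities).
    Labels are arbitrary integers, reproducible for a fixed ``cfg.seed``.

    The kNN graph is bipartite (edges run peak -> gene only), and at
    resolution gamma = 1 the Potts objective provably favors splitting even
    a homogeneous dense bipartite block into straddling sub-communities, so
    the default resolution is 0.5, which keeps such blocks whole while
    still separating unrelated blocks. Annealing is restarted
    ``n_restarts`` times per component and the partition with the best
    generalized modularity (at the same resolution) is kept.
    """
    import igraph

    weights: dict[tuple[str, str], float] = {}
    for a, b, dist, _ in graph.edges:
        w = max(0.0, 1.0 - dist)
        key = (a, b) if a <= b else (b, a)
        weights[key] = max(w, weights.get(key, 0.0))
    weights = {k: w for k, w in weights.items() if w > 0}

    if not weights:
        warnings.warn("graph has no positively weighted edges; "
                      "every node is its own community", stacklevel=2)
        community = {n: i for i, n in enumerate(graph.nodes)}
        return PeakGeneGraph(graph.nodes, graph.node_types, graph.edges, community)

    community: dict[str, int] = {}
    next_label = 0
    for ci, comp in enumerate(_weakly_connected_components(graph)):
        comp_set = set(comp)
        comp_edges = [(a, b, w) for (a, b), w in weights.items() if a in comp_set]
        if not comp_edges:
            for n in comp:
                community[n] = next_label
                next_label += 1
            continue
        names = sorted(comp_set)
        index = {n: i for i, n in enumerate(names)}
        g = igraph.Graph(
            n=len(names),
            edges=[(index[a], index[b]) for a, b, _ in comp_edges],
            edge_attrs={"weight": [w for _, _, w in comp_edges]},
        )
        best_membership, best_q = [0] * len(names), -np.inf
        for t in range(n_restarts):
            sub_seed = (cfg.seed * 1000003 + ci * 9973 + t * 101) % (2 ** 31)
            igraph.set_random_number_generator(random.Random(sub_seed))
            clustering = g.community_spinglass(weights="weight", gamma=gamma)
            q = g.modularity(clustering.membership, weights="weight", resolution=gamma)
            if q > best_q:
                best_q, best_membership = q, clustering.membership
        for i, n in enumerate(names):
            community[n] = next_label + best_membership[i]
        next_label += max(best_membership) + 1

    return PeakGeneGraph(graph.nodes, graph.node_types, graph.edges, community)


def export_peak_gene_table(graph: PeakGeneGraph) -> pd.DataFrame:
    """One row per edge: peak, rank, gene, cosine distance, communities."""
    rows = []
    for peak, gene, dist, rank in graph.edges:
        rows.append(
            (
                peak, rank, gene, dist,
                graph.community.get(peak, -1), graph.community.get(gene, -1),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["peak_mz", "rank", "gene", "cosine_distance",
                 "community_of_peak", "community_of_gene"],
    )
    return table.sort_values(["peak_mz", "rank"], kind="stable").reset_index(drop=True)


def import_peak_gene_table(table: pd.DataFrame) -> PeakGeneGraph:
    """Rebuild a PeakGeneGraph from an exported edge table."""
    edges = [
        (str(r.peak_mz), str(r.gene), float(r.cosine_distance), int(r.rank))
        for r in table.itertuples()
    ]
    peaks = sorted({e[0] for e in edges})
    genes = sorted({e[1] for e in edges})
    node_types = {n: "peak" for n in peaks}
    node_types.update({n: "gene" for n in genes})
    community = {}
    for r in table.itertuples():
        if int(r.community_of_peak) >= 0:
            community[str(r.peak_mz)] = int(r.community_of_peak)
        if int(r.community_of_gene) >= 0:
            community[str(r.gene)] = int(r.community_of_gene)
    return PeakGeneGraph(genes + peaks, node_types, edges, community)
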