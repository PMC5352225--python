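"""Seed clustering, the triplet/re-clustering iteration, tree assembly and
the within-cluster discreteness test.

The loop alternates (i) scoring every cluster triplet for marker and
transition genes plus its topology posterior, (ii) collecting the genes
supported in at least one confident triplet, and (iii) re-clustering the
cells inside that gene subspace, until the assignment stops changing or
the gene subspace stabilizes.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
import json
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from statefate.errors import ConvergenceError, PreconditionError, ValidationError
from statefate.io_prep import ExpressionMatrix
from statefate.triplet import (
    MIN_CELLS,
    Triplet,
    TripletPriors,
    TripletResult,
    analyze_triplet,
)


@dataclasses.dataclass
class ClusterAssignment:
    """Per-cell cluster labels (contiguous integers starting at 0)."""

    labels: np.ndarray
    cell_ids: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels must match cell ids")
        uniq = np.unique(self.labels)
        remap = {int(u): i for i, u in enumerate(uniq)}
        self.labels = np.array([remap[int(l)] for l in self.labels], dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_cells(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels}).to_csv(
            path, sep="\t", index=False
        )


@dataclasses.dataclass
class LineageTree:
    """Clusters as nodes, inferred transitions as undirected edges."""

    graph: nx.Graph
    score: float = float("nan")

    def __post_init__(self):
        if self.graph.number_of_nodes() > 1:
            if not nx.is_tree(self.graph):
                raise ValidationError("lineage tree must be connected and acyclic")

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def newick(self, root=None) -> str:
        if self.graph.number_of_nodes() == 0:
            return ";"
        root = root if root is not None else self.nodes[0]

        def render(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(render(c, node) for c in sorted(children))
            return f"({inner}){node}"

        return render(root, None) + ";"


@dataclasses.dataclass
class IterationState:
    iteration: int
    gene_subspace: set
    assignment: ClusterAssignment
    triplet_results: list
    converged: bool
    history: list


# ---------------------------------------------------------------------------
# seed clustering
# ---------------------------------------------------------------------------

def gap_statistic_k(
    values: np.ndarray,
    k_max: int = 20,
    seed: int = 0,
    n_refs: int = 10,
    n_init: int = 10,
) -> int:
    """Number of clusters by the gap statistic (uniform-box reference nulls).

    Picks the smallest k with gap(k) >= gap(k+1) - s(k+1).
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    k_max = min(k_max, values.shape[0])
    lo, hi = values.min(axis=0), values.max(axis=0)

    def dispersion(X, k, rs):
        if k == 1:
            return float(((X - X.mean(axis=0)) ** 2).sum())
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(X)
        return float(km.inertia_)

    log_w = np.empty(k_max)
    gap = np.empty(k_max)
    s_k = np.empty(k_max)
    refs = [rng.uniform(lo, hi, size=values.shape) for _ in range(n_refs)]
    for k in range(1, k_max + 1):
        log_w[k - 1] = np.log(max(dispersion(values, k, seed), 1e-12))
        ref_logs = np.array(
            [np.log(max(dispersion(r, k, seed), 1e-12)) for r in refs]
        )
        gap[k - 1] = ref_logs.mean() - log_w[k - 1]
        s_k[k - 1] = ref_logs.std(ddof=1) * np.sqrt(1 + 1 / n_refs)
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s_k[k]:
            return k
    return int(np.argmax(gap)) + 1


def seed_clusters(
    mat: ExpressionMatrix | np.ndarray,
    method: str = "kmeans_gap",
    seed: int = 0,
    k_max: int = 20,
    n_clusters: int | None = None,
    n_pcs: int = 10,
) -> ClusterAssignment:
    """Initial cell clustering.

    ``kmeans_gap``: gap statistic chooses k, then k-means with 20 restarts.
    ``embed_density``: PCA (top components) -> 2-D stochastic-neighbor
    embedding -> density-based clustering; noise points join their nearest
    cluster. Fixing ``n_clusters`` bypasses model selection (used to build
    deliberately over/under-split seeds).
    """
    if isinstance(mat, ExpressionMatrix):
        values = mat.counts.astype(float)
        cell_ids = mat.cell_ids
    else:
        values = np.asarray(mat, dtype=float)
        cell_ids = [f"cell{i}" for i in range(values.shape[0])]
    if method == "kmeans_gap":
        k = n_clusters or gap_statistic_k(values, k_max=k_max, seed=seed)
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(values)
        return ClusterAssignment(km.labels_, cell_ids)
    if method == "embed_density":
        n_comp = min(n_pcs, values.shape[1], values.shape[0] - 1)
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(values)
        emb = TSNE(
            n_components=2, random_state=seed, perplexity=min(30, values.shape[0] - 1) / 1.0,
            init="pca",
        ).fit_transform(pcs)
        span = float(np.linalg.norm(emb.max(axis=0) - emb.min(axis=0)))
        db = DBSCAN(eps=max(span / 16.0, 1e-6), min_samples=5).fit(emb)
        labels = db.labels_.copy()
        if (labels == -1).any():
            centroids = {
                k: emb[labels == k].mean(axis=0) for k in np.unique(labels) if k != -1
            }
            if not centroids:
                labels[:] = 0
            else:
                for i in np.flatnonzero(labels == -1):
                    labels[i] = min(
                        centroids, key=lambda k: np.linalg.norm(emb[i] - centroids[k])
                    )
        return ClusterAssignment(labels, cell_ids)
    raise ValidationError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# triplet enumeration and the iteration loop
# ---------------------------------------------------------------------------

def enumerate_triplets(
    assignment: ClusterAssignment, min_cells: int = MIN_CELLS
) -> list:
    """All unordered cluster triplets whose members all have >= min_cells cells."""
    triplets = []
    eligible = [
        k for k in range(assignment.n_clusters)
        if assignment.cluster_cells(k).size >= min_cells
    ]
    for a, b, c in itertools.combinations(eligible, 3):
        triplets.append(
            Triplet(
                cluster_ids=(a, b, c),
                cells=(
                    tuple(assignment.cluster_cells(a)),
                    tuple(assignment.cluster_cells(b)),
                    tuple(assignment.cluster_cells(c)),
                ),
            )
        )
    return triplets


def _analyze_all_triplets(values, assignment, gene_ids, priors, min_cells):
    return [
        analyze_triplet(values, t, gene_ids, priors=priors, min_cells=min_cells)
        for t in enumerate_triplets(assignment, min_cells)
    ]


def select_gene_subspace(
    triplet_results: Sequence[TripletResult],
    gene_cutoff: float = 0.5,
    triplet_cutoff: float = 0.6,
) -> set:
    """Genes with marker-or-transition posterior above the cutoff in at least
    one triplet whose best topology posterior reaches the triplet cutoff."""
    genes: set = set()
    for result in triplet_results:
        if float(np.max(result.p_topology)) < triplet_cutoff:
            continue
        for gp in result.gene_posteriors:
            if 1.0 - gp.p_null > gene_cutoff:
                genes.add(gp.gene_id)
    return genes


def run_iterations(
    mat: ExpressionMatrix,
    seed_assignment: ClusterAssignment,
    gene_cutoff: float = 0.5,
    triplet_cutoff: float = 0.6,
    max_iter: int = 20,
    method: str = "kmeans_gap",
    seed: int = 0,
    priors: TripletPriors | None = None,
    min_cells: int = MIN_CELLS,
    k_max: int = 20,
) -> IterationState:
    """Iterate triplet inference and re-clustering until convergence.

    Stops when the assignment is reproduced exactly (ARI = 1 against the
    previous iteration) or the gene subspace changes by less than 10 percent
    (Jaccard); otherwise runs ``max_iter`` iterations and warns.
    """
    if seed_assignment.n_clusters < 3:
        raise PreconditionError("need at least 3 seed clusters")
    values = mat.counts.astype(float)
    gene_ids = list(mat.gene_ids)
    priors = priors or TripletPriors()
    assignment = seed_assignment
    prev_genes: set | None = None
    history: list = []
    converged = False
    results: list = []
    genes: set = set()
    for it in range(1, max_iter + 1):
        results = _analyze_all_triplets(values, assignment, gene_ids, priors, min_cells)
        genes = select_gene_subspace(results, gene_cutoff, triplet_cutoff)
        if not genes:
            raise ConvergenceError(
                f"iteration {it}: empty gene subspace "
                f"({len(results)} triplets, cutoffs {gene_cutoff}/{triplet_cutoff})"
            )
        cols = [j for j, g in enumerate(gene_ids) if g in genes]
        new_assignment = seed_clusters(
            values[:, cols], method=method, seed=seed, k_max=k_max
        )
        new_assignment = ClusterAssignment(new_assignment.labels, list(mat.cell_ids))
        ari = adjusted_rand_score(assignment.labels, new_assignment.labels)
        jaccard = (
            len(genes & prev_genes) / len(genes | prev_genes)
            if prev_genes
            else 0.0
        )
        history.append(
            {
                "iteration": it,
                "n_clusters": new_assignment.n_clusters,
                "n_genes": len(genes),
                "ari_vs_previous": float(ari),
                "gene_jaccard_vs_previous": float(jaccard),
            }
        )
        stable_assignment = ari == 1.0 and new_assignment.n_clusters == assignment.n_clusters
        stable_genes = prev_genes is not None and (1.0 - jaccard) < 0.10
        if stable_assignment or stable_genes:
            converged = True
            if not stable_assignment:
                # recompute triplet scores for the final assignment
                assignment = new_assignment
                results = _analyze_all_triplets(
                    values, assignment, gene_ids, priors, min_cells
                )
                genes = select_gene_subspace(results, gene_cutoff, triplet_cutoff)
            break
        assignment = new_assignment
        prev_genes = genes
    if not converged:
        warnings.warn(f"no convergence after {max_iter} iterations", stacklevel=2)
    return IterationState(
        iteration=len(history),
        gene_subspace=genes,
        assignment=assignment,
        triplet_results=results,
        converged=converged,
        history=history,
    )


def write_history(state: IterationState, path: str | Path) -> None:
    with open(path, "w") as fh:
        for record in state.history:
            fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# tree assembly
# ---------------------------------------------------------------------------

def _prufer_trees(nodes: list):
    """All labeled trees on the given nodes, via Prüfer sequences."""
    n = len(nodes)
    if n == 2:
        yield [(nodes[0], nodes[1])]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for i in seq:
            degree[i] += 1
        edges = []
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        for i in seq:
            leaf = heapq.heappop(heap)
            edges.append((nodes[leaf], nodes[i]))
            degree[i] -= 1
            if degree[i] == 1:
                heapq.heappush(heap, i)
        # exactly two leaves remain once the sequence is consumed
        a = heapq.heappop(heap)
        b = heapq.heappop(heap)
        edges.append((nodes[a], nodes[b]))
        yield edges


def _tree_distances(nodes: list, edges: list) -> np.ndarray:
    """All-pairs hop distances on a tree (BFS per node)."""
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[] for _ in nodes]
    for u, v in edges:
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])
    n = len(nodes)
    dist = np.full((n, n), -1, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            frontier = nxt
    return dist


def tree_score(
    nodes: list,
    edges: list,
    triplet_probs: dict,
    external_logp: float = np.log(1 / 3),
) -> float:
    """Sum of log topology posteriors implied by the tree.

    For each scored triplet the implied intermediate is its tree median
    (the node minimizing summed distance to the three); when the median is
    outside the triplet no candidate topology applies and the triplet
    contributes the agnostic ``external_logp``.
    """
    idx = {v: i for i, v in enumerate(nodes)}
    dist = _tree_distances(nodes, edges)
    score = 0.0
    for trip_ids, probs in triplet_probs.items():
        ia, ib, ic = (idx[t] for t in trip_ids)
        med = int(np.argmin(dist[:, ia] + dist[:, ib] + dist[:, ic]))
        positions = {idx[t]: k for k, t in enumerate(trip_ids)}
        if med in positions:
            score += float(np.log(max(probs[positions[med]], 1e-300)))
        else:
            score += external_logp
    return score


def _triplet_prob_table(triplet_results: Sequence[TripletResult]) -> dict:
    return {
        tuple(r.triplet.cluster_ids): np.asarray(r.p_topology, dtype=float)
        for r in triplet_results
    }


def _neighbor_trees(nodes, edges):
    """Trees reachable by replacing one edge with another cross edge."""
    idx = {v: i for i, v in enumerate(nodes)}
    for k, (u, v) in enumerate(edges):
        rest = [e for j, e in enumerate(edges) if j != k]
        g = nx.Graph(rest)
        g.add_nodes_from(nodes)
        comp_u = nx.node_connected_component(g, u)
        comp_v = set(nodes) - comp_u
        for x in comp_u:
            for y in comp_v:
                if (x, y) == (u, v) or (y, x) == (u, v):
                    continue
                yield rest + [(x, y)]


def assemble_tree(
    triplet_results: Sequence[TripletResult],
    cluster_ids: Sequence | None = None,
    exhaustive_limit: int = 7,
) -> LineageTree:
    """Most-parsimonious tree: maximize the summed log topology posteriors.

    Exhaustive over all labeled trees up to ``exhaustive_limit`` clusters;
    beyond that, steepest-ascent edge replacement from chain, star and
    topology-seeded starting trees.
    """
    probs = _triplet_prob_table(triplet_results)
    if cluster_ids is None:
        nodes = sorted({c for ids in probs for c in ids})
    else:
        nodes = sorted(cluster_ids)
    if len(nodes) < 3:
        warnings.warn("fewer than 3 clusters; trivial tree returned", stacklevel=2)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        if len(nodes) == 2:
            g.add_edge(nodes[0], nodes[1])
        return LineageTree(g, score=0.0)

    if len(nodes) <= exhaustive_limit:
        best_edges, best_score = None, -np.inf
        for edges in _prufer_trees(nodes):
            s = tree_score(nodes, edges, probs)
            if s > best_score:
                best_score, best_edges = s, edges
        g = nx.Graph(best_edges)
        g.add_nodes_from(nodes)
        return LineageTree(g, score=best_score)

    starts = [[(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)]]
    for center in nodes:
        starts.append([(center, v) for v in nodes if v != center])
    best_edges, best_score = None, -np.inf
    for edges in starts:
        score = tree_score(nodes, edges, probs)
        improved = True
        while improved:
            improved = False
            for cand in _neighbor_trees(nodes, edges):
                s = tree_score(nodes, cand, probs)
                if s > score + 1e-12:
                    edges, score = cand, s
                    improved = True
                    break
        if score > best_score:
            best_score, best_edges = score, edges
    g = nx.Graph(best_edges)
    g.add_nodes_from(nodes)
    return LineageTree(g, score=best_score)


# ---------------------------------------------------------------------------
# discreteness test
# ---------------------------------------------------------------------------

def _pc_variances(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    svals = np.linalg.svd(Xc, compute_uv=False)
    return svals ** 2 / (X.shape[0] - 1)


def discreteness_test(
    mat: ExpressionMatrix | np.ndarray,
    assignment: ClusterAssignment,
    genes: Sequence | None = None,
    n_rand: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-cluster test of whether any principal component is significant.

    Null distribution: each gene's values permuted independently across the
    cluster's cells; statistic = maximum PC variance per randomization.
    ``pc1_variance_ratio`` is observed PC1 variance divided by the maximum
    over randomizations; a ratio above 1 flags residual structure.
    """
    if isinstance(mat, ExpressionMatrix):
        values = mat.counts.astype(float)
        if genes is not None:
            keep = [j for j, g in enumerate(mat.gene_ids) if g in set(genes)]
            values = values[:, keep]
    else:
        values = np.asarray(mat, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for k in range(assignment.n_clusters):
        cells = assignment.cluster_cells(k)
        if cells.size < 3:
            raise PreconditionError(f"cluster {k} has fewer than 3 cells")
        X = values[cells]
        if np.allclose(X.var(axis=0), 0):
            out[k] = {"pc1_variance_ratio": 0.0, "significant": False}
            continue
        obs = _pc_variances(X)[0]
        null_max = 0.0
        Xr = X.copy()
        for _ in range(n_rand):
            for j in range(Xr.shape[1]):
                rng.shuffle(Xr[:, j])
            null_max = max(null_max, float(_pc_variances(Xr)[0]))
        ratio = float(obs / null_max) if null_max > 0 else 0.0
        out[k] = {"pc1_variance_ratio": ratio, "significant": ratio > 1.0}
    return out
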