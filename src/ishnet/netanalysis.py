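"""Downstream analyses of an estimated gene network.

Covers the standard battery applied to inferred interaction networks:
scale-free (power-law) fit of the degree distribution, spectral clustering
and the within-cluster edge ratio as a modularity proxy, hypergeometric
enrichment of annotation terms with Bonferroni correction, hub selection,
and per-gene neighbor-regression residue analysis (how well each gene's
spatial pattern is explained as a linear combination of its network
neighbors, the key observable consequence of the Gaussian model).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .glasso import SparseNetwork

__all__ = [
    "PowerLawFit",
    "EnrichmentResult",
    "degree_ccdf",
    "fit_power_law_ccdf",
    "degree_ccdf_power_law",
    "spectral_cluster",
    "within_cluster_edge_ratio",
    "enrichment_test",
    "select_hubs",
    "neighbor_regression_residues",
]


@dataclass
class PowerLawFit:
    """Least-squares power-law fit of the degree CCDF, P(k) ~ c * k^(-gamma)."""

    gamma: float
    c: float
    degrees_used: np.ndarray

    def predict(self, k):
        return self.c * np.asarray(k, dtype=float) ** (-self.gamma)


@dataclass
class EnrichmentResult:
    """One term's hypergeometric enrichment in one gene set."""

    term: str
    cluster_id: object
    k_in: int  # annotated members of the set
    n_in: int  # set size
    K_bg: int  # annotated genes in the background
    N_bg: int  # background size
    p_raw: float
    p_corrected: float
    enriched: bool


def _as_graph(network) -> nx.Graph:
    """Accept a SparseNetwork, an nx.Graph, or an iterable of edges."""
    if isinstance(network, nx.Graph):
        return network
    G = nx.Graph()
    if isinstance(network, SparseNetwork):
        G.add_nodes_from(network.gene_ids)
        G.add_edges_from(network.edges)
    else:
        G.add_edges_from(network)
    return G


def degree_ccdf(network, min_tail_count: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """P(k) = fraction of genes with at least k interactions, for k >= 1.

    Evaluated at the distinct observed degrees (the plotted support).  With
    ``min_tail_count`` > 1, support points backed by fewer than that many
    genes are dropped: the empirical CCDF cannot fall below 1/p, so the
    extreme tail flattens artificially and would bias a slope fit.  If
    fewer than two points survive the cutoff, all points are kept.
    """
    G = _as_graph(network)
    degrees = np.array([d for _, d in G.degree()])
    if degrees.size == 0:
        raise ValueError("network has no nodes")
    if degrees.max() < 1:
        raise ValueError("network has no edges")
    ks = np.unique(degrees[degrees >= 1])
    counts = np.array([(degrees >= k).sum() for k in ks])
    pk = counts / degrees.size
    keep = counts >= min_tail_count
    if keep.sum() < 2:
        keep = np.ones_like(keep, dtype=bool)
    return ks[keep], pk[keep]


def fit_power_law_ccdf(k: np.ndarray, pk: np.ndarray) -> PowerLawFit:
    """Fit log P(k) = log c - gamma * log k by ordinary least squares."""
    k = np.asarray(k, dtype=float)
    pk = np.asarray(pk, dtype=float)
    if k.size < 2 or np.unique(k).size < 2:
        raise ValueError("power-law fit needs at least two distinct degrees")
    logk, logp = np.log(k), np.log(pk)
    slope, intercept = np.polyfit(logk, logp, 1)
    return PowerLawFit(gamma=float(-slope), c=float(np.exp(intercept)), degrees_used=k)


def degree_ccdf_power_law(network, min_tail_count: int = 10) -> PowerLawFit:
    """Scale-free fit of a network's degree distribution.

    Computes the CCDF over its support (k >= 1), drops unreliable extreme
    tail points (fewer than ``min_tail_count`` genes, see
    :func:`degree_ccdf`), and fits the log-log line.  All-equal degrees give
    a single support point and raise (degenerate fit).
    """
    ks, pk = degree_ccdf(network, min_tail_count=min_tail_count)
    return fit_power_law_ccdf(ks, pk)


def spectral_cluster(
    network,
    k: int = 12,
    seed: int = 0,
    restarts: int = 10,
    weighted: bool = False,
) -> dict:
    """Normalized spectral clustering of the network into k clusters.

    The classic recipe on the (binary, or |theta|-weighted) adjacency: form
    the symmetric-normalized Laplacian, take the k eigenvectors with smallest
    eigenvalues, row-normalize them, and run k-means with a fixed seed and
    ``restarts`` restarts.  Deterministic given the seed.  Returns
    {node: cluster label}.
    """
    G = _as_graph(network)
    nodes = list(G.nodes())
    n = len(nodes)
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} nodes")
    if weighted and isinstance(network, SparseNetwork):
        A = np.abs(network.theta.copy())
        np.fill_diagonal(A, 0.0)
    else:
        A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    w, V = np.linalg.eigh(L)
    U = V[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(U)
    return {node: int(lab) for node, lab in zip(nodes, labels)}


def within_cluster_edge_ratio(network, labels: dict) -> float:
    """Fraction of edges whose two endpoints share a cluster label."""
    G = _as_graph(network)
    edges = list(G.edges())
    if not edges:
        raise ValueError("within-cluster ratio undefined for an edgeless network")
    missing = [v for v in G.nodes() if v not in labels]
    if missing:
        raise ValueError(f"labels missing for nodes: {missing[:5]}")
    within = sum(1 for a, b in edges if labels[a] == labels[b])
    return within / len(edges)


def enrichment_test(
    member_genes,
    annotations: pd.DataFrame | dict,
    background_genes,
    alpha: float = 0.05,
    cluster_id=None,
) -> list[EnrichmentResult]:
    """Hypergeometric (upper-tail) term enrichment with Bonferroni correction.

    For each term annotating at least one member gene, computes
    P(X >= k_in) for X hypergeometric with ``n_in`` draws from ``N_bg`` genes
    of which ``K_bg`` carry the term.  The Bonferroni multiplier is the
    number of terms tested in this analysis; corrected p-values are capped at
    1 and flagged enriched when below ``alpha``.

    ``annotations`` maps gene -> set of terms, or is a DataFrame with
    ``gene_id`` and ``term`` columns restricted to background genes.
    """
    members = set(member_genes)
    background = set(background_genes)
    if not members <= background:
        raise ValueError("member genes must be a subset of the background")
    if isinstance(annotations, pd.DataFrame):
        gene_terms: dict = {}
        for g, t in zip(annotations["gene_id"], annotations["term"]):
            gene_terms.setdefault(g, set()).add(t)
    else:
        gene_terms = {g: set(ts) for g, ts in annotations.items()}

    term_bg: dict = {}
    term_members: dict = {}
    for g in background:
        for t in gene_terms.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in members:
                term_members[t] = term_members.get(t, 0) + 1

    terms = sorted(term_members)  # terms with >= 1 annotated member
    n_tests = len(terms)
    N, n = len(background), len(members)
    results = []
    for t in terms:
        K, kin = term_bg[t], term_members[t]
        p_raw = float(stats.hypergeom.sf(kin - 1, N, K, n))
        p_corr = min(1.0, p_raw * n_tests)
        results.append(
            EnrichmentResult(
                term=t,
                cluster_id=cluster_id,
                k_in=kin,
                n_in=n,
                K_bg=K,
                N_bg=N,
                p_raw=p_raw,
                p_corrected=p_corr,
                enriched=p_corr < alpha,
            )
        )
    return results


def select_hubs(network, top_fraction: float = 0.05) -> set:
    """Genes in the top ``top_fraction`` of network degree, ties included.

    Returns the smallest set with at least ceil(top_fraction * p) genes such
    that no excluded gene out-ranks an included one; every gene tied at the
    threshold degree is included.
    """
    G = _as_graph(network)
    degrees = dict(G.degree())
    if not degrees:
        raise ValueError("network is empty")
    p = len(degrees)
    n_top = int(np.ceil(top_fraction * p))
    ranked = sorted(degrees.values(), reverse=True)
    threshold = ranked[n_top - 1]
    return {g for g, d in degrees.items() if d >= threshold}


def neighbor_regression_residues(
    gene,
    network,
    feature_data: pd.DataFrame,
    rescale: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Regress a gene's spatial expression on its network neighbors.

    ``feature_data`` is a triangles x genes table.  Expression is first
    rescaled so the global maximum is 1 (unless ``rescale=False``), then the
    gene's per-triangle values are fit by OLS (with intercept) on its
    neighbors'.  Returns (weights including intercept first, signed residual
    per triangle as true - predicted, mean absolute error).  A gene with no
    neighbors is fit on the intercept alone, so its residuals are its
    centered values.
    """
    G = _as_graph(network)
    if gene not in G:
        raise ValueError(f"gene {gene!r} is not in the network")
    if gene not in feature_data.columns:
        raise ValueError(f"gene {gene!r} is not in the feature table")
    neighbors = sorted(G.neighbors(gene))
    missing = [g for g in neighbors if g not in feature_data.columns]
    if missing:
        raise ValueError(f"feature table lacks neighbor columns: {missing}")
    values = feature_data.to_numpy(dtype=float)
    if rescale:
        peak = np.abs(values).max()
        if peak > 0:
            values = values / peak
        feature_data = pd.DataFrame(
            values, index=feature_data.index, columns=feature_data.columns
        )
    y = feature_data[gene].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones_like(y)]
        + [feature_data[g].to_numpy(dtype=float) for g in neighbors]
    )
    weights, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ weights
    return weights, residuals, float(np.abs(residuals).mean())


def render_residue_map(
    mean_residues: np.ndarray, mesh, display_scale: float = 10.0
) -> np.ndarray:
    """Paint per-triangle mean residues onto the mesh frame for display.

    Residues are multiplied by ``display_scale`` (contrast only) and mapped
    through a diverging colormap: positive residues (expression higher than
    predicted) toward red, negative toward blue.  Returns an (H, W, 3) uint8
    image; pixels outside the mesh are white.
    """
    import matplotlib.cm as cm

    if mesh.assignment is None:
        raise ValueError("mesh needs a pixel assignment to render")
    scaled = np.clip(np.asarray(mean_residues) * display_scale, -1.0, 1.0)
    rgba = cm.RdBu_r((scaled + 1.0) / 2.0)
    img = np.ones(mesh.assignment.shape + (3,), dtype=float)
    inside = mesh.assignment >= 0
    img[inside] = rgba[mesh.assignment[inside], :3]
    return (img * 255).astype(np.uint8)
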