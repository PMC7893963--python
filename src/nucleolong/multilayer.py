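"""Multilayer integration, clustering, annotation and differential tests.

The abundance, splicing and APA layers are each depth-normalized per
nucleus (to the layer's median depth), log1p-transformed and
feature-standardized, then horizontally concatenated over the nuclei shared
by all layers.  Clustering is PCA -> kNN graph -> Louvain community
detection with a fixed seed.  Cell types are assigned by marker scores
(mean marker expression minus a size- and expression-bin-matched control
set); a nucleus takes the argmax type when the best score is positive,
otherwise it is *unknown*, and each cluster is annotated with its modal
type.  Differential machinery: two-sided Fisher exact test on 2x2
spliced/unspliced tables, one-sided two-sample Kolmogorov-Smirnov test on
incompletely-spliced ratios, and Wilcoxon-ranked cluster-enriched genes
with out-group-fraction and fold-change filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .matrix import LayerMatrix

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass
class MultilayerMatrix:
    """Standardized, horizontally concatenated layer blocks over shared nuclei."""

    nuclei: list[str]
    features: list[str]
    layer_of_feature: list[str]
    X: np.ndarray = field(repr=False)  # dense, standardized
    norm_params: dict[str, float] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def _normalize_layer(matrix: LayerMatrix, weight: float = 1.0) -> np.ndarray:
    """Depth-normalize to the layer median depth, log1p, standardize features."""
    X = np.asarray(matrix.counts.todense(), dtype=np.float64)
    depth = X.sum(axis=1)
    depth[depth == 0] = 1.0
    target = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    X = X / depth[:, None] * target
    X = np.log1p(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd * weight


def normalize_and_merge(
    layers: Sequence[LayerMatrix], layer_weights: Mapping[str, float] | None = None
) -> MultilayerMatrix:
    """Normalize each layer independently and concatenate over shared nuclei.

    Nuclei absent from any layer are dropped (intersection).  Equal layer
    weight by default; ``layer_weights`` rescales a layer's standardized
    block.
    """
    if not layers:
        raise ValueError("at least one layer required")
    shared = set(layers[0].nuclei)
    for m in layers[1:]:
        shared &= set(m.nuclei)
    if not shared:
        raise ValueError("no nuclei shared by all layers")
    nuclei = [b for b in layers[0].nuclei if b in shared]

    blocks = []
    features: list[str] = []
    provenance: list[str] = []
    for m in layers:
        sub = m.subset_nuclei(nuclei)
        w = 1.0 if layer_weights is None else float(layer_weights.get(m.layer, 1.0))
        blocks.append(_normalize_layer(sub, w))
        features.extend(f"{m.layer}:{f}" for f in sub.features)
        provenance.extend([m.layer] * len(sub.features))
    X = np.hstack(blocks) if blocks else np.empty((len(nuclei), 0))
    return MultilayerMatrix(nuclei=nuclei, features=features, layer_of_feature=provenance, X=X)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_nuclei(
    matrix: MultilayerMatrix | np.ndarray,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """PCA -> kNN graph -> Louvain; deterministic under a fixed seed."""
    import networkx as nx
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    X = matrix.X if isinstance(matrix, MultilayerMatrix) else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nuclei to cluster")
    if n_pcs >= n:
        raise ValueError(
            f"n_pcs={n_pcs} must be below the nucleus count ({n}); lower n_pcs"
        )
    n_pcs = min(n_pcs, X.shape[1])
    if n_pcs >= 1 and X.shape[1] > n_pcs:
        X = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    k = min(n_neighbors, n - 1)
    graph = kneighbors_graph(X, n_neighbors=k, mode="distance", include_self=False)
    # symmetrize; weight = 1/(1+d) so closer neighbours weigh more
    graph = graph.maximum(graph.T).tocoo()
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i, j, d in zip(graph.row, graph.col, graph.data):
        if i < j:
            G.add_edge(int(i), int(j), weight=1.0 / (1.0 + d))
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(n, dtype=np.int64)
    for label, nodes in enumerate(sorted(communities, key=lambda c: (-len(c), min(c)))):
        for node in nodes:
            labels[node] = label
    return labels


# ---------------------------------------------------------------------------
# marker scoring
# ---------------------------------------------------------------------------


def score_cell_types(
    abundance: LayerMatrix,
    marker_sets: Mapping[str, Sequence[str]],
    n_bins: int = 25,
    ctrl_factor: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Marker score per (nucleus, cell type) and the per-nucleus assignment.

    The score of a type is the mean normalized expression of its marker set
    minus the mean of a control set sampled from the same expression bins
    (``n_bins`` bins, control size up to ``ctrl_factor`` x the marker set).
    A nucleus is assigned the argmax type when its best score exceeds zero,
    else ``unknown``.
    """
    import scanpy as sc

    adata = abundance.to_anndata()
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)

    scores = pd.DataFrame(index=pd.Index(abundance.nuclei, name="barcode"))
    present = set(abundance.features)
    for celltype, markers in marker_sets.items():
        if not markers:
            raise ValueError(f"marker set for {celltype!r} is empty")
        usable = [g for g in markers if g in present]
        missing = sorted(set(markers) - set(usable))
        if missing:
            logger.info("%s: %d marker genes not in matrix", celltype, len(missing))
        if not usable:
            logger.warning("marker set for %s has no resolvable genes; skipped", celltype)
            continue
        ctrl = min(ctrl_factor * len(usable), max(adata.n_vars - len(usable), 1))
        bins = min(n_bins, max(adata.n_vars // 2, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sc.tl.score_genes(
                    adata, usable, score_name="_score", ctrl_size=ctrl, n_bins=bins, random_state=seed
                )
            except RuntimeError:
                # tiny feature spaces can leave every expression bin without a
                # control gene; fall back to the whole non-marker pool
                X = np.asarray(adata.X.todense() if sp.issparse(adata.X) else adata.X)
                midx = [adata.var_names.get_loc(g) for g in usable]
                cidx = [i for i in range(adata.n_vars) if i not in set(midx)]
                ctrl_mean = X[:, cidx].mean(axis=1) if cidx else 0.0
                adata.obs["_score"] = X[:, midx].mean(axis=1) - ctrl_mean
        scores[celltype] = np.asarray(adata.obs["_score"])
    if scores.shape[1] == 0:
        raise ValueError("no marker set had resolvable genes")
    best = scores.idxmax(axis=1)
    assignment = best.where(scores.max(axis=1) > 0, UNKNOWN)
    assignment.name = "celltype"
    return scores, assignment


def annotate_clusters(labels: Sequence[int], assignment: pd.Series) -> pd.DataFrame:
    """Modal cell type per cluster plus composition tallies."""
    df = pd.DataFrame({"cluster": list(labels), "celltype": assignment.to_numpy()})
    rows = []
    for cluster, grp in df.groupby("cluster"):
        tally = grp["celltype"].value_counts()
        rows.append(
            {
                "cluster": cluster,
                "celltype": tally.idxmax(),
                "n_nuclei": len(grp),
                "composition": dict(tally),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------


def fisher_splicing_test(
    cluster_a_counts: tuple[int, int], cluster_b_counts: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p-value on a (spliced, unspliced) x (A, B) table.

    A table with a zero margin carries no association information and
    returns p = 1.0.
    """
    table = np.array([cluster_a_counts, cluster_b_counts], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table with a zero margin; p = 1.0")
        return 1.0
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def ks_ratio_test(
    cluster_ratios: Sequence[float], other_ratios: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample KS test: is the cluster stochastically greater?

    Returns (statistic, p).  The alternative is that the cluster's ratios
    are stochastically greater than the others' (its empirical CDF lies
    below), the direction of an elevated incompletely-spliced ratio.
    """
    a = np.asarray(cluster_ratios, dtype=float)
    b = np.asarray(other_ratios, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if min(a.size, b.size) < 3:
        logger.warning("KS test on a sample of size < 3 is unreliable")
    res = scipy.stats.ks_2samp(a, b, alternative="less", method="asymp")
    return float(res.statistic), float(res.pvalue)


def enriched_genes(
    abundance: LayerMatrix,
    labels: Sequence[int],
    max_out_group_fraction: float = 0.25,
    min_fold_change: float = 1.50,
) -> dict[int, pd.DataFrame]:
    """Cluster-enriched genes by Wilcoxon rank-sum with detection/fold filters.

    Per cluster, every gene is ranked against the rest by Wilcoxon score;
    genes detected in more than ``max_out_group_fraction`` of out-group
    nuclei, or with fold change below ``min_fold_change``, are filtered.
    Set the fraction to 1 and the fold change to 0 for the raw ranking.
    Clusters of a single nucleus are skipped.
    """
    import scanpy as sc

    labels = np.asarray(list(labels))
    adata = abundance.to_anndata()
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    adata.obs["cluster"] = pd.Categorical([str(l) for l in labels])

    sizes = pd.Series(labels).value_counts()
    usable = [str(c) for c in sizes.index if sizes[c] >= 2]
    skipped = [c for c in sizes.index if sizes[c] < 2]
    for c in skipped:
        logger.warning("cluster %s has a single nucleus; skipped", c)
    if len(usable) < 2:
        raise ValueError("need at least two clusters of size >= 2")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            adata, "cluster", groups=usable, method="wilcoxon", pts=True
        )
        sc.tl.filter_rank_genes_groups(
            adata,
            max_out_group_fraction=max_out_group_fraction,
            min_fold_change=min_fold_change,
            min_in_group_fraction=0.0,
        )
    out: dict[int, pd.DataFrame] = {}
    res = adata.uns["rank_genes_groups_filtered"]
    for grp in usable:
        names = np.asarray(res["names"][grp])
        scores = np.asarray(res["scores"][grp], dtype=float)
        lfc = np.asarray(res["logfoldchanges"][grp], dtype=float)
        pvals = np.asarray(res["pvals_adj"][grp], dtype=float)
        keep = pd.notna(names)
        out[int(grp)] = pd.DataFrame(
            {
                "gene": names[keep],
                "score": scores[keep],
                "log2_fold_change": lfc[keep],
                "p_adj": pvals[keep],
            }
        ).reset_index(drop=True)
    return out
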