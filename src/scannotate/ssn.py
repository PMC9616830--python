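"""Scale-free shared-nearest-neighbor (SSN) gene-program discovery.

Genes passing a minimal expression criterion are embedded by PCA of the
transposed (gene x cell) scaled expression matrix; a KNN graph in PC space
yields a Jaccard-weighted shared-nearest-neighbor graph ``G``.  Following the
WGCNA soft-thresholding idea, ``G`` is raised elementwise to the smallest
power whose connectivity distribution fits a power law (signed R^2 below a
threshold), giving the scale-free graph ``G'`` that accentuates network
modularity.  Programs are Louvain-family communities of ``G'`` at the
maximal resolution that keeps gene neighborhoods cluster-pure, pruned of
low-connectivity genes; programs are annotated by hypergeometric
over-representation and evaluated by a Jaccard-based recovery score against
known program collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA

from .cdi import _bh_fdr
from .io import Clustering, CountMatrix, GeneSet, GeneSetCatalog, knn_indices, snn_from_knn
from .mikoscore import CellModuleScore, standardized_module_score

DEFAULT_POWER_GRID = tuple(np.round(np.arange(0.5, 5.01, 0.5), 2))
PROGRAM_RESOLUTIONS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))


# ---------------------------------------------------------------------------
# feature selection and graph construction
# ---------------------------------------------------------------------------


def select_program_features(
    m: CountMatrix, c: Clustering, min_cluster_fraction: float = 0.5
) -> list[str]:
    """Genes whose expressing fraction exceeds the threshold in >= 1 cluster."""
    expr = m.expressed()
    keep = np.zeros(m.n_genes, dtype=bool)
    for k in c.cluster_ids():
        mask = c.members(k)
        n_expr = np.asarray(expr[:, mask].sum(axis=1)).ravel()  # exact integers
        keep |= n_expr / mask.sum() > min_cluster_fraction
    if not keep.any():
        raise ValueError(
            "no gene passes the expression criterion; lower min_cluster_fraction"
        )
    return [g for g, k in zip(m.genes, keep) if k]


@dataclass
class GeneGraph:
    """SNN gene graph with optional scale-free transform."""

    genes: list[str]
    G: sp.csr_matrix
    soft_power: float | None = None
    signed_r2_trace: pd.DataFrame | None = None

    @property
    def Gp(self) -> sp.csr_matrix:
        """Scale-free adjacency G' = G ** soft_power (elementwise)."""
        if self.soft_power is None:
            raise ValueError("fit_soft_power has not been run")
        return self.G.power(self.soft_power).tocsr()

    def connectivity(self, transformed: bool = True) -> np.ndarray:
        """Row sums (diagonal excluded) of G' (default) or G."""
        a = self.Gp if transformed else self.G
        return np.asarray(a.sum(axis=1)).ravel()


def gene_snn_graph(
    m: CountMatrix,
    features: list[str],
    k: int = 20,
    var_explained: float = 0.9,
    max_pcs: int = 50,
    seed: int = 0,
) -> GeneGraph:
    """Jaccard SNN graph over genes from KNN in gene-space PCA.

    PCA runs on the per-gene z-scored log layer with genes as observations;
    the smallest number of components whose cumulative explained variance
    exceeds ``var_explained`` (capped at ``max_pcs``) defines the space.
    """
    if m.lognorm is None:
        raise ValueError("log_normalize the matrix first")
    if len(features) < k + 1:
        raise ValueError("need more features than neighbors")
    idx = m.gene_index(features)
    X = np.asarray(m.lognorm[idx].todense(), dtype=np.float64)
    X -= X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X /= sd
    n_comp = min(max_pcs, X.shape[0] - 1, X.shape[1] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_explained) + 1) if cum[-1] > var_explained else n_comp
    g = snn_from_knn(knn_indices(emb[:, :n_keep], k))
    return GeneGraph(genes=list(features), G=g)


# ---------------------------------------------------------------------------
# scale-free soft thresholding
# ---------------------------------------------------------------------------


def scale_free_fit(w: np.ndarray, n_bins: int = 20) -> float:
    """Signed R^2 of log(p(W)) ~ log(W) for binned connectivity ``w``.

    Equal-width bins over the connectivity range; empty bins (and bins with
    non-positive centers) are dropped before regressing.  Returns
    ``sign(slope) * R^2``; strongly negative values indicate a power-law
    (scale-free) connectivity distribution.
    """
    w = np.asarray(w, dtype=np.float64)
    edges = np.linspace(w.min(), w.max(), n_bins + 1)
    which = np.clip(np.digitize(w, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable connectivity bins")
    p = counts[keep] / w.size
    res = stats.linregress(np.log(centers[keep]), np.log(p))
    return float(np.sign(res.slope) * res.rvalue**2)


def fit_soft_power(
    graph: GeneGraph,
    powers=DEFAULT_POWER_GRID,
    n_bins: int = 20,
    r2_threshold: float = -0.9,
) -> GeneGraph:
    """Choose the smallest power whose transformed connectivity is scale-free.

    If no candidate reaches the signed-R^2 threshold, the power with minimal
    signed R^2 is used with a warning.
    """
    if graph.G.nnz == 0:
        raise ValueError("empty gene graph")
    rows = []
    for power in powers:
        w = np.asarray(graph.G.power(power).sum(axis=1)).ravel()
        try:
            r2 = scale_free_fit(w, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append({"power": float(power), "signed_r2": r2})
    trace = pd.DataFrame(rows)
    ok = trace[trace["signed_r2"] < r2_threshold]
    if len(ok):
        chosen = float(ok["power"].iloc[0])
    else:
        chosen = float(trace.loc[trace["signed_r2"].idxmin(), "power"])
        warnings.warn(
            f"no power reaches signed R^2 < {r2_threshold}; "
            f"falling back to power {chosen} (min signed R^2)"
        )
    graph.soft_power = chosen
    graph.signed_r2_trace = trace
    return graph


# ---------------------------------------------------------------------------
# purity-optimized program detection
# ---------------------------------------------------------------------------


@dataclass
class ProgramPartition:
    """Gene -> program assignment at the purity-selected resolution."""

    resolution: float
    genes: list[str]
    labels: np.ndarray
    purity: np.ndarray  # per-gene neighborhood purity at the chosen resolution
    purity_trace: pd.DataFrame | None = None
    pruned: list[str] = field(default_factory=list)

    @property
    def global_purity(self) -> float:
        return float(self.purity.mean())

    def programs(self) -> GeneSetCatalog:
        catalog = GeneSetCatalog()
        for pid in sorted(set(self.labels.tolist())):
            members = [g for g, l in zip(self.genes, self.labels) if l == pid]
            if members:
                catalog.add(GeneSet(name=f"program_{pid}", genes=members, description="SSN program"))
        return catalog


def _top_weight_neighborhoods(a: sp.csr_matrix, k: int) -> list[np.ndarray]:
    """Per-gene top-k neighbors by edge weight (ties broken by index)."""
    hoods = []
    for i in range(a.shape[0]):
        row = a.getrow(i)
        cols, vals = row.indices, row.data
        if cols.size > k:
            order = np.lexsort((cols, -vals))[:k]
            cols = cols[order]
        hoods.append(np.sort(cols))
    return hoods


def _neighborhood_purity(labels: np.ndarray, hoods: list[np.ndarray]) -> np.ndarray:
    purity = np.ones(len(hoods))
    for g, hood in enumerate(hoods):
        if hood.size == 0:
            continue
        counts = np.bincount(labels[hood], minlength=labels.max() + 1)
        # the majority count is unchanged by how mode ties are resolved; when
        # tied, the gene's own cluster is taken as the mode
        purity[g] = counts.max() / hood.size
    return purity


def purity_optimized_clustering(
    graph: GeneGraph,
    resolutions=PROGRAM_RESOLUTIONS,
    p_target: float = 0.8,
    k_purity: int = 20,
    seed: int = 42,
) -> ProgramPartition:
    """Community detection on G' at the maximal resolution keeping global
    neighborhood purity above ``p_target``; falls back to the smallest
    candidate resolution with a warning when none qualifies."""
    from .resolution import cluster_graph

    gp = graph.Gp
    hoods = _top_weight_neighborhoods(gp, k_purity)
    trace_rows = []
    partitions = {}
    for rho in resolutions:
        clustering = cluster_graph(gp, rho, seed=seed)
        purity = _neighborhood_purity(clustering.labels, hoods)
        partitions[float(rho)] = (clustering, purity)
        trace_rows.append(
            {"resolution": float(rho), "global_purity": float(purity.mean()),
             "n_programs": clustering.k_clusters}
        )
    trace = pd.DataFrame(trace_rows)
    ok = trace[trace["global_purity"] >= p_target]
    if len(ok):
        chosen = float(ok["resolution"].max())
    else:
        chosen = float(min(partitions))
        warnings.warn(
            f"no resolution satisfies target purity {p_target}; using {chosen}"
        )
    clustering, purity = partitions[chosen]
    return ProgramPartition(
        resolution=chosen,
        genes=list(graph.genes),
        labels=clustering.labels,
        purity=purity,
        purity_trace=trace,
    )


def prune_low_connectivity(
    graph: GeneGraph, partition: ProgramPartition, threshold: float = 0.1
) -> ProgramPartition:
    """Drop genes whose L2-normalized G' connectivity falls below threshold."""
    w = graph.connectivity(transformed=True)
    norm = np.linalg.norm(w)
    w_norm = w / norm if norm > 0 else w
    keep = w_norm >= threshold
    if not keep.any():
        raise ValueError("connectivity pruning removed every gene")
    return ProgramPartition(
        resolution=partition.resolution,
        genes=[g for g, k in zip(partition.genes, keep) if k],
        labels=partition.labels[keep],
        purity=partition.purity[keep],
        purity_trace=partition.purity_trace,
        pruned=[g for g, k in zip(partition.genes, keep) if not k],
    )


# ---------------------------------------------------------------------------
# embedding, annotation and evaluation
# ---------------------------------------------------------------------------


def embed_network(
    graph: GeneGraph, seed: int = 0, edge_quantile: float = 0.9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D UMAP layout of G' plus the edge list above the weight quantile."""
    gp = graph.Gp
    n = gp.shape[0]
    if n < 3:
        raise ValueError("need at least 3 genes to embed")
    import umap

    dense = np.asarray(gp.todense())
    dist = 1.0 - dense
    np.fill_diagonal(dist, 0.0)
    reducer = umap.UMAP(
        metric="precomputed",
        random_state=seed,
        n_neighbors=min(15, n - 1),
        init="spectral",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(dist)
    layout = pd.DataFrame({"gene": graph.genes, "umap1": coords[:, 0], "umap2": coords[:, 1]})

    triu = sp.triu(gp, k=1).tocoo()
    if triu.nnz and edge_quantile < 1.0:
        cutoff = np.quantile(triu.data, edge_quantile)
        keep = triu.data >= cutoff
    else:
        keep = np.zeros(triu.nnz, dtype=bool)
    edges = pd.DataFrame(
        {
            "source": [graph.genes[i] for i in triu.row[keep]],
            "target": [graph.genes[j] for j in triu.col[keep]],
            "weight": triu.data[keep],
        }
    )
    return layout, edges


def hypergeometric_ora(
    program: GeneSet, annotations: GeneSetCatalog, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of a program in annotation sets.

    Upper-tail p on (universe, annotation-in-universe, program, overlap)
    with BH correction across annotation sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    prog = set(program.genes) & uni
    if set(program.genes) - uni:
        raise ValueError("program contains genes outside the universe")
    rows = []
    for s in annotations.values():
        ann = set(s.genes) & uni
        overlap = len(prog & ann)
        p = stats.hypergeom.sf(overlap - 1, len(uni), len(ann), len(prog))
        rows.append(
            {
                "annotation": s.name,
                "overlap": overlap,
                "annotation_size": len(ann),
                "program_size": len(prog),
                "universe_size": len(uni),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table.sort_values("p", ignore_index=True)


def program_activity(
    m: CountMatrix, partition: ProgramPartition, seed: int = 0
) -> dict[str, CellModuleScore]:
    """Per-cell standardized module score of each program (>= 2 genes)."""
    out: dict[str, CellModuleScore] = {}
    for name, s in partition.programs().items():
        if len(s) < 2:
            warnings.warn(f"{name} has fewer than 2 genes; skipped")
            continue
        out[name] = standardized_module_score(m, s, seed=seed)
    return out


def recovery_score(observed: GeneSetCatalog, known: GeneSetCatalog) -> float:
    """Mean over known programs of the best Jaccard similarity achieved by
    any observed program."""
    if not observed or not known:
        raise ValueError("both catalogs must be nonempty")
    best = []
    for ks in known.values():
        kg = set(ks.genes)
        best.append(
            max(
                len(kg & set(os.genes)) / len(kg | set(os.genes))
                for os in observed.values()
            )
        )
    return float(np.mean(best))


def signature_refinement(
    program: GeneSet,
    datasets: list[CountMatrix],
    seed: int = 0,
) -> GeneSet | None:
    """Intersection across datasets of member genes positively correlated
    with the program's activity score in each dataset."""
    if not datasets:
        raise ValueError("need at least one dataset")
    coherent: set[str] | None = None
    for m in datasets:
        scores = standardized_module_score(m, program, seed=seed)
        X = np.asarray(m.lognorm[m.gene_index(scores.members_used)].todense())
        zc = scores.z - scores.z.mean()
        keep_rows = X.std(axis=1) > 0
        corr = (X - X.mean(axis=1, keepdims=True)) @ zc
        genes_here = {
            g for g, ok, r in zip(scores.members_used, keep_rows, corr) if ok and r > 0
        }
        coherent = genes_here if coherent is None else (coherent & genes_here)
    if not coherent:
        warnings.warn("no gene coherent across all datasets; empty refinement")
        return None
    return GeneSet(
        name=f"{program.name}_refined",
        genes=[g for g in program.genes if g in coherent],
        description="coherent across datasets",
    )
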