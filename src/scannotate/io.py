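"""Count-matrix containers, readers/writers, normalization and cell-graph construction.

The central container is :class:`CountMatrix`, a sparse gene x cell matrix of
non-negative integer UMI counts with unique gene symbols and cell barcodes.
Normalization follows the standard CP10K log transform
(``ln(1 + 1e4 * count / cell_total)``), and the cell neighbor graph is a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights computed over
k-nearest-neighbor sets in PCA space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse gene x cell integer count matrix.

    Parameters
    ----------
    genes
        Unique gene symbols (rows).
    cells
        Unique cell barcodes (columns).
    counts
        Sparse non-negative integer matrix of shape ``(len(genes), len(cells))``.
    lognorm
        Optional CP10K log-normalized layer of the same shape,
        ``ln(1 + 1e4 * count / cell_total)``.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    lognorm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for label, ids in (("gene", self.genes), ("cell", self.cells)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise FormatError(f"duplicate {label} identifiers: {sorted(set(dup))[:5]}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, names) -> np.ndarray:
        """Row indices for ``names``; raises KeyError on missing genes."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def expressed(self) -> sp.csr_matrix:
        """Binary gene x cell indicator of raw count > 0."""
        out = self.counts.copy()
        out.data = (out.data > 0).astype(np.int8)
        out.eliminate_zeros()
        return out


@dataclass
class Clustering:
    """Assignment of each cell to one cluster at a stated resolution."""

    resolution: float
    labels: np.ndarray  # one label per cell, aligned with CountMatrix.cells
    cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.cells and len(self.cells) != len(self.labels):
            raise ValueError("labels and cells differ in length")

    @property
    def k_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_ids(self) -> list:
        return sorted(pd.unique(self.labels).tolist(), key=str)

    def members(self, cluster) -> np.ndarray:
        return np.asarray(self.labels == cluster)


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dups = False
        for g in self.genes:
            if g in seen:
                dups = True
            seen[g] = None
        if dups:
            warnings.warn(f"gene set {self.name!r}: duplicate members deduplicated")
        self.genes = list(seen)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCatalog(dict):
    """Ordered mapping of set name -> :class:`GeneSet`."""

    def add(self, s: GeneSet) -> None:
        self[s.name] = s

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.values():
            out.update(s.genes)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountMatrix:
    """Read counts from an MTX-triplet directory or a delimited text file.

    MTX dialect: MatrixMarket coordinate integer ``matrix.mtx`` (1-based
    indices) with ``genes.tsv`` and ``barcodes.tsv`` line files.  Delimited
    dialect: genes as rows, first column the gene symbol, header row of cell
    barcodes.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    return _read_delimited(path)


def _read_mtx_dir(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    for required in (mtx, path / "genes.tsv", path / "barcodes.tsv"):
        if not required.exists():
            raise FormatError(f"missing {required.name} in {path}")
    genes = (path / "genes.tsv").read_text().split()
    cells = (path / "barcodes.tsv").read_text().split()
    try:
        m = mmread(str(mtx))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    m = sp.csr_matrix(m)
    if np.any(m.data != np.round(m.data)):
        raise FormatError(f"{mtx}: non-integer entries in coordinate data")
    return CountMatrix(genes, cells, m.astype(np.int64))


def _read_delimited(path: Path) -> CountMatrix:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:
        raise FormatError(f"malformed delimited file {path}: {exc}") from exc
    values = df.to_numpy()
    if values.size == 0:
        raise FormatError(f"{path}: no data rows")
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.round(values)):
        bad = df.index[np.where(~np.isclose(values.astype(float), np.round(values.astype(float))))[0][:1]]
        raise FormatError(f"{path}: non-integer entries (first offending gene row: {list(bad)})")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated gene row {dup[0]!r}")
    return CountMatrix(list(df.index), list(df.columns), sp.csr_matrix(values.astype(np.int64)))


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write an MTX-triplet directory (inverse of :func:`read_counts`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), m.counts.tocoo(), field="integer")
    (path / "genes.tsv").write_text("\n".join(m.genes) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(m.cells) + "\n")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata TSV with at least a ``cell`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "cell" not in df.columns:
        raise FormatError(f"{path}: metadata requires a 'cell' column")
    if df["cell"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell barcodes in metadata")
    return df


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a tab-separated GMT file (name, description, members...)."""
    catalog = GeneSetCatalog()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        catalog.add(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description or "."] + list(s.genes)) for s in catalog.values()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# normalization and depth homogenization
# ---------------------------------------------------------------------------


def log_normalize(m: CountMatrix) -> CountMatrix:
    """Fill the CP10K log layer: ``ln(1 + 1e4 * count / cell_total)``."""
    totals = m.cell_totals()
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero cells: {[m.cells[i] for i in zero[:10]]}")
    scaled = (m.counts.astype(np.float64) @ sp.diags(1e4 / totals)).tocsr()
    scaled.data = np.log1p(scaled.data)
    return CountMatrix(m.genes, m.cells, m.counts, lognorm=scaled)


def downsample_depth(m: CountMatrix, target_depth: int, seed: int = 0) -> CountMatrix:
    """Binomially thin each cell so its expected total equals ``target_depth``.

    Cells whose total is already at or below the target are left unchanged
    (flagged via a warning), mirroring depth homogenization across merged
    datasets of heterogeneous sequencing depth.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    rng = np.random.default_rng(seed)
    totals = m.cell_totals()
    shallow = totals < target_depth
    if shallow.any():
        warnings.warn(
            f"{int(shallow.sum())} cells below target depth left unchanged"
        )
    out = m.counts.tocsc(copy=True)
    for j in range(m.n_cells):
        if totals[j] <= target_depth:
            continue
        p = target_depth / totals[j]
        sl = slice(out.indptr[j], out.indptr[j + 1])
        out.data[sl] = rng.binomial(out.data[sl].astype(np.int64), p)
    out.eliminate_zeros()
    return CountMatrix(m.genes, m.cells, out.tocsr())


# ---------------------------------------------------------------------------
# neighbor graphs
# ---------------------------------------------------------------------------


def _top_variable_genes(lognorm: sp.csr_matrix, n_top: int) -> np.ndarray:
    """Rank genes by dispersion (variance/mean of the log layer); ties by index."""
    dense = np.asarray(lognorm.todense())
    mean = dense.mean(axis=1)
    var = dense.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.lexsort((np.arange(len(disp)), -disp))
    return np.sort(order[:n_top])


def pca_embedding(
    m: CountMatrix, n_pcs: int = 30, n_top_genes: int = 2000, seed: int = 0
) -> np.ndarray:
    """Cells x PCs embedding of z-scored log-normalized expression.

    Restricted to the ``n_top_genes`` most dispersed genes; each gene is
    centered and unit-scaled before PCA.
    """
    if m.lognorm is None:
        raise ValueError("log_normalize the matrix before PCA")
    keep = _top_variable_genes(m.lognorm, min(n_top_genes, m.n_genes))
    X = np.asarray(m.lognorm[keep].todense(), dtype=np.float64)
    X -= X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X /= sd
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1] - 1)
    return PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X.T)


def knn_indices(embedding: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor index sets (self included) in Euclidean space."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    return nn.kneighbors(embedding, return_distance=False)


def snn_from_knn(indices: np.ndarray) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph from KNN index sets.

    ``weight(i, j) = |KNN(i) & KNN(j)| / |KNN(i) | KNN(j)|`` with self-loops
    removed; each KNN set includes the point itself.
    """
    n, k = indices.shape
    rows = np.repeat(np.arange(n), k)
    member = sp.csr_matrix(
        (np.ones(n * k), (rows, indices.ravel())), shape=(n, n)
    )
    inter = (member @ member.T).tocoo()
    jac = inter.data / (2 * k - inter.data)
    g = sp.csr_matrix((jac, (inter.row, inter.col)), shape=(n, n))
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def cell_neighbor_graph(
    m: CountMatrix, n_pcs: int = 30, k: int = 20, n_top_genes: int = 2000, seed: int = 0
) -> sp.csr_matrix:
    """Symmetric Jaccard-weighted SNN graph over cells (PCA -> KNN -> SNN)."""
    emb = pca_embedding(m, n_pcs=n_pcs, n_top_genes=n_top_genes, seed=seed)
    return snn_from_knn(knn_indices(emb, k))
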