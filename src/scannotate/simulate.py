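"""Gamma-Poisson scRNA-seq simulators with DEG ground truth.

Two-group design: gene means are gamma-distributed, library sizes log-normal,
and counts Poisson.  A fraction ``de_prob`` of genes receives a multiplicative
differential-expression factor in Group2 (log-normal magnitude; a coin flip
decides up- versus down-regulation, as in Splatter-style simulators).  Half of
the true DE genes are then converted to *binary* DEGs (bDEGs) by zeroing their
counts in Group1 cells; the remainder are *graded* DEGs (gDEGs), expressed in
both groups at different levels.

The multi-type hierarchy design adds cell types carrying exclusive marker
genes (expressed only within their type) and, optionally, nested subtypes that
differ from their siblings by graded factors only — a fixture for resolution
selection and marker-based scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSet

NON_DE = "nonDE"
BINARY_DE = "bDEG"
GRADED_DE = "gDEG"


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-group gamma-Poisson simulation.

    ``lib_location``/``lib_scale`` parameterize log-normal library sizes; the
    drawn sizes are rescaled so that the empirical mean cell total equals
    ``exp(lib_location + lib_scale**2 / 2)`` (the log-normal mean), so
    ``mean_depth`` is the target sequencing depth in counts per cell.
    """

    n_genes: int = 2000
    n_cells: int = 2000
    group_prob: tuple[float, float] = (0.5, 0.5)
    de_prob: float = 0.1
    de_factor_location: float = 0.7
    de_factor_scale: float = 0.4
    de_down_prob: float = 0.5
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_location: float = np.log(5000.0)
    lib_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if not np.isclose(sum(self.group_prob), 1.0):
            raise ValueError("group_prob must sum to 1")
        if not 0.0 <= self.de_prob < 1.0:
            raise ValueError("de_prob must be in [0, 1)")
        if self.de_prob > 0 and self.de_prob * self.n_genes < 2:
            raise ValueError("de_prob * n_genes must be >= 2 when de_prob > 0")
        for name in ("de_factor_location", "mean_shape", "mean_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def mean_depth(self) -> float:
        return float(np.exp(self.lib_location + self.lib_scale**2 / 2))

    def with_mean_depth(self, depth: float) -> "SimParams":
        return replace(self, lib_location=float(np.log(depth) - self.lib_scale**2 / 2))


@dataclass
class SimTruth:
    """Per-gene ground-truth labels and Group2 DE factors."""

    labels: pd.Series  # gene -> {nonDE, bDEG, gDEG}
    factors: pd.Series  # gene -> multiplicative Group2 factor (1 for nonDE)

    def genes_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


#: The benchmark grid: sequencing depth (counts/cell) x DE-factor location
#: (log-scale effect magnitude), at 2,000 genes x 2,000 cells, de_prob 0.1.
BENCHMARK_CONFIGS: dict[str, SimParams] = {
    f"depth-{dname}_lfc-{lname}": SimParams(
        de_factor_location=loc
    ).with_mean_depth(depth)
    for dname, depth in (("low", 1000.0), ("mid", 5000.0), ("high", 20000.0))
    for lname, loc in (("low", 0.3), ("mid", 0.7), ("high", 1.2))
}

#: Configs at mid/high effect size (used for graded-DEG recovery bounds).
MID_HIGH_EFFECT = tuple(
    name for name in BENCHMARK_CONFIGS if not name.endswith("lfc-low")
)


def simulate_two_group(
    p: SimParams, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Simulate a two-group count matrix with bDEG/gDEG ground truth.

    Returns the count matrix, a cell metadata frame with a ``group`` column
    (Group1/Group2), and the per-gene truth.
    """
    rng = np.random.default_rng(p.seed if seed is None else seed)
    genes = [f"Gene{i + 1}" for i in range(p.n_genes)]
    cells = [f"Cell{i + 1}" for i in range(p.n_cells)]

    mu = rng.gamma(shape=p.mean_shape, scale=1.0 / p.mean_rate, size=p.n_genes)
    mu = np.maximum(mu, 1e-12)
    lib = rng.lognormal(mean=p.lib_location, sigma=p.lib_scale, size=p.n_cells)
    lib *= p.mean_depth / lib.mean()

    group2 = rng.random(p.n_cells) < p.group_prob[1]

    factors = np.ones(p.n_genes)
    labels = np.full(p.n_genes, NON_DE, dtype=object)
    bdeg_idx = np.array([], dtype=int)
    if p.de_prob > 0:
        n_de = int(round(p.de_prob * p.n_genes))
        de_idx = rng.choice(p.n_genes, size=n_de, replace=False)
        magnitude = rng.lognormal(p.de_factor_location, p.de_factor_scale, size=n_de)
        magnitude = np.maximum(magnitude, np.exp(1e-3))  # factor != 1 by construction
        down = rng.random(n_de) < p.de_down_prob
        factors[de_idx] = np.where(down, 1.0 / magnitude, magnitude)
        shuffled = rng.permutation(de_idx)
        bdeg_idx = np.sort(shuffled[: n_de // 2])
        labels[bdeg_idx] = BINARY_DE
        labels[np.sort(shuffled[n_de // 2 :])] = GRADED_DE

    # per-group expression proportions; library sizes stay comparable between
    # groups so depth itself is not a confounder
    prop1 = mu / mu.sum()
    mu2 = mu * factors
    prop2 = mu2 / mu2.sum()
    lam = np.where(group2[None, :], prop2[:, None], prop1[:, None]) * lib[None, :]
    counts = rng.poisson(lam).astype(np.int64)
    if bdeg_idx.size:
        counts[np.ix_(bdeg_idx, ~group2)] = 0

    meta = pd.DataFrame(
        {"cell": cells, "group": np.where(group2, "Group2", "Group1")}
    )
    truth = SimTruth(
        labels=pd.Series(labels, index=genes, name="label"),
        factors=pd.Series(factors, index=genes, name="de_factor_group2"),
    )
    return CountMatrix(genes, cells, sp.csr_matrix(counts)), meta, truth


def simulate_hierarchy(
    n_types: int,
    nesting: int = 0,
    p: SimParams | None = None,
    n_markers: int = 25,
    marker_log_factor: float = 1.0,
    n_subtypes: int = 2,
    n_graded_per_subtype: int = 15,
    graded_log_factor: float = 0.8,
    seed: int | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a multi-type dataset with exclusive markers per cell type.

    Each type carries ``n_markers`` marker genes expressed (at a
    ``exp(marker_log_factor)``-fold elevated mean) exclusively within that
    type — counts outside the type are zeroed.  With ``nesting=1`` each type
    is split into ``n_subtypes`` subtypes that share all parental markers and
    differ only by graded factors on subtype-specific gene subsets.

    Returns the count matrix and metadata with ``curated_label`` (coarse type)
    and, when nested, ``subtype_label``.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if nesting < 0:
        raise ValueError("nesting must be >= 0")
    p = p or SimParams(n_genes=400, n_cells=600).with_mean_depth(2000.0)
    rng = np.random.default_rng(p.seed if seed is None else seed)
    genes = [f"Gene{i + 1}" for i in range(p.n_genes)]
    cells = [f"Cell{i + 1}" for i in range(p.n_cells)]

    if n_types * n_markers > p.n_genes:
        raise ValueError("not enough genes for the requested marker blocks")

    types = np.repeat(np.arange(n_types), int(np.ceil(p.n_cells / n_types)))[: p.n_cells]
    if nesting:
        subtypes = types * n_subtypes + np.arange(p.n_cells) % n_subtypes
    else:
        subtypes = types.copy()

    mu = rng.gamma(shape=p.mean_shape, scale=1.0 / p.mean_rate, size=p.n_genes)
    mu = np.maximum(mu, 1e-12)
    lib = rng.lognormal(mean=p.lib_location, sigma=p.lib_scale, size=p.n_cells)
    lib *= p.mean_depth / lib.mean()

    n_groups = n_types * n_subtypes if nesting else n_types
    fac = np.ones((p.n_genes, n_groups))
    marker_rows = {}
    for t in range(n_types):
        rows = np.arange(t * n_markers, (t + 1) * n_markers)
        marker_rows[t] = rows
        own = [g for g in range(n_groups) if (g // n_subtypes if nesting else g) == t]
        other = [g for g in range(n_groups) if g not in own]
        fac[np.ix_(rows, other)] = 0.0
        fac[np.ix_(rows, own)] = np.exp(marker_log_factor)
    if nesting:
        pool = np.arange(n_types * n_markers, p.n_genes)
        for g in range(n_groups):
            picked = rng.choice(pool, size=min(n_graded_per_subtype, pool.size), replace=False)
            fac[picked, g] *= np.exp(rng.normal(graded_log_factor, 0.2, size=picked.size) * rng.choice([-1, 1], size=picked.size))

    eff = mu[:, None] * fac
    props = eff / eff.sum(axis=0, keepdims=True)
    lam = props[:, subtypes] * lib[None, :]
    counts = rng.poisson(lam).astype(np.int64)
    # enforce exact marker exclusivity (Poisson already yields zero mean there,
    # this guards the invariant under any later parameter change)
    for t, rows in marker_rows.items():
        counts[np.ix_(rows, types != t)] = 0

    meta = pd.DataFrame({"cell": cells, "curated_label": [f"Type{t + 1}" for t in types]})
    if nesting:
        meta["subtype_label"] = [f"Type{t + 1}.{s % n_subtypes + 1}" for t, s in zip(types, subtypes)]
    return CountMatrix(genes, cells, sp.csr_matrix(counts)), meta


def marker_catalog(meta: pd.DataFrame, m: CountMatrix, n_markers: int = 25):
    """Catalog of each hierarchy type's exclusive marker set (by construction
    the first ``n_markers`` gene rows per type, in type order)."""
    from .io import GeneSetCatalog

    catalog = GeneSetCatalog()
    types = sorted(meta["curated_label"].unique())
    for t, name in enumerate(types):
        rows = range(t * n_markers, (t + 1) * n_markers)
        catalog.add(GeneSet(name=name, genes=[m.genes[i] for i in rows], description="simulated markers"))
    return catalog


def simulate_coexpression(
    n_modules: int = 3,
    genes_per_module: int = 60,
    n_background: int = 120,
    n_cells: int = 450,
    activity_sd: float = 0.8,
    shared_sd: float = 0.6,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series, np.ndarray]:
    """Planted-module coexpression fixture for gene-program discovery.

    Each module carries a graded per-cell activity (log-normal, sd
    ``activity_sd``) multiplying its member genes, so members co-vary across
    cells; a shared per-cell factor (sd ``shared_sd``) covaries *all* genes,
    planting the weak spurious between-module association structure that the
    scale-free transform is designed to suppress.  Background genes carry
    only the shared factor.

    Returns the counts, a gene -> module label Series ('module0', ..., or
    'background'), and a per-cell state (index of the most active module).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_modules * genes_per_module + n_background
    base = rng.gamma(2.0, 1.0, n_genes)
    activity = rng.lognormal(0.0, activity_sd, (n_modules, n_cells))
    shared = rng.lognormal(0.0, shared_sd, n_cells)
    lam = np.tile(base[:, None], (1, n_cells))
    for g in range(n_modules):
        rows = slice(g * genes_per_module, (g + 1) * genes_per_module)
        lam[rows] *= activity[g][None, :]
    lam *= shared[None, :]
    counts = rng.poisson(lam)
    genes = [f"G{i}" for i in range(n_genes)]
    labels = pd.Series(
        [f"module{i // genes_per_module}" if i < n_modules * genes_per_module else "background"
         for i in range(n_genes)],
        index=genes,
        name="module",
    )
    m = CountMatrix(genes, [f"C{i}" for i in range(n_cells)], sp.csr_matrix(counts))
    states = np.argmax(activity, axis=0)
    return m, labels, states


def permute_gene_set(
    s: GeneSet, rate: float, universe: list[str], seed: int = 0
) -> GeneSet:
    """Replace ``ceil(rate * |s|)`` members with random genes from outside ``s``.

    Emulates corrupting curated marker sets at a controlled substitution rate;
    the set size is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if len(s) > len(universe):
        raise ValueError("gene set larger than universe")
    rng = np.random.default_rng(seed)
    n_swap = int(np.ceil(rate * len(s)))
    if n_swap == 0:
        return GeneSet(s.name, list(s.genes), s.description)
    candidates = sorted(set(universe) - set(s.genes))
    if n_swap > len(candidates):
        raise ValueError("universe too small to draw replacements")
    drop = rng.choice(len(s), size=n_swap, replace=False)
    new = list(rng.choice(candidates, size=n_swap, replace=False))
    genes = [g for i, g in enumerate(s.genes) if i not in set(drop.tolist())] + new
    return GeneSet(s.name, genes, s.description)
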