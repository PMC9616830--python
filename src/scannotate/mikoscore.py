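"""Gene-set-size-corrected cluster scoring (Miko score).

A gene set is first scored per cell with a *standardized module score*: the
mean expression of set members minus the mean of expression-bin-matched
control genes, divided by the pooled within-cell standard deviation of member
and control values (Tirosh-style control binning).  Cluster-level means of
these scores are then centered by a fitted size-dependent null mean and
scaled by a size-dependent null standard deviation
estimated from randomly sampled gene sets, yielding the Miko score ``M_k`` —
a Z statistic comparable across gene sets of different sizes, from which
two-sided normal p-values and BH FDR are derived.

Two post-scoring filters refine catalog annotation: the *coherent fraction*
(fraction of member genes positively correlated with the per-cell score) and
the *frequent flier* flag (sets significant across most clusters, hence
non-discriminative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cdi import _bh_fdr
from .io import Clustering, CountMatrix, GeneSet, GeneSetCatalog

DEFAULT_NULL_SIZES = (2, 3, 4, 5, 7, 10, 14, 20, 28, 40, 56, 80, 100)


@dataclass
class CellModuleScore:
    """Per-cell standardized module score of one gene set."""

    set_name: str
    z: np.ndarray  # Z_j per cell
    x: np.ndarray  # mean member expression per cell
    y: np.ndarray  # mean control expression per cell
    members_used: list[str]
    degenerate: np.ndarray  # cells where both variances were zero (Z forced to 0)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bins of genes by dataset-average expression (rank-based)."""
    order = np.argsort(mean_expr, kind="mergesort")
    bins = np.empty(mean_expr.size, dtype=int)
    bins[order] = (np.arange(mean_expr.size) * n_bins) // mean_expr.size
    return bins


def standardized_module_score(
    m: CountMatrix,
    s: GeneSet,
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
) -> CellModuleScore:
    """Score a gene set per cell against expression-matched controls.

    Members absent from the matrix are dropped with a warning; fewer than two
    matched members is an error.  Control genes are drawn per member from the
    member's expression bin (without replacement within a bin when the bin is
    large enough).
    """
    if m.lognorm is None:
        raise ValueError("log_normalize the matrix first")
    present = [g for g in s.genes if g in set(m.genes)]
    if len(present) < len(s.genes):
        warnings.warn(
            f"gene set {s.name!r}: {len(s.genes) - len(present)} members absent, dropped"
        )
    if len(present) < 2:
        raise ValueError(f"gene set {s.name!r} has fewer than 2 matched members")
    X = np.asarray(m.lognorm.todense(), dtype=np.float64)
    rng = np.random.default_rng(seed)
    mean_expr = X.mean(axis=1)
    bins = _expression_bins(mean_expr, n_bins)
    member_idx = m.gene_index(present)

    ctrl_lists = []
    for gi in member_idx:
        pool = np.where(bins == bins[gi])[0]
        pool = pool[pool != gi]
        if pool.size == 0:
            pool = np.array([gi])
        take = min(n_ctrl_per_gene, pool.size)
        ctrl_lists.append(rng.choice(pool, size=take, replace=False))

    member_vals = X[member_idx]  # members x cells
    ctrl_vals = X[np.concatenate(ctrl_lists)]
    x = member_vals.mean(axis=0)
    # each member's control pool enters with equal weight, mirroring the equal
    # weight of members in x; pooling the raw control multiset instead biases
    # the score when control-list lengths vary across bins
    y = np.mean([X[lst].mean(axis=0) for lst in ctrl_lists], axis=0)
    var_sum = member_vals.var(axis=0) + ctrl_vals.var(axis=0)
    degenerate = var_sum == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - y) / np.sqrt(var_sum)
    z[degenerate] = 0.0
    return CellModuleScore(
        set_name=s.name, z=z, x=x, y=y, members_used=present, degenerate=degenerate
    )


@dataclass
class NullModel:
    """Size-dependent null for cluster-level standardized module scores.

    The null mean is a cubic polynomial fit (in log size) of the observed
    mean of random-set cluster scores; the variance of cluster-level null
    scores is modeled as a gamma-family GLM (log link) with a cubic basis in
    log gene-set size — a curved power-law decay matching the empirical
    scaling of the variance of a mean of randomly sampled genes.
    """

    sizes: np.ndarray
    var_observed: np.ndarray  # observed Var(Z_null,k) per size
    mean_observed: np.ndarray  # observed mean(Z_null,k) per size
    var_coef: np.ndarray  # gamma GLM coefficients in powers of log size
    mean_coef: np.ndarray  # cubic polynomial (in log size) of the null mean
    n_random: int
    seed: int
    universe: list[str] = field(default_factory=list)
    center: str = "fitted"  # "fitted" subtracts the mean model, "zero" the 0-approximation

    def predict_var(self, size: int) -> float:
        size = int(np.clip(size, self.sizes.min(), self.sizes.max()))
        ls = np.log(size)
        return float(np.exp(np.dot(self.var_coef, [ls**d for d in range(len(self.var_coef))])))

    def predict_mean(self, size: int) -> float:
        """Size-matched null mean Z_null^pred.

        The null mean of the within-cell-standardized score is slightly
        positive for small sets (the score is a ratio with a correlated
        denominator), so the fitted mean model is subtracted by default; the
        theoretical zero approximation is available via ``center='zero'``.
        """
        if self.center == "zero":
            return 0.0
        size = int(np.clip(size, self.sizes.min(), self.sizes.max()))
        return float(np.polyval(self.mean_coef, np.log(size)))


def _expressed_universe(m: CountMatrix, min_frac: float = 0.01) -> list[str]:
    frac = np.asarray(m.expressed().mean(axis=1)).ravel()
    return [g for g, f in zip(m.genes, frac) if f > min_frac]


def fit_null_model(
    m: CountMatrix,
    c: Clustering,
    sizes=DEFAULT_NULL_SIZES,
    n_random: int = 30,
    seed: int = 0,
) -> NullModel:
    """Estimate the null score variance as a function of gene-set size.

    For each size, ``n_random`` uniformly sampled gene sets (from genes with
    expressing fraction > 1%) are scored; cluster-level means are pooled over
    sets and clusters, and their per-size variance is fitted by the gamma GLM.
    """
    sizes = np.asarray(sorted(sizes), dtype=int)
    universe = _expressed_universe(m)
    if sizes.max() > len(universe):
        raise ValueError("size grid exceeds the expressed gene universe")
    rng = np.random.default_rng(seed)
    cluster_masks = [c.members(k) for k in c.cluster_ids()]

    var_obs, mean_obs = [], []
    for size in sizes:
        vals = []
        for r in range(n_random):
            genes = list(rng.choice(universe, size=size, replace=False))
            score = standardized_module_score(
                m, GeneSet(name=f"null_{size}_{r}", genes=genes),
                seed=int(rng.integers(2**31 - 1)),
            )
            vals.extend(score.z[mask].mean() for mask in cluster_masks)
        vals = np.asarray(vals)
        var_obs.append(vals.var(ddof=1))
        mean_obs.append(vals.mean())
    var_obs = np.asarray(var_obs)
    mean_obs = np.asarray(mean_obs)

    log_sizes = np.log(sizes.astype(float))
    deg = min(3, len(sizes) - 1)
    if len(sizes) >= 3:
        exog = np.column_stack([log_sizes**d for d in range(deg + 1)])
        try:
            fit = sm.GLM(var_obs, exog, family=sm.families.Gamma(sm.families.links.Log())).fit()
            coef = np.asarray(fit.params)
        except Exception:  # fall back to least squares on the log scale
            coef = np.polyfit(log_sizes, np.log(var_obs), deg)[::-1]
    else:  # degenerate grid: interpolate the observed variances directly
        coef = np.polyfit(log_sizes, np.log(var_obs), deg)[::-1]
    mean_coef = np.polyfit(log_sizes, mean_obs, deg=min(3, len(sizes) - 1))
    return NullModel(
        sizes=sizes,
        var_observed=var_obs,
        mean_observed=mean_obs,
        var_coef=coef,
        mean_coef=mean_coef,
        n_random=n_random,
        seed=seed,
        universe=universe,
    )


def miko_score(
    m: CountMatrix,
    c: Clustering,
    s: GeneSet,
    null: NullModel,
    seed: int = 0,
    scores: CellModuleScore | None = None,
) -> pd.DataFrame:
    """Miko score per cluster for one gene set (no FDR; see catalog runners)."""
    scores = scores or standardized_module_score(m, s, seed=seed)
    size = len(scores.members_used)
    if size < null.sizes.min() or size > null.sizes.max():
        warnings.warn(
            f"set size {size} outside fitted grid "
            f"[{null.sizes.min()}, {null.sizes.max()}]; nearest-size extrapolation"
        )
    sd = np.sqrt(null.predict_var(size))
    rows = []
    for k in c.cluster_ids():
        z_obs = float(scores.z[c.members(k)].mean())
        m_k = (z_obs - null.predict_mean(size)) / sd
        p = float(2.0 * stats.norm.sf(abs(m_k)))
        rows.append(
            {
                "cluster": str(k),
                "set_name": s.name,
                "set_size": size,
                "z_obs": z_obs,
                "miko": m_k,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def score_catalog(
    m: CountMatrix,
    c: Clustering,
    catalog: GeneSetCatalog,
    null: NullModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Miko scores of every catalog set in every cluster, with CF and BH FDR."""
    frames = []
    for i, s in enumerate(catalog.values()):
        cell_scores = standardized_module_score(m, s, seed=seed + i)
        block = miko_score(m, c, s, null, scores=cell_scores)
        block["coherent_fraction"] = coherent_fraction_cells(m, s, cell_scores)
        frames.append(block)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "set_name", "set_size", "z_obs", "miko", "p", "coherent_fraction", "fdr"]
        )
    table = pd.concat(frames, ignore_index=True)
    table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table


def coherent_fraction_cells(
    m: CountMatrix, s: GeneSet, scores: CellModuleScore
) -> float:
    """Fraction of member genes positively correlated (Pearson, log layer)
    with the per-cell module score; zero-variance genes are excluded."""
    X = np.asarray(m.lognorm[m.gene_index(scores.members_used)].todense())
    z = scores.z
    if np.std(z) == 0:
        return 0.0
    keep = X.std(axis=1) > 0
    if not keep.any():
        return 0.0
    zc = z - z.mean()
    corr = (X[keep] - X[keep].mean(axis=1, keepdims=True)) @ zc
    return float((corr > 0).mean())


def frequent_flier_flag(results: pd.DataFrame, threshold: float = 0.75, fdr: float = 0.05) -> pd.Series:
    """Flag sets enriched (FDR < ``fdr``, positive score when available) in
    more than ``threshold`` of clusters; significant depletion does not count
    toward the rate."""
    sig = results["fdr"] < fdr
    if "miko" in results.columns:
        sig &= results["miko"] > 0
    sig_rate = results.assign(sig=sig).groupby("set_name")["sig"].mean()
    flags = sig_rate > threshold
    flags.name = "frequent_flier"
    return flags


def annotate_clusters(
    m: CountMatrix,
    c: Clustering,
    catalog: GeneSetCatalog,
    null: NullModel,
    cf_threshold: float = 0.5,
    ff_threshold: float = 0.75,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked per-cluster annotations with word weights.

    Sets must be positively enriched (``miko > 0``), significant at the FDR,
    pass the coherence filter, and not be frequent fliers; clusters with no
    surviving set are labeled ``unassigned``.  Word weights are proportional
    to the Miko score among a cluster's significant sets.
    """
    results = score_catalog(m, c, catalog, null, seed=seed)
    if results.empty:
        return pd.DataFrame(
            columns=["cluster", "set_name", "miko", "fdr", "coherent_fraction", "word_weight", "rank"]
        )
    flags = frequent_flier_flag(results, threshold=ff_threshold, fdr=fdr)
    results = results.merge(flags, on="set_name")
    keep = (
        (results["miko"] > 0)
        & (results["fdr"] < fdr)
        & (results["coherent_fraction"] >= cf_threshold)
        & (~results["frequent_flier"])
    )
    rows = []
    for k in map(str, c.cluster_ids()):
        block = results[(results["cluster"] == k) & keep].sort_values(
            "miko", ascending=False
        )
        if block.empty:
            rows.append(
                {"cluster": k, "set_name": "unassigned", "miko": np.nan,
                 "fdr": np.nan, "coherent_fraction": np.nan, "word_weight": np.nan, "rank": 1}
            )
            continue
        total = block["miko"].sum()
        for rank, rec in enumerate(block.itertuples(index=False), start=1):
            rows.append(
                {
                    "cluster": k,
                    "set_name": rec.set_name,
                    "miko": rec.miko,
                    "fdr": rec.fdr,
                    "coherent_fraction": rec.coherent_fraction,
                    "word_weight": rec.miko / total,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)
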