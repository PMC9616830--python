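"""Co-dependency index (CDI) differential expression and baselines.

The CDI tests whether a gene's expression (raw count > 0) co-occurs with a
reference feature (cluster membership, a grouping variable, or a second
gene's binarized expression) more often than expected under independence.
With ``N`` cells, ``pi_gk = P(g expressed) * P(k member)`` and ``I`` observed
coincident cells, the p-value is the inclusive upper binomial tail
``P(X >= I), X ~ Binomial(N, pi_gk)``, carried in log space;
``CDI = -log10 p`` and ``nCDI`` divides by the CDI of a perfectly
co-dependent gene for that reference (expression coinciding exactly with
membership), clamping to [0, 1].

The one-vs-rest Wilcoxon rank-sum/AUROC marker test (presto-style) and the
descriptive cluster-discrimination metrics are provided as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.special import logsumexp

from .io import CountMatrix, Clustering

#: cap on CDI when the tail probability underflows double precision
CDI_CAP = 1e4
_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# binomial tail in log space
# ---------------------------------------------------------------------------


def _log_binom_tail(I: np.ndarray, N: int, pi: np.ndarray) -> np.ndarray:
    """Natural log of the inclusive upper tail P(X >= I), X ~ Binomial(N, pi).

    Uses the survival function where it does not underflow and falls back to
    a log-sum-exp over log pmf terms otherwise, so extreme co-occurrence
    still yields a finite log-probability.
    """
    I = np.atleast_1d(np.asarray(I, dtype=np.int64)).ravel()
    pi = np.clip(np.atleast_1d(np.asarray(pi, dtype=np.float64)).ravel(), 0.0, 1.0)
    if I.size != pi.size:
        raise ValueError("I and pi must have the same length")
    out = np.zeros(I.size, dtype=np.float64)
    rest = I > 0
    if rest.any():
        with np.errstate(divide="ignore"):
            logp = stats.binom.logsf(I[rest] - 1, N, pi[rest])
        under = ~np.isfinite(logp)
        if under.any():
            rest_idx = np.where(rest)[0]
            for j in np.where(under)[0]:
                pos = rest_idx[j]
                x = np.arange(I[pos], N + 1)
                logp[j] = logsumexp(stats.binom.logpmf(x, N, pi[pos]))
        out[rest] = logp
    return out


@dataclass
class CDIResult:
    """Result of a single gene-vs-reference co-dependency test."""

    gene: str
    reference: str
    n_cells: int
    coincidence: int
    pi_gk: float
    log10_p: float  # log10 of the tail probability (<= 0)
    cdi: float
    ncdi: float

    @property
    def p(self) -> float:
        return float(10.0**self.log10_p)


def _perfect_cdi(member: np.ndarray, N: int) -> float:
    """CDI of a perfectly co-dependent gene for this reference (Eq. denominator)."""
    n_k = int(member.sum())
    pi_kk = (n_k / N) ** 2
    log_tail = _log_binom_tail(np.array([n_k]), N, np.array([pi_kk]))[0]
    return min(-log_tail / _LN10, CDI_CAP)


def cdi_test(expr_g: np.ndarray, member_k: np.ndarray, gene: str = "g", reference: str = "k") -> CDIResult:
    """Binomial co-occurrence test of one gene against one reference feature."""
    expr_g = np.asarray(expr_g).astype(bool)
    member_k = np.asarray(member_k).astype(bool)
    if expr_g.shape != member_k.shape or expr_g.ndim != 1:
        raise ValueError("expr_g and member_k must be equal-length 1-D vectors")
    N = expr_g.size
    if N == 0:
        raise ValueError("empty cell universe")
    if not member_k.any():
        raise ValueError("all-zero reference feature")
    I = int(np.sum(expr_g & member_k))
    pi = (expr_g.sum() / N) * (member_k.sum() / N)
    log_tail = _log_binom_tail(np.array([I]), N, np.array([pi]))[0]
    cdi = min(-log_tail / _LN10, CDI_CAP)
    denom = _perfect_cdi(member_k, N)
    ncdi = float(np.clip(cdi / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return CDIResult(
        gene=gene,
        reference=reference,
        n_cells=N,
        coincidence=I,
        pi_gk=float(pi),
        log10_p=float(log_tail / _LN10),
        cdi=float(cdi),
        ncdi=ncdi,
    )


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=np.float64)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _cdi_block(
    expr: sp.csr_matrix, member: np.ndarray, genes: list[str], reference: str
) -> pd.DataFrame:
    """Vectorized CDI of every gene against one membership indicator."""
    N = member.size
    n_k = int(member.sum())
    n_g = np.asarray(expr.sum(axis=1)).ravel()
    I = np.asarray(expr[:, np.where(member)[0]].sum(axis=1)).ravel().astype(np.int64)
    pi = (n_g / N) * (n_k / N)
    log_tail = _log_binom_tail(I, N, pi)
    cdi = np.minimum(-log_tail / _LN10, CDI_CAP)
    denom = _perfect_cdi(member, N)
    ncdi = np.clip(cdi / denom, 0.0, 1.0) if denom > 0 else np.zeros_like(cdi)
    pct_in = 100.0 * I / n_k
    pct_out = 100.0 * (n_g - I) / (N - n_k) if N > n_k else np.zeros_like(pi)
    return pd.DataFrame(
        {
            "gene": genes,
            "cluster": reference,
            "method": "cdi",
            "n_cells": N,
            "coincidence": I,
            "pi_gk": pi,
            "statistic": cdi,
            "cdi": cdi,
            "ncdi": ncdi,
            "log10_p": log_tail / _LN10,
            "p": np.exp(log_tail),
            "pct_in": pct_in,
            "pct_out": pct_out,
        }
    )


def find_cdi_markers(m: CountMatrix, c: Clustering) -> pd.DataFrame:
    """One CDI test per (gene, cluster) with joint BH correction.

    The reference feature for each cluster is its membership indicator; the
    test is one-sided toward over-representation, so only up-regulated
    markers attain small p-values.
    """
    ids = c.cluster_ids()
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    expr = m.expressed()
    blocks = []
    for k in ids:
        member = c.members(k)
        if member.sum() == 0:
            raise ValueError(f"cluster {k} has no cells")
        blocks.append(_cdi_block(expr, member, m.genes, str(k)))
    table = pd.concat(blocks, ignore_index=True)
    table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table


def find_cdi_gene_gene(
    m: CountMatrix, features_x: list[str], features_y: list[str]
) -> pd.DataFrame:
    """CDI of each x-gene against each y-gene's binarized expression."""
    xi = m.gene_index(features_x)
    yi = m.gene_index(features_y)
    expr = m.expressed()
    x_block = expr[xi]
    rows = []
    for j, y in zip(yi, features_y):
        member = np.asarray(expr[j].todense()).ravel().astype(bool)
        if not member.any():
            raise ValueError(f"reference gene {y} is expressed in no cell")
        block = _cdi_block(x_block, member, list(features_x), y)
        block = block.rename(columns={"cluster": "reference"})
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)
    table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table


def find_conserved_cdi_markers(
    m: CountMatrix, c: Clustering, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Group-wise CDI tests pooled with Fisher's method.

    Each replicate/batch group contributes an independent CDI p-value per
    (gene, cluster); the combined statistic is ``chi2 = -2 * sum(ln p)`` on
    ``2 * n_groups`` degrees of freedom.  Groups missing a cluster are
    skipped for that cluster with an adjusted df.
    """
    groups = np.asarray(groups)
    if groups.size != m.n_cells:
        raise ValueError("groups must align with cells")
    unique_groups = sorted(pd.unique(groups).tolist(), key=str)
    per_group: dict[str, pd.DataFrame] = {}
    import warnings as _warnings

    for g in unique_groups:
        mask = groups == g
        sub = CountMatrix(
            m.genes, [c_ for c_, keep in zip(m.cells, mask) if keep], m.counts[:, mask]
        )
        sub_c = Clustering(resolution=c.resolution, labels=c.labels[mask])
        present = set(sub_c.cluster_ids())
        absent = set(c.cluster_ids()) - present
        if absent:
            _warnings.warn(f"group {g}: clusters {sorted(map(str, absent))} absent, skipped")
        if len(present) >= 2:
            per_group[g] = find_cdi_markers(sub, sub_c)
        else:
            blocks = [
                _cdi_block(sub.expressed(), sub_c.members(k), sub.genes, str(k))
                for k in sub_c.cluster_ids()
            ]
            per_group[g] = pd.concat(blocks, ignore_index=True)

    combined = []
    for k in map(str, c.cluster_ids()):
        frames = [
            df[df["cluster"] == k][["gene", "log10_p"]].set_index("gene")
            for df in per_group.values()
            if (df["cluster"] == k).any()
        ]
        n_groups = len(frames)
        if n_groups == 0:
            continue
        ln_p = sum(f["log10_p"] for f in frames) * _LN10
        chi2 = -2.0 * ln_p
        p_comb = stats.chi2.sf(chi2, df=2 * n_groups)
        combined.append(
            pd.DataFrame(
                {
                    "gene": ln_p.index,
                    "cluster": k,
                    "method": "cdi_conserved",
                    "statistic": chi2.to_numpy(),
                    "df": 2 * n_groups,
                    "n_groups": n_groups,
                    "p": p_comb,
                }
            )
        )
    table = pd.concat(combined, ignore_index=True)
    table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Wilcoxon / AUROC baseline
# ---------------------------------------------------------------------------


def wilcoxon_auc_markers(m: CountMatrix, c: Clustering) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum with AUROC, tie-corrected normal p.

    Operates on the log-normalized layer.  ``log_fold_change`` is the
    difference of within- minus outside-cluster mean log expression; rows
    with non-positive logFC are flagged ``excluded`` (the co-dependency test
    only scores up-regulation, so cross-method comparisons drop them).
    """
    if m.lognorm is None:
        raise ValueError("log_normalize the matrix first")
    X = np.asarray(m.lognorm.todense(), dtype=np.float64)
    n_genes, N = X.shape
    ranks = stats.rankdata(X, axis=1)
    # tie correction term per gene: sum(t^3 - t) over tied groups
    tie_term = np.empty(n_genes)
    for i in range(n_genes):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(np.float64) ** 3 - counts)

    out = []
    for k in c.cluster_ids():
        mask = c.members(k)
        n1 = int(mask.sum())
        n2 = N - n1
        if n1 < 2 or n2 < 2:
            raise ValueError(f"cluster {k} too small for rank-sum test")
        r1 = ranks[:, mask].sum(axis=1)
        u1 = r1 - n1 * (n1 + 1) / 2.0
        auroc = u1 / (n1 * n2)
        mu = n1 * n2 / 2.0
        sigma2 = (n1 * n2 / 12.0) * ((N + 1) - tie_term / (N * (N - 1.0)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (u1 - mu - np.sign(u1 - mu) * 0.5) / sigma
        z[sigma == 0] = 0.0
        p = 2.0 * stats.norm.sf(np.abs(z))
        lfc = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
        expr = X > 0
        pct_in = 100.0 * expr[:, mask].mean(axis=1)
        pct_out = 100.0 * expr[:, ~mask].mean(axis=1)
        out.append(
            pd.DataFrame(
                {
                    "gene": m.genes,
                    "cluster": str(k),
                    "method": "wilcoxon",
                    "statistic": u1,
                    "auroc": auroc,
                    "log_fold_change": lfc,
                    "p": np.minimum(p, 1.0),
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "excluded": lfc <= 0,
                }
            )
        )
    table = pd.concat(out, ignore_index=True)
    table["fdr"] = _bh_fdr(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# descriptive cluster-discrimination metrics
# ---------------------------------------------------------------------------


def gini_index(cluster_means: np.ndarray, printed: bool = False) -> float:
    """Cluster-exclusivity index of a gene from its per-cluster mean expression.

    Default (normalized) form: ``sum_k(1 - x_k / max(x)) / (n_clusters - 1)``,
    equal to 1 for a gene expressed in exactly one cluster and 0 for a
    uniformly expressed gene.  ``printed=True`` evaluates the alternative
    unnormalized form ``sum_k(1 - (x_k - max(x))) / (n_clusters - 1)`` kept
    for auditability; note it is not bounded in [0, 1].
    """
    x = np.asarray(cluster_means, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 clusters")
    mx = x.max()
    if printed:
        return float(np.sum(1.0 - (x - mx)) / (n - 1))
    if mx == 0:
        return 0.0
    return float(np.sum(1.0 - x / mx) / (n - 1))


def de_descriptive_metrics(
    top_genes: pd.DataFrame, m: CountMatrix, c: Clustering, printed_gini: bool = False
) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV from expressing percentages, plus Gini.

    ``top_genes`` must carry ``gene``, ``cluster``, ``pct_in``, ``pct_out``
    columns (percent scale).  The four metrics reduce algebraically to
    functions of the within-/outside-cluster expressing percentages and
    describe how discriminative each marker is, not test accuracy.
    """
    if m.lognorm is None:
        raise ValueError("log_normalize the matrix first")
    X = np.asarray(m.lognorm.todense())
    ids = c.cluster_ids()
    cl_means = np.column_stack([X[:, c.members(k)].mean(axis=1) for k in ids])
    gene_row = {g: i for i, g in enumerate(m.genes)}

    rows = []
    for rec in top_genes.itertuples(index=False):
        p_in, p_out = float(rec.pct_in), float(rec.pct_out)
        sens = p_in / 100.0
        spec = (100.0 - p_out) / 100.0
        ppv = p_in / (p_in + p_out) if (p_in + p_out) > 0 else np.nan
        npv_den = (100.0 - p_out) + (100.0 - p_in)
        npv = (100.0 - p_out) / npv_den if npv_den > 0 else np.nan
        gini = gini_index(cl_means[gene_row[rec.gene]], printed=printed_gini)
        rows.append(
            {
                "gene": rec.gene,
                "cluster": rec.cluster,
                "sensitivity": sens,
                "specificity": spec,
                "ppv": ppv,
                "npv": npv,
                "gini": gini,
            }
        )
    return pd.DataFrame(rows)
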