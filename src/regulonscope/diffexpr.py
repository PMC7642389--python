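"""FPKM, negative-binomial differential expression, DEG filtering and clustering.

The test is a self-contained stand-in with the interface and thresholds of a
transcript-quantification pipeline's differential step: per-gene
negative-binomial likelihood-ratio test (method-of-moments dispersion,
library-size offsets), log2 fold changes from mean FPKM with a pseudo-count,
and the strict DEG filter |log2FC| > 1.0 and p < 0.05 on raw p-values (no
multiple-testing correction by default; Benjamini-Hochberg behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

DE_COLUMNS = ["gene_id", "mean_fpkm_A", "mean_fpkm_B", "log2fc", "p_value", "significant"]


@dataclass
class ExpressionMatrix:
    """Counts (gene x sample) plus gene lengths and sample annotations."""

    counts: pd.DataFrame
    gene_lengths: pd.Series  # bp
    samples: pd.DataFrame  # columns: sample, strain, media, replicate

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without lengths: {sorted(missing)[:3]}...")
        if (self.gene_lengths <= 0).any():
            raise ValueError("zero-length gene")


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts / (gene length in kb x library size in millions).

    Library size defaults to the column sum of counts (the synthetic data
    has no external mapped-read total).
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("zero-length gene")
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib <= 0).any():
        raise ValueError("library size must be > 0")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to composition bias).

    Each sample's factor is the median across genes of its counts divided by
    the per-gene geometric mean over samples (genes with any zero excluded).
    Total-count normalization is biased when a few operons change 10-fold on
    a small gene set; the median ratio is not. Factors are scaled to mean 1.
    """
    x = counts.values.astype(float)
    positive = (x > 0).all(axis=1)
    if positive.sum() < 3:
        # degenerate matrix: fall back to total counts
        lib = counts.sum(axis=0).astype(float)
        return lib / lib.mean()
    logx = np.log(x[positive])
    log_gm = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_gm, axis=0))
    factors = factors / factors.mean()
    return pd.Series(factors, index=counts.columns)


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 1e-8:
        return float(stats.poisson.logpmf(k, mu).sum())
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(k, r, p).sum())


def _mom_dispersion(y: np.ndarray) -> float:
    """Method-of-moments NB dispersion from library-size-normalized counts."""
    m = y.mean()
    if m <= 0:
        return 0.0
    v = y.var(ddof=1)
    return max(0.0, (v - m) / m**2)


def test_differential(
    matrix: ExpressionMatrix,
    group_A: list[str],
    group_B: list[str],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of group B vs group A.

    log2FC is computed on mean FPKM with pseudo-count ``config.pseudo_fpkm``
    (B over A); the p-value comes from a chi-square(1) likelihood-ratio test
    of separate vs shared group means at a pooled method-of-moments
    dispersion. Library-size offsets and the FPKM depth term use
    median-of-ratios size factors so a handful of strongly shifted operons
    cannot drag every other gene's fold change (composition bias).
    Deterministic; identical groups give log2FC 0 and p = 1.
    """
    cfg = config or RunConfig()
    if set(group_A) & set(group_B):
        raise ValueError("groups overlap")
    if len(group_A) < 2 or len(group_B) < 2:
        raise ValueError("need >= 2 replicates per group")
    counts = matrix.counts
    missing = (set(group_A) | set(group_B)) - set(counts.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")

    size = median_of_ratios_size_factors(counts[list(group_A) + list(group_B)])
    size = size.reindex(counts.columns).fillna(1.0)
    lib_mean = float(counts.sum(axis=0).mean())
    effective_lib = size * lib_mean
    fpkm = compute_fpkm(counts, matrix.gene_lengths, library_sizes=effective_lib)
    c = cfg.pseudo_fpkm

    rows = []
    sA = size[group_A].values
    sB = size[group_B].values
    s_all = np.concatenate([sA, sB])
    for gene in counts.index:
        kA = counts.loc[gene, group_A].values.astype(float)
        kB = counts.loc[gene, group_B].values.astype(float)
        muA = kA.sum() / sA.sum()
        muB = kB.sum() / sB.sum()
        mu0 = (kA.sum() + kB.sum()) / s_all.sum()

        alpha = 0.5 * (_mom_dispersion(kA / sA) + _mom_dispersion(kB / sB))
        alpha = min(alpha, 10.0)

        ll1 = _nb_loglik(kA, np.maximum(muA * sA, 1e-12), alpha) + _nb_loglik(
            kB, np.maximum(muB * sB, 1e-12), alpha
        )
        ll0 = _nb_loglik(np.concatenate([kA, kB]), np.maximum(mu0 * s_all, 1e-12), alpha)
        lr = max(0.0, 2.0 * (ll1 - ll0))
        p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0

        mfA = float(fpkm.loc[gene, group_A].mean())
        mfB = float(fpkm.loc[gene, group_B].mean())
        lfc = float(np.log2((mfB + c) / (mfA + c)))
        rows.append(
            {
                "gene_id": gene,
                "mean_fpkm_A": mfA,
                "mean_fpkm_B": mfB,
                "log2fc": lfc,
                "p_value": p,
                "significant": abs(lfc) > cfg.lfc_threshold and p < cfg.p_threshold,
            }
        )
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def filter_degs(
    results: pd.DataFrame, config: RunConfig | None = None, bh_correct: bool = False
) -> pd.DataFrame:
    """Strictly thresholded DEGs: |log2FC| > threshold AND p < threshold.

    Both inequalities are strict, so log2FC exactly 1.0 is excluded. With
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted first.
    """
    cfg = config or RunConfig()
    p = results["p_value"].values.astype(float)
    if bh_correct:
        n = p.size
        order = np.argsort(p)
        adj = np.empty(n)
        adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        p = np.minimum(adj, 1.0)
    keep = (np.abs(results["log2fc"].values) > cfg.lfc_threshold) & (p < cfg.p_threshold)
    out = results.loc[keep].copy()
    out["significant"] = True
    return out


def summarize_degs(significant: pd.DataFrame, total_genes: int) -> dict:
    """DEG counts and percentages (one decimal, of ``total_genes``)."""
    n_up = int((significant["log2fc"] > 0).sum())
    n_down = int((significant["log2fc"] < 0).sum())
    n_total = len(significant)
    if total_genes < n_total:
        raise ValueError("total_genes smaller than number of DEGs")

    def pct(n: int) -> float:
        return round(100.0 * n / total_genes, 1) if total_genes else 0.0

    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_total": n_total,
        "total_genes": total_genes,
        "pct_up": pct(n_up),
        "pct_down": pct(n_down),
        "pct_total": pct(n_total),
    }


def cluster_degs(
    fpkm: pd.DataFrame,
    significant_genes: list[str],
    method: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of DEGs on 1 - Pearson correlation.

    Rows are z-scored log2(FPKM + 1); a constant (zero-variance) row is
    assigned correlation 0 with everything (distance 1). Returns the
    deterministic dendrogram leaf order and the scipy linkage matrix.
    """
    from scipy.cluster import hierarchy

    genes = [g for g in significant_genes if g in fpkm.index]
    if len(genes) < 2:
        raise ValueError("need >= 2 genes to cluster")
    x = np.log2(fpkm.loc[genes].values + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    const = (sd.ravel() == 0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    corr = np.corrcoef(z)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform

    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(link)
    return [genes[i] for i in order], link
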