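"""Two-cluster differential expression for spot count data.

The test is an sSeq-style negative-binomial conditional exact test:

* per-spot size factors equalize depth (``total / median(total)``);
* per-gene dispersions are method-of-moments estimates on
  size-corrected counts, shrunk toward the mean dispersion with a
  data-driven James-Stein-type weight;
* the p-value conditions on the pooled gene count and asks how the
  total splits between the two clusters. Under the null the cluster
  sums are negative-binomial with means proportional to the cluster
  size-factor sums; all splits of the pooled total are enumerated and
  the probabilities at most that of the observed split are summed
  (two-sided). Above a pooled-total cutoff (default 900) a normal
  approximation with continuity correction replaces the enumeration.

At dispersion zero the conditional law is exactly binomial, which
serves as an independent oracle in the tests.

Significance uses the screening convention of the analysis: raw
p < 0.05 and |log2 fold change| >= 0.6. A Benjamini-Hochberg adjusted
column is always reported and may be selected instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SpotDataset
from .spatial import ClusterSelection

__all__ = [
    "DispersionModel",
    "low_count_filter",
    "estimate_dispersions",
    "nb_exact_test",
    "log_fold_change",
    "differential_expression",
    "significance_filter",
]

#: Pooled-total cutoff above which the normal approximation is used.
ENUMERATION_CUTOFF = 900

#: Relative tie tolerance when summing probabilities <= the observed one.
_TIE_RTOL = 1e-12


@dataclass
class DispersionModel:
    """Per-gene NB dispersions with shrinkage toward the pooled mean."""

    genes: pd.Index
    phi_mom: np.ndarray  # method-of-moments estimates, clamped at 0
    phi_bar: float  # pooled shrinkage target (mean of phi_mom)
    delta: float  # shrinkage weight in [0, 1]
    phi_shrunk: np.ndarray

    def phi_for(self, gene: str) -> float:
        return float(self.phi_shrunk[self.genes.get_loc(gene)])


def _barcodes(cluster) -> list[str]:
    if isinstance(cluster, ClusterSelection):
        return list(cluster.barcodes)
    return list(cluster)


def _cluster_arrays(ds: SpotDataset, A, B):
    """Dense per-gene count blocks and per-spot totals for two clusters."""
    a_bc, b_bc = _barcodes(A), _barcodes(B)
    if not a_bc or not b_bc:
        raise ValueError("clusters must be non-empty")
    if set(a_bc) & set(b_bc):
        raise ValueError("clusters must be disjoint")
    a = ds.counts[:, ds.columns_for(a_bc)].toarray().astype(float)
    b = ds.counts[:, ds.columns_for(b_bc)].toarray().astype(float)
    return a, b


def low_count_filter(ds: SpotDataset, A, B) -> np.ndarray:
    """Keep genes averaging at least one raw count per spot in a cluster.

    A gene is removed only if its mean raw count is below 1 in *both*
    clusters.
    """
    a, b = _cluster_arrays(ds, A, B)
    return (a.mean(axis=1) >= 1.0) | (b.mean(axis=1) >= 1.0)


def _size_factors(a: np.ndarray, b: np.ndarray):
    totals = np.concatenate([a.sum(axis=0), b.sum(axis=0)])
    med = np.median(totals[totals > 0])
    s = totals / med
    return s[: a.shape[1]], s[a.shape[1]:]


def estimate_dispersions(ds: SpotDataset, A, B, genes=None) -> DispersionModel:
    """Method-of-moments NB dispersions with James-Stein-type shrinkage.

    Dispersions are estimated on size-corrected counts pooled over both
    clusters: ``phi_hat = max(0, (v - m) / m^2)``. Each estimate is then
    shrunk toward the across-gene mean ``phi_bar`` with weight

        delta = min(1, sum_g v_g / sum_g (phi_hat_g - phi_bar)^2)

    where ``v_g`` is the delta-method sampling variance of ``phi_hat_g``
    (fourth NB moment evaluated at ``phi_bar``). When the estimates
    scatter no more than their sampling noise the weight saturates at 1
    and all genes share the pooled dispersion.
    """
    a, b = _cluster_arrays(ds, A, B)
    gene_index = ds.genes if genes is None else pd.Index(genes)
    if genes is not None:
        pos = ds.genes.get_indexer(gene_index)
        a, b = a[pos], b[pos]
    if a.shape[1] < 2 or b.shape[1] < 2:
        warnings.warn(
            "single-spot cluster: falling back to pooled dispersion", stacklevel=2
        )
    s_a, s_b = _size_factors(a, b)
    y = np.concatenate([a / s_a, b / s_b], axis=1)
    n = y.shape[1]
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1) if n > 1 else np.zeros_like(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), 0.0)
    phi_bar = float(phi_mom.mean()) if len(phi_mom) else 0.0

    # delta-method sampling variance of the moment estimator at phi_bar:
    # var(s^2) ~ sigma^4 (kappa + 2) / n with NB excess kurtosis
    # kappa = 6 phi + 1 / sigma^2, and phi_hat ~ (s^2 - m) / m^2.
    sigma2 = m * (1.0 + phi_bar * m)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = 6.0 * phi_bar + np.where(sigma2 > 0, 1.0 / sigma2, 0.0)
        var_phi = np.where(
            m > 0, sigma2**2 * (kappa + 2.0) / max(n, 2) / m**4, 0.0
        )
    spread = float(np.sum((phi_mom - phi_bar) ** 2))
    if spread <= 0:
        delta = 1.0
    else:
        delta = float(min(1.0, np.sum(var_phi) / spread))
    phi_shrunk = (1.0 - delta) * phi_mom + delta * phi_bar
    return DispersionModel(
        genes=gene_index,
        phi_mom=phi_mom,
        phi_bar=phi_bar,
        delta=delta,
        phi_shrunk=np.maximum(phi_shrunk, 0.0),
    )


def _sum_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a cluster count sum modelled as NB (Poisson if var<=mean)."""
    if mean <= 0:
        out = np.full_like(k, -np.inf, dtype=float)
        out[k == 0] = 0.0
        return out
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _split_moments(total: int, S_A: float, S_B: float, T_A: float, T_B: float, phi: float):
    """Null means/variances of the two cluster sums given the pooled total."""
    mu = total / (S_A + S_B)  # common per-size-unit mean under H0
    m_a, m_b = mu * S_A, mu * S_B
    v_a = m_a + phi * mu**2 * T_A
    v_b = m_b + phi * mu**2 * T_B
    return m_a, m_b, v_a, v_b


def nb_exact_test(
    a_sum: float,
    b_sum: float,
    S_A: float,
    S_B: float,
    T_A: float,
    T_B: float,
    phi: float,
    cutoff: int = ENUMERATION_CUTOFF,
) -> float:
    """Two-sided conditional test of a pooled count's split between clusters.

    ``S`` are the cluster sums of size factors and ``T`` the sums of
    squared size factors (they set the variance of a cluster's count
    sum under NB dispersion ``phi``). Counts must be integers.
    """
    for val, name in ((a_sum, "A"), (b_sum, "B")):
        if abs(val - round(val)) > 1e-9 or val < 0:
            raise ValueError(f"cluster {name} sum must be a non-negative integer")
    a_sum, b_sum = int(round(a_sum)), int(round(b_sum))
    total = a_sum + b_sum
    if total == 0:
        return 1.0
    m_a, m_b, v_a, v_b = _split_moments(total, S_A, S_B, T_A, T_B, phi)
    if total <= cutoff:
        k = np.arange(total + 1)
        logp = _sum_logpmf(k, m_a, v_a) + _sum_logpmf(k[::-1], m_b, v_b)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        obs = prob[a_sum]
        p = float(prob[prob <= obs * (1.0 + _TIE_RTOL)].sum())
    else:
        var_c = v_a * v_b / (v_a + v_b)
        sd = np.sqrt(var_c)
        lo = stats.norm.cdf(a_sum + 0.5, loc=m_a, scale=sd)
        hi = stats.norm.sf(a_sum - 0.5, loc=m_a, scale=sd)
        p = float(2.0 * min(lo, hi))
    return min(max(p, np.finfo(float).tiny), 1.0)


def log_fold_change(a_sum: float, b_sum: float, S_A: float, S_B: float) -> float:
    """Pseudocount-regularized log2 fold change of A over B.

    ``log2((sum_A + 1)/(S_A + 1)) - log2((sum_B + 1)/(S_B + 1))`` with
    ``S`` the per-cluster size-factor sums; finite even for one-sided
    zeros, and exactly antisymmetric under swapping the clusters.
    """
    return float(
        np.log2((a_sum + 1.0) / (S_A + 1.0)) - np.log2((b_sum + 1.0) / (S_B + 1.0))
    )


def differential_expression(
    ds: SpotDataset,
    A,
    B,
    alpha: float = 0.05,
    lfc_min: float = 0.6,
    p_column: str = "raw",
    cutoff: int = ENUMERATION_CUTOFF,
) -> pd.DataFrame:
    """Full two-cluster DE: filter, dispersions, exact test, LFC, flags.

    Returns a table sorted by p-value with columns ``gene``,
    ``mean_norm_A``, ``mean_norm_B``, ``lfc``, ``p``, ``p_adj`` (BH) and
    ``significant`` (p_used < alpha and |lfc| >= lfc_min).
    """
    if p_column not in ("raw", "bh"):
        raise ValueError("p_column must be 'raw' or 'bh'")
    a, b = _cluster_arrays(ds, A, B)
    keep = (a.mean(axis=1) >= 1.0) | (b.mean(axis=1) >= 1.0)
    genes = ds.genes[keep]
    a, b = a[keep], b[keep]
    if len(genes) == 0:
        return pd.DataFrame(
            columns=[
                "gene", "mean_norm_A", "mean_norm_B", "lfc", "p", "p_adj",
                "significant",
            ]
        )
    disp = estimate_dispersions(ds, A, B, genes=genes)
    s_a, s_b = _size_factors(a, b)
    S_A, S_B = float(s_a.sum()), float(s_b.sum())
    T_A, T_B = float((s_a**2).sum()), float((s_b**2).sum())
    a_sums = a.sum(axis=1)
    b_sums = b.sum(axis=1)
    pvals = np.array(
        [
            nb_exact_test(
                a_sums[g], b_sums[g], S_A, S_B, T_A, T_B,
                float(disp.phi_shrunk[g]), cutoff=cutoff,
            )
            for g in range(len(genes))
        ]
    )
    lfc = np.array(
        [log_fold_change(a_sums[g], b_sums[g], S_A, S_B) for g in range(len(genes))]
    )
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_norm_A": a_sums / S_A,
            "mean_norm_B": b_sums / S_B,
            "lfc": lfc,
            "p": pvals,
            "p_adj": p_adj,
        }
    )
    p_used = table["p"] if p_column == "raw" else table["p_adj"]
    table["significant"] = (p_used < alpha) & (table["lfc"].abs() >= lfc_min)
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return table


def significance_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.6,
    p_column: str = "raw",
) -> pd.DataFrame:
    """Rows with p_used strictly below alpha and |lfc| >= lfc_min."""
    p_used = table["p"] if p_column == "raw" else table["p_adj"]
    keep = (p_used < alpha) & (table["lfc"].abs() >= lfc_min)
    return table[keep].reset_index(drop=True)
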