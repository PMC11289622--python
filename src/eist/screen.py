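"""Biomarker screen: from DE gene lists to candidate genes per metric.

The screen consolidates the significant DE genes found at each
timepoint into one list (keeping, for genes found at several
timepoints, the log fold change of largest magnitude), builds the
gene x sample matrix of electrode-site MNA values, and asks which genes
(or small gene sets, via principal component regression on PC1) best
predict each recording-quality or histology metric (MUA, LFP, SNR,
GFAP, ND). Candidates are the genes scoring high on *both* axes of the
LFC-vs-R^2 plane.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import mna_normalize
from .spatial import select_cluster

__all__ = [
    "ConsolidatedGene",
    "RegressionResult",
    "PCRResult",
    "CandidateSet",
    "consolidate_de_lists",
    "electrode_site_expression",
    "single_gene_regression",
    "pca_inspect",
    "enumerate_gene_sets",
    "gene_set_pcr",
    "select_candidates",
    "predict_metric",
]


@dataclass(frozen=True)
class ConsolidatedGene:
    gene: str
    lfc: float  # per-timepoint LFC of largest magnitude, sign preserved
    timepoints: tuple[str, ...]
    lfc_by_timepoint: dict


@dataclass(frozen=True)
class RegressionResult:
    """Single-gene OLS of a metric on electrode-site MNA."""

    label: str  # gene name
    metric: str
    slope: float
    intercept: float
    r2: float
    p: float  # F-test p for the slope (non-adjusted)
    n: int


@dataclass(frozen=True)
class PCRResult:
    """Principal component regression of a metric on a gene set's PC1."""

    genes: tuple[str, ...]
    metric: str
    pc1_scores: np.ndarray  # per sample
    explained_var: float  # PC1 explained-variance fraction
    loadings: np.ndarray  # PC1 gene loadings (diagnostic)
    gene_means: np.ndarray  # z-scoring parameters, for prediction
    gene_sds: np.ndarray
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    mean_abs_lfc: float

    @property
    def label(self) -> str:
        return "+".join(self.genes)


@dataclass(frozen=True)
class CandidateSet:
    metric: str
    table: pd.DataFrame  # ranked: label, lfc, r2, p, score
    k: int


def consolidate_de_lists(
    tables: dict[str, pd.DataFrame]
) -> list[ConsolidatedGene]:
    """Union the per-timepoint significant DE gene lists.

    A gene present at several timepoints is represented by the LFC of
    largest magnitude (sign preserved), so strong down-regulation is not
    discarded in favour of a weaker positive value.
    """
    by_gene: dict[str, dict[str, float]] = {}
    for tp, table in tables.items():
        if table["gene"].duplicated().any():
            dups = table.loc[table["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in {tp} table: {dups[:5]}")
        for gene, lfc in zip(table["gene"], table["lfc"]):
            by_gene.setdefault(gene, {})[tp] = float(lfc)
    out = []
    for gene in sorted(by_gene):
        per_tp = by_gene[gene]
        rep = max(per_tp.values(), key=abs)
        out.append(
            ConsolidatedGene(
                gene=gene,
                lfc=rep,
                timepoints=tuple(sorted(per_tp)),
                lfc_by_timepoint=dict(per_tp),
            )
        )
    return out


def electrode_site_expression(
    samples, genes: list[str], rmax_um: float = 300.0
) -> pd.DataFrame:
    """Gene x sample matrix of electrode-site MNA values.

    For each implanted sample, the <=``rmax_um`` cluster is selected and
    median-normalized; entry (g, i) is gene g's MNA over that cluster.
    Naive samples carry no metrics and are excluded. Genes missing from
    a sample's feature list are recorded as 0 with a warning.
    """
    cols = {}
    for sample in samples:
        if not getattr(sample, "implanted", True):
            continue
        ds = sample.dataset
        cluster = select_cluster(ds.spots, ds.tract, rmax_um=rmax_um,
                                 name=f"{sample.name}_site")
        mna = mna_normalize(ds, cluster).gene_mna
        vals = np.zeros(len(genes))
        for i, g in enumerate(genes):
            if g in mna.index:
                vals[i] = mna.loc[g]
            else:
                warnings.warn(
                    f"gene {g!r} absent from sample {sample.name}; recorded as 0",
                    stacklevel=2,
                )
        cols[sample.name] = vals
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def single_gene_regression(
    x: np.ndarray, y: np.ndarray, gene: str, metric: str
) -> RegressionResult | None:
    """OLS of one metric on one gene's per-sample MNA.

    Samples with a missing metric are dropped; requires n >= 3. For
    simple regression the F-test p-value of the slope equals the t-test
    p-value reported by :func:`scipy.stats.linregress`. Returns None
    (logged) when x has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"{gene}/{metric}: need at least 3 paired samples")
    if np.ptp(x) == 0:
        warnings.warn(
            f"{gene}/{metric}: zero variance in expression; no regression",
            stacklevel=2,
        )
        return None
    res = stats.linregress(x, y)
    return RegressionResult(
        label=gene,
        metric=metric,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(min(max(res.pvalue, np.finfo(float).tiny), 1.0)),
        n=len(x),
    )


def pca_inspect(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a gene x sample MNA matrix for cohort inspection.

    Genes are centered across samples (no scaling) and the sample
    scores on PC1/PC2 are returned with the explained-variance
    fractions. Used to eyeball sample-to-sample variability (implanted
    samples scatter more than naive ones).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    out = pd.DataFrame(
        {
            "PC1": scores[:, 0],
            "PC2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
        },
        index=matrix.columns,
    )
    return out, frac


def enumerate_gene_sets(pool: list[str], sizes, cap: int = 100_000):
    """All gene subsets of the requested sizes, lexicographic, capped.

    Yields tuples in deterministic order; stops with a warning once
    ``cap`` subsets have been produced.
    """
    if not pool:
        raise ValueError("empty gene pool")
    if cap <= 0:
        raise ValueError("cap must be positive")
    sizes = [sizes] if isinstance(sizes, int) else list(sizes)
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"subset size {size} exceeds pool of {len(pool)}")
    produced = 0
    for size in sizes:
        for combo in itertools.combinations(sorted(pool), size):
            if produced >= cap:
                warnings.warn(
                    f"gene-set enumeration truncated at cap={cap}", stacklevel=2
                )
                return
            produced += 1
            yield combo


def gene_set_pcr(
    expr: pd.DataFrame,
    y: np.ndarray,
    metric: str,
    lfcs: dict[str, float] | None = None,
) -> PCRResult | None:
    """Regress a metric on PC1 of a z-scored gene set.

    ``expr`` holds the subset's rows of the gene x sample MNA matrix.
    Each gene is z-scored across samples (so no gene dominates by
    scale), PC1 scores are computed per sample, and the metric is
    regressed on them. For a singleton set this reduces exactly to the
    single-gene regression. Zero-variance genes are dropped with a
    warning; None is returned if none remain.
    """
    y = np.asarray(y, dtype=float)
    if expr.shape[1] != len(y):
        raise ValueError("expression columns and metric values must align")
    if expr.shape[1] < 3:
        raise ValueError("PCR needs at least 3 samples")
    X = expr.to_numpy(dtype=float)
    sds = X.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = list(expr.index[~keep])
        warnings.warn(f"dropping zero-variance genes {dropped}", stacklevel=2)
        X = X[keep]
        if X.shape[0] == 0:
            return None
    genes = tuple(expr.index[keep])
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=0)
    Z = ((X - means[:, None]) / sds[:, None]).T  # samples x genes
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0, keepdims=True), full_matrices=False)
    i = np.argmax(np.abs(Vt[0]))
    sign = 1.0 if Vt[0, i] >= 0 else -1.0
    loadings = sign * Vt[0]
    scores = sign * U[:, 0] * s[0]
    var = s**2
    evr = float(var[0] / var.sum()) if var.sum() > 0 else 0.0
    res = stats.linregress(scores, y)
    mean_abs_lfc = (
        float(np.mean([abs(lfcs[g]) for g in genes])) if lfcs else float("nan")
    )
    return PCRResult(
        genes=genes,
        metric=metric,
        pc1_scores=scores,
        explained_var=evr,
        loadings=loadings,
        gene_means=means,
        gene_sds=sds,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(min(max(res.pvalue, np.finfo(float).tiny), 1.0)),
        n=len(y),
        mean_abs_lfc=mean_abs_lfc,
    )


def select_candidates(results: pd.DataFrame, k: int = 5) -> CandidateSet:
    """Pick the genes/sets that are high on both |LFC| and R^2.

    |LFC| and R^2 are min-max normalized to [0, 1] across the results
    and each item is scored by the *smaller* of the two (a conservative
    "both axes high" rule). Items are ranked by descending score, ties
    broken by R^2 then label. ``results`` needs columns ``label``,
    ``lfc``, ``r2`` (and optionally ``p``).
    """
    if not 4 <= k <= 7:
        raise ValueError("k must be between 4 and 7")
    metric = results["metric"].iloc[0] if "metric" in results.columns else ""
    df = results.copy()
    if len(df) < k:
        warnings.warn(
            f"only {len(df)} results available for k={k}; returning all",
            stacklevel=2,
        )
    abs_lfc = df["lfc"].abs()

    def _minmax(v: pd.Series) -> pd.Series:
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else pd.Series(0.0, index=v.index)

    df["norm_lfc"] = _minmax(abs_lfc)
    df["norm_r2"] = _minmax(df["r2"])
    df["score"] = np.minimum(df["norm_lfc"], df["norm_r2"])
    df = df.sort_values(
        ["score", "r2", "label"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return CandidateSet(metric=metric, table=df.head(k), k=min(k, len(df)))


def predict_metric(
    result: RegressionResult | PCRResult,
    expr: pd.DataFrame,
    y: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fitted metric values from a stored regression or PCR model.

    ``expr`` is the gene x sample MNA matrix; for a PCR model the stored
    z-scoring parameters and PC1 loadings are applied to compute scores.
    Returns a per-sample table of predictor value, fitted value and
    (when ``y`` is given) actual value and residual, for
    predicted-vs-actual plots.
    """
    if isinstance(result, PCRResult):
        missing = [g for g in result.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression matrix missing genes {missing}")
        X = expr.loc[list(result.genes)].to_numpy(dtype=float)
        Z = ((X - result.gene_means[:, None]) / result.gene_sds[:, None]).T
        x = (Z - Z.mean(axis=0, keepdims=True)) @ result.loadings
    else:
        if result.label not in expr.index:
            raise KeyError(f"expression matrix missing gene {result.label!r}")
        x = expr.loc[result.label].to_numpy(dtype=float)
    fitted = result.intercept + result.slope * x
    out = pd.DataFrame({"x": x, "fitted": fitted}, index=expr.columns)
    if y is not None:
        out["actual"] = np.asarray(y, dtype=float)
        out["residual"] = out["actual"] - out["fitted"]
    return out
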