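"""End-to-end orchestration: simulate or load a cohort, QC, profiles,
differential expression, and the biomarker screen, with seeded
reproducibility and TSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .core import SpotDataset
from .diffexp import differential_expression, significance_filter
from .normalization import binned_mna_profile, depth_qc, housekeeping_linearity
from .screen import (
    consolidate_de_lists,
    electrode_site_expression,
    enumerate_gene_sets,
    gene_set_pcr,
    select_candidates,
    single_gene_regression,
)
from .simulate import (
    METRICS,
    CohortTruthSpec,
    SimulationConfig,
    default_panel,
    simulate_cohort,
)
from .spatial import assign_bins, select_cluster, select_naive_sites, spot_distances

log = logging.getLogger("eist")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All pipeline constants in one place; round-trips to JSON."""

    # cohort simulation (used when no sample paths are given)
    n_implanted: int = 8
    n_naive: int = 3
    grid_shape: tuple[int, int] = (20, 20)
    mean_depth: float = 55_000.0  # the study's samples exceeded the 50k guideline
    dispersion: float = 0.02
    n_neutral_genes: int = 50
    betas: dict = field(
        default_factory=lambda: {"MUA": {"Gfap": -0.002}, "SNR": {"Snap25": 0.004}}
    )
    # geometry / binning
    bin_width_um: float = 100.0
    rmax_um: float = 300.0
    max_bin: int = 9
    profile_genes: list = field(default_factory=lambda: ["Gfap", "Snap25"])
    housekeeping_genes: list = field(default_factory=lambda: ["Gapdh", "Actb"])
    # differential expression
    alpha: float = 0.05
    lfc_min: float = 0.6
    p_column: str = "raw"
    # screen
    pool_size: int = 20
    set_sizes: list = field(default_factory=lambda: [2])
    set_cap: int = 500
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.lfc_min < 0 or self.rmax_um <= 0:
            raise ValueError("thresholds must be non-negative, rmax positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _pooled_dataset(pairs: list[tuple[SpotDataset, list[str]]]) -> tuple[SpotDataset, list[str]]:
    """Stack the selected spot columns of several samples into one dataset.

    Used to pool per-timepoint electrode-site clusters (and naive-site
    clusters) into single comparison clusters for DE.
    """
    genes = pairs[0][0].genes
    blocks, frames, barcodes = [], [], []
    for i, (ds, bcs) in enumerate(pairs):
        if not ds.genes.equals(genes):
            raise ValueError("samples must share one feature list")
        blocks.append(ds.subset_counts(bcs))
        sub = ds.spots.loc[bcs].copy()
        sub.index = [f"s{i}:{b}" for b in bcs]
        frames.append(sub)
        barcodes.extend(sub.index)
    pooled = SpotDataset(
        counts=sp.hstack(blocks).tocsr(),
        genes=genes,
        spots=pd.concat(frames),
        tract=pairs[0][0].tract,
    )
    return pooled, barcodes


def run_pipeline(config: RunConfig, outdir: str | Path, samples=None, truth=None):
    """Run the full analysis and write every stage's outputs.

    With no ``samples``, a cohort is simulated under ``config``. Outputs
    (QC report, radial MNA profiles, per-timepoint DE and volcano
    tables, consolidated gene list, per-metric screen results and
    candidates, run log) are written under ``outdir``. Deterministic for
    a fixed config: re-running reproduces the outputs byte for byte.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    if samples is None:
        panel = default_panel(n_neutral=config.n_neutral_genes)
        sim_cfg = SimulationConfig(
            grid_shape=tuple(config.grid_shape),
            mean_depth=config.mean_depth,
            dispersion=config.dispersion,
            seed=rng_seed,
        )
        truth_spec = CohortTruthSpec(betas=config.betas)
        samples, truth = simulate_cohort(
            config.n_implanted,
            config.n_naive,
            panel,
            truth_spec,
            cfg=sim_cfg,
            seed=rng_seed,
        )
    implanted = [s for s in samples if s.implanted]
    naive = [s for s in samples if not s.implanted]
    if not implanted or not naive:
        raise ValueError("pipeline needs both implanted and naive samples")

    # --- QC ------------------------------------------------------------
    qc_rows = []
    for s in samples:
        rep = depth_qc(s.dataset)
        row = {
            "sample": s.name,
            "timepoint": s.timepoint,
            "mean_umi_per_spot": rep.mean_umi_per_spot,
            "depth_pass": rep.passed,
        }
        for g in config.housekeeping_genes:
            if g in s.dataset.genes:
                lin = housekeeping_linearity(s.dataset, g)
                row[f"{g}_r2"] = lin.r2
                row[f"{g}_pass"] = lin.passed
        qc_rows.append(row)
    qc = pd.DataFrame(qc_rows)
    _write(qc, outdir / "qc_report.tsv")
    log.info("QC: %d/%d samples pass depth", int(qc["depth_pass"].sum()), len(qc))

    # --- radial MNA profiles -------------------------------------------
    prof_rows = []
    for s in samples:
        d = spot_distances(s.dataset.spots, s.dataset.tract)
        bins = assign_bins(d, config.bin_width_um, (config.max_bin + 1) * config.bin_width_um)
        for g in config.profile_genes:
            if g not in s.dataset.genes:
                continue
            prof = binned_mna_profile(s.dataset, bins, g, max_bin=config.max_bin)
            prof.insert(0, "gene", g)
            prof.insert(0, "sample", s.name)
            prof_rows.append(prof)
    if prof_rows:
        _write(pd.concat(prof_rows, ignore_index=True), outdir / "mna_profiles.tsv")

    # --- per-timepoint DE ----------------------------------------------
    naive_pairs = []
    for j, s in enumerate(naive):
        sites = select_naive_sites(
            s.dataset.spots, n_sites=1, radius_um=config.rmax_um,
            seed=rng_seed + 1000 + j,
        )
        naive_pairs.append((s.dataset, list(sites[0].barcodes)))
    sig_tables: dict[str, pd.DataFrame] = {}
    for tp in sorted({s.timepoint for s in implanted}):
        tp_pairs = []
        for s in implanted:
            if s.timepoint != tp:
                continue
            cl = select_cluster(s.dataset.spots, s.dataset.tract, config.rmax_um)
            tp_pairs.append((s.dataset, list(cl.barcodes)))
        pooled, a_bcs = _pooled_dataset(tp_pairs + naive_pairs)
        n_a = sum(len(b) for _, b in tp_pairs)
        table = differential_expression(
            pooled, a_bcs[:n_a], a_bcs[n_a:],
            alpha=config.alpha, lfc_min=config.lfc_min, p_column=config.p_column,
        )
        _write(table, outdir / f"de_{tp}.tsv")
        volcano = pd.DataFrame(
            {
                "gene": table["gene"],
                "lfc": table["lfc"],
                "neg_log10_p": -np.log10(table["p"]),
            }
        )
        _write(volcano, outdir / f"volcano_{tp}.tsv")
        sig = significance_filter(
            table, alpha=config.alpha, lfc_min=config.lfc_min,
            p_column=config.p_column,
        )
        sig_tables[tp] = sig
        log.info("DE %s: %d tested, %d significant", tp, len(table), len(sig))

    # --- consolidate + screen ------------------------------------------
    n_sig = sum(len(t) for t in sig_tables.values())
    if n_sig == 0:
        warnings.warn("no significant DE genes; screen skipped", stacklevel=2)
        _finish(outdir, config, t0, screened=False)
        return outdir
    consolidated = consolidate_de_lists(sig_tables)
    cons = pd.DataFrame(
        [
            {"gene": c.gene, "lfc": c.lfc, "timepoints": ",".join(c.timepoints)}
            for c in consolidated
        ]
    )
    _write(cons, outdir / "consolidated_genes.tsv")
    lfc_map = {c.gene: c.lfc for c in consolidated}
    expr = electrode_site_expression(
        implanted, [c.gene for c in consolidated], rmax_um=config.rmax_um
    )
    _write(expr, outdir / "site_expression.tsv", index=True)
    metrics_table = (
        truth.metrics
        if truth is not None
        else pd.DataFrame(
            {m: {s.name: s.metrics[m] for s in implanted} for m in METRICS}
        )
    )
    _write(metrics_table, outdir / "sample_metrics.tsv", index=True)

    candidates = {}
    for metric in METRICS:
        y = metrics_table.loc[expr.columns, metric].to_numpy()
        rows = []
        for gene in expr.index:
            res = single_gene_regression(expr.loc[gene].to_numpy(), y, gene, metric)
            if res is None:
                continue
            rows.append(
                {
                    "label": res.label, "metric": metric, "lfc": lfc_map[gene],
                    "r2": res.r2, "p": res.p, "slope": res.slope,
                    "intercept": res.intercept, "n": res.n,
                }
            )
        results = pd.DataFrame(rows)
        _write(results, outdir / f"screen_{metric}.tsv")
        if len(results) >= 1:
            sel = select_candidates(results, k=min(max(config.top_k, 4), 7))
            candidates[metric] = sel.table["label"].tolist()
        # gene-set PCR over the top pool by |lfc|
        pool = (
            results.reindex(results["lfc"].abs().sort_values(ascending=False).index)
            ["label"].head(config.pool_size).tolist()
        )
        pcr_rows = []
        for combo in enumerate_gene_sets(pool, config.set_sizes, cap=config.set_cap):
            res = gene_set_pcr(expr.loc[list(combo)], y, metric, lfcs=lfc_map)
            if res is None:
                continue
            pcr_rows.append(
                {
                    "label": res.label, "metric": metric,
                    "mean_abs_lfc": res.mean_abs_lfc, "r2": res.r2, "p": res.p,
                    "explained_var": res.explained_var,
                }
            )
        if pcr_rows:
            _write(pd.DataFrame(pcr_rows), outdir / f"pcr_{metric}.tsv")
    (outdir / "candidates.json").write_text(
        json.dumps(candidates, indent=1, sort_keys=True)
    )
    _finish(outdir, config, t0, screened=True)
    return outdir


def _finish(outdir: Path, config: RunConfig, t0: float, screened: bool) -> None:
    run_log = {
        "eist_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "lfc_min": config.lfc_min,
        "p_column": config.p_column,
        "rmax_um": config.rmax_um,
        "screened": screened,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    log.info("pipeline finished in %.1f s", time.time() - t0)
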