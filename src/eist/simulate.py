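"""Synthetic data generators with known ground truth.

These generators emulate the statistical structure the analysis
consumes, so that every downstream stage can be exercised and verified
without the deposited sequencing data:

* a Visium-like rectangular spot lattice (100 µm pitch) whose UMI
  counts are negative-binomial with a mean depth of ~50 000 per spot,
  and whose genes can be radially perturbed around a planted tract
  (multiplicative fold change decaying exponentially with distance);
* multichannel recordings composed of Poisson spike trains of a known
  biphasic template, spike-band-limited background noise, a 60 Hz line
  component, a band-limited LFP component, and an optional common-mode
  artifact shared by all channels;
* IHC samples: neuron centroids from an inhomogeneous Poisson process
  with near-tract suppression, and a GFAP-like intensity field decaying
  exponentially from the tract;
* multi-sample cohorts in which selected genes carry planted linear
  relationships to the recording-quality and histology metrics.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from .core import SpotDataset
from .ephys import EphysRecording
from .spatial import IntensityField, TractGeometry, spot_distances

__all__ = [
    "SimulationConfig",
    "GeneSpec",
    "EphysSimConfig",
    "CohortTruthSpec",
    "CohortSample",
    "CohortTruth",
    "SpotTruth",
    "RecordingTruth",
    "default_panel",
    "biphasic_template",
    "simulate_spot_dataset",
    "simulate_recording",
    "simulate_ihc_sample",
    "simulate_cohort",
]

METRICS = ("MUA", "LFP", "SNR", "GFAP", "ND")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated spot dataset.

    ``mean_depth`` defaults to the recommended sequencing depth of
    50 000 UMI per spot; ``spot_pitch_um`` to the 100 µm lattice pitch.
    ``depth_cv`` sets the spot-to-spot lognormal variation in depth
    (real capture areas are not perfectly uniform).
    """

    grid_shape: tuple[int, int] = (30, 30)
    spot_pitch_um: float = 100.0
    tract_center_um: tuple[float, float] | None = None
    mean_depth: float = 50_000.0
    n_genes: int | None = None
    dispersion: float = 0.02
    depth_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_pitch_um <= 0:
            raise ValueError("spot_pitch_um must be positive")
        if self.mean_depth <= 0 or not np.isfinite(self.mean_depth):
            raise ValueError("mean_depth must be positive and finite")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be >= 0 and finite")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be a positive integer pair")


@dataclass(frozen=True)
class GeneSpec:
    """Radial expression program of one gene.

    The expected proportion of a spot's UMIs at distance ``d`` is
    ``baseline_prop * (1 + (effect_amplitude - 1) * exp(-d/decay_um))``
    (renormalized across the panel at each spot), so the fold change at
    the tract is ``effect_amplitude`` and decays to 1 far away.
    """

    name: str
    baseline_prop: float
    effect_amplitude: float = 1.0
    decay_um: float = 150.0
    role: str = "neutral"  # housekeeping | up_marker | down_marker | neutral

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_prop) and self.baseline_prop > 0):
            raise ValueError(f"{self.name}: baseline_prop must be positive")
        if not (np.isfinite(self.effect_amplitude) and self.effect_amplitude >= 0):
            raise ValueError(f"{self.name}: effect_amplitude must be >= 0")
        if not (np.isfinite(self.decay_um) and self.decay_um > 0):
            raise ValueError(f"{self.name}: decay_um must be positive")
        if self.role not in ("housekeeping", "up_marker", "down_marker", "neutral"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "housekeeping" and self.effect_amplitude != 1.0:
            raise ValueError(
                f"{self.name}: housekeeping genes must have effect_amplitude 1"
            )


def default_panel(n_neutral: int = 50) -> list[GeneSpec]:
    """A small panel with housekeeping genes, tract markers and neutrals.

    Mirrors the qualitative cast of the experiment: *Gfap* strongly
    up-regulated at the tract, *Snap25* down-regulated (neuronal loss),
    *Lcn2*/*Hspb1* inflammatory up-markers, *Gapdh*/*Actb* housekeeping.
    """
    panel = [
        GeneSpec("Gapdh", 0.03, 1.0, role="housekeeping"),
        GeneSpec("Actb", 0.03, 1.0, role="housekeeping"),
        GeneSpec("Gfap", 0.01, 8.0, 150.0, role="up_marker"),
        GeneSpec("Lcn2", 0.005, 6.0, 150.0, role="up_marker"),
        GeneSpec("Hspb1", 0.005, 4.0, 150.0, role="up_marker"),
        # neuronal loss extends further than the glial reaction
        GeneSpec("Snap25", 0.02, 0.3, 300.0, role="down_marker"),
    ]
    used = sum(g.baseline_prop for g in panel)
    each = (1.0 - used) / n_neutral
    panel += [GeneSpec(f"neutral_{i:03d}", each) for i in range(n_neutral)]
    return panel


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for a simulated spot dataset."""

    distances_um: np.ndarray
    depths: np.ndarray  # per-spot expected total UMI
    props: np.ndarray  # genes x spots expected proportions (renormalized)
    panel: tuple[GeneSpec, ...]

    def radial_prop(self, gene_idx: int, d: np.ndarray) -> np.ndarray:
        """Unnormalized expected proportion of gene ``gene_idx`` at distance d."""
        g = self.panel[gene_idx]
        return g.baseline_prop * (
            1.0 + (g.effect_amplitude - 1.0) * np.exp(-np.asarray(d) / g.decay_um)
        )


def _panel_props(panel: list[GeneSpec], d: np.ndarray) -> np.ndarray:
    base = np.array([g.baseline_prop for g in panel])
    if base.sum() > 1.0 + 1e-9:
        raise ValueError(
            f"panel baseline proportions sum to {base.sum():.3f} > 1"
        )
    amp = np.array([g.effect_amplitude for g in panel])
    decay = np.array([g.decay_um for g in panel])
    props = base[:, None] * (
        1.0 + (amp[:, None] - 1.0) * np.exp(-d[None, :] / decay[:, None])
    )
    return props / props.sum(axis=0, keepdims=True)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_spot_dataset(
    cfg: SimulationConfig, panel: list[GeneSpec]
) -> tuple[SpotDataset, SpotTruth]:
    """Simulate a spot lattice with radially perturbed NB counts.

    Counts for gene ``g`` at spot ``j`` are NB with mean
    ``depth_j * p_g(d_j)`` and dispersion ``cfg.dispersion`` (Poisson at
    zero), where ``p_g`` is the renormalized radial proportion profile.
    Returns the dataset together with the generating truth.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    if cfg.n_genes is not None and cfg.n_genes != len(panel):
        raise ValueError("cfg.n_genes does not match panel size")
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.grid_shape
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    rows, cols = rows.ravel(), cols.ravel()
    x = cols * cfg.spot_pitch_um
    y = rows * cfg.spot_pitch_um
    if cfg.tract_center_um is None:
        center = (float(x.mean()), float(y.mean()))
    else:
        center = (float(cfg.tract_center_um[0]), float(cfg.tract_center_um[1]))
    tract = TractGeometry(center_um=center)
    barcodes = [f"spot_{r:03d}_{c:03d}" for r, c in zip(rows, cols)]
    spots = pd.DataFrame(
        {
            "x_um": x.astype(float),
            "y_um": y.astype(float),
            "row": rows,
            "col": cols,
            "in_tissue": True,
            "artifact": False,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    d = spot_distances(spots, tract)
    props = _panel_props(panel, d)
    if cfg.depth_cv > 0:
        s = np.sqrt(np.log1p(cfg.depth_cv**2))
        depths = cfg.mean_depth * rng.lognormal(-(s**2) / 2.0, s, size=len(d))
    else:
        depths = np.full(len(d), cfg.mean_depth)
    mean = depths[None, :] * props
    counts = _nb_draw(rng, mean, cfg.dispersion)
    ds = SpotDataset(
        counts=sp.csr_matrix(counts),
        genes=pd.Index([g.name for g in panel]),
        spots=spots,
        tract=tract,
    )
    truth = SpotTruth(
        distances_um=d, depths=depths, props=props, panel=tuple(panel)
    )
    return ds, truth


# --------------------------------------------------------------------------
# recordings


@dataclass(frozen=True)
class EphysSimConfig:
    """Study conditions for one simulated implant recording.

    Defaults follow the recording setup the metrics expect: ~48 kHz
    sampling and a 16-channel single-shank array. ``noise_sd_uv`` is the
    standard deviation of the spike-band background noise (the operative
    noise floor for SNR); ``lfp_sd_uv`` that of the 1-300 Hz component.
    """

    fs_hz: float = 48_828.0
    duration_s: float = 5.0
    n_channels: int = 16
    spike_rate_hz: float = 20.0
    template_p2p_uv: float = 100.0
    template: np.ndarray | None = None
    noise_sd_uv: float = 3.0
    line_amp_uv: float = 1.0
    lfp_sd_uv: float = 20.0
    common_artifact_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 12_000:
            raise ValueError("fs_hz must exceed 12 kHz (Nyquist above 6 kHz)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("noise_sd_uv", "line_amp_uv", "lfp_sd_uv",
                     "common_artifact_uv", "template_p2p_uv", "spike_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def biphasic_template(
    fs_hz: float, p2p_uv: float, width_ms: float = 0.1
) -> np.ndarray:
    """A biphasic extracellular spike template with exact peak-to-peak.

    Gaussian-derivative shape (negative-leading), total span ~0.6 ms
    (typical of extracellular action potentials), energy concentrated
    around 1.6 kHz so it passes the 500-6000 Hz spike band essentially
    unattenuated.
    """
    sigma = width_ms * 1e-3
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs_hz)
    w = t * np.exp(-(t**2) / (2 * sigma**2))
    w = -w  # negative-leading: absolute minimum first
    return w * (p2p_uv / (w.max() - w.min()))


@dataclass(frozen=True)
class RecordingTruth:
    """Planted ground truth for a simulated recording."""

    spike_indices: tuple[np.ndarray, ...]  # per-channel template-minimum samples
    template_p2p_uv: float
    noise_sd_uv: float
    lfp_sd_uv: float


#: Bands of the planted LFP and background-noise components. Both are
#: kept strictly interior to their measurement bands (1-300 Hz and
#: 500-6000 Hz respectively), so the planted SDs are the operative
#: ground truth for the amplitude metrics rather than being re-shaped
#: by the analysis filters.
LFP_SIM_BAND_HZ = (2.0, 200.0)
NOISE_SIM_BAND_HZ = (600.0, 5000.0)


def _brickwall_noise(
    rng: np.random.Generator, n: int, sd: float, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Gaussian noise with a flat spectrum confined exactly to ``band``."""
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, n)
    return y * (sd / y.std())


def simulate_recording(
    cfg: EphysSimConfig,
) -> tuple[EphysRecording, RecordingTruth]:
    """Simulate a multichannel recording with planted spikes.

    Each channel is an independent Poisson spike train of the template
    plus spike-band background noise, a 60 Hz sinusoid (random phase per
    channel), a band-limited LFP component, and a common-mode artifact
    injected identically on all channels. Spike rates whose expected
    inter-spike interval is under two template lengths are clamped with
    a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    template = (
        cfg.template
        if cfg.template is not None
        else biphasic_template(fs, cfg.template_p2p_uv)
    )
    template = np.asarray(template, dtype=float)
    L = len(template)
    if L >= int(round(0.0024 * fs)):
        raise ValueError("template must be shorter than the 2.4 ms snippet window")
    rate = cfg.spike_rate_hz
    max_rate = fs / (2.0 * L)
    if rate > max_rate:
        warnings.warn(
            f"spike_rate_hz {rate} too high for template length; "
            f"clamping to {max_rate:.1f} Hz",
            stacklevel=2,
        )
        rate = max_rate
    t = np.arange(n) / fs
    common = (
        cfg.common_artifact_uv * np.sin(2 * np.pi * 7.0 * t)
        if cfg.common_artifact_uv > 0
        else 0.0
    )
    tmin = int(np.argmin(template))
    signal = np.empty((cfg.n_channels, n))
    spike_indices = []
    for c in range(cfg.n_channels):
        x = _brickwall_noise(rng, n, cfg.noise_sd_uv, fs, NOISE_SIM_BAND_HZ)
        x = x + _brickwall_noise(rng, n, cfg.lfp_sd_uv, fs, LFP_SIM_BAND_HZ)
        if cfg.line_amp_uv > 0:
            x = x + cfg.line_amp_uv * np.sin(
                2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
            )
        n_spikes = rng.poisson(rate * cfg.duration_s)
        starts = np.sort(rng.integers(0, n - L, size=n_spikes))
        # enforce non-overlapping templates (greedy)
        kept = []
        last_end = -1
        for s0 in starts:
            if s0 > last_end:
                kept.append(s0)
                last_end = s0 + L
        for s0 in kept:
            x[s0: s0 + L] += template
        spike_indices.append(np.asarray(kept, dtype=int) + tmin)
        signal[c] = x + common
    rec = EphysRecording(signal=signal, fs_hz=fs)
    truth = RecordingTruth(
        spike_indices=tuple(spike_indices),
        template_p2p_uv=float(template.max() - template.min()),
        noise_sd_uv=cfg.noise_sd_uv,
        lfp_sd_uv=cfg.lfp_sd_uv,
    )
    return rec, truth


# --------------------------------------------------------------------------
# IHC


def simulate_ihc_sample(
    tract: TractGeometry,
    density_far: float = 1000.0,
    suppression_radius_um: float = 100.0,
    gfap_peak: float = 100.0,
    gfap_decay_um: float = 100.0,
    seed: int = 0,
    extent_um: float = 1000.0,
    pixel_um: float = 5.0,
    gfap_baseline: float = 50.0,
    gfap_noise_sd: float = 5.0,
) -> tuple[np.ndarray, IntensityField]:
    """Simulate neuron centroids and a GFAP-like intensity field.

    Neurons follow an inhomogeneous Poisson process with density
    ``density_far * (1 - exp(-d / suppression_radius_um))`` (neuronal
    loss at the tract, recovering to the far-field density); the
    intensity field is ``baseline + peak * exp(-d / decay)`` plus
    Gaussian pixel noise (elevated astrocyte reactivity at the tract).
    """
    if min(density_far, suppression_radius_um, gfap_decay_um, extent_um,
           pixel_um) <= 0 or gfap_peak < 0:
        raise ValueError("all IHC simulation parameters must be positive")
    rng = np.random.default_rng(seed)
    cx, cy = tract.center_um
    area_mm2 = (2 * extent_um / 1000.0) ** 2
    n_cand = rng.poisson(density_far * area_mm2)
    pts = np.column_stack(
        [
            rng.uniform(cx - extent_um, cx + extent_um, n_cand),
            rng.uniform(cy - extent_um, cy + extent_um, n_cand),
        ]
    )
    if n_cand:
        import shapely

        d = shapely.distance(shapely.points(pts), tract.as_shapely())
        keep = rng.random(n_cand) < (1.0 - np.exp(-d / suppression_radius_um))
        pts = pts[keep]
    x_ax = np.arange(cx - extent_um + pixel_um / 2, cx + extent_um, pixel_um)
    y_ax = np.arange(cy - extent_um + pixel_um / 2, cy + extent_um, pixel_um)
    xx, yy = np.meshgrid(x_ax, y_ax)
    import shapely

    dpix = shapely.distance(
        shapely.points(np.column_stack([xx.ravel(), yy.ravel()])),
        tract.as_shapely(),
    ).reshape(xx.shape)
    values = (
        gfap_baseline
        + gfap_peak * np.exp(-dpix / gfap_decay_um)
        + rng.normal(0, gfap_noise_sd, xx.shape)
    )
    return pts, IntensityField(values=values, x_um=x_ax, y_um=y_ax)


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortTruthSpec:
    """Planted gene-metric relationships for a simulated cohort.

    Each metric is generated as ``alpha + sum_g beta_g * x_g + eps``
    where ``x_g`` is the planted electrode-site MNA of gene ``g`` for
    that sample and ``eps ~ N(0, noise_sd)``. Sample-to-sample variation
    in ``x`` comes from a per-sample severity factor ``eta`` that scales
    each gene's log fold effect by its responsiveness (defaulting to
    |log2 effect_amplitude|, so tract-responsive genes co-vary with
    severity while flat genes stay flat).
    """

    betas: dict[str, dict[str, float]]  # metric -> {gene: beta}
    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "MUA": 20.0, "LFP": 200.0, "SNR": 4.0, "GFAP": 150.0, "ND": 800.0
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "MUA": 1.0, "LFP": 10.0, "SNR": 0.2, "GFAP": 5.0, "ND": 20.0
        }
    )
    severity_sd: float = 0.5
    responsiveness: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for metric in self.betas:
            if metric not in METRICS:
                raise ValueError(f"unknown metric {metric!r}")


@dataclass
class CohortSample:
    """One animal/section: spot data plus (for implanted) metric values."""

    name: str
    timepoint: str  # 24h | 1wk | 6wk | naive
    dataset: SpotDataset
    truth: SpotTruth
    metrics: dict[str, float] | None  # None for naive samples

    @property
    def implanted(self) -> bool:
        return self.metrics is not None


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    x_planted: pd.DataFrame  # genes x implanted samples, planted site MNA
    metrics: pd.DataFrame  # implanted samples x metrics
    betas: dict[str, dict[str, float]]
    noise_sd: dict[str, float]
    severity: pd.Series  # per implanted sample


def _planted_site_mna(
    cfg: SimulationConfig, panel: list[GeneSpec], rmax_um: float = 300.0
) -> np.ndarray:
    """Expected electrode-site MNA per gene under the panel's profiles."""
    nrow, ncol = cfg.grid_shape
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    x = cols.ravel() * cfg.spot_pitch_um
    y = rows.ravel() * cfg.spot_pitch_um
    if cfg.tract_center_um is None:
        center = (x.mean(), y.mean())
    else:
        center = cfg.tract_center_um
    d = np.hypot(x - center[0], y - center[1])
    props = _panel_props(panel, d[d < rmax_um])
    # MNA rescales every spot to the cluster's *median* total; under the
    # lognormal depth model the median is mean * exp(-s^2/2)
    s2 = np.log1p(cfg.depth_cv**2)
    median_depth = cfg.mean_depth * np.exp(-s2 / 2.0)
    return median_depth * props.mean(axis=1)


def simulate_cohort(
    n_implanted: int,
    n_naive: int,
    panel: list[GeneSpec],
    truth_spec: CohortTruthSpec,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[CohortSample], CohortTruth]:
    """Simulate a cohort with planted gene-metric linear relationships.

    Implanted samples get spot datasets whose per-gene effect amplitudes
    vary with a per-sample severity factor, plus metric values generated
    from the planted linear model on the (analytic) electrode-site MNA.
    Naive samples get flat-amplitude datasets and no metrics.
    """
    if n_implanted < 3:
        raise ValueError("need at least 3 implanted samples")
    if cfg is None:
        cfg = SimulationConfig(grid_shape=(20, 20), seed=seed)
    gene_names = {g.name for g in panel}
    for metric, bs in truth_spec.betas.items():
        missing = set(bs) - gene_names
        if missing:
            raise ValueError(f"betas for {metric} name unknown genes: {missing}")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_implanted + n_naive)
    resp = {
        g.name: (
            truth_spec.responsiveness.get(g.name, abs(np.log2(max(g.effect_amplitude, 1e-12))))
            if truth_spec.responsiveness
            else abs(np.log2(max(g.effect_amplitude, 1e-12)))
        )
        for g in panel
    }
    timepoints = ["24h", "1wk", "6wk"]
    samples: list[CohortSample] = []
    x_cols = {}
    metric_rows = {}
    etas = {}
    for i in range(n_implanted):
        name = f"implant_{i:02d}"
        eta = rng.normal(0.0, truth_spec.severity_sd)
        etas[name] = eta
        sample_panel = [
            GeneSpec(
                g.name,
                g.baseline_prop,
                (
                    1.0
                    if g.role == "housekeeping"
                    else float(
                        max(g.effect_amplitude, 1e-12) * 2.0 ** (resp[g.name] * eta)
                    )
                ),
                g.decay_um,
                g.role,
            )
            for g in panel
        ]
        scfg = SimulationConfig(
            grid_shape=cfg.grid_shape,
            spot_pitch_um=cfg.spot_pitch_um,
            tract_center_um=cfg.tract_center_um,
            mean_depth=cfg.mean_depth,
            dispersion=cfg.dispersion,
            depth_cv=cfg.depth_cv,
            seed=int(seeds[i]),
        )
        ds, truth = simulate_spot_dataset(scfg, sample_panel)
        x = _planted_site_mna(scfg, sample_panel)
        x_cols[name] = x
        metrics = {}
        for metric in METRICS:
            bs = truth_spec.betas.get(metric, {})
            lin = truth_spec.intercepts.get(metric, 0.0)
            for gname, beta in bs.items():
                gi = [g.name for g in panel].index(gname)
                lin += beta * x[gi]
            sd = truth_spec.noise_sd.get(metric, 0.0)
            metrics[metric] = float(lin + (rng.normal(0.0, sd) if sd > 0 else 0.0))
        metric_rows[name] = metrics
        samples.append(
            CohortSample(
                name=name,
                timepoint=timepoints[i % len(timepoints)],
                dataset=ds,
                truth=truth,
                metrics=metrics,
            )
        )
    for i in range(n_naive):
        name = f"naive_{i:02d}"
        flat_panel = [
            GeneSpec(g.name, g.baseline_prop, 1.0, g.decay_um,
                     g.role if g.role == "housekeeping" else "neutral")
            for g in panel
        ]
        scfg = SimulationConfig(
            grid_shape=cfg.grid_shape,
            spot_pitch_um=cfg.spot_pitch_um,
            tract_center_um=cfg.tract_center_um,
            mean_depth=cfg.mean_depth,
            dispersion=cfg.dispersion,
            depth_cv=cfg.depth_cv,
            seed=int(seeds[n_implanted + i]),
        )
        ds, truth = simulate_spot_dataset(scfg, flat_panel)
        samples.append(
            CohortSample(
                name=name, timepoint="naive", dataset=ds, truth=truth, metrics=None
            )
        )
    gene_index = pd.Index([g.name for g in panel])
    truth = CohortTruth(
        x_planted=pd.DataFrame(x_cols, index=gene_index),
        metrics=pd.DataFrame(metric_rows).T[list(METRICS)],
        betas=truth_spec.betas,
        noise_sd=truth_spec.noise_sd,
        severity=pd.Series(etas),
    )
    return samples, truth
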