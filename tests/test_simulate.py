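"""Synthetic-data generators: determinism, marginals, planted effects."""

import numpy as np
import pytest

from eist.ephys import car_subtract
from eist.screen import single_gene_regression
from eist.simulate import (
    CohortTruthSpec,
    EphysSimConfig,
    GeneSpec,
    SimulationConfig,
    default_panel,
    simulate_cohort,
    simulate_ihc_sample,
    simulate_recording,
    simulate_spot_dataset,
)
from eist.spatial import TractGeometry, assign_bins, spot_distances


class TestSpotDataset:
    def test_deterministic_bitwise(self):
        cfg = SimulationConfig(grid_shape=(10, 10), seed=42)
        ds1, _ = simulate_spot_dataset(cfg, default_panel(10))
        ds2, _ = simulate_spot_dataset(cfg, default_panel(10))
        assert (ds1.counts != ds2.counts).nnz == 0
        assert ds1.spots.equals(ds2.spots)

    def test_flat_poisson_means(self):
        # phi=0, no effects: per-gene counts Poisson with distance-free rates
        panel = [GeneSpec(f"g{i}", 0.1) for i in range(10)]
        cfg = SimulationConfig(
            grid_shape=(20, 20), dispersion=0.0, depth_cv=0.0,
            mean_depth=10_000, seed=1,
        )
        ds, truth = simulate_spot_dataset(cfg, panel)
        counts = ds.counts.toarray()
        for g in range(10):
            expect = 10_000 * 0.1
            se = np.sqrt(expect / 400)
            assert abs(counts[g].mean() - expect) < 3 * se

    def test_depth_marginal(self):
        cfg = SimulationConfig(grid_shape=(20, 20), seed=2)
        ds, _ = simulate_spot_dataset(cfg, default_panel(30))
        totals = ds.spot_totals()
        se = totals.std() / np.sqrt(len(totals))
        assert abs(totals.mean() - cfg.mean_depth) < 3 * se

    def test_up_marker_gradient_across_seeds(self):
        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(grid_shape=(21, 21), seed=seed)
            ds, _ = simulate_spot_dataset(cfg, default_panel(30))
            d = spot_distances(ds.spots, ds.tract)
            bins = assign_bins(d, 100.0, 1000.0)
            g = ds.genes.get_loc("Gfap")
            row = ds.counts[g].toarray().ravel() / ds.spot_totals()
            near = row[bins.index == 0].mean()
            far = row[bins.index == 9].mean()
            wins += near > far
        assert wins >= 19

    def test_effect_amplitude_monotone_in_expectation(self):
        # increasing amplitude strictly increases the 0-100 um bin mean
        near_means = []
        for amp in (1.0, 2.0, 4.0, 8.0):
            bin0 = []
            for seed in range(30):
                panel = [
                    GeneSpec("m", 0.01, amp, 150.0,
                             "up_marker" if amp > 1 else "neutral"),
                    GeneSpec("bulk", 0.9),
                ]
                cfg = SimulationConfig(grid_shape=(11, 11), seed=seed,
                                       depth_cv=0.0)
                ds, _ = simulate_spot_dataset(cfg, panel)
                d = spot_distances(ds.spots, ds.tract)
                sel = d < 100.0
                bin0.append(
                    (ds.counts[0].toarray().ravel() / ds.spot_totals())[sel].mean()
                )
            near_means.append(np.mean(bin0))
        assert all(a < b for a, b in zip(near_means, near_means[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(mean_depth=-1)
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-0.1)
        with pytest.raises(ValueError):
            GeneSpec("g", baseline_prop=0.0)
        with pytest.raises(ValueError, match="housekeeping"):
            GeneSpec("g", 0.1, 2.0, role="housekeeping")
        panel = [GeneSpec("a", 0.7), GeneSpec("b", 0.7)]
        with pytest.raises(ValueError, match="sum"):
            simulate_spot_dataset(SimulationConfig(grid_shape=(3, 3)), panel)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_spot_dataset(SimulationConfig(grid_shape=(3, 3)), [])


class TestRecording:
    def test_deterministic(self):
        cfg = EphysSimConfig(duration_s=0.5, seed=3)
        r1, t1 = simulate_recording(cfg)
        r2, t2 = simulate_recording(cfg)
        np.testing.assert_array_equal(r1.signal, r2.signal)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(t1.spike_indices, t2.spike_indices)
        )

    def test_variance_additivity(self):
        cfg = EphysSimConfig(
            duration_s=2.0, spike_rate_hz=0.0, noise_sd_uv=3.0,
            lfp_sd_uv=20.0, line_amp_uv=0.0, seed=4,
        )
        rec, _ = simulate_recording(cfg)
        expect = np.hypot(3.0, 20.0)
        assert rec.signal[0].std() == pytest.approx(expect, rel=0.05)

    def test_car_removes_common_artifact_exactly(self):
        base = dict(duration_s=1.0, spike_rate_hz=0.0, noise_sd_uv=3.0,
                    lfp_sd_uv=10.0, line_amp_uv=0.0, seed=5)
        with_art, _ = simulate_recording(
            EphysSimConfig(common_artifact_uv=500.0, **base)
        )
        without, _ = simulate_recording(EphysSimConfig(**base))
        resid = car_subtract(with_art).signal - car_subtract(without).signal
        assert np.abs(resid).max() / 500.0 < 1e-9

    def test_detected_count_near_planted(self):
        from eist.ephys import bandpass_spike, detect_snippets

        cfg = EphysSimConfig(duration_s=4.0, spike_rate_hz=20.0,
                             template_p2p_uv=100.0, noise_sd_uv=3.0, seed=6)
        rec, truth = simulate_recording(cfg)
        filt = bandpass_spike(rec)
        snips = detect_snippets(filt.signal[0], rec.fs_hz)
        planted = len(truth.spike_indices[0])
        assert abs(snips.n_snippets - planted) <= 0.15 * planted

    def test_excessive_rate_clamped_with_warning(self):
        cfg = EphysSimConfig(duration_s=0.2, spike_rate_hz=1e5, seed=7)
        with pytest.warns(UserWarning, match="clamping"):
            simulate_recording(cfg)

    def test_template_longer_than_window_rejected(self):
        tpl = np.zeros(200)  # 4.1 ms at 48828 Hz
        cfg = EphysSimConfig(duration_s=0.2, template=tpl, seed=8)
        with pytest.raises(ValueError, match="2.4 ms"):
            simulate_recording(cfg)


class TestIhc:
    TRACT = TractGeometry(center_um=(0.0, 0.0))

    def test_no_suppression_limit_flat(self):
        pts, _ = simulate_ihc_sample(
            self.TRACT, density_far=2000.0, suppression_radius_um=1e-9,
            seed=9, extent_um=1000.0,
        )
        d = np.hypot(pts[:, 0], pts[:, 1])
        n0 = np.sum(d < 100.0)
        expect = 2000.0 * np.pi * 0.1**2
        assert abs(n0 - expect) < 3 * np.sqrt(expect)

    def test_flat_intensity_when_no_peak(self):
        _, field = simulate_ihc_sample(self.TRACT, gfap_peak=0.0,
                                       gfap_noise_sd=1.0, seed=10)
        assert field.values.std() < 2.0  # only pixel noise remains

    def test_gfap_declines_with_distance(self):
        from eist.spatial import intensity_profile

        wins = 0
        for seed in range(10):
            _, field = simulate_ihc_sample(self.TRACT, seed=seed)
            prof = intensity_profile(field, self.TRACT, 10.0, 300.0)
            wins += prof["mean_intensity"].iloc[0] > prof["mean_intensity"].iloc[-1]
        assert wins >= 9

    def test_deterministic(self):
        p1, f1 = simulate_ihc_sample(self.TRACT, seed=11)
        p2, f2 = simulate_ihc_sample(self.TRACT, seed=11)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(f1.values, f2.values)


class TestCohort:
    @staticmethod
    def _panel():
        return [
            GeneSpec("Gapdh", 0.02, 1.0, role="housekeeping"),
            GeneSpec("mark", 0.005, 6.0, 150.0, "up_marker"),
            GeneSpec("bulk", 0.9),
        ]

    def test_noiseless_single_gene_recovery(self):
        spec = CohortTruthSpec(
            betas={"MUA": {"mark": 0.01}},
            noise_sd={m: 0.0 for m in ("MUA", "LFP", "SNR", "GFAP", "ND")},
        )
        samples, truth = simulate_cohort(
            6, 1, self._panel(), spec,
            cfg=SimulationConfig(grid_shape=(10, 10), seed=0), seed=12,
        )
        x = truth.x_planted.loc["mark"].to_numpy()
        y = truth.metrics["MUA"].to_numpy()
        res = single_gene_regression(x, y, "mark", "MUA")
        assert abs(res.r2 - 1.0) < 1e-9

    def test_null_r2_mean_matches_one_over_n_minus_one(self):
        spec = CohortTruthSpec(
            betas={}, noise_sd={"MUA": 1.0}, severity_sd=0.5
        )
        n = 8
        r2s = []
        for seed in range(150):
            _, truth = simulate_cohort(
                n, 0, self._panel(), spec,
                cfg=SimulationConfig(grid_shape=(6, 6), seed=0), seed=seed,
            )
            x = truth.x_planted.loc["mark"].to_numpy()
            y = truth.metrics["MUA"].to_numpy()
            r2s.append(single_gene_regression(x, y, "mark", "MUA").r2)
        assert abs(np.mean(r2s) - 1.0 / (n - 1)) < 0.05

    def test_measured_expression_tracks_planted_values(self):
        from eist.screen import electrode_site_expression

        spec = CohortTruthSpec(betas={"MUA": {"mark": 0.01}})
        samples, truth = simulate_cohort(
            4, 1, self._panel(), spec,
            cfg=SimulationConfig(grid_shape=(14, 14), depth_cv=0.2, seed=0),
            seed=13,
        )
        implanted = [s for s in samples if s.implanted]
        expr = electrode_site_expression(implanted, ["mark"])
        planted = truth.x_planted.loc["mark", expr.columns]
        rel = np.abs(expr.loc["mark"] / planted - 1.0)
        assert rel.max() < 0.15

    def test_naive_samples_have_no_metrics(self):
        spec = CohortTruthSpec(betas={})
        samples, _ = simulate_cohort(
            3, 2, self._panel(), spec,
            cfg=SimulationConfig(grid_shape=(6, 6), seed=0), seed=14,
        )
        assert [s.metrics is None for s in samples] == [False] * 3 + [True] * 2

    def test_deterministic(self):
        spec = CohortTruthSpec(betas={"MUA": {"mark": 0.01}})
        _, t1 = simulate_cohort(3, 1, self._panel(), spec,
                                cfg=SimulationConfig(grid_shape=(6, 6), seed=0),
                                seed=15)
        _, t2 = simulate_cohort(3, 1, self._panel(), spec,
                                cfg=SimulationConfig(grid_shape=(6, 6), seed=0),
                                seed=15)
        assert t1.metrics.equals(t2.metrics)
        assert t1.x_planted.equals(t2.x_planted)

    def test_guards(self):
        spec = CohortTruthSpec(betas={"MUA": {"nope": 1.0}})
        with pytest.raises(ValueError, match="unknown genes"):
            simulate_cohort(3, 1, self._panel(), spec, seed=0)
        with pytest.raises(ValueError, match="at least 3"):
            simulate_cohort(2, 1, self._panel(), CohortTruthSpec(betas={}),
                            seed=0)
        with pytest.raises(ValueError, match="unknown metric"):
            CohortTruthSpec(betas={"XYZ": {}})
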