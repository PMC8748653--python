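"""Synthetic-data generator tests: placement, rendering statistics,
determinism, and the nuclei fixture generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from phasorplex.classify import puncta_phasor
from phasorplex.codebook import Codebook, FluorophoreSpec, build_codebook
from phasorplex.detect import detect_puncta
from phasorplex.phasor import single_exponential_position, transform_stack
from phasorplex.simulate import (
    SimulationConfig,
    _axis_weights,
    default_panel,
    place_transcripts,
    render_photon_stack,
    simulate_experiment,
    simulate_nuclei,
)

REP = 78e6


def analytic_mean_photons(truth, config):
    """Poisson-mean oracle: per-axis Gaussian voxel masses summed directly."""
    nz, ny, nx = config.grid_shape
    dx, dy, dz = config.voxel_um
    s_xy, s_z = config.psf_sigma_um
    total = 0.0
    for row in truth.itertuples(index=False):
        _, wx = _axis_weights(row.x_um, s_xy, dx, nx)
        _, wy = _axis_weights(row.y_um, s_xy, dy, ny)
        _, wz = _axis_weights(row.z_um, s_z, dz, nz)
        total += (
            row.intensity
            * config.photons_per_unit_intensity
            * wx.sum() * wy.sum() * wz.sum()
        )
    nvox = nz * ny * nx
    return total + config.background_rate * nvox


class TestPlacement:
    def test_zero_counts_empty_truth(self, codebook10):
        cfg = SimulationConfig(codebook=codebook10, counts_per_target=0)
        truth = place_transcripts(cfg, np.random.default_rng(0))
        assert len(truth) == 0

    @pytest.mark.parametrize("per_target, expected", [(1, 66), (2000, 132_000)])
    def test_66_codeword_panel_counts(self, per_target, expected):
        cb = build_codebook(default_panel(12, n_channels=4), [f"g{i}" for i in range(66)])
        cfg = SimulationConfig(codebook=cb, counts_per_target=per_target)
        truth = place_transcripts(cfg, np.random.default_rng(1))
        assert len(truth) == expected

    def test_positions_inside_volume_and_intensity_floor(self, codebook10):
        cfg = SimulationConfig(codebook=codebook10, counts_per_target=50)
        truth = place_transcripts(cfg, np.random.default_rng(2))
        lx, ly, lz = cfg.volume_um
        assert truth["x_um"].between(0, lx).all()
        assert truth["z_um"].between(0, lz).all()
        assert (truth["intensity"] >= cfg.intensity_floor).all()

    def test_default_geometry_matches_printed_grid(self, codebook10):
        cfg = SimulationConfig(codebook=codebook10)
        assert cfg.grid_shape == (33, 1000, 1000)


class TestRendering:
    def test_empty_truth_no_background_is_zero(self, codebook10):
        cfg = SimulationConfig(
            codebook=codebook10, volume_um=(5, 5, 3), background_rate=0.0,
            counts_per_target=0, n_time_bins=16,
        )
        truth = place_transcripts(cfg, np.random.default_rng(0))
        stack = render_photon_stack(truth, cfg, np.random.default_rng(0))
        assert stack.counts.sum() == 0

    def test_single_dye_photons_stay_in_band(self, lifetime_pair_codebook):
        # singleton codeword: emission confined to the dye's channel
        dyes = default_panel(4)
        cb = Codebook(
            [*dyes], {"solo": (dyes[2].name,)}, n_channels=4
        )
        cfg = SimulationConfig(
            codebook=cb, volume_um=(5, 5, 3), background_rate=0.0,
            counts_per_target=1, n_time_bins=16, seed=4,
        )
        stack, truth = simulate_experiment(cfg)
        per_channel = stack.counts.sum(axis=(0, 1, 2, 4))
        # channel edges sit 2.5 emission sigmas from the center: ~1% of the
        # photons legitimately land in the two adjacent channels
        assert per_channel[2] >= 0.97 * per_channel.sum()
        assert per_channel[1:4].sum() == per_channel.sum()

    def test_total_photons_match_poisson_mean(self, codebook10):
        cfg = SimulationConfig(
            codebook=codebook10, volume_um=(8, 8, 3), counts_per_target=3,
            n_time_bins=32, seed=9,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = place_transcripts(cfg, rng)
        stack = render_photon_stack(truth, cfg, rng)
        mean = analytic_mean_photons(truth, cfg)
        assert abs(stack.counts.sum() - mean) < 3 * np.sqrt(mean)

    def test_photon_count_linearity(self, codebook10):
        # doubling the per-punctum budget doubles the expected signal
        base = SimulationConfig(
            codebook=codebook10, volume_um=(8, 8, 3), counts_per_target=3,
            background_rate=0.0, n_time_bins=32, seed=9,
        )
        truth = place_transcripts(base, np.random.default_rng(0))
        m1 = analytic_mean_photons(truth, base)
        doubled = SimulationConfig(
            codebook=codebook10, volume_um=(8, 8, 3), counts_per_target=3,
            background_rate=0.0, n_time_bins=32, seed=9,
            photons_per_unit_intensity=2 * base.photons_per_unit_intensity,
        )
        assert analytic_mean_photons(truth, doubled) == pytest.approx(2 * m1)
        s1 = render_photon_stack(truth, base, np.random.default_rng(1)).counts.sum()
        s2 = render_photon_stack(truth, doubled, np.random.default_rng(1)).counts.sum()
        assert abs(s2 - 2 * s1) < 3 * np.sqrt(2 * m1) + 3 * np.sqrt(m1)

    def test_determinism_and_seed_sensitivity(self, codebook10):
        cfg = SimulationConfig(
            codebook=codebook10, volume_um=(6, 6, 3), counts_per_target=2,
            n_time_bins=16, seed=21,
        )
        s1, t1 = simulate_experiment(cfg)
        s2, t2 = simulate_experiment(cfg)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        pd.testing.assert_frame_equal(t1, t2)
        cfg2 = SimulationConfig(
            codebook=codebook10, volume_um=(6, 6, 3), counts_per_target=2,
            n_time_bins=16, seed=22,
        )
        _, t3 = simulate_experiment(cfg2)
        assert not np.allclose(t1[["x_um", "y_um"]], t3[["x_um", "y_um"]])

    def test_pure_dye_punctum_phasor_recovery(self):
        # >=1e4 photons: recovered puncta phasor within 0.01 phasor units
        dyes = default_panel(2)
        cb = Codebook(dyes, {"solo": (dyes[0].name,)}, n_channels=2)
        cfg = SimulationConfig(
            codebook=cb, volume_um=(4, 4, 3), counts_per_target=0,
            photons_per_unit_intensity=1000.0, background_rate=0.0,
            n_time_bins=128, seed=3,
        )
        truth = pd.DataFrame(
            [(2.0, 2.0, 1.5, "solo", 1.0)],
            columns=["x_um", "y_um", "z_um", "target", "intensity"],
        )
        stack = render_photon_stack(truth, cfg, np.random.default_rng(3))
        assert stack.counts.sum() > 10_000
        field = transform_stack(stack, min_photons=10)
        records, _, _ = detect_puncta(
            stack.channel_marginal().astype(float), voxel_um=cfg.voxel_um
        )
        assert len(records) == 1
        phasor = puncta_phasor(records[0], field)
        ref = single_exponential_position(dyes[0].lifetime_tau, REP)
        assert np.hypot(phasor[2] - ref.g, phasor[3] - ref.s) < 0.01


class TestNuclei:
    def test_zero_cells_background_only(self):
        stack, centers = simulate_nuclei(
            0, (8, 32, 32), (0.25, 0.25, 0.5), np.random.default_rng(0)
        )
        assert len(centers) == 0
        assert stack.mean() < 3.0

    @pytest.mark.parametrize("n_cells", [2, 5])
    def test_threshold_recovers_components(self, n_cells):
        # connected-components oracle on a hard threshold
        stack, centers = simulate_nuclei(
            n_cells, (10, 48, 48), (0.25, 0.25, 0.5), np.random.default_rng(42),
            radius_um=(1.5, 1.0),
        )
        assert len(centers) == n_cells
        mask = stack > 20
        _, n_found = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n_found == n_cells

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError, match="non-overlapping"):
            simulate_nuclei(
                50, (4, 16, 16), (0.25, 0.25, 0.5), np.random.default_rng(0),
                radius_um=(2.0, 1.0), max_tries=60,
            )
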