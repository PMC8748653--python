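"""Mixture-model clustering, posterior assignment and decoding rules."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phasorplex.classify import (
    AUTOFLUORESCENCE,
    OVERLAPPING,
    UNDETERMINED,
    GmmModel,
    assign_pixels,
    classify_stack,
    component_fraction,
    decode_puncta,
    fit_gmm,
    puncta_phasor,
    signature_table,
    summarize_labels,
)
from phasorplex.codebook import Codebook, FluorophoreSpec
from phasorplex.detect import PunctaRecord
from phasorplex.phasor import PhasorField
from phasorplex.simulate import SimulationConfig, simulate_experiment

REP = 78e6


def make_model(means, covs=None, mapping=None, use_spectral=True):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, d = means.shape
    if covs is None:
        covs = np.repeat((np.eye(d) * 1e-4)[None], k, axis=0)
    if mapping is None:
        mapping = [f"c{i}" for i in range(k)]
    return GmmModel(means, covs, np.full(k, 1.0 / k), mapping, use_spectral)


def field_from_points(points):
    """Wrap (n, 4) phasor points as a 1-z-slice PhasorField."""
    pts = np.atleast_2d(points)
    n = len(pts)
    arr = pts.reshape(1, 1, n, 4)
    return PhasorField(
        spectral_g=arr[..., 0], spectral_s=arr[..., 1],
        lifetime_g=arr[..., 2], lifetime_s=arr[..., 3],
        intensity=np.full((1, 1, n), 100.0), valid=np.ones((1, 1, n), bool),
        voxel_um=(0.1, 0.1, 0.3), rep_frequency=REP,
    )


class TestFitGmm:
    def test_single_component_recovers_sample_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([0.3, 0.4], 0.02, size=(500, 2))
        m = fit_gmm(pts, 1, seed=0)
        np.testing.assert_allclose(m.means[0], pts.mean(axis=0), atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_gmm(np.zeros((15, 2)), 2)

    def test_signature_init_maps_components(self):
        rng = np.random.default_rng(1)
        sig = np.array([[0.2, 0.2], [0.6, 0.6]])
        pts = np.vstack(
            [rng.normal(s, 0.01, size=(300, 2)) for s in sig]
        )
        m = fit_gmm(pts, 3, seed=0, signatures=sig, signature_names=["a", "b"])
        assert sorted(m.mapping) == ["a", AUTOFLUORESCENCE, "b"]
        ia, ib = m.mapping.index("a"), m.mapping.index("b")
        np.testing.assert_allclose(m.means[ia], sig[0], atol=5e-3)
        np.testing.assert_allclose(m.means[ib], sig[1], atol=5e-3)


class TestAssignPixels:
    def test_point_at_mean_is_confident(self):
        model = make_model([[0.2, 0.2, 0.2, 0.2], [0.7, 0.7, 0.7, 0.7]])
        field = field_from_points([[0.2, 0.2, 0.2, 0.2]])
        labels, post = assign_pixels(model, field)
        assert labels[0, 0, 0] == 0
        assert post[0, 0, 0, 0] > 0.99

    def test_equidistant_point_splits_evenly(self):
        model = make_model([[0.2, 0.2, 0.2, 0.2], [0.4, 0.2, 0.2, 0.2]])
        field = field_from_points([[0.3, 0.2, 0.2, 0.2]])
        _, post = assign_pixels(model, field)
        np.testing.assert_allclose(post[0, 0, 0], [0.5, 0.5], atol=1e-9)

    def test_posterior_matches_bayes_rule_oracle(self):
        rng = np.random.default_rng(2)
        means = rng.uniform(0, 1, size=(3, 4))
        covs = np.repeat((np.eye(4) * 0.02)[None], 3, axis=0)
        w = np.array([0.5, 0.3, 0.2])
        model = GmmModel(means, covs, w, ["a", "b", "c"])
        pts = rng.uniform(0, 1, size=(100, 4))
        post = model.posterior(pts)
        dens = np.stack(
            [w[k] * multivariate_normal.pdf(pts, means[k], covs[k]) for k in range(3)],
            axis=1,
        )
        np.testing.assert_allclose(post, dens / dens.sum(1, keepdims=True), atol=1e-9)

    def test_invalid_voxels_skipped(self):
        model = make_model([[0.2] * 4])
        field = field_from_points([[0.2] * 4, [0.9] * 4])
        field.valid[0, 0, 1] = False
        labels, post = assign_pixels(model, field)
        assert labels[0, 0, 1] == -1
        assert post[0, 0, 1].sum() == 0.0

    def test_misassignment_within_bayes_error(self):
        # two equal, isotropic clusters: Bayes error = Phi(-d / 2 sigma)
        from scipy.stats import norm as norm1d

        rng = np.random.default_rng(3)
        d, sigma, n = 0.06, 0.02, 10_000
        means = np.array([[0.3, 0.3], [0.3 + d, 0.3]])
        covs = np.repeat((np.eye(2) * sigma**2)[None], 2, axis=0)
        model = GmmModel(means, covs, np.array([0.5, 0.5]), ["a", "b"])
        truth = rng.integers(2, size=n)
        pts = means[truth] + rng.normal(0, sigma, size=(n, 2))
        pred = model.posterior(pts).argmax(axis=1)
        bayes = norm1d.cdf(-d / (2 * sigma))
        assert (pred != truth).mean() <= bayes + 0.02


class TestPunctaPhasor:
    def _record(self, z=0, y=0, x=1):
        return PunctaRecord(0, (z, y, x), (0, 0, 0), 1, 1.0, 1.0, frozenset({0}))

    def test_uniform_phasors_pass_through(self):
        field = field_from_points([[0.3, 0.4, 0.5, 0.6]] * 5)
        assert puncta_phasor(self._record(x=2), field) == pytest.approx(
            [0.3, 0.4, 0.5, 0.6]
        )

    def test_equal_intensity_midpoint(self):
        field = field_from_points([[0.2, 0.2, 0.2, 0.2], [0.4, 0.4, 0.4, 0.4]])
        out = puncta_phasor(self._record(x=0), field)
        np.testing.assert_allclose(out, [0.3, 0.3, 0.3, 0.3], atol=1e-12)

    def test_intensity_weighting_matches_hand_computation(self):
        field = field_from_points(
            [[0.0, 0.0, 0.1, 0.1], [1.0, 1.0, 0.5, 0.5], [0.5, 0.5, 0.3, 0.3]]
        )
        field.intensity[0, 0] = [100.0, 300.0, 0.0]
        field.valid[0, 0, 2] = False
        out = puncta_phasor(self._record(x=1), field)
        np.testing.assert_allclose(out, [0.75, 0.75, 0.4, 0.4], atol=1e-12)

    def test_no_valid_voxels_returns_none(self):
        field = field_from_points([[0.2] * 4])
        field.valid[:] = False
        assert puncta_phasor(self._record(x=0), field) is None


class TestDecodePuncta:
    @pytest.fixture()
    def pair_codebook(self):
        dyes = [
            FluorophoreSpec("d0", 520, 8, 1.0, 0),
            FluorophoreSpec("d1", 560, 8, 2.0, 1),
            FluorophoreSpec("d2", 600, 8, 3.0, 2),
            FluorophoreSpec("d3", 640, 8, 4.0, 3),
        ]
        return Codebook(dyes, {"gA": ("d0", "d2"), "gB": ("d1", "d3")})

    def _punctum(self, channels, phasor):
        return PunctaRecord(
            0, (0, 0, 0), (0, 0, 0), 1, 1.0, 1.0, frozenset(channels),
            mean_phasor=np.asarray(phasor, dtype=float),
        )

    def _model_for(self, codebook):
        targets, sigs = signature_table(codebook, REP)
        means = np.vstack([sigs, sigs.mean(axis=0, keepdims=True)])
        return make_model(means, mapping=targets + [AUTOFLUORESCENCE])

    def test_matching_channels_and_phasor_decode(self, pair_codebook):
        model = self._model_for(pair_codebook)
        targets, sigs = signature_table(pair_codebook, REP)
        label, post = decode_puncta(
            self._punctum({0, 2}, sigs[targets.index("gA")]), model, pair_codebook
        )
        assert label == "gA" and post > 0.99

    def test_single_channel_rejected_without_singleton(self, pair_codebook):
        label, _ = decode_puncta(
            self._punctum({2}, [0.2] * 4), model := self._model_for(pair_codebook),
            pair_codebook,
        )
        assert label == UNDETERMINED

    def test_three_channels_is_overlapping(self, pair_codebook):
        label, _ = decode_puncta(
            self._punctum({0, 1, 3}, [0.2] * 4), self._model_for(pair_codebook),
            pair_codebook,
        )
        assert label == OVERLAPPING

    def test_singleton_codeword_enables_single_channel(self, lifetime_pair_codebook):
        cb = lifetime_pair_codebook
        targets, sigs = signature_table(cb, REP)
        # noise component placed off the codeword chord
        noise = np.array([[0.0, 0.0, 0.45, 0.25]])
        model = make_model(
            np.vstack([sigs, noise]),
            mapping=targets + [AUTOFLUORESCENCE],
        )
        label, post = decode_puncta(
            self._punctum({0}, sigs[targets.index("t_both")]), model, cb
        )
        assert label == "t_both" and post > 0.99

    def test_low_posterior_becomes_undetermined(self, pair_codebook):
        model = self._model_for(pair_codebook)
        targets, sigs = signature_table(pair_codebook, REP)
        mid = (sigs[0] + model.means[-1]) / 2  # ambiguous point
        label, post = decode_puncta(
            self._punctum({0, 2}, mid), model, pair_codebook, posterior_threshold=0.999
        )
        assert label == UNDETERMINED and post < 0.999


class TestComponentFraction:
    A, B = np.array([0.8, 0.4]), np.array([0.25, 0.44])

    def test_endpoints(self):
        assert component_fraction(self.A, self.A, self.B) == 1.0
        assert component_fraction(self.B, self.A, self.B) == 0.0

    def test_midpoint(self):
        assert component_fraction((self.A + self.B) / 2, self.A, self.B) == pytest.approx(0.5)

    def test_off_chord_projects_orthogonally(self):
        t = 0.3
        p = self.B + t * (self.A - self.B)
        chord = self.A - self.B
        perp = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)
        assert component_fraction(p + 0.05 * perp, self.A, self.B) == pytest.approx(t)

    def test_out_of_range_clamped(self):
        beyond = self.A + 2 * (self.A - self.B)
        assert component_fraction(beyond, self.A, self.B) == 1.0

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            component_fraction(self.A, self.A, self.A)


class TestClassifyStack:
    def test_summary_conserves_counts(self, small_sim_config, codebook10):
        stack, _ = simulate_experiment(small_sim_config)
        table, summary, _ = classify_stack(stack, codebook10, seed=0)
        assert (
            summary["assigned"] + summary[UNDETERMINED] + summary[OVERLAPPING]
            == summary["total"] == len(table)
        )

    def test_decoding_invariant_to_intensity_scaling(self, small_sim_config, codebook10):
        stack, _ = simulate_experiment(small_sim_config)
        t1, _, _ = classify_stack(stack, codebook10, seed=0)
        stack.counts = stack.counts * 3
        t3, _, _ = classify_stack(stack, codebook10, seed=0)
        merged = t1.merge(t3, on=["z", "y", "x"], suffixes=("_1", "_3"))
        assert len(merged) >= 0.95 * len(t1)
        agree = (merged["label_1"] == merged["label_3"]).mean()
        assert agree >= 0.95

    def test_negative_control_yields_no_targets(self, codebook10):
        cfg = SimulationConfig(
            codebook=codebook10, volume_um=(10, 10, 3), counts_per_target=0,
            autofluorescence_count=10, n_time_bins=32, seed=5,
        )
        stack, _ = simulate_experiment(cfg)
        table, summary, _ = classify_stack(stack, codebook10, seed=0)
        assert summary["assigned"] <= max(1, 0.05 * summary["total"])


class TestSummarize:
    def test_percentages_and_conservation(self):
        labels = ["gA"] * 5 + [UNDETERMINED] * 3 + [OVERLAPPING] * 2
        s = summarize_labels(labels)
        assert s["total"] == 10 and s["assigned"] == 5
        assert s["undetermined_pct"] == 30.0
        assert s["overlapping_pct"] == 20.0
        assert s["per_target"] == {"gA": 5}
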