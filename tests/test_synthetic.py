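from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wormassay import (
    ELEGANS_LIKE, INOPINATA_LIKE, EndpointModel, SpeciesParams,
    head_swinging_index, make_two_species_study, simulate_plate,
    simulate_track, summarize_track, chemotaxis_index,
)
from wormassay.errors import ParameterError

from oracles import multinomial_ci_expectation

BALLISTIC = SpeciesParams(name="ballistic", mean_speed=0.3, speed_cv=0.0,
                          speed_ar1=0.0, heading_diffusion=0.0,
                          head_offset=0.5, head_amp=0.0, head_freq=0.0,
                          pirouette_rate=0.0, gap_prob=0.0, noise_sd=0.0)


class TestSimulateTrack:
    def test_same_seed_is_bitwise_identical(self):
        a = simulate_track(ELEGANS_LIKE, 30, 0.1, seed=42)
        b = simulate_track(ELEGANS_LIKE, 30, 0.1, seed=42)
        np.testing.assert_array_equal(a.centroid, b.centroid)
        np.testing.assert_array_equal(a.head, b.head)
        np.testing.assert_array_equal(a.valid, b.valid)
        np.testing.assert_array_equal(a.meta["true_event_times"],
                                      b.meta["true_event_times"])

    def test_different_seed_differs(self):
        a = simulate_track(ELEGANS_LIKE, 30, 0.1, seed=1)
        b = simulate_track(ELEGANS_LIKE, 30, 0.1, seed=2)
        assert not np.array_equal(a.centroid, b.centroid)

    def test_ballistic_limit_is_straight_at_mean_speed(self):
        """All noise sources at zero collapse to a straight line
        traversed at exactly mean_speed."""
        tr = simulate_track(BALLISTIC, 10, 0.1, seed=0)
        steps = np.diff(tr.centroid, axis=0)
        speeds = np.linalg.norm(steps, axis=1) / 0.1
        np.testing.assert_allclose(speeds, 0.3, rtol=1e-12)
        # collinear: all step directions identical
        dirs = steps / np.linalg.norm(steps, axis=1, keepdims=True)
        np.testing.assert_allclose(dirs, np.broadcast_to(dirs[0], dirs.shape),
                                   atol=1e-12)

    def test_zero_amplitude_head_swinging_index_is_one(self):
        tr = simulate_track(BALLISTIC, 60, 0.1, seed=3)
        assert head_swinging_index(tr) == pytest.approx(1.0, abs=1e-6)

    def test_zero_rate_has_empty_ground_truth(self):
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=0.0),
                            60, 0.1, seed=5)
        assert len(tr.meta["true_event_times"]) == 0

    def test_events_respect_leadin_and_tail(self):
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=2.0,
                                    gap_prob=0.0), 300, 0.1, seed=9)
        t = tr.meta["true_event_times"]
        assert len(t) > 0
        assert t.min() >= 3.0
        assert t.max() <= 300 - ELEGANS_LIKE.pirouette_duration - 1.0
        # hard-core refractory: no overlapping injections
        assert np.all(np.diff(t) >= ELEGANS_LIKE.pirouette_duration + 4.0 - 1e-9)

    @pytest.mark.parametrize("duration,dt", [(0.05, 0.1), (10, 0.0),
                                             (10, -0.1)])
    def test_degenerate_timing_rejected(self, duration, dt):
        with pytest.raises(ParameterError):
            simulate_track(BALLISTIC, duration, dt, seed=0)

    def test_rate_too_high_for_refractory_rejected(self):
        with pytest.raises(ParameterError, match="refractory"):
            simulate_track(replace(ELEGANS_LIKE, pirouette_rate=30.0),
                           60, 0.1, seed=0)

    def test_gap_prob_produces_invalid_frames(self):
        tr = simulate_track(replace(BALLISTIC, gap_prob=0.3), 60, 0.1, seed=7)
        frac = 1.0 - tr.n_valid / len(tr)
        assert 0.2 < frac < 0.4


class TestSpeciesParams:
    @pytest.mark.parametrize("kwargs", [
        {"mean_speed": -1.0}, {"speed_ar1": 1.0},
        {"pirouette_speed_factor": 1.0}, {"gap_prob": -0.1},
        {"noise_sd": -0.01},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SpeciesParams(**kwargs)

    def test_presets_encode_the_species_contrasts(self):
        """inopinata-like: slower, bigger/faster head swings, almost no
        pirouettes."""
        assert INOPINATA_LIKE.mean_speed < ELEGANS_LIKE.mean_speed
        assert INOPINATA_LIKE.head_amp > ELEGANS_LIKE.head_amp
        assert INOPINATA_LIKE.head_freq > ELEGANS_LIKE.head_freq
        assert INOPINATA_LIKE.pirouette_rate < 0.1 < ELEGANS_LIKE.pirouette_rate


class TestSimulatePlate:
    def test_degenerate_multinomial(self):
        plate = simulate_plate(EndpointModel(0.0, 1.0, 0.0, n_worms=10),
                               seed=0)
        assert (plate.count_control, plate.count_odorant,
                plate.count_central) == (0, 10, 0)
        assert chemotaxis_index(plate).ci == 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    def test_counts_conserve_n_worms(self, seed):
        plate = simulate_plate(EndpointModel(0.2, 0.7, 0.1, n_worms=10),
                               seed=seed)
        assert (plate.count_control + plate.count_odorant
                + plate.count_central) == 10

    def test_symmetric_probabilities_give_mean_ci_near_zero(self):
        cis = [chemotaxis_index(simulate_plate(
            EndpointModel(0.5, 0.5, 0.0), seed=s)).ci for s in range(500)]
        assert abs(np.mean(cis)) < 0.05

    def test_mean_ci_matches_enumeration_oracle(self):
        """Monte-Carlo mean of per-plate CI converges to the conditional
        multinomial expectation computed by direct enumeration."""
        model = EndpointModel(0.2, 0.7, 0.1, n_worms=10)
        cis = np.array([chemotaxis_index(simulate_plate(model, seed=s)).ci
                        for s in range(1000)])
        expected = multinomial_ci_expectation((0.2, 0.7, 0.1), 10)
        se = cis.std(ddof=1) / np.sqrt(len(cis))
        assert abs(cis.mean() - expected) < 3 * se

    @pytest.mark.parametrize("probs", [(0.5, 0.6, -0.1), (0.3, 0.3, 0.3)])
    def test_invalid_probabilities_rejected(self, probs):
        with pytest.raises(ParameterError):
            EndpointModel(*probs)


class TestTwoSpeciesStudy:
    def test_balanced_labels(self):
        tracks = make_two_species_study(ELEGANS_LIKE, INOPINATA_LIKE, 3,
                                        duration=30, dt=0.1, seed=0)
        assert len(tracks) == 6
        groups = [t.meta["group"] for t in tracks]
        assert groups.count("elegans-like") == 3
        assert groups.count("inopinata-like") == 3

    def test_reproducible(self):
        a = make_two_species_study(ELEGANS_LIKE, INOPINATA_LIKE, 2, 30, 0.1, 5)
        b = make_two_species_study(ELEGANS_LIKE, INOPINATA_LIKE, 2, 30, 0.1, 5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.centroid, tb.centroid)

    def test_head_swinging_orders_with_generator_amplitude(self):
        """Group medians of the head-swinging index follow the presets'
        head_amp ordering."""
        tracks = make_two_species_study(ELEGANS_LIKE, INOPINATA_LIKE, 8,
                                        duration=120, dt=0.1, seed=11)
        med = {}
        for name in ("elegans-like", "inopinata-like"):
            vals = [summarize_track(t).head_swinging_index
                    for t in tracks if t.meta["group"] == name]
            med[name] = np.median(vals)
        assert med["inopinata-like"] > med["elegans-like"]
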