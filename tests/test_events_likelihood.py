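"""Event sequences, trajectories, and the staged-likelihood machinery."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from amypath.markers import MarkerPanel, MarkerSpec
from amypath.sustain.events import (Event, EventSequence, all_events,
                                    enumerate_sequences, random_sequence,
                                    valid_insert_positions)
from amypath.sustain.likelihood import (expected_trajectory, mixture_loglik,
                                        stage_likelihood, stage_loglik,
                                        subject_likelihood, subject_logliks,
                                        trajectory_matrix)


class TestEventSequence:
    def test_rejects_threshold_disorder(self, panel6):
        ev = all_events(panel6)
        good = EventSequence(ev, panel6)
        assert len(good) == 6
        bad = [Event(0, 1), Event(0, 0)] + ev[2:]
        with pytest.raises(ValueError, match="order"):
            EventSequence(bad, panel6)

    def test_rejects_non_permutations(self, panel6):
        ev = all_events(panel6)
        with pytest.raises(ValueError, match="permutation"):
            EventSequence(ev[:-1], panel6)
        with pytest.raises(ValueError, match="permutation"):
            EventSequence(ev[:-1] + [ev[0]], panel6)

    def test_enumeration_count(self, panel3, panel6):
        # N=3 single-threshold markers: all 3! orderings are valid
        assert len(enumerate_sequences(panel3)) == 6
        # 3 markers x 2 thresholds: 6!/(2!^3) orderings respect the constraint
        assert len(enumerate_sequences(panel6)) == math.factorial(6) // 8

    def test_random_sequences_are_valid_and_cover(self, panel6, rng):
        seen = set()
        for _ in range(200):
            s = random_sequence(panel6, rng)  # constructor validates
            seen.add(s)
        assert len(seen) > 30

    def test_insert_positions_respect_neighbours(self, panel6):
        ev = all_events(panel6)
        seq = EventSequence(ev, panel6)  # m1@1, m1@2, m2@1, m2@2, m3@1, m3@2
        rest = [e for e in seq.events if e != Event(0, 1)]
        slots = valid_insert_positions(rest, Event(0, 1))
        assert list(slots) == [1, 2, 3, 4, 5]  # after m1@1, anywhere later


class TestTrajectory:
    def test_anchor_points(self, panel6, rng):
        for _ in range(20):
            seq = random_sequence(panel6, rng)
            for m in range(len(panel6)):
                assert expected_trajectory(seq, panel6, m, 0) == 0.0
                assert expected_trajectory(seq, panel6, m, len(seq)) == panel6[m].z_max

    def test_hand_interpolation(self):
        # marker with events at positions 2, 5, 9 of an 18-event sequence:
        # between (5, z=2) and (9, z=3), stage 7 interpolates to 2.5
        panel = MarkerPanel(
            (MarkerSpec("a", "higher_is_worse"),) +
            tuple(MarkerSpec(n, "higher_is_worse") for n in "bcdef")
        )
        order = [(1, 0), (0, 0), (2, 0), (3, 0), (0, 1), (4, 0), (5, 0), (1, 1),
                 (0, 2), (2, 1), (3, 1), (4, 1), (5, 1), (1, 2), (2, 2), (3, 2),
                 (4, 2), (5, 2)]
        seq = EventSequence([Event(m, t) for m, t in order], panel)
        assert seq.positions(0) == (2, 5, 9)
        assert expected_trajectory(seq, panel, 0, 7) == pytest.approx(2.5)

    def test_monotone_in_stage(self, panel6, rng):
        for _ in range(10):
            seq = random_sequence(panel6, rng)
            traj = trajectory_matrix(seq, panel6)
            assert np.all(np.diff(traj, axis=1) >= -1e-12)


class TestStageLikelihood:
    def test_peak_density_at_matching_stage(self, panel3):
        seq = enumerate_sequences(panel3)[0]
        traj = trajectory_matrix(seq, panel3)
        for k in range(4):
            z = traj[:, k]
            lik = stage_likelihood(z, seq, k, panel3)
            assert lik == pytest.approx((2 * np.pi) ** (-1.5), rel=1e-9)
            others = [stage_likelihood(z, seq, j, panel3) for j in range(4)]
            assert max(others) == pytest.approx(lik)

    def test_matches_scalar_normal_products(self, panel6, rng):
        seq = random_sequence(panel6, rng)
        traj = trajectory_matrix(seq, panel6)
        z = rng.normal(0, 2, size=3)
        sd = np.array([1.0, 0.5, 2.0])
        for k in (0, 3, 6):
            direct = np.sum(stats.norm.logpdf(z, traj[:, k], sd))
            assert stage_loglik(z, seq, k, panel6, sd) == pytest.approx(direct, abs=1e-9)


class TestSubjectLikelihood:
    def test_single_event_space_is_mean_of_two_stages(self):
        panel = MarkerPanel((MarkerSpec("m", "higher_is_worse",
                                        z_thresholds=(1.0,), z_max=2.0),))
        seq = EventSequence([Event(0, 0)], panel)
        z = np.array([0.4])
        lik = subject_likelihood(z, seq, panel)
        # stage 0 sits at 0; stage N=1 sits at the terminal anchor z_max=2
        brute = 0.5 * (stats.norm.pdf(0.4, 0.0, 1.0) + stats.norm.pdf(0.4, 2.0, 1.0))
        assert lik == pytest.approx(brute, rel=1e-9)

    def test_matches_brute_force_stage_sum(self, panel6, rng):
        seq = random_sequence(panel6, rng)
        traj = trajectory_matrix(seq, panel6)
        for _ in range(5):
            z = rng.normal(1, 1.5, size=3)
            brute = np.mean([
                np.prod(stats.norm.pdf(z, traj[:, k], 1.0)) for k in range(7)
            ])
            assert subject_likelihood(z, seq, panel6) == pytest.approx(brute, rel=1e-9)

    def test_marker_relabelling_symmetry(self, panel3, rng):
        seq = enumerate_sequences(panel3)[2]
        z = rng.normal(0, 1, size=3)
        perm = [2, 0, 1]
        seq_p = EventSequence(
            [Event(perm.index(e.marker_index), 0) for e in seq.events], panel3
        )
        lik = subject_likelihood(z, seq, panel3)
        lik_p = subject_likelihood(z[perm], seq_p, panel3)
        assert lik == pytest.approx(lik_p, rel=1e-12)


class TestMixtureLoglik:
    def test_single_subtype_reduces_to_sum(self, panel6, rng):
        seq = random_sequence(panel6, rng)
        Z = rng.normal(0, 1, size=(15, 3))
        total = mixture_loglik(Z, [seq], [1.0], panel6)
        assert total == pytest.approx(float(subject_logliks(Z, seq, panel6).sum()))

    def test_duplicating_subjects_doubles_loglik(self, panel6, seq6_pair, rng):
        Z = rng.normal(0, 1, size=(10, 3))
        one = mixture_loglik(Z, seq6_pair, [0.6, 0.4], panel6)
        two = mixture_loglik(np.vstack([Z, Z]), seq6_pair, [0.6, 0.4], panel6)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_hand_summed_mixture(self, rng):
        panel = MarkerPanel(tuple(
            MarkerSpec(n, "higher_is_worse", z_thresholds=(1.0,), z_max=2.0)
            for n in ("a", "b")
        ))
        s1 = EventSequence([Event(0, 0), Event(1, 0)], panel)
        s2 = EventSequence([Event(1, 0), Event(0, 0)], panel)
        Z = rng.normal(0.5, 1, size=(4, 2))
        f = [0.3, 0.7]
        brute = sum(
            np.log(f[0] * subject_likelihood(z, s1, panel)
                   + f[1] * subject_likelihood(z, s2, panel))
            for z in Z
        )
        assert mixture_loglik(Z, [s1, s2], f, panel) == pytest.approx(brute, rel=1e-12)

    def test_invalid_fractions_rejected(self, panel6, seq6_pair, rng):
        Z = rng.normal(0, 1, size=(5, 3))
        with pytest.raises(ValueError):
            mixture_loglik(Z, seq6_pair, [0.5, 0.4], panel6)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.integers(0, 6))
def test_trajectory_anchors_property(seed, stage_offset):
    """Random valid sequences: trajectory starts at 0, ends at z_max, monotone."""
    panel = MarkerPanel(tuple(
        MarkerSpec(n, "higher_is_worse", z_thresholds=(1.0, 2.0), z_max=5.0)
        for n in ("m1", "m2", "m3")
    ))
    seq = random_sequence(panel, np.random.default_rng(seed))
    traj = trajectory_matrix(seq, panel)
    assert np.all(traj[:, 0] == 0.0)
    assert np.all(traj[:, -1] == 5.0)
    k = min(stage_offset, traj.shape[1] - 2)
    assert np.all(traj[:, k + 1] >= traj[:, k] - 1e-12)
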