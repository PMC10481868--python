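"""Euler decomposition against an independent matrix oracle; excursion laws."""
import numpy as np
import pytest

from gazeflow import (
    EulerSeries,
    HeadStream,
    InsufficientDataError,
    axis_excursion,
    euler_to_quat,
    quat_to_euler,
)


def quat_to_matrix(q):
    """Rotation matrix from a scalar-first unit quaternion (textbook formula)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_ypr(R):
    """Independent yaw(z)→pitch(y)→roll(x) decomposition of R = Rz·Ry·Rx."""
    pitch = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
    yaw = np.arctan2(R[1, 0], R[0, 0])
    roll = np.arctan2(R[2, 1], R[2, 2])
    return np.degrees([yaw, pitch, roll])


def stream_from_euler(yaw, pitch, roll, dt_ms=100.0):
    q = euler_to_quat(yaw, pitch, roll)
    return HeadStream(t_ms=np.arange(len(q)) * dt_ms, quat=q)


class TestQuatToEuler:
    def test_identity_sequence_is_all_zero(self):
        s = HeadStream(t_ms=np.arange(5.0), quat=np.tile([1.0, 0, 0, 0], (5, 1)))
        e = quat_to_euler(s)
        assert np.allclose(e.yaw_deg, 0) and np.allclose(e.pitch_deg, 0) and np.allclose(e.roll_deg, 0)

    def test_pure_yaw_rotation(self):
        s = stream_from_euler([0.0, 90.0], [0.0, 0.0], [0.0, 0.0])
        e = quat_to_euler(s)
        assert e.yaw_deg[1] == pytest.approx(90.0, abs=1e-9)
        assert abs(e.pitch_deg[1]) < 1e-9 and abs(e.roll_deg[1]) < 1e-9

    def test_composite_rotations_match_matrix_oracle(self, rng):
        """Random orientations decompose identically to a hand-rolled
        rotation-matrix decomposition."""
        q = rng.normal(size=(300, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        expected = np.array([matrix_to_ypr(quat_to_matrix(qi)) for qi in q])
        keep = np.abs(expected[:, 1]) < 85.0  # stay clear of the gimbal region
        q, expected = q[keep], expected[keep]
        for qi, exp in zip(q, expected):
            s = HeadStream(t_ms=np.array([0.0]), quat=qi[None, :])
            with np.errstate(all="ignore"):
                e = quat_to_euler(s)
            got = np.array([e.yaw_deg[0], e.pitch_deg[0], e.roll_deg[0]])
            # decomposition is 2-to-1 in q; compare wrapped angles
            diff = (got - exp + 180.0) % 360.0 - 180.0
            assert np.allclose(diff, 0.0, atol=1e-6)

    def test_unwrap_keeps_path_continuous_across_180(self):
        yaw = np.linspace(0.0, 350.0, 36)
        e = quat_to_euler(stream_from_euler(yaw, np.zeros(36), np.zeros(36)))
        assert np.allclose(np.diff(e.yaw_deg), 10.0, atol=1e-9)

    def test_gimbal_proximity_warns_but_returns(self):
        s = stream_from_euler([0.0, 10.0], [0.0, 89.5], [0.0, 0.0])
        with pytest.warns(RuntimeWarning, match="gimbal"):
            e = quat_to_euler(s)
        assert len(e.pitch_deg) == 2


class TestAxisExcursion:
    def test_static_head_is_zero(self):
        e = quat_to_euler(stream_from_euler(np.zeros(10), np.zeros(10), np.zeros(10)))
        m = axis_excursion(e, duration_ms=900.0, ref_duration_ms=900.0)
        assert m.roll_exc_deg == m.pitch_exc_deg == m.yaw_exc_deg == 0.0

    def test_monotone_yaw_ramp_has_path_equal_to_range(self):
        yaw = np.linspace(0.0, 30.0, 20)
        e = quat_to_euler(stream_from_euler(yaw, np.zeros(20), np.zeros(20)))
        m = axis_excursion(e, duration_ms=1900.0, ref_duration_ms=1900.0)
        assert m.yaw_exc_deg == pytest.approx(30.0, abs=1e-9)
        assert m.roll_exc_deg == pytest.approx(0.0, abs=1e-9)

    def test_there_and_back_counts_both_directions(self):
        roll = np.concatenate([np.linspace(0, 10, 10), np.linspace(10, 0, 10)[1:]])
        n = len(roll)
        e = quat_to_euler(stream_from_euler(np.zeros(n), np.zeros(n), roll))
        m = axis_excursion(e, duration_ms=1000.0, ref_duration_ms=1000.0)
        assert m.roll_exc_deg == pytest.approx(20.0, abs=1e-9)

    def test_duration_normalization_rescales(self):
        yaw = np.linspace(0.0, 30.0, 20)
        e = quat_to_euler(stream_from_euler(yaw, np.zeros(20), np.zeros(20)))
        m = axis_excursion(e, duration_ms=7200.0, ref_duration_ms=3600.0)
        assert m.yaw_exc_deg == pytest.approx(15.0, abs=1e-9)

    def test_range_mode_ignores_oscillation(self):
        roll = np.concatenate([np.linspace(0, 10, 10), np.linspace(10, 0, 10)[1:]])
        n = len(roll)
        e = quat_to_euler(stream_from_euler(np.zeros(n), np.zeros(n), roll))
        m = axis_excursion(e, 1000.0, 1000.0, mode="range")
        assert m.roll_exc_deg == pytest.approx(10.0, abs=1e-9)

    def test_single_sample_raises(self):
        e = EulerSeries(np.array([0.0]), np.zeros(1), np.zeros(1), np.zeros(1))
        with pytest.raises(InsufficientDataError):
            axis_excursion(e, 1000.0)


class TestExcursionProperties:
    def _random_series(self, rng, n=60):
        ang = np.cumsum(rng.normal(0, 2.0, size=(n, 3)), axis=0)
        ang[:, 1] = np.clip(ang[:, 1], -60, 60)  # keep pitch off the gimbal
        return ang

    def test_offset_invariance_about_first_axis(self, rng):
        """A constant pre-rotation about the vertical axis shifts yaw by a
        constant and leaves yaw excursion unchanged."""
        from scipy.spatial.transform import Rotation

        ang = self._random_series(rng)
        q = euler_to_quat(ang[:, 0], ang[:, 1], ang[:, 2])
        base = quat_to_euler(HeadStream(np.arange(len(q)) * 10.0, q))
        off = Rotation.from_euler("Z", 25.0, degrees=True)
        q_off = (off * Rotation.from_quat(q, scalar_first=True)).as_quat(scalar_first=True)
        shifted = quat_to_euler(HeadStream(np.arange(len(q)) * 10.0, q_off))
        m0 = axis_excursion(base, 1000.0, 1000.0)
        m1 = axis_excursion(shifted, 1000.0, 1000.0)
        assert m1.yaw_exc_deg == pytest.approx(m0.yaw_exc_deg, rel=1e-9)

    def test_additivity_over_concatenation(self, rng):
        ang = self._random_series(rng, n=40)
        t = np.arange(40) * 10.0

        def exc(a, tt):
            e = EulerSeries(tt, a[:, 2], a[:, 1], a[:, 0])
            return axis_excursion(e, tt[-1] - tt[0], tt[-1] - tt[0])

        whole = exc(ang, t)
        part1 = exc(ang[:20], t[:20])
        part2 = exc(ang[19:], t[19:])
        assert whole.yaw_exc_deg == pytest.approx(part1.yaw_exc_deg + part2.yaw_exc_deg, rel=1e-9)

    def test_refinement_never_decreases_excursion(self, rng):
        ang = self._random_series(rng, n=30)
        t = np.arange(30) * 10.0
        # insert perturbed midpoints between consecutive samples
        mid = 0.5 * (ang[:-1] + ang[1:]) + rng.normal(0, 0.5, size=(29, 3))
        fine = np.empty((59, 3))
        fine[0::2] = ang
        fine[1::2] = mid
        t_fine = np.empty(59)
        t_fine[0::2] = t
        t_fine[1::2] = 0.5 * (t[:-1] + t[1:])

        def exc(a, tt):
            e = EulerSeries(tt, a[:, 2], a[:, 1], a[:, 0])
            return axis_excursion(e, tt[-1] - tt[0], tt[-1] - tt[0])

        coarse, refined = exc(ang, t), exc(fine, t_fine)
        assert refined.roll_exc_deg >= coarse.roll_exc_deg - 1e-9
        assert refined.yaw_exc_deg >= coarse.yaw_exc_deg - 1e-9

    def test_euler_quaternion_roundtrip(self, rng):
        ang = self._random_series(rng)
        q = euler_to_quat(ang[:, 0], ang[:, 1], ang[:, 2])
        e = quat_to_euler(HeadStream(np.arange(len(q)) * 10.0, q))
        got = np.column_stack([e.yaw_deg, e.pitch_deg, e.roll_deg])
        diff = (got - ang + 180.0) % 360.0 - 180.0
        assert np.allclose(diff, 0.0, atol=1e-8)
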