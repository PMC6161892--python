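import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from residyn import (Trajectory, build_walking_model, default_anthropometric_table,
                     determinacy_counts, forward_kinematics,
                     segment_lengths_from_markers)
from residyn.model import (DEFAULT_MARKER_MAP, SEGMENT_NAMES, ConfigurationError,
                           MarkerSet)

LENGTHS = {"foot": 0.15, "shank": 0.42, "thigh": 0.40, "trunk": 0.52}


def test_build_model_masses_follow_table():
    m = build_walking_model(66.1, LENGTHS)
    table = default_anthropometric_table()
    total_fraction = 2 * sum(table[s]["mass_fraction"] for s in ("foot", "shank", "thigh")) \
        + table["trunk"]["mass_fraction"]
    assert np.isclose(m.masses.sum(), total_fraction * 66.1)
    assert m.masses.sum() <= m.subject_mass + 1e-9


def test_thigh_inertia_matches_hand_evaluation():
    # inertia = mass * (gyration_fraction * length)^2, evaluated by hand for
    # the shipped table with thigh length 0.4 m and subject mass 66.1 kg
    table = default_anthropometric_table()
    m = build_walking_model(66.1, LENGTHS, table)
    expected = (0.100 * 66.1) * (0.323 * 0.40) ** 2
    assert np.isclose(m.segment("thigh_r").inertia_com, expected, rtol=1e-12)


def test_missing_table_entry_names_segment():
    table = default_anthropometric_table()
    del table["shank"]
    with pytest.raises(ConfigurationError, match="shank"):
        build_walking_model(66.1, LENGTHS, table)


def test_com_fraction_zero_puts_com_at_proximal_joint(rng):
    table = default_anthropometric_table()
    table["thigh"]["com_fraction_proximal"] = 0.0
    m = build_walking_model(66.1, LENGTHS, table)
    Q = rng.normal(size=(5, 9))
    fr = forward_kinematics(m, Q)
    k = SEGMENT_NAMES.index("thigh_r")
    np.testing.assert_allclose(fr.Z[:, k], fr.P["hip"], atol=1e-14)


def _markers_from_positions(points, n):
    labels = tuple(DEFAULT_MARKER_MAP)
    S = np.stack([np.broadcast_to(points[lb], (n, 2)) for lb in labels], axis=1)
    return MarkerSet(labels, S.copy(), 0.01)


def test_segment_lengths_constant_and_alternating():
    m = build_walking_model(66.1, LENGTHS)
    fr = forward_kinematics(m, np.zeros((4, 9)) + [[0, 0, 0, 0, 0, 0, np.pi / 2, 0, 0]])
    clean = MarkerSet(m.marker_labels, fr.S, 0.01)
    lengths = segment_lengths_from_markers(clean)
    for seg in SEGMENT_NAMES:
        assert np.isclose(lengths[seg], m.segment(seg).length, atol=1e-12)
    # alternating distances average arithmetically
    S = clean.S.copy()
    j = clean.index("mtp_r")
    base = S[:, clean.index("ankle_r"), :]
    S[0::2, j] = base[0::2] + [0.40, 0.0]
    S[1::2, j] = base[1::2] + [0.42, 0.0]
    assert np.isclose(segment_lengths_from_markers(
        MarkerSet(clean.labels, S, 0.01))["foot_r"], 0.41)


def test_segment_length_under_noisy_rotation(rng):
    # rigidly rotating 0.5 m segment with 5 mm marker noise: the mean distance
    # estimator stays within 3 sigma/sqrt(N) of the truth (Monte Carlo)
    n, L, sig = 4000, 0.5, 0.005
    ang = rng.uniform(0, 2 * np.pi, n)
    a = rng.normal(scale=sig, size=(n, 2))
    b = np.stack([L * np.cos(ang), L * np.sin(ang)], -1) + rng.normal(scale=sig, size=(n, 2))
    d = np.linalg.norm(b - a, axis=1)
    assert abs(d.mean() - L) < 3 * (sig * np.sqrt(2)) / np.sqrt(n) + 2 * sig**2 / L


def test_missing_marker_raises_with_name():
    m = build_walking_model(66.1, LENGTHS)
    fr = forward_kinematics(m, np.zeros((4, 9)))
    bad = MarkerSet(tuple(lb for lb in m.marker_labels if lb != "knee_l"),
                    fr.S[:, :-1], 0.01)
    with pytest.raises(KeyError, match="knee_l"):
        segment_lengths_from_markers(bad)


def test_zero_angle_pose_lies_on_x_axis(model):
    Q = np.zeros((3, 9))
    fr = forward_kinematics(model, Q)
    L = {s.name: s.length for s in model.segments}
    np.testing.assert_allclose(fr.P["knee_r"][0], [L["thigh_r"], 0.0], atol=1e-14)
    np.testing.assert_allclose(fr.P["ankle_r"][0], [L["thigh_r"] + L["shank_r"], 0.0],
                               atol=1e-14)
    np.testing.assert_allclose(
        fr.P["mtp_r"][0], [L["thigh_r"] + L["shank_r"] + L["foot_r"], 0.0], atol=1e-14)
    assert np.allclose(fr.S[..., 1], 0.0)


def test_rotating_all_angles_by_pi_flips_through_hip(model, rng):
    Q = rng.normal(size=(6, 9))
    Q2 = Q.copy()
    Q2[:, :7] += np.pi
    f1, f2 = forward_kinematics(model, Q), forward_kinematics(model, Q2)
    hip = Q[:, None, 7:9]
    np.testing.assert_allclose(f2.S, 2 * hip - f1.S, atol=1e-12)


def test_random_pose_matches_per_point_trigonometry(model, rng):
    Q = rng.normal(size=(1, 9))
    fr = forward_kinematics(model, Q)
    q = Q[0]
    hip = q[7:9]
    L = model.lengths
    # independent evaluation of the right-MTP marker
    u = lambda a: np.array([np.cos(a), np.sin(a)])
    mtp = hip + L[2] * u(q[2]) + L[1] * u(q[1]) + L[0] * u(q[0])
    j = model.marker_labels.index("mtp_r")
    np.testing.assert_allclose(fr.S[0, j], mtp, atol=1e-13)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**32 - 1))
def test_rigidity_and_translation_equivariance(seed):
    model = build_walking_model(66.1, LENGTHS)
    rng = np.random.default_rng(seed)
    Q = rng.normal(size=(4, 9)) * [1, 1, 1, 1, 1, 1, 1, 3, 3]
    fr = forward_kinematics(model, Q)
    for prox, dist, seg in (("hip", "knee_r", "thigh_r"), ("knee_r", "ankle_r", "shank_r"),
                            ("ankle_r", "mtp_r", "foot_r"), ("hip", "shoulder", "trunk")):
        d = np.linalg.norm(fr.P[dist] - fr.P[prox], axis=1)
        np.testing.assert_allclose(d, model.segment(seg).length, rtol=1e-13)
    shift = rng.normal(size=2)
    Q2 = Q.copy()
    Q2[:, 7:9] += shift
    fr2 = forward_kinematics(model, Q2)
    np.testing.assert_allclose(fr2.S, fr.S + shift, atol=1e-12)
    np.testing.assert_allclose(fr2.Z, fr.Z + shift, atol=1e-12)


def test_walking_model_has_nine_dof(model):
    assert model.n_dof == 9
    assert len(model.segments) == 7


def test_determinacy_accounting():
    # three equations per segment per node vs (4n-3) unknowns per node:
    # balanced exactly at n = 3, underdetermined above, overdetermined below
    for N in (1, 50):
        eqs, unk = determinacy_counts(3, N)
        assert eqs == unk == 9 * N
    eqs, unk = determinacy_counts(9, 100)
    assert eqs == 2700 and unk == 3300 and unk > eqs
    eqs, unk = determinacy_counts(2, 10)
    assert eqs > unk


def test_trajectory_validation():
    with pytest.raises(ValueError):
        Trajectory(np.zeros((2, 9)), 0.01)
    with pytest.raises(ValueError):
        Trajectory(np.zeros((5, 9)), -1.0)
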