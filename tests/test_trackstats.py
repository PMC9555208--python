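import numpy as np
import pytest

from mothmpc.trackstats import (IncidenceTable, Track, box_dimension,
                                generate_track, incidence_chi_squared,
                                incidence_percentages, rank_sum_compare,
                                rms_kinematics, segment_spectra,
                                sliding_tortuosity)


def test_track_validation():
    with pytest.raises(ValueError, match="consecutive"):
        Track(frames=[0, 2, 3], x=[0, 1, 2], y=[0, 0, 0])
    with pytest.raises(ValueError, match="fps"):
        Track(frames=[0, 1], x=[0, 1], y=[0, 0], fps=0.0)


def test_track_csv_round_trip(tmp_path):
    t = generate_track("smooth-random", n_frames=60, seed=4)
    path = tmp_path / "track.csv"
    t.to_csv(path)
    t2 = Track.from_csv(path)
    assert np.allclose(t2.x, t.x) and np.allclose(t2.y, t.y)


def test_rms_kinematics_uniform_and_stationary():
    v = 0.8
    t = generate_track("straight", n_frames=100, speed=v)
    speed = np.hypot(v, 0.5 * v)
    rms_v, rms_a = rms_kinematics(t)
    assert rms_v == pytest.approx(speed, rel=1e-9)
    assert rms_a == pytest.approx(0.0, abs=1e-9)
    still = Track(frames=np.arange(10), x=np.zeros(10), y=np.zeros(10))
    assert rms_kinematics(still) == (0.0, 0.0)


def test_rms_kinematics_circular_motion():
    r, omega = 0.3, 4.0
    t = generate_track("circle", n_frames=400, radius=r, speed=r * omega)
    rms_v, rms_a = rms_kinematics(t)
    assert rms_v == pytest.approx(r * omega, rel=5e-3)
    assert rms_a == pytest.approx(r * omega**2, rel=5e-2)


def test_tortuosity_straight_line_is_one():
    t = generate_track("straight", n_frames=200)
    values, mean, n_excl = sliding_tortuosity(t)
    assert mean == pytest.approx(1.0)
    assert n_excl == 0
    assert np.nanmin(values) >= 1.0 - 1e-12


def test_tortuosity_l_shape_hand_value():
    # 3-point toy with a 2-step window: legs a=3, b=4
    t = Track(frames=[0, 1, 2], x=[0.0, 3.0, 3.0], y=[0.0, 0.0, 4.0])
    values, mean, _ = sliding_tortuosity(t, window=2)
    assert values[0] == pytest.approx(7.0 / 5.0)
    assert mean == pytest.approx(7.0 / 5.0)


def test_tortuosity_out_and_back_window_excluded():
    # out-and-back (zero net displacement) followed by a straight run
    x = np.array([0.0, 0.5, 1.0, 0.5, 0.0, 1.0, 2.0, 3.0, 4.0])
    t = Track(frames=np.arange(len(x)), x=x, y=np.zeros(len(x)))
    values, mean, n_excl = sliding_tortuosity(t, window=4)
    assert np.isnan(values[0])  # the out-and-back window
    assert n_excl >= 1
    assert np.isfinite(mean)


def test_tortuosity_all_degenerate_raises():
    x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    t = Track(frames=np.arange(5), x=x, y=np.zeros(5))
    with pytest.raises(ValueError, match="degenerate"):
        sliding_tortuosity(t, window=4)


def test_tortuosity_at_least_one_for_random_walks():
    for seed in range(5):
        t = generate_track("smooth-random", n_frames=120, seed=seed)
        values, mean, _ = sliding_tortuosity(t)
        assert np.nanmin(values) >= 1.0 - 1e-12
        assert mean >= 1.0


def test_box_dimension_line_and_plane_limits():
    line = generate_track("straight", n_frames=500)
    assert 0.9 <= box_dimension(line) <= 1.1
    # serpentine sweep filling the unit square: 512 rows, so the row
    # spacing (2 px on the 1024 grid) is below the smallest box size
    rows = 512
    r = np.arange(rows)
    x = np.empty(2 * rows)
    x[0::4], x[1::4] = 0.0, 1.0   # even rows sweep right
    x[2::4], x[3::4] = 1.0, 0.0   # odd rows sweep back
    y = np.repeat(r / (rows - 1), 2)
    serp = Track(frames=np.arange(2 * rows), x=x, y=y)
    assert 1.8 <= box_dimension(serp) <= 2.0


def test_box_dimension_scale_invariant():
    t = generate_track("smooth-random", n_frames=300, seed=9)
    d1 = box_dimension(t)
    t2 = Track(frames=t.frames, x=1000 * t.x, y=1000 * t.y, fps=t.fps)
    assert abs(box_dimension(t2) - d1) < 0.05


def test_segment_spectra_tone_and_dc():
    t = generate_track("sinusoid", n_frames=400, freq_hz=5.0, speed=0.0)
    freqs, power = segment_spectra(t, window=40)
    assert freqs[np.argmax(power[1:]) + 1] == pytest.approx(5.0)
    const = Track(frames=np.arange(100), x=np.full(100, 2.0),
                  y=np.full(100, -1.0))
    freqs, power = segment_spectra(const, window=40)
    assert power[0] == pytest.approx(5.0)  # 2^2 + 1^2
    assert np.allclose(power[1:], 0.0, atol=1e-20)


def test_segment_spectra_parseval():
    t = generate_track("smooth-random", n_frames=200, seed=2)
    window = 40
    freqs, power = segment_spectra(t, window=window)
    n_seg = len(t) // window
    ms = 0.0
    for comp in (t.x, t.y):
        segs = comp[:n_seg * window].reshape(n_seg, window)
        ms += np.mean(segs**2, axis=1).mean()
    assert np.sum(power) == pytest.approx(ms, abs=1e-9)


def test_incidence_chi_squared_matches_printed_flight_study():
    table = IncidenceTable(counts=[[7, 33], [18, 19]])
    chi2, df, p = incidence_chi_squared(table)
    assert round(chi2, 4) == 8.5053
    assert df == 1
    assert p == pytest.approx(0.003541, abs=5e-7)


def test_incidence_chi_squared_identical_rows_and_oracle():
    chi2, _, p = incidence_chi_squared(IncidenceTable([[10, 5], [10, 5]]))
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        c = rng.integers(1, 50, (2, 2))
        chi2, _, _ = incidence_chi_squared(IncidenceTable(c))
        tot = c.sum()
        exp = np.outer(c.sum(1), c.sum(0)) / tot
        assert chi2 == pytest.approx(((c - exp) ** 2 / exp).sum())


def test_incidence_percentages_printed_values():
    flight = IncidenceTable([[7, 33], [18, 19]])
    assert incidence_percentages(flight) == {
        "experimental": 17.5, "sham": 48.6}
    rolls = IncidenceTable([[45, 51], [23, 89]])
    assert incidence_percentages(rolls) == {
        "experimental": 46.9, "sham": 20.5}
    zero = IncidenceTable([[0, 12], [3, 4]])
    assert incidence_percentages(zero)["experimental"] == 0.0


def test_rank_sum_identical_groups():
    w, p = rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_rank_sum_fully_separated_exact():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [10.0, 11.0, 12.0, 13.0, 14.0]
    w, p = rank_sum_compare(a, b)
    assert w == pytest.approx(15.0)  # ranks 1..5
    assert p == pytest.approx(2.0 / 252.0)


def test_rank_sum_invariant_under_monotone_transform(rng):
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 1, 9)
    w1, p1 = rank_sum_compare(a, b)
    w2, p2 = rank_sum_compare(np.exp(a), np.exp(b))
    assert w1 == w2 and p1 == pytest.approx(p2)
    with pytest.raises(ValueError, match="tied"):
        rank_sum_compare([1.0, 1.0], [1.0, 1.0])


def test_generator_determinism_and_kinds():
    a = generate_track("smooth-random", n_frames=80, seed=5, noise_sd=0.01)
    b = generate_track("smooth-random", n_frames=80, seed=5, noise_sd=0.01)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
    with pytest.raises(ValueError, match="kind"):
        generate_track("spiral")
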