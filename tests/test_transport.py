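import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axodyne.imaging import Kymograph, build_kymograph
from axodyne.profiles import SimConfig
from axodyne.synthetic import simulate_transport_movie, straight_axon_trace
from axodyne.transport import (
    MotilityCriterion,
    Track,
    classify_motile,
    extract_tracks,
    segment_runs,
    summarize_transport,
)

from .conftest import make_transport_profile


def _track(positions, dt=1.0):
    positions = np.asarray(positions, dtype=float)
    return Track(0, np.arange(positions.size), positions, dt)


def _ridge_kymo(tracks_px, n_frames=60, n_bins=250, amp=200.0, bin_size=0.2):
    """Kymograph with one Gaussian ridge per position series (in bins)."""
    m = np.full((n_frames, n_bins), 5.0)
    cols = np.arange(n_bins)
    for series in tracks_px:
        for t in range(n_frames):
            m[t] += amp * np.exp(-0.5 * ((cols - series[t]) / 1.5) ** 2)
    return Kymograph(m, bin_size=bin_size, frame_interval=1.0)


# ---------------------------------------------------------------------------
# extraction


def test_blank_kymograph_yields_no_tracks():
    kymo = Kymograph(np.zeros((50, 100)), bin_size=0.2, frame_interval=1.0)
    assert extract_tracks(kymo) == []


def test_single_static_ridge_is_one_stationary_track():
    kymo = _ridge_kymo([np.full(60, 80.0)])
    tracks = extract_tracks(kymo)
    assert len(tracks) == 1
    assert np.ptp(tracks[0].positions_um) < 0.2  # under one bin


def test_five_separated_ridges_recovered_with_positions():
    # three static and two moving, all well separated
    n = 60
    series = [
        np.full(n, 30.0),
        np.full(n, 100.0),
        np.full(n, 220.0),
        60.0 + 2.0 * np.arange(n),  # 0.4 μm/s
        200.0 - 1.5 * np.arange(n),  # retrograde 0.3 μm/s
    ]
    kymo = _ridge_kymo(series, n_frames=n)
    tracks = extract_tracks(kymo)
    assert len(tracks) == 5
    recovered = sorted(t.positions_um[0] for t in tracks)
    expected = sorted(s[0] * 0.2 for s in series)
    np.testing.assert_allclose(recovered, expected, atol=0.4)
    for t in tracks:
        assert t.n_samples == n
    # RMS position error within one bin against the generating series
    for s in series:
        best = min(
            tracks, key=lambda t: abs(t.positions_um[0] - s[0] * 0.2)
        )
        rms = np.sqrt(np.mean((best.positions_um - s * 0.2) ** 2))
        assert rms < 0.2


def test_short_lived_detections_are_discarded():
    n = 60
    series = np.full(n, 50.0)
    kymo = _ridge_kymo([series], n_frames=n)
    kymo.matrix[20:25] += 0  # no extra ridge; add a 5-frame blip manually
    blip = np.zeros_like(kymo.matrix)
    for t in range(20, 25):
        blip[t] += 180 * np.exp(-0.5 * ((np.arange(250) - 150.0) / 1.5) ** 2)
    kymo = Kymograph(kymo.matrix + blip, bin_size=0.2, frame_interval=1.0)
    tracks = extract_tracks(kymo)
    assert len(tracks) == 1  # the 5-frame blip is below the minimum length


# ---------------------------------------------------------------------------
# run segmentation


def test_constant_velocity_track_is_single_anterograde_run():
    segs = segment_runs(_track(0.5 * np.arange(100)))
    assert len(segs) == 1
    assert segs[0].state == "anterograde"
    assert segs[0].speed_um_s == pytest.approx(0.5, abs=0.01)


def test_run_pause_reverse_track_gives_three_segments():
    t = np.arange(181)
    pos = np.where(t <= 60, 0.5 * t, 30.0)
    pos = np.where(t > 120, 30.0 - 0.5 * (t - 120), pos)
    segs = segment_runs(_track(pos))
    states = [s.state for s in segs]
    assert states == ["anterograde", "paused", "retrograde"]
    assert segs[0].displacement_um == pytest.approx(30.0, abs=0.6)
    assert segs[2].displacement_um == pytest.approx(-30.0, abs=0.6)
    assert segs[2].speed_um_s == pytest.approx(0.5, abs=0.02)


def test_jitter_only_track_is_one_pause():
    rng = np.random.default_rng(0)
    pos = 10.0 + np.clip(rng.normal(0, 0.03, 200), -0.09, 0.09)
    segs = segment_runs(_track(pos))
    assert len(segs) == 1
    assert segs[0].state == "paused"


def test_track_too_short_rejected():
    with pytest.raises(ValueError):
        segment_runs(_track([1.0]))


# ---------------------------------------------------------------------------
# motility criterion


def test_three_micron_run_is_motile():
    pos = np.concatenate([0.3 * np.arange(11), np.full(30, 3.0)])
    assert classify_motile(_track(pos))


def test_sub_threshold_travel_is_stationary():
    # 1.9 μm at 0.5 μm/s fails the 2-μm travel threshold
    pos = np.concatenate([np.linspace(0, 1.9, 5), np.full(40, 1.9)])
    assert not classify_motile(_track(pos))


def test_slow_drift_below_speed_threshold_is_stationary():
    # 2.5 μm net drift over 360 s is 0.007 μm/s: every frame below the
    # 0.1 μm/s speed cutoff, so it must not count as motility
    pos = np.linspace(0, 2.5, 360)
    assert not classify_motile(_track(pos))


def test_custom_criterion_thresholds_apply():
    pos = np.concatenate([0.3 * np.arange(11), np.full(30, 3.0)])
    assert not classify_motile(_track(pos), MotilityCriterion(min_travel_um=5.0))


# ---------------------------------------------------------------------------
# summaries


def test_all_stationary_summary_flags_undefined_fractions():
    tracks = [_track(np.full(50, x)) for x in (5.0, 10.0, 20.0)]
    s = summarize_transport(tracks)
    assert s.pct_motile == 0.0
    assert np.isnan(s.pct_time_paused) and np.isnan(s.mean_anterograde_speed)


def test_percent_motile_arithmetic():
    moving = [_track(0.5 * np.arange(60) + 10 * i) for i in range(4)]
    still = [_track(np.full(60, 40.0 + i)) for i in range(16)]
    s = summarize_transport(moving + still)
    assert s.pct_motile == pytest.approx(20.0)


def test_known_state_durations_give_expected_fractions():
    # 60 s anterograde, 60 s paused, 60 s retrograde: a third each, and all
    # of the travelled distance splits evenly between the two directions
    t = np.arange(181)
    pos = np.where(t <= 60, 0.5 * t, 30.0)
    pos = np.where(t > 120, 30.0 - 0.5 * (t - 120), pos)
    s = summarize_transport([_track(pos)])
    assert s.pct_time_anterograde == pytest.approx(100 / 3, abs=1.5)
    assert s.pct_time_retrograde == pytest.approx(100 / 3, abs=1.5)
    assert s.pct_time_paused == pytest.approx(100 / 3, abs=1.5)
    assert s.pct_distance_retrograde == pytest.approx(50.0, abs=0.5)
    assert s.pct_time_anterograde + s.pct_time_retrograde + s.pct_time_paused == pytest.approx(
        100.0, abs=0.01
    )


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        summarize_transport([])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    offset=st.floats(-50, 50),
    seed=st.integers(0, 10_000),
)
def test_speed_invariant_to_position_offset(offset, seed):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.choice([0.0, 0.5], size=80))
    segs_a = segment_runs(_track(pos))
    segs_b = segment_runs(_track(pos + offset))
    assert [s.state for s in segs_a] == [s.state for s in segs_b]
    np.testing.assert_allclose(
        [s.speed_um_s for s in segs_a], [s.speed_um_s for s in segs_b], atol=1e-9
    )


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_axis_reversal_swaps_directions(seed):
    rng = np.random.default_rng(seed)
    steps = rng.choice([-0.5, 0.0, 0.5], size=120, p=[0.3, 0.4, 0.3])
    pos = 60.0 + np.cumsum(steps)
    s_fwd = summarize_transport([_track(pos)]) if classify_motile(_track(pos)) else None
    s_rev = summarize_transport([_track(120.0 - pos)]) if classify_motile(_track(120.0 - pos)) else None
    if s_fwd is None or np.isnan(s_fwd.pct_time_paused):
        assert s_rev is None or np.isnan(s_rev.pct_time_paused)
        return
    assert s_fwd.pct_time_anterograde == pytest.approx(s_rev.pct_time_retrograde, abs=1e-6)
    assert s_fwd.pct_distance_retrograde == pytest.approx(
        s_rev.pct_distance_anterograde, abs=1e-6
    )


def test_per_mito_time_fractions_sum_to_100(wt):
    sim = SimConfig()
    rng = np.random.default_rng(2)
    stack, _ = simulate_transport_movie(wt.transport, sim, 6, rng)
    trace = straight_axon_trace(sim, 6.0, stack.frames.shape[2])
    tracks = extract_tracks(build_kymograph(stack, trace))
    s = summarize_transport(tracks)
    if s.n_motile:
        total = s.pct_time_anterograde + s.pct_time_retrograde + s.pct_time_paused
        assert total == pytest.approx(100.0, abs=0.01)


def test_end_to_end_recovery_of_motile_fraction(wt):
    # full chain on a medium simulation: the latent motile fraction must be
    # recovered within its binomial confidence interval
    from axodyne.pipeline import recover_transport

    s = recover_transport(wt, SimConfig(), n_mito_total=150, n_mito_per_movie=2, seed=10)
    p = wt.transport.motile_fraction
    ci = 3 * 100 * np.sqrt(p * (1 - p) / s.n_total)
    assert s.pct_motile == pytest.approx(100 * p, abs=ci + 2.0)
    assert s.mean_anterograde_speed == pytest.approx(
        wt.transport.anterograde_run_speed_mean, abs=0.06
    )
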