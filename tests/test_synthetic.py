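import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from axodyne.profiles import (
    AxonopathyProfile,
    ConditionProfile,
    MorphologyProfile,
    SimConfig,
    TimingProfile,
)
from axodyne.synthetic import (
    simulate_axon_profile,
    simulate_cohort,
    simulate_degeneration_series,
    simulate_morphology_image,
    simulate_transport_movie,
    simulate_wd_timecourse,
)

from .conftest import make_transport_profile

# ---------------------------------------------------------------------------
# transport movies


def test_all_stationary_profile_yields_no_motion(sim):
    profile = make_transport_profile(motile_fraction=0.0)
    _, truth = simulate_transport_movie(profile, sim, n_mito=12, rng=0)
    spans = truth.groupby("mito_id")["position_um"].agg(lambda p: p.max() - p.min())
    assert (spans < 2.0).all()


def test_movie_has_one_frame_per_second_for_six_minutes(wt):
    sim = SimConfig(frame_interval_s=1.0, movie_duration_s=360.0)
    stack, truth = simulate_transport_movie(wt.transport, sim, n_mito=3, rng=0)
    assert stack.n_frames == 360
    assert truth.frame.max() == 359
    assert len(truth) == 3 * 360


def test_single_constant_anterograde_run_travels_speed_times_time():
    # one mitochondrion locked into runs at 0.5 μm/s for a 60-s movie:
    # total path length equals 30 μm (constant-velocity kinematics)
    profile = make_transport_profile(
        motile_fraction=1.0,
        anterograde_run_speed_mean=0.5,
        anterograde_run_speed_sd=0.0,
        prob_next_run_retrograde=0.0,
        mean_run_duration=1e6,
        mean_pause_duration=1.0,
        target_time_fraction_paused=1e-6,
    )
    sim = SimConfig(movie_duration_s=60.0, segment_length_um=50.0)
    _, truth = simulate_transport_movie(profile, sim, n_mito=1, rng=3)
    path_length = truth.position_um.diff().abs().sum()
    assert path_length == pytest.approx(30.0, abs=0.5)


def test_movie_errors():
    with pytest.raises(ValueError):
        simulate_transport_movie(make_transport_profile(), SimConfig(), n_mito=0)


def test_identical_seed_reproduces_stack_and_truth_bitwise(wt, sim):
    s1, t1 = simulate_transport_movie(wt.transport, sim, 6, rng=42)
    s2, t2 = simulate_transport_movie(wt.transport, sim, 6, rng=42)
    np.testing.assert_array_equal(s1.frames, s2.frames)
    pd.testing.assert_frame_equal(t1, t2)


def test_ground_truth_conservation_noise_free(wt):
    # every rendered mitochondrion appears in the truth table, and with no
    # noise the image contains exactly the rendered spots
    sim = SimConfig(noise_sigma=0.0)
    stack, truth = simulate_transport_movie(wt.transport, sim, 7, rng=5)
    assert truth.mito_id.nunique() == 7
    assert (truth.groupby("mito_id").size() == sim.n_frames).all()
    assert stack.frames.max() > 50  # spots rendered well above background


def test_positions_stay_inside_segment(wt, sim):
    _, truth = simulate_transport_movie(wt.transport, sim, 10, rng=9)
    assert truth.position_um.between(0, sim.segment_length_um).all()


def test_paused_time_fraction_converges_to_profile_target(wt):
    sim = SimConfig(noise_sigma=0.0)
    rng = np.random.default_rng(17)
    fracs = []
    for _ in range(60):
        _, truth = simulate_transport_movie(wt.transport, sim, 4, rng=rng)
        motile = truth[truth.motile]
        for _, g in motile.groupby("mito_id"):
            fracs.append((g.state == "paused").mean())
    target = wt.transport.target_time_fraction_paused
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert np.mean(fracs) == pytest.approx(target, abs=4 * se + 0.01)


# ---------------------------------------------------------------------------
# morphology images


def _morph_profile(**over):
    base = dict(
        density_per_100um=22.6,
        aspect_ratio_mean=2.01,
        aspect_ratio_sd=0.8,
        mito_minor_axis_um=0.7,
        swollen_fraction=0.05,
    )
    base.update(over)
    return MorphologyProfile(**base)


def test_zero_density_gives_empty_shape_table(sim):
    _, truth = simulate_morphology_image(_morph_profile(density_per_100um=0.0), sim, 100.0, 1)
    assert truth.empty


def test_degenerate_ratio_distribution(sim):
    prof = _morph_profile(aspect_ratio_sd=0.0, aspect_ratio_mean=2.0, swollen_fraction=0.0)
    _, truth = simulate_morphology_image(prof, sim, 200.0, 2)
    assert len(truth) > 0
    np.testing.assert_allclose(truth.aspect_ratio, 2.0)


def test_sampled_ratio_mean_matches_profile(sim):
    rng = np.random.default_rng(4)
    ratios = []
    while len(ratios) < 600:
        _, truth = simulate_morphology_image(_morph_profile(), sim, 100.0, rng)
        ratios.extend(truth.aspect_ratio.tolist())
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert np.mean(ratios) == pytest.approx(2.01, abs=3 * se)


def test_morphology_rejects_negative_axon():
    with pytest.raises(ValueError):
        simulate_morphology_image(_morph_profile(), SimConfig(), -5.0, 1)


# ---------------------------------------------------------------------------
# axon profiles


def test_stage1_profile_is_smooth(quiet_sim):
    p = simulate_axon_profile(1, quiet_sim, 100.0, rng=1)
    assert p.std() / p.mean() < 0.3


def test_stage5_profile_is_mostly_background(quiet_sim):
    p = simulate_axon_profile(5, quiet_sim, 100.0, rng=1)
    background = np.median(p)
    assert (p > 2 * background).mean() < 0.1


def test_stage3_bead_density_exceeds_mild_boundary(quiet_sim):
    # independent peak count: local maxima rising at least 50 units above
    # the surrounding ridge, via a plain prominence-based peak finder
    for seed in range(5):
        p = simulate_axon_profile(3, quiet_sim, 100.0, rng=seed)
        peaks, _ = find_peaks(p, prominence=50)
        assert peaks.size > 10  # beads per 100 μm above the stage-2/3 boundary


def test_stage_out_of_range_rejected(quiet_sim):
    with pytest.raises(ValueError):
        simulate_axon_profile(0, quiet_sim, 100.0)
    with pytest.raises(ValueError):
        simulate_axon_profile(6, quiet_sim, 100.0)


# ---------------------------------------------------------------------------
# cohorts


def _condition(survival, new_rate, transition=None):
    p0 = (0.6, 0.3, 0.1, 0.0, 0.0)
    if transition is None:
        transition = tuple(tuple(r) for r in np.eye(5))
    return ConditionProfile(
        name="test",
        transport=make_transport_profile(),
        morphology=_morph_profile(),
        axonopathy=AxonopathyProfile(p0, transition, 0.5),
        timing=TimingProfile(129.1, 33.2, 58.2, 22.9, 4.0, 30.0),
        survival_2to3dpf=survival,
        new_expression_rate=new_rate,
    )


def test_full_survival_without_new_cells_is_exactly_100():
    table = simulate_cohort(_condition(1.0, 0.0), 50, 1)
    assert table.present_at_t2.sum() == table.present_at_t1.sum() == 50


def test_new_expression_pushes_survival_above_100():
    table = simulate_cohort(_condition(1.0, 0.03), 3000, 2)
    n_t1 = table.present_at_t1.sum()
    n_t2 = table.present_at_t2.sum()
    assert n_t2 > n_t1  # percentage survival exceeds 100


def test_identity_transition_keeps_stage_distribution(rng):
    table = simulate_cohort(_condition(1.0, 0.0), 4000, 3)
    d1 = table.stage_2dpf.value_counts().sort_index()
    d2 = table.stage_3dpf.value_counts().sort_index()
    assert (d1.values == d2.values).all()


def test_dead_cells_recorded_stage5():
    table = simulate_cohort(_condition(0.5, 0.0), 500, 4)
    dead = table[~table.soma_alive_3dpf]
    assert len(dead) > 0
    assert (dead.stage_3dpf == 5).all()


def test_stage_sequences_never_decrease():
    prof = _condition(
        1.0,
        0.0,
        transition=(
            (0.7, 0.2, 0.1, 0.0, 0.0),
            (0.0, 0.6, 0.3, 0.1, 0.0),
            (0.0, 0.0, 0.5, 0.3, 0.2),
            (0.0, 0.0, 0.0, 0.5, 0.5),
            (0.0, 0.0, 0.0, 0.0, 1.0),
        ),
    )
    table = simulate_cohort(prof, 2000, 5)
    resident = table[table.present_at_t1]
    assert (resident.stage_3dpf >= resident.stage_2dpf).all()


# ---------------------------------------------------------------------------
# WD time courses


def test_degenerate_lag_fragmentation_on_the_grid():
    prof = TimingProfile(120.0, 0.0, 60.0, 0.0, 4.0, 30.0)
    series, truth = simulate_wd_timecourse(prof, 1)
    first_frag = series.times[np.flatnonzero(series.n_fragments >= 2)[0]]
    assert first_frag == 120.0
    assert truth.lag_true_min == 120.0


def test_degenerate_clearance_reaches_zero_exactly():
    prof = TimingProfile(120.0, 0.0, 60.0, 0.0, 4.0, 30.0)
    series, _ = simulate_wd_timecourse(prof, 1)
    t_zero = series.times[np.flatnonzero(series.debris_fraction == 0)[0]]
    assert t_zero == 180.0  # 60 min after fragmentation at 120


def test_fragmentation_is_synchronous_single_interval_jump():
    series, _ = simulate_wd_timecourse(TimingProfile(129.1, 33.2, 58.2, 22.9, 4.0, 30.0), 7)
    n = series.n_fragments
    jumps = np.flatnonzero(np.diff(n) != 0)
    assert len(jumps) == 1  # 1 -> max within one sampling interval


def test_wd_replicates_recover_generator_mean_lag(wt):
    rng = np.random.default_rng(6)
    true_lags = [simulate_wd_timecourse(wt.timing, rng)[1].lag_true_min for _ in range(500)]
    se = np.std(true_lags, ddof=1) / np.sqrt(len(true_lags))
    assert np.mean(true_lags) == pytest.approx(wt.timing.lag_mean, abs=3 * se)


def test_degeneration_series_orders_swelling_before_death(asyn):
    times, stages, soma, truth = simulate_degeneration_series(asyn.timing, 8)
    assert stages[0] == 1 and not soma[-1]
    t2 = times[np.flatnonzero(stages >= 2)[0]]
    t4 = times[np.flatnonzero(stages >= 4)[0]]
    t_death = times[np.flatnonzero(~soma)[0]]
    assert t2 < t_death <= t4
    assert (np.diff(stages) >= 0).all()
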