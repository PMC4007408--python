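"""Synthetic microscopy and event-table generator.

Every downstream stage of the pipeline (kymograph tracking, morphometrics,
staging, WD kinetics, cohort statistics) can be exercised against data from
this module, with exact ground truth for recovery tests.  The generators
emulate, per experimental condition:

* time-lapse movies of labeled mitochondria moving along a 50-μm axon
  segment imaged at ~1 Hz for 6 minutes (``simulate_transport_movie``),
* single-frame images of mitochondria along an axon for density/shape
  measurements (``simulate_morphology_image``),
* 1D axon intensity profiles at each of the five axonopathy stages
  (``simulate_axon_profile``),
* per-cell 2→3 dpf cohort survival/stage tables (``simulate_cohort``),
* post-transection fragmentation/clearance time courses sampled every
  30 minutes (``simulate_wd_timecourse``).

Motility is a latent per-mitochondrion Bernoulli label; motile organelles
follow an alternating run/pause renewal process with exponential
(memoryless) dwell times, started from its stationary distribution so the
expected fraction of frames paused equals the profile target.  Run speeds are
drawn from a lower-truncated normal whose location is adjusted so that the
post-truncation mean equals the profile's target mean speed (truncation keeps
every run above the motility speed criterion).  Mitochondria reflect at the
segment ends, which keeps dwell and speed statistics intact inside the
imaged window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging import ImageStack
from .profiles import (
    AxonopathyProfile,
    ConditionProfile,
    MorphologyProfile,
    SimConfig,
    TimingProfile,
    TransportProfile,
)
from .timing import EventSeries

__all__ = [
    "simulate_transport_movie",
    "simulate_morphology_image",
    "simulate_axon_profile",
    "simulate_cohort",
    "simulate_wd_timecourse",
    "simulate_degeneration_series",
    "straight_axon_trace",
]

#: Sub-pixel positional jitter (μm) of stationary/paused mitochondria.
#: Kept below half a pixel (0.1 μm at the default 0.2 μm/px scale).
_JITTER_SD_UM = 0.03
_JITTER_MAX_UM = 0.09

#: Lower truncation of run speeds (μm/s); comfortably above the 0.1 μm/s
#: pause/motility speed threshold so every generated run is a real run.
_MIN_RUN_SPEED = 0.15


def _truncated_speed_dist(target_mean: float, sd: float, lower: float = _MIN_RUN_SPEED):
    """Normal truncated at ``lower`` with post-truncation mean == target_mean."""
    if sd == 0:
        return None  # degenerate: caller returns target_mean
    def mean_gap(loc: float) -> float:
        a = (lower - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - target_mean
    lo, hi = target_mean - 6 * sd, target_mean + sd
    loc = optimize.brentq(mean_gap, lo, hi)
    a = (lower - loc) / sd
    return stats.truncnorm(a, np.inf, loc=loc, scale=sd)


def straight_axon_trace(sim: SimConfig, y_px: float, n_px: int):
    """Horizontal proximal→distal trace through a synthetic movie frame."""
    from .imaging import AxonTrace

    return AxonTrace(
        np.array([[0.0, y_px], [n_px - 1.0, y_px]]), pixel_size=sim.pixel_size_um
    )


# ---------------------------------------------------------------------------
# transport movies


def _simulate_motile_path(
    profile: TransportProfile,
    sim: SimConfig,
    rng: np.random.Generator,
    x0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One motile mitochondrion: per-frame positions (μm) and state labels.

    States: 0 = paused, +1 = anterograde run, -1 = retrograde run.  The
    process starts in its stationary distribution (paused with the profile's
    target time fraction); reflection at the segment ends flips the run
    direction and relabels the state accordingly.
    """
    T = sim.movie_duration_s
    L = sim.segment_length_um
    ant = _truncated_speed_dist(profile.anterograde_run_speed_mean, profile.anterograde_run_speed_sd)
    ret = _truncated_speed_dist(profile.retrograde_run_speed_mean, profile.retrograde_run_speed_sd)

    # piecewise-linear path: breakpoints (t, x) and a state per interval
    bp_t = [0.0]
    bp_x = [float(rng.uniform(0.0, L)) if x0 is None else float(x0)]
    seg_state: list[int] = []
    t = 0.0
    paused = rng.random() < profile.target_time_fraction_paused
    while t < T:
        if paused:
            dwell = rng.exponential(profile.mean_pause_duration)
            t_end = min(t + dwell, T)
            bp_t.append(t_end)
            bp_x.append(bp_x[-1])
            seg_state.append(0)
            t = t_end
        else:
            retro = rng.random() < profile.prob_next_run_retrograde
            if retro:
                speed = profile.retrograde_run_speed_mean if ret is None else float(ret.rvs(random_state=rng))
            else:
                speed = profile.anterograde_run_speed_mean if ant is None else float(ant.rvs(random_state=rng))
            v = -speed if retro else speed
            dwell = rng.exponential(profile.mean_run_duration)
            remaining = min(dwell, T - t)
            while remaining > 1e-12:
                x = bp_x[-1]
                # time to the boundary in the current direction
                t_hit = ((L - x) / v) if v > 0 else (x / -v)
                step = min(remaining, t_hit)
                bp_t.append(t + step)
                bp_x.append(x + v * step)
                seg_state.append(1 if v > 0 else -1)
                t += step
                remaining -= step
                if step == t_hit and remaining > 1e-12:
                    v = -v  # reflect off the segment end
        paused = not paused
    bp_t_arr = np.asarray(bp_t)
    bp_x_arr = np.asarray(bp_x)
    frame_times = np.arange(sim.n_frames) * sim.frame_interval_s
    pos = np.interp(frame_times, bp_t_arr, bp_x_arr)
    idx = np.clip(np.searchsorted(bp_t_arr, frame_times, side="right") - 1, 0, len(seg_state) - 1)
    states = np.asarray(seg_state, dtype=int)[idx]
    return pos, states


def _render_movie(
    positions_um: np.ndarray,  # (n_mito, n_frames)
    amplitudes: np.ndarray,
    sim: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render mitochondria as Gaussian spots on a straight horizontal axon."""
    n_mito, n_frames = positions_um.shape
    w = int(math.ceil(sim.segment_length_um / sim.pixel_size_um))
    h = 13
    y0 = h // 2
    sigma = sim.psf_sigma_um / sim.pixel_size_um
    half = int(math.ceil(4 * sigma))
    yy = np.arange(h)
    gy = np.exp(-0.5 * ((yy - y0) / sigma) ** 2)
    stack = np.full((n_frames, h, w), 6.0, dtype=float)
    xpix = positions_um / sim.pixel_size_um
    for t in range(n_frames):
        frame = stack[t]
        for i in range(n_mito):
            cx = xpix[i, t]
            lo = max(0, int(math.floor(cx)) - half)
            hi = min(w, int(math.floor(cx)) + half + 1)
            if hi <= lo:
                continue
            gx = np.exp(-0.5 * ((np.arange(lo, hi) - cx) / sigma) ** 2)
            frame[:, lo:hi] += amplitudes[i] * gy[:, None] * gx[None, :]
    if sim.noise_sigma > 0:
        stack += rng.normal(0.0, sim.noise_sigma, size=stack.shape)
    return np.clip(stack, 0, 255).astype(np.uint8)


def simulate_transport_movie(
    profile: TransportProfile,
    sim: SimConfig,
    n_mito: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate a mitochondrial transport movie along one axon segment.

    Returns the rendered image stack and a tidy ground-truth table with one
    row per mitochondrion per frame (``mito_id, frame, time_s, position_um,
    state, motile``).  States are ``anterograde``/``retrograde``/``paused``
    for motile mitochondria and ``stationary`` otherwise.
    """
    if n_mito < 1:
        raise ValueError("n_mito must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(sim.rng_seed if rng is None else int(rng))
    n_frames = sim.n_frames
    L = sim.segment_length_um
    positions = np.empty((n_mito, n_frames))
    state_names = np.empty((n_mito, n_frames), dtype=object)
    motile_flags = rng.random(n_mito) < profile.motile_fraction
    label = {0: "paused", 1: "anterograde", -1: "retrograde"}
    # initial positions with a hard-core exclusion: mitochondria are ~1-μm
    # discrete organelles and do not start superimposed
    starts: list[float] = []
    for _ in range(n_mito):
        for _ in range(200):
            c = float(rng.uniform(0.0, L))
            if all(abs(c - s) >= 1.2 for s in starts):
                break
        starts.append(c)
    for i in range(n_mito):
        if motile_flags[i]:
            pos, st = _simulate_motile_path(profile, sim, rng, x0=starts[i])
            jitter = np.clip(
                rng.normal(0.0, _JITTER_SD_UM, n_frames), -_JITTER_MAX_UM, _JITTER_MAX_UM
            )
            pos = pos + np.where(st == 0, jitter, 0.0)
            state_names[i] = [label[s] for s in st]
        else:
            jitter = np.clip(
                rng.normal(0.0, _JITTER_SD_UM, n_frames), -_JITTER_MAX_UM, _JITTER_MAX_UM
            )
            pos = starts[i] + jitter
            state_names[i] = "stationary"
        positions[i] = np.clip(pos, 0.0, L)
    # laser power set so even two coincident mitochondria stay below the
    # 8-bit ceiling (saturated flat-top blobs would corrupt peak detection)
    amplitudes = np.clip(rng.normal(110.0, 15.0, n_mito), 80.0, 140.0)
    stack = ImageStack(
        _render_movie(positions, amplitudes, sim, rng),
        frame_interval=sim.frame_interval_s,
        pixel_size=sim.pixel_size_um,
    )
    frames = np.tile(np.arange(n_frames), n_mito)
    truth = pd.DataFrame(
        {
            "mito_id": np.repeat(np.arange(n_mito), n_frames),
            "frame": frames,
            "time_s": frames * sim.frame_interval_s,
            "position_um": positions.ravel(),
            "state": state_names.ravel(),
            "motile": np.repeat(motile_flags, n_frames),
        }
    )
    return stack, truth


# ---------------------------------------------------------------------------
# morphology images


def _sample_aspect_ratios(
    profile: MorphologyProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Aspect ratios and swollen flags; overall mean equals the profile mean.

    Non-swollen ratios are 1 + LogNormal with the log-normal parameterized so
    that the mixture mean over swollen (ratio 1) and non-swollen organelles
    is exactly ``aspect_ratio_mean``.
    """
    f = profile.swollen_fraction
    target = profile.aspect_ratio_mean
    swollen = rng.random(n) < f
    if f >= 1.0 or target <= 1.0:
        return np.ones(n), swollen
    base_mean = (target - f) / (1.0 - f)  # mean of the non-swollen component
    m = base_mean - 1.0
    s = profile.aspect_ratio_sd
    if m <= 0:
        ratios = np.full(n, target)
        ratios[swollen] = 1.0
        return ratios, swollen
    if s == 0:
        ratios = np.full(n, base_mean)
    else:
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        ratios = 1.0 + rng.lognormal(mu, math.sqrt(sigma2), n)
    ratios[swollen] = 1.0
    return ratios, swollen


def simulate_morphology_image(
    profile: MorphologyProfile,
    sim: SimConfig,
    axon_length_um: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render mitochondria as ellipses along a straight axon.

    The number of organelles is Poisson(density × length / 100); centers are
    placed by dart throwing with a hard-core exclusion so discrete organelles
    do not touch (real axonal mitochondria are resolvable objects).  Returns
    the 2D image and a ground-truth table (centroid, length, width, ratio).
    """
    if axon_length_um <= 0:
        raise ValueError("axon_length_um must be > 0")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(sim.rng_seed if rng is None else int(rng))
    px = sim.pixel_size_um
    w = int(math.ceil(axon_length_um / px))
    h = max(25, int(math.ceil(5.0 / px)))
    y0_um = (h // 2) * px
    n_target = rng.poisson(profile.density_per_100um * axon_length_um / 100.0)
    ratios, swollen = _sample_aspect_ratios(profile, n_target, rng)
    widths = np.full(n_target, profile.mito_minor_axis_um)
    widths[swollen] *= 1.6
    lengths = ratios * widths
    # hard-core placement by gap allocation: organelles laid out in random
    # order with a minimum edge-to-edge gap, the leftover space distributed
    # as Dirichlet-random slack.  Unlike dart throwing with rejection, this
    # never discriminates against long organelles (which would length-bias
    # the shape statistics); if the axon is overfull, a uniformly random
    # subset is dropped instead.
    min_gap = 0.4
    order = list(rng.permutation(n_target))
    while order and np.sum(lengths[order]) + min_gap * (len(order) + 1) > axon_length_um:
        order.pop(int(rng.integers(len(order))))
    kept = order
    centers: list[float] = []
    if kept:
        slack = axon_length_um - float(np.sum(lengths[kept])) - min_gap * (len(kept) + 1)
        gaps = rng.dirichlet(np.ones(len(kept) + 1)) * slack
        edge = 0.0
        for k, i in enumerate(kept):
            edge += gaps[k] + min_gap
            centers.append(edge + lengths[i] / 2.0)
            edge += lengths[i]
    # render hard-edged ellipses on a 4× supersampled grid, then area-average
    # down to the pixel grid (correct partial-pixel coverage at the boundary)
    ss = 4
    sub = px / ss
    fine = np.zeros((h * ss, w * ss), dtype=float)
    yy = ((np.arange(h * ss) + 0.5) * sub)[:, None]
    xx = ((np.arange(w * ss) + 0.5) * sub)[None, :]
    rows = []
    for c, i in zip(centers, kept):
        a = lengths[i] / 2.0
        b = widths[i] / 2.0
        r2 = ((xx - c) / a) ** 2 + ((yy - y0_um - px / 2) / b) ** 2
        fine += (r2 <= 1.0).astype(float)
        rows.append(
            {
                "mito_id": len(rows),
                "centroid_x_um": c,
                "centroid_y_um": y0_um,
                "length_um": lengths[i],
                "width_um": widths[i],
                "aspect_ratio": ratios[i],
                "swollen": bool(swollen[i]),
            }
        )
    from scipy.ndimage import gaussian_filter

    image = 200.0 * fine.reshape(h, ss, w, ss).mean(axis=(1, 3))
    image = gaussian_filter(image, sigma=sim.psf_sigma_um / px)
    image += 5.0
    if sim.noise_sigma > 0:
        image += rng.normal(0.0, sim.noise_sigma, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=[
            "mito_id",
            "centroid_x_um",
            "centroid_y_um",
            "length_um",
            "width_um",
            "aspect_ratio",
            "swollen",
        ],
    )
    return image, truth


# ---------------------------------------------------------------------------
# axonopathy stage profiles


def _add_bumps(
    profile: np.ndarray,
    x_um: np.ndarray,
    centers: np.ndarray,
    amp: np.ndarray,
    sigma_um: float,
) -> None:
    for c, a in zip(centers, amp):
        profile += a * np.exp(-0.5 * ((x_um - c) / sigma_um) ** 2)


def _spaced_positions(
    rng: np.random.Generator, n: int, length: float, min_gap: float, margin: float
) -> np.ndarray:
    """n positions in [margin, length-margin] with pairwise spacing >= min_gap."""
    pos: list[float] = []
    for _ in range(n * 200):
        c = rng.uniform(margin, length - margin)
        if all(abs(c - p) >= min_gap for p in pos):
            pos.append(c)
            if len(pos) == n:
                break
    return np.asarray(pos)


def simulate_axon_profile(
    stage: int,
    sim: SimConfig,
    axon_length_um: float = 100.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate a 1D axon intensity profile exhibiting one axonopathy stage.

    Stage phenotypes: 1 — smooth continuous ridge; 2 — sparse beads on the
    ridge (below the mild-beading density boundary); 3 — dense beads plus at
    least one large varicosity; 4 — beading plus fragmentation gaps covering
    10–70% of the length; 5 — >90% of the length at background (complete
    degeneration, scattered debris only).
    """
    if stage not in (1, 2, 3, 4, 5):
        raise ValueError(f"stage must be in 1..5, got {stage}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(sim.rng_seed if rng is None else int(rng))
    px = sim.pixel_size_um
    n = int(math.ceil(axon_length_um / px))
    x_um = (np.arange(n) + 0.5) * px
    background = 8.0
    ridge = 100.0
    if stage == 5:
        profile = np.full(n, background)
        n_specks = max(1, int(round(axon_length_um / 35.0)))
        centers = _spaced_positions(rng, n_specks, axon_length_um, min_gap=8.0, margin=2.0)
        _add_bumps(profile, x_um, centers, np.full(len(centers), 80.0), sigma_um=0.4)
        return profile
    # smooth ridge with a gentle large-scale undulation (CV ~ 2%)
    phase = rng.uniform(0, 2 * math.pi)
    profile = ridge * (1.0 + 0.02 * np.sin(2 * math.pi * x_um / 40.0 + phase))
    if stage >= 2:
        bead_density = 5.0 if stage == 2 else (20.0 if stage == 3 else 14.0)
        n_beads = max(1, int(round(bead_density * axon_length_um / 100.0)))
        # sparse beads are kept well separated so adjacent beads never blur
        # into a varicosity-wide structure
        centers = _spaced_positions(
            rng, n_beads, axon_length_um, min_gap=6.0 if stage == 2 else 3.0, margin=1.0
        )
        amps = rng.uniform(120.0, 160.0, len(centers))
        _add_bumps(profile, x_um, centers, amps, sigma_um=0.5)
    if stage == 3:
        n_var = max(1, int(round(axon_length_um / 100.0)))
        centers = _spaced_positions(rng, n_var, axon_length_um, min_gap=20.0, margin=8.0)
        _add_bumps(profile, x_um, centers, np.full(len(centers), 160.0), sigma_um=2.5)
    if stage == 4:
        gap_fraction = rng.uniform(0.15, 0.5)
        n_gaps = rng.integers(2, 5)
        gap_len = gap_fraction * axon_length_um / n_gaps
        centers = _spaced_positions(
            rng, int(n_gaps), axon_length_um, min_gap=gap_len + 6.0, margin=gap_len / 2 + 1.0
        )
        for c in centers:
            mask = np.abs(x_um - c) <= gap_len / 2.0
            profile[mask] = background
    return profile


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    profile: ConditionProfile, n_cells: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Simulate one embryo cohort of cells followed from 2 to 3 dpf.

    Each initial cell survives with probability ``survival_2to3dpf``; dead
    cells are recorded at stage 5 with the soma dead.  Surviving cells evolve
    their axonopathy stage by the per-day transition matrix.  Additional
    cells newly express the reporter between the time points with probability
    ``new_expression_rate`` per initial cell (so 3-dpf counts can exceed
    2-dpf counts).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ax: AxonopathyProfile = profile.axonopathy
    p0 = ax.stage_probs
    P = ax.transition_matrix
    stages_t1 = rng.choice(5, size=n_cells, p=p0) + 1
    survives = rng.random(n_cells) < profile.survival_2to3dpf
    stages_t2 = np.empty(n_cells, dtype=int)
    for i, s in enumerate(stages_t1):
        if survives[i]:
            stages_t2[i] = rng.choice(5, p=P[s - 1]) + 1
        else:
            stages_t2[i] = 5
    rows = pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
            "condition": profile.name,
            "present_at_t1": True,
            "present_at_t2": survives,
            "newly_appeared": False,
            "stage_2dpf": stages_t1.astype(float),
            "stage_3dpf": stages_t2,
            "soma_alive_3dpf": survives,
        }
    )
    n_new = rng.binomial(n_cells, profile.new_expression_rate)
    if n_new:
        new_stages = rng.choice(5, size=n_new, p=p0) + 1
        new_rows = pd.DataFrame(
            {
                "cell_id": [f"new{i:04d}" for i in range(n_new)],
                "condition": profile.name,
                "present_at_t1": False,
                "present_at_t2": True,
                "newly_appeared": True,
                "stage_2dpf": np.nan,
                "stage_3dpf": new_stages,
                "soma_alive_3dpf": True,
            }
        )
        rows = pd.concat([rows, new_rows], ignore_index=True)
    return rows


# ---------------------------------------------------------------------------
# Wallerian degeneration time courses


@dataclass(frozen=True)
class WDTruth:
    """Generator draw log for one simulated WD time course."""

    lag_true_min: float
    clearance_true_min: float
    n_fragments_max: int


def simulate_wd_timecourse(
    profile: TimingProfile,
    seed: int | np.random.Generator,
    total_duration_min: float = 720.0,
) -> tuple[EventSeries, WDTruth]:
    """Simulate one post-transection time course sampled every Δ minutes.

    The true lag (transection → fragmentation) and clearance interval are
    drawn from normal distributions truncated at zero.  Fragmentation is
    synchronous: the fragment count jumps from 1 to its maximum within one
    inter-frame interval; debris then declines linearly to zero over the
    clearance interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profile.sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")

    def truncated(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        a = (0.0 - mean) / sd
        return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))

    lag = truncated(profile.lag_mean, profile.lag_sd)
    clearance = max(truncated(profile.clearance_mean, profile.clearance_sd), 1e-6)
    n_frag_max = int(rng.integers(4, 12))
    times = np.arange(0.0, total_duration_min + 1e-9, profile.sampling_interval)
    fragmented = times >= lag
    n_fragments = np.where(fragmented, n_frag_max, 1)
    debris = np.where(fragmented, np.clip(1.0 - (times - lag) / clearance, 0.0, 1.0), 1.0)
    series = EventSeries(
        times=times,
        debris_fraction=debris,
        n_fragments=n_fragments,
        soma_alive=np.ones_like(times, dtype=bool),
    )
    return series, WDTruth(lag, clearance, n_frag_max)


def simulate_degeneration_series(
    profile: TimingProfile,
    seed: int | np.random.Generator,
    sampling_min: float = 20.0,
    duration_h: float = 12.0,
    death_occurs: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Simulate a longitudinal stage/soma series for one uninjured aSyn-like cell.

    Axonopathy (stage ≥ 2 swelling) begins ``axonopathy_onset_lead_hours``
    before soma death (with ±30 min noise); overt fragmentation (stage ≥ 4)
    follows, not precedes, the death of the soma — the empirical ordering for
    uninjured degeneration in this system.  Returns (times_min, stages,
    soma_alive, truth_dict).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(0.0, duration_h * 60.0 + 1e-9, sampling_min)
    stages = np.ones(times.size, dtype=int)
    soma = np.ones(times.size, dtype=bool)
    if not death_occurs:
        return times, stages, soma, {"t_death": math.nan}
    lead = profile.axonopathy_onset_lead_hours * 60.0
    t_death = rng.uniform(lead + 60.0, duration_h * 60.0 - 90.0)
    t_onset2 = max(sampling_min, t_death - lead + rng.normal(0.0, 30.0))
    t_onset3 = (t_onset2 + t_death) / 2.0
    t_frag = t_death + abs(rng.normal(30.0, 15.0))
    stages[times >= t_onset2] = 2
    stages[times >= t_onset3] = 3
    stages[times >= t_frag] = 4
    stages[times >= t_frag + 60.0] = 5
    soma[times >= t_death] = False
    stages[~soma] = np.maximum(stages[~soma], stages[~soma])  # stages never decrease
    truth = {"t_death": t_death, "t_onset2": t_onset2, "t_frag": t_frag}
    return times, stages, soma, truth
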