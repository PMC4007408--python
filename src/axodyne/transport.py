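"""Mitochondrial track extraction and transport statistics from kymographs.

A mitochondrion appears on a kymograph as a ridge: vertical while stationary
or paused, sloped while running.  Tracks are extracted by per-row peak
detection followed by greedy nearest-neighbour linking; runs and pauses are
segmented from the smoothed instantaneous velocity; a mitochondrion counts as
motile only if at least one run carries it ≥ 2 μm at ≥ 0.1 μm/s (the standard
in-vivo motility criterion, both thresholds configurable).

Sign convention: position is arc length from the proximal (cell-body) end, so
positive slope/displacement is anterograde and negative is retrograde.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .imaging import Kymograph

__all__ = [
    "MotilityCriterion",
    "Track",
    "RunSegment",
    "TransportSummary",
    "extract_tracks",
    "segment_runs",
    "classify_motile",
    "summarize_transport",
    "tracks_to_frame",
    "runs_to_frame",
]


@dataclass(frozen=True)
class MotilityCriterion:
    """Motility thresholds: a single run of ≥ min_travel_um at ≥ min_speed_um_s.

    The travel threshold is applied per run (one excursion), not to the
    cumulative path, so accumulated jitter can never qualify as motility.
    The speed threshold doubles as the pause cutoff during run segmentation.
    """

    min_travel_um: float = 2.0
    min_speed_um_s: float = 0.1

    def __post_init__(self) -> None:
        if self.min_travel_um <= 0 or self.min_speed_um_s <= 0:
            raise ValueError("motility thresholds must be > 0")


@dataclass
class Track:
    """One kymograph ridge: sampled positions (μm) at consecutive frames."""

    mito_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    frame_interval: float  # s
    identity_uncertain: bool = False  # True if the ridge crossed another

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.size != self.positions_um.size:
            raise ValueError("frames and positions must have equal length")
        if self.frames.size >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.frames.size

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval


@dataclass(frozen=True)
class RunSegment:
    """A maximal run or pause within a track.

    ``displacement_um`` is signed (positive = anterograde); ``speed_um_s`` is
    the unsigned least-squares slope of position vs time over the segment.
    Sample indices are inclusive and refer to the parent track.
    """

    start_index: int
    end_index: int
    start_frame: int
    end_frame: int
    state: str  # "anterograde" | "retrograde" | "paused"
    displacement_um: float
    speed_um_s: float
    n_frames: int


# ---------------------------------------------------------------------------
# track extraction


class _ActiveTrack:
    __slots__ = ("tid", "frames", "pos", "gap", "n_real", "shared")

    def __init__(self, tid: int, frame: int, x: float) -> None:
        self.tid = tid
        self.frames = [frame]
        self.pos = [x]
        self.gap = 0
        self.n_real = 1  # exclusively matched detections
        self.shared = False

    def predict(self, frame: int) -> float:
        if len(self.pos) >= 2:
            v = (self.pos[-1] - self.pos[-2]) / (self.frames[-1] - self.frames[-2])
        else:
            v = 0.0
        return self.pos[-1] + v * (frame - self.frames[-1])


def _link_detections(
    detections: list[np.ndarray],
    max_jump_um: float,
    max_gap_frames: int,
    share_radius_um: float = 0.8,
    share_min_real: int = 10,
) -> list[_ActiveTrack]:
    """Greedy nearest-neighbour linking of per-frame detections.

    Candidate (track, detection) pairs are taken in order of increasing
    distance from the track's constant-velocity prediction, ties broken in
    favour of the longer-established track and then the lower track id; the
    jump limit scales with the number of frames since the track was last
    seen.  Two ridges closer than the detector's resolution merge into a
    single detection, so an established track (≥ ``share_min_real`` exclusive
    matches) left unmatched may share a detection already claimed within
    ``share_radius_um`` of its prediction instead of accruing a gap; such
    tracks are flagged as identity-uncertain.  Otherwise unmatched tracks
    tolerate ``max_gap_frames`` missed frames before closing; unmatched
    detections seed new tracks.
    """
    active: list[_ActiveTrack] = []
    closed: list[_ActiveTrack] = []
    next_id = 0
    for f, dets in enumerate(detections):
        assigned: set[int] = set()
        matched: set[int] = set()
        if active and dets.size:
            cand = []
            for ti, tr in enumerate(active):
                p = tr.predict(f)
                # sub-linear growth with gap length: a briefly occluded mover
                # re-appears near its prediction, whereas a linear allowance
                # would let flicker hop between neighbouring static ridges
                limit = max_jump_um * math.sqrt(tr.gap + 1)
                d = np.abs(dets - p)
                for di in np.flatnonzero(d <= limit):
                    # distance quantized to 0.3 μm so that an established
                    # track beats a freshly seeded one at a near-tie (spurious
                    # duplicate detections must not steal the ridge)
                    cand.append((int(d[di] / 0.3), -len(tr.pos), float(d[di]), tr.tid, ti, int(di)))
            for _, _, _, _, ti, di in sorted(cand):
                if ti in matched or di in assigned:
                    continue
                tr = active[ti]
                tr.frames.append(f)
                tr.pos.append(float(dets[di]))
                tr.gap = 0
                tr.n_real += 1
                matched.add(ti)
                assigned.add(di)
        survivors: list[_ActiveTrack] = []
        for ti, tr in enumerate(active):
            if ti in matched:
                survivors.append(tr)
                continue
            share_di = None
            if tr.n_real >= share_min_real and assigned:
                p = tr.predict(f)
                share_di = min(assigned, key=lambda di: abs(dets[di] - p))
                if abs(dets[share_di] - p) > share_radius_um:
                    share_di = None
            if share_di is not None:
                tr.frames.append(f)
                tr.pos.append(float(dets[share_di]))
                tr.gap = 0
                tr.shared = True
                survivors.append(tr)
            else:
                tr.gap += 1
                if tr.gap > max_gap_frames:
                    closed.append(tr)
                else:
                    survivors.append(tr)
        active = survivors
        preds = np.array([tr.predict(f) for tr in active]) if active else None
        for di in range(dets.size):
            if di in assigned:
                continue
            # a detection right next to an existing track is a subtraction
            # shadow or a splitting lobe, not a new mitochondrion
            if preds is not None and np.abs(preds - dets[di]).min() <= 1.0:
                continue
            active.append(_ActiveTrack(next_id, f, float(dets[di])))
            next_id += 1
    closed.extend(active)
    return closed


def _stitch_segments(
    parts: list[tuple[np.ndarray, np.ndarray, bool]],
    max_gap_frames: int = 60,
    max_overlap_frames: int = 360,
    overlap_tol_um: float = 1.2,
    max_jump_um: float = 1.5,
    long_gap_tol_um: float = 2.5,
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Merge track fragments that describe the same mitochondrion.

    Subtraction shadows near static ridges and detector dropouts (a mover
    pausing on top of a saturated static ridge leaves no residual) can split
    one mover into several overlapping or abutting fragments.  Pairs whose
    endpoints are contiguous in time and consistent in space are stitched,
    lowest-cost pair first, until no pair qualifies.  For short gaps the
    spatial limit follows the per-frame jump limit; across long occlusions
    (up to ``max_gap_frames`` frames) the mover is presumed paused, so the
    fragments must re-appear within ``long_gap_tol_um`` of where they
    vanished.  Overlapping fragments (subtraction shadows) must agree in
    position to ``overlap_tol_um`` over the overlap.
    """
    parts = [(f, p, s) for f, p, s in parts]
    while True:
        best = None
        for i, (fa, pa, _) in enumerate(parts):
            for j, (fb, pb, _) in enumerate(parts):
                if i == j or fb[0] < fa[0] or (fb[0] == fa[0] and j < i):
                    continue
                if fb[-1] <= fa[-1]:
                    continue  # B must extend beyond A
                d = int(fb[0] - fa[-1])
                if d > max_gap_frames or d < -max_overlap_frames:
                    continue
                if d >= 0:
                    va = (pa[-1] - pa[-2]) / (fa[-1] - fa[-2]) if fa.size >= 2 else 0.0
                    if d <= 4:
                        cost = abs(pb[0] - (pa[-1] + va * d))
                        limit = max_jump_um * (d + 1)
                    else:
                        cost = abs(pb[0] - pa[-1])
                        limit = long_gap_tol_um
                else:
                    sel = fa >= fb[0]
                    if not np.any(sel):
                        continue
                    cost = float(np.median(np.abs(pa[sel] - np.interp(fa[sel], fb, pb))))
                    limit = overlap_tol_um
                if cost <= limit and (best is None or cost < best[0]):
                    best = (cost, i, j)
        if best is None:
            return parts
        _, i, j = best
        fa, pa, sa = parts[i]
        fb, pb, sb = parts[j]
        keep = fb > fa[-1]
        frames = np.concatenate([fa, fb[keep]])
        pos = np.concatenate([pa, pb[keep]])
        merged = (frames, pos, True)
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]


def extract_tracks(
    kymo: Kymograph,
    max_jump_um: float = 1.5,
    max_gap_frames: int = 2,
    min_track_frames: int = 10,
    static_exclusion_um: float = 0.5,
) -> list[Track]:
    """Extract mitochondrial tracks from a kymograph.

    The kymograph is first decomposed into its static and moving components.
    The per-column temporal median captures the vertical ridges of stationary
    (and latent-motile but never-moving) mitochondria, which become
    full-length constant-position tracks directly.  Moving mitochondria are
    then detected in the static-subtracted residual — where crossing or
    pausing next to a stationary organelle no longer occludes them — as
    per-row local maxima above an Otsu-derived threshold, and linked by
    greedy nearest-neighbour assignment with constant-velocity prediction
    (jump limit ``max_jump_um`` per frame, gaps of up to ``max_gap_frames``
    frames bridged by linear interpolation).  Moving tracks that never leave
    a ``static_exclusion_um`` neighbourhood of a static ridge are artifacts
    of sub-pixel flicker and are dropped, as are tracks with fewer than
    ``min_track_frames`` samples.  Two movers crossing each other are not
    disambiguated (greedy linking may swap identities; summary statistics
    are identity-insensitive).
    """
    if kymo.n_frames < 2:
        raise ValueError("kymograph must have at least 2 rows")
    matrix = kymo.matrix.astype(float)
    if matrix.max() == matrix.min():
        return []
    thr = float(threshold_otsu(matrix))
    bin_size = kymo.bin_size
    n_frames = kymo.n_frames

    def _row_peaks(row: np.ndarray, height: float, distance: int) -> np.ndarray:
        # zero-pad so maxima sitting on the first/last bin are still peaks
        peaks, _ = find_peaks(np.pad(row, 1), height=height, distance=distance)
        return peaks - 1

    static_profile = np.median(matrix, axis=0)
    static_peaks = _row_peaks(static_profile, thr, 2)
    static_pos = (static_peaks + 0.5) * bin_size

    tracks: list[Track] = []
    all_frames = np.arange(n_frames)
    for x in static_pos:
        tracks.append(
            Track(
                mito_id=len(tracks),
                frames=all_frames,
                positions_um=np.full(n_frames, x),
                frame_interval=kymo.frame_interval,
            )
        )

    residual = np.clip(matrix - static_profile[None, :], 0.0, None)
    thr_mov = 0.5 * thr
    # one mitochondrion can shed two residual lobes while crossing a static
    # ridge; a 0.8-μm minimum peak separation keeps only the stronger lobe
    min_sep_bins = max(2, int(round(0.8 / bin_size)))
    detections = []
    for row in residual:
        peaks = _row_peaks(row, thr_mov, min_sep_bins)
        detections.append((peaks + 0.5) * bin_size)
    parts = [
        (np.asarray(tr.frames), np.asarray(tr.pos), tr.shared)
        for tr in _link_detections(detections, max_jump_um, max_gap_frames)
    ]
    for frames, pos, shared in _stitch_segments(parts, max_jump_um=max_jump_um):
        full = np.arange(frames[0], frames[-1] + 1)
        pos_full = np.interp(full, frames, pos)  # bridge gap frames
        if full.size < min_track_frames or frames.size < 8:
            continue  # too short, or mostly interpolation over sparse flicker
        if static_pos.size and (
            np.abs(pos_full[:, None] - static_pos[None, :]).min(axis=1) < static_exclusion_um
        ).all():
            continue  # flicker shadow of a static ridge
        tracks.append(
            Track(
                mito_id=len(tracks),
                frames=full,
                positions_um=pos_full,
                frame_interval=kymo.frame_interval,
                identity_uncertain=shared,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# run segmentation


def _smoothed_velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """Instantaneous velocity over a 3-frame window.

    For interior frames the velocity is the smaller-magnitude of the backward
    and forward one-step differences (one-sided at the track ends).  Unlike a
    moving-average/centred-difference estimate, this assigns a frame to a
    pause as soon as *either* adjacent interval is still, so run→pause
    transitions do not bleed run velocity into pause frames and bias the
    time-fraction and run-speed statistics.
    """
    n = positions.size
    step = np.diff(positions) / dt  # step[i] = motion in [i, i+1]
    v = np.empty(n)
    v[0] = step[0]
    v[-1] = step[-1]
    if n > 2:
        bw = step[:-1]
        fw = step[1:]
        v[1:-1] = np.where(np.abs(bw) <= np.abs(fw), bw, fw)
    return v


def _ls_speed(times: np.ndarray, positions: np.ndarray) -> float:
    """Unsigned least-squares slope of position vs time."""
    if times.size < 2:
        return 0.0
    t = times - times.mean()
    denom = float(t @ t)
    if denom == 0:
        return 0.0
    return abs(float(t @ (positions - positions.mean())) / denom)


#: A "run" must displace the organelle by more than one detection bin
#: (0.2 μm at the default scale); smaller excursions are quantization
#: flicker of a paused ridge and are relabeled as pause time.
MIN_RUN_DISPLACEMENT_UM = 0.3


def segment_runs(
    track: Track,
    criterion: MotilityCriterion = MotilityCriterion(),
    min_run_displacement_um: float = MIN_RUN_DISPLACEMENT_UM,
) -> list[RunSegment]:
    """Segment a track into anterograde runs, retrograde runs and pauses.

    Frames with smoothed |velocity| below the criterion speed threshold are
    paused; maximal constant-sign excursions between pauses form runs.
    Moving excursions displacing less than ``min_run_displacement_um`` are
    position-quantization flicker, not transport, and are folded back into
    the surrounding pause.  Run speed is the least-squares slope of (raw)
    position vs time over the run.
    """
    if track.n_samples < 2:
        raise ValueError("track must have at least 2 samples")
    dt = track.frame_interval
    v = _smoothed_velocity(track.positions_um, dt)
    labels = np.where(np.abs(v) < criterion.min_speed_um_s, 0, np.sign(v)).astype(int)

    def _bounds(lab: np.ndarray) -> list[tuple[int, int]]:
        out = []
        start = 0
        for i in range(1, lab.size + 1):
            if i < lab.size and lab[i] == lab[start]:
                continue
            out.append((start, i - 1))
            start = i
        return out

    # fold sub-quantization excursions back into pause
    for start, end in _bounds(labels):
        if labels[start] != 0 and abs(
            track.positions_um[end] - track.positions_um[start]
        ) < min_run_displacement_um:
            labels[start : end + 1] = 0

    segments: list[RunSegment] = []
    for start, end in _bounds(labels):
        state = {0: "paused", 1: "anterograde", -1: "retrograde"}[labels[start]]
        disp = float(track.positions_um[end] - track.positions_um[start])
        speed = _ls_speed(track.times_s[start : end + 1], track.positions_um[start : end + 1])
        segments.append(
            RunSegment(
                start_index=start,
                end_index=end,
                start_frame=int(track.frames[start]),
                end_frame=int(track.frames[end]),
                state=state,
                displacement_um=disp,
                speed_um_s=speed,
                n_frames=end - start + 1,
            )
        )
    return segments


def _state_durations(track: Track, segments: list[RunSegment]) -> dict[str, float]:
    """Continuous-time duration (s) spent in each state, with sub-frame
    boundaries.

    A transition between a run and a pause happens somewhere inside one frame
    interval; counting whole frames systematically overstates pause time
    (the run-adjacent frame is conservatively labeled paused).  The boundary
    instant is therefore refined to where the run's least-squares line
    crosses the pause's mean position, clamped to one frame on either side of
    the nominal boundary.
    """
    dt = track.frame_interval
    t = track.times_s
    x = track.positions_um
    n_seg = len(segments)
    boundaries = np.empty(n_seg + 1)
    boundaries[0] = t[0] - dt / 2
    boundaries[-1] = t[-1] + dt / 2
    for k in range(n_seg - 1):
        a, b = segments[k], segments[k + 1]
        nominal = (t[a.end_index] + t[b.start_index]) / 2
        refined = nominal
        pair = {a.state, b.state}
        if "paused" in pair and len(pair) == 2:
            run, pause = (a, b) if a.state != "paused" else (b, a)
            xp = float(np.mean(x[pause.start_index : pause.end_index + 1]))
            tr_ = t[run.start_index : run.end_index + 1]
            xr = x[run.start_index : run.end_index + 1]
            if tr_.size >= 2:
                v, c = np.polyfit(tr_, xr, 1)
                if v != 0:
                    refined = float(np.clip((xp - c) / v, nominal - dt, nominal + dt))
        boundaries[k + 1] = refined
    durations = {"anterograde": 0.0, "retrograde": 0.0, "paused": 0.0}
    for k, seg in enumerate(segments):
        durations[seg.state] += max(boundaries[k + 1] - boundaries[k], 0.0)
    return durations


def classify_motile(track: Track, criterion: MotilityCriterion = MotilityCriterion()) -> bool:
    """True iff one run carries the mitochondrion ≥ min_travel_um at ≥ min_speed."""
    for seg in segment_runs(track, criterion):
        if (
            seg.state != "paused"
            and abs(seg.displacement_um) >= criterion.min_travel_um
            and seg.speed_um_s >= criterion.min_speed_um_s
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class TransportSummary:
    """Axon-segment transport statistics.

    Time and distance fractions are computed per motile mitochondrion and then
    averaged across mitochondria (each organelle weighted equally); they are
    NaN when no mitochondrion is motile.  Mean run speeds average the
    least-squares slopes of uninterrupted runs, per mitochondrion first.
    """

    n_total: int
    n_motile: int
    pct_motile: float
    pct_time_anterograde: float
    pct_time_retrograde: float
    pct_time_paused: float
    pct_distance_anterograde: float
    pct_distance_retrograde: float
    mean_anterograde_speed: float
    mean_retrograde_speed: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_transport(
    tracks: list[Track], criterion: MotilityCriterion = MotilityCriterion()
) -> TransportSummary:
    """Summarize transport over all tracks of one or more axon segments."""
    if not tracks:
        raise ValueError("summarize_transport requires at least one track")
    n_total = len(tracks)
    time_fracs: list[tuple[float, float, float]] = []
    dist_retro: list[float] = []
    ant_speeds: list[float] = []
    ret_speeds: list[float] = []
    n_motile = 0
    for track in tracks:
        segs = segment_runs(track, criterion)
        motile = any(
            s.state != "paused"
            and abs(s.displacement_um) >= criterion.min_travel_um
            and s.speed_um_s >= criterion.min_speed_um_s
            for s in segs
        )
        if not motile:
            continue
        n_motile += 1
        durations = _state_durations(track, segs)
        total = sum(durations.values())
        time_fracs.append(
            (
                100.0 * durations["anterograde"] / total,
                100.0 * durations["retrograde"] / total,
                100.0 * durations["paused"] / total,
            )
        )
        run_disps = [(s.state, abs(s.displacement_um)) for s in segs if s.state != "paused"]
        total_dist = sum(d for _, d in run_disps)
        if total_dist > 0:
            dist_retro.append(
                100.0 * sum(d for st, d in run_disps if st == "retrograde") / total_dist
            )
        a = [s.speed_um_s for s in segs if s.state == "anterograde"]
        r = [s.speed_um_s for s in segs if s.state == "retrograde"]
        if a:
            ant_speeds.append(float(np.mean(a)))
        if r:
            ret_speeds.append(float(np.mean(r)))

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else math.nan

    if n_motile == 0:
        ta = tr = tp = pr = pa = sa = sr = math.nan
    else:
        fr = np.asarray(time_fracs)
        ta, tr, tp = (float(x) for x in fr.mean(axis=0))
        pr = _mean(dist_retro)
        pa = 100.0 - pr if not math.isnan(pr) else math.nan
        sa = _mean(ant_speeds)
        sr = _mean(ret_speeds)
    return TransportSummary(
        n_total=n_total,
        n_motile=n_motile,
        pct_motile=100.0 * n_motile / n_total,
        pct_time_anterograde=ta,
        pct_time_retrograde=tr,
        pct_time_paused=tp,
        pct_distance_anterograde=pa,
        pct_distance_retrograde=pr,
        mean_anterograde_speed=sa,
        mean_retrograde_speed=sr,
    )


# ---------------------------------------------------------------------------
# tidy exports


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "mito_id": t.mito_id,
                    "frame": t.frames,
                    "position_um": t.positions_um,
                    "identity_uncertain": t.identity_uncertain,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["mito_id", "frame", "position_um", "identity_uncertain"]
    )


def runs_to_frame(tracks: list[Track], criterion: MotilityCriterion = MotilityCriterion()) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for s in segment_runs(t, criterion):
            rows.append(
                {
                    "mito_id": t.mito_id,
                    "start_frame": s.start_frame,
                    "end_frame": s.end_frame,
                    "state": s.state,
                    "displacement_um": s.displacement_um,
                    "speed_um_s": s.speed_um_s,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mito_id", "start_frame", "end_frame", "state", "displacement_um", "speed_um_s"],
    )
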