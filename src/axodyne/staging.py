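"""Five-point axonopathy staging of axon intensity profiles.

Stages: 1 — smooth, continuous axon; 2 — mild beading; 3 — severe beading
and/or large varicosities; 4 — partial fragmentation (intensity gaps);
5 — complete degeneration or death of the cell body.  A dead soma always
scores stage 5 regardless of the axon profile.

The rubric is operationalized with explicit, configurable numeric thresholds
(:class:`StagingThresholds`).  All intensity comparisons are relative (beads
vs the local median, background as a fraction of the bright percentile), so
the assigned stage is invariant to multiplying the profile by a positive
constant.  When several rules fire, the highest stage wins: completeness of
loss is checked first, then gaps, then severe beading/varicosities, then any
beading, then smoothness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "StagingThresholds",
    "StageRecord",
    "StageDistribution",
    "stage_axon",
    "summarize_stages",
    "records_to_frame",
    "records_from_frame",
]


@dataclass(frozen=True)
class StagingThresholds:
    """Numeric boundaries of the staging rubric (all configurable)."""

    smoothness_cv_max: float = 0.3  # stage-1 ceiling on the profile CV
    bead_density_mild_max: float = 10.0  # beads/100 μm at the stage-2/3 boundary
    varicosity_width_min_um: float = 3.0  # half-prominence width that makes a bead a varicosity
    gap_fraction_partial: float = 0.1  # stage-4 floor on the below-background fraction
    loss_fraction_complete: float = 0.9  # stage-5 floor on the lost fraction
    background_fraction: float = 0.25  # background cutoff as a fraction of the 99th percentile
    bead_local_median_factor: float = 2.0  # a bead peak must reach this × the local median
    bead_median_window_um: float = 20.0  # must exceed the footprint of one varicosity
    varicosity_smooth_um: float = 1.0  # bead-suppressing smoothing before width measurement

    def __post_init__(self) -> None:
        if not 0 < self.gap_fraction_partial < self.loss_fraction_complete <= 1:
            raise ValueError("need 0 < gap_fraction_partial < loss_fraction_complete <= 1")


@dataclass(frozen=True)
class StageRecord:
    cell_id: str
    timepoint: float  # dpf
    stage: int
    soma_alive: bool

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4, 5):
            raise ValueError("stage must be in 1..5")
        if not self.soma_alive and self.stage != 5:
            raise ValueError("a dead soma must be recorded as stage 5")


def _find_beads(
    profile: np.ndarray, bin_size_um: float, thresholds: StagingThresholds
) -> np.ndarray:
    """Indices of bead peaks.

    A bead is a local maximum reaching at least ``bead_local_median_factor``
    times the local (rolling-median) intensity; the median window is wide
    enough that a varicosity does not raise its own baseline.
    """
    window = max(3, int(round(thresholds.bead_median_window_um / bin_size_um)) | 1)
    local_med = median_filter(profile, size=window, mode="nearest")
    floor = np.maximum(local_med, 1e-9)
    peaks, _ = find_peaks(profile, prominence=0.2 * float(np.percentile(profile, 99)))
    if peaks.size == 0:
        return peaks
    return peaks[profile[peaks] >= thresholds.bead_local_median_factor * floor[peaks]]


def _varicosity_widths(
    profile: np.ndarray, bin_size_um: float, thresholds: StagingThresholds
) -> np.ndarray:
    """Half-prominence widths (μm) of swellings in a bead-suppressed profile.

    Narrow beads are smoothed away first; otherwise a bead riding on top of a
    broad varicosity becomes the local maximum and its (narrow) width masks
    the swelling underneath.
    """
    smoothed = gaussian_filter1d(profile, thresholds.varicosity_smooth_um / bin_size_um)
    prom = 0.3 * float(np.median(smoothed))
    peaks, _ = find_peaks(smoothed, prominence=prom)
    if peaks.size == 0:
        return np.empty(0)
    return peak_widths(smoothed, peaks, rel_height=0.5)[0] * bin_size_um


def stage_axon(
    profile: np.ndarray,
    bin_size_um: float,
    thresholds: StagingThresholds = StagingThresholds(),
    soma_alive: bool = True,
) -> int:
    """Assign the 1–5 axonopathy stage to a 1D intensity profile.

    ``profile`` is intensity vs arc length at ``bin_size_um`` spacing; the
    axon must span at least 10 μm.  A dead soma forces stage 5.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be 1D")
    length_um = profile.size * bin_size_um
    if length_um < 10.0:
        raise ValueError("profile must span at least 10 μm")
    if not soma_alive:
        return 5
    if np.all(profile <= 0):
        warnings.warn("all-zero profile with a live soma; scoring stage 5", stacklevel=2)
        return 5
    background_level = thresholds.background_fraction * float(np.percentile(profile, 99))
    above = profile > background_level
    above_fraction = float(above.mean())
    if above_fraction < (1.0 - thresholds.loss_fraction_complete):
        return 5
    gap_fraction = 1.0 - above_fraction  # runs below background
    if gap_fraction >= thresholds.gap_fraction_partial:
        return 4
    peaks = _find_beads(profile, bin_size_um, thresholds)
    bead_density = 100.0 * peaks.size / length_um
    widths = _varicosity_widths(profile, bin_size_um, thresholds)
    if bead_density > thresholds.bead_density_mild_max or np.any(
        widths > thresholds.varicosity_width_min_um
    ):
        return 3
    if peaks.size > 0:
        return 2
    cv = float(profile.std() / profile.mean())
    if cv <= thresholds.smoothness_cv_max:
        return 1
    return 2  # irregular but unbroken: mild dystrophy


@dataclass(frozen=True)
class StageDistribution:
    """Counts, fractions, and mean ± s.e.m. of stages at one timepoint."""

    counts: tuple[int, int, int, int, int]
    n: int
    mean_stage: float
    sem_stage: float
    fractions_pct: tuple[float, float, float, float, float]

    def to_dict(self) -> dict:
        return {
            "counts": list(self.counts),
            "n": self.n,
            "mean_stage": self.mean_stage,
            "sem_stage": self.sem_stage,
            "fractions_pct": list(self.fractions_pct),
        }


def summarize_stages(records: list[StageRecord]) -> StageDistribution:
    """Stage distribution of a cohort at a single timepoint."""
    if not records:
        raise ValueError("need at least one record")
    timepoints = {r.timepoint for r in records}
    if len(timepoints) != 1:
        raise ValueError(f"records mix timepoints: {sorted(timepoints)}")
    stages = np.array([r.stage for r in records])
    counts = tuple(int(np.sum(stages == k)) for k in range(1, 6))
    n = stages.size
    mean = float(stages.mean())
    sem = float(stages.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    fractions = tuple(100.0 * c / n for c in counts)
    return StageDistribution(counts, n, mean, sem, fractions)


def records_to_frame(records: list[StageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "timepoint": r.timepoint,
                "stage": r.stage,
                "soma_alive": r.soma_alive,
            }
            for r in records
        ],
        columns=["cell_id", "timepoint", "stage", "soma_alive"],
    )


def records_from_frame(df: pd.DataFrame) -> list[StageRecord]:
    return [
        StageRecord(str(row.cell_id), float(row.timepoint), int(row.stage), bool(row.soma_alive))
        for row in df.itertuples()
    ]
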