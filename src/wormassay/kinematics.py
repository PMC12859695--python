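"""Per-animal locomotion measures.

Instantaneous speed is the frame-to-frame centroid displacement divided
by the actual inter-frame interval.  Per-animal speed is the median of
instantaneous speeds after excluding gap steps and immobile steps
(< 0.2 mm/s, i.e. 0.02 cm/s).  Animals whose median exceeds the
0.5 mm/s (500 um/s) tracker ceiling are flagged as outliers and removed
from statistics.  Track length is the summed Euclidean distance over
steps whose both endpoint frames are valid — gap steps are excised, not
bridged or interpolated, because interpolation would fabricate path
length and bias the head-swinging index (head track length / centroid
track length) downward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedIndexError
from .trackio import Track

logger = logging.getLogger("wormassay")

#: 0.02 cm/s immobility cutoff, in mm/s.
IMMOBILITY_THRESHOLD = 0.2
#: 500 um/s tracker ceiling, in mm/s.
OUTLIER_MAX_SPEED = 0.5


@dataclass
class SpeedSeries:
    """Per-step instantaneous speeds of one track.

    ``times`` are the step start times; ``step_valid`` marks steps whose
    both endpoint frames are valid.  Speeds at invalid steps are NaN.
    """

    times: np.ndarray
    speeds: np.ndarray
    step_valid: np.ndarray
    step_dt: np.ndarray

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass
class KinematicSummary:
    animal_id: str
    median_speed: float          # mm/s; NaN if the animal is immobile
    centroid_track_length: float  # mm
    head_track_length: float      # mm
    head_swinging_index: float    # dimensionless
    n_valid_steps: int
    excluded_as_outlier: bool
    immobile: bool = False


def instantaneous_speeds(track: Track) -> SpeedSeries:
    """Frame-to-frame centroid speed series (mm/s)."""
    if len(track) < 2 or track.n_valid < 2:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: need >= 2 valid frames"
        )
    dts = np.diff(track.times)
    disp = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    step_valid = track.valid[:-1] & track.valid[1:]
    speeds = np.where(step_valid, disp / dts, np.nan)
    return SpeedSeries(times=track.times[:-1], speeds=speeds,
                       step_valid=step_valid, step_dt=dts)


def median_speed(series: SpeedSeries,
                 immobility_threshold: float = IMMOBILITY_THRESHOLD) -> float:
    """Median instantaneous speed after excluding gap steps and steps
    slower than the immobility threshold.

    Returns NaN (the designated "immobile" result, distinct from 0) when
    no step survives the immobility filter.
    """
    if len(series) == 0:
        raise InsufficientDataError("empty speed series")
    keep = series.step_valid & (series.speeds >= immobility_threshold)
    if not keep.any():
        return float("nan")
    return float(np.median(series.speeds[keep]))


def track_length(track: Track, which: str = "centroid") -> float:
    """Summed Euclidean step distance (mm) over valid steps.

    Steps touching an invalid frame contribute nothing: the gap is
    excised, never bridged.
    """
    if which not in ("centroid", "head"):
        raise ValueError(f"which must be 'centroid' or 'head', got {which!r}")
    if track.n_valid < 2:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: need >= 2 valid frames"
        )
    pts = track.centroid if which == "centroid" else track.head
    step_valid = track.valid[:-1] & track.valid[1:]
    disp = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(disp[step_valid].sum())


def head_swinging_index(track: Track) -> float:
    """Head track length / centroid track length, computed with the same
    step-validity mask for numerator and denominator."""
    cl = track_length(track, "centroid")
    if cl == 0.0:
        raise UndefinedIndexError(
            f"track {track.animal_id!r}: centroid track length is zero; "
            "head-swinging index undefined"
        )
    return track_length(track, "head") / cl


def summarize_track(track: Track,
                    immobility_threshold: float = IMMOBILITY_THRESHOLD,
                    max_speed: float = OUTLIER_MAX_SPEED) -> KinematicSummary:
    """Full kinematic summary of one animal."""
    series = instantaneous_speeds(track)
    med = median_speed(series, immobility_threshold)
    cl = track_length(track, "centroid")
    hl = track_length(track, "head")
    try:
        hsi = head_swinging_index(track)
    except UndefinedIndexError:
        hsi = float("nan")
    immobile = math.isnan(med)
    return KinematicSummary(
        animal_id=track.animal_id,
        median_speed=med,
        centroid_track_length=cl,
        head_track_length=hl,
        head_swinging_index=hsi,
        n_valid_steps=int(series.step_valid.sum()),
        excluded_as_outlier=(not immobile) and med > max_speed,
        immobile=immobile,
    )


def apply_outlier_filter(summaries: list[KinematicSummary],
                         max_speed: float = OUTLIER_MAX_SPEED,
                         ) -> tuple[list[KinematicSummary], list[KinematicSummary]]:
    """Partition animals by the tracker-ceiling rule.

    Median speeds strictly greater than ``max_speed`` are excluded
    ("up to 500 um/s" is trackable, so exactly 0.5 mm/s is kept).
    Exclusions are logged with the animal id.
    """
    kept, excluded = [], []
    for s in summaries:
        if (not math.isnan(s.median_speed)) and s.median_speed > max_speed:
            s.excluded_as_outlier = True
            logger.info("animal %s excluded as outlier (median speed "
                        "%.4g mm/s > %.4g mm/s)", s.animal_id,
                        s.median_speed, max_speed)
            excluded.append(s)
        else:
            s.excluded_as_outlier = False
            kept.append(s)
    return kept, excluded
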