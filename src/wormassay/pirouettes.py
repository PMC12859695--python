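"""Pirouette (sharp reorientation) detection from centroid trajectories.

A pirouette fires when the cumulative turning angle of the centroid
heading exceeds 120 degrees within a 3-s window, accompanied by a
concurrent speed drop of >= 40% relative to the animal's 2-s pre-event
baseline.  "Cumulative" defaults to the |net signed sum| of wrapped
heading increments (config switch ``mode='absolute'`` sums magnitudes
instead): summing magnitudes would fire on vigorous head or body
oscillation without any actual reorientation.

Headings are computed on the centroid resampled to a coarser timebase
(default 0.5 s).  At typical plate-tracking frame rates, per-frame
displacements are comparable to positional jitter, so per-frame headings
are noise; displacement over ~0.5 s is dominated by true motion while
3-s-scale reorientations are fully preserved.  A minimum-displacement
floor additionally masks headings at near-zero speeds.  Detection uses
the centroid only — head oscillation never enters the turning signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .trackio import Track

logger = logging.getLogger("wormassay")

#: Detector defaults (degrees, seconds, fraction, mm).
ANGLE_THRESHOLD = 120.0
WINDOW = 3.0
DROP_THRESHOLD = 0.40
BASELINE = 2.0
MIN_STEP = 0.01
RESAMPLE_DT = 0.5
MERGE_GAP = 1.0


def wrap_degrees(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


@dataclass
class HeadingSeries:
    """Per-span centroid headings and wrapped turn increments.

    Spans are the (possibly resampled) steps of the trajectory;
    ``headings`` are NaN where a span touches an invalid frame or its
    displacement is below the minimum-displacement floor, and
    ``turn_increments[k]`` (= wrapped ``headings[k] - headings[k-1]``) is
    NaN where either heading is undefined.
    """

    times: np.ndarray        # span start times, s
    end_times: np.ndarray    # span end times, s
    speeds: np.ndarray       # chord speed per span, mm/s (NaN if invalid)
    valid: np.ndarray        # both span endpoints valid
    headings: np.ndarray     # degrees in (-180, 180], NaN if masked
    turn_increments: np.ndarray  # signed degrees, NaN if undefined

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PirouetteEvent:
    """One detected reorientation interval."""

    t_start: float
    t_end: float
    net_turn: float        # signed degrees over the winning sub-interval
    baseline_speed: float  # mm/s, mean over the 2 s before t_start
    event_speed: float     # mm/s, mean over [t_start, t_end]
    speed_drop: float      # 1 - event_speed / baseline_speed


@dataclass
class PirouetteSummary:
    animal_id: str
    n_events: int
    observed_minutes: float  # valid-time only
    rate: float              # events/min


def heading_series(track: Track, min_step: float = MIN_STEP,
                   resample_dt: float | None = None) -> HeadingSeries:
    """Centroid heading series, optionally on a decimated timebase.

    With ``resample_dt`` set, every k-th frame is kept where
    k = round(resample_dt / nominal_dt); headings are then defined over
    k-frame displacement spans.  A span is valid when both endpoint
    frames are valid; its heading is defined when it is valid and its
    displacement is at least ``min_step`` mm.
    """
    if track.n_valid < 3:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: need >= 3 valid frames"
        )
    if resample_dt is None:
        k = 1
    else:
        k = max(1, int(round(resample_dt / track.nominal_dt)))
    idx = np.arange(0, len(track), k)
    if len(idx) < 3:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: too short for resample_dt="
            f"{resample_dt}"
        )
    t = track.times[idx]
    pos = track.centroid[idx]
    valid_f = track.valid[idx]

    d = np.diff(pos, axis=0)
    span_dt = np.diff(t)
    span_valid = valid_f[:-1] & valid_f[1:]
    disp = np.linalg.norm(d, axis=1)
    speeds = np.where(span_valid, disp / span_dt, np.nan)

    defined = span_valid & (disp >= min_step)
    headings = np.where(defined, np.degrees(np.arctan2(d[:, 1], d[:, 0])),
                        np.nan)
    # atan2 returns -180 for due-west motion; map to +180 for (-180, 180]
    headings = np.where(headings == -180.0, 180.0, headings)

    inc = np.full(len(headings), np.nan)
    if len(headings) > 1:
        raw = headings[1:] - headings[:-1]
        inc[1:] = np.where(defined[1:] & defined[:-1], wrap_degrees(raw),
                           np.nan)
    return HeadingSeries(times=t[:-1], end_times=t[1:], speeds=speeds,
                         valid=span_valid, headings=headings,
                         turn_increments=inc)


def _merge_candidates(cands: list[tuple], merge_gap: float) -> list[PirouetteEvent]:
    """Merge overlapping/abutting candidates and candidates separated by
    less than ``merge_gap``; each merged group is represented by its
    maximal-|net_turn| candidate."""
    events: list[PirouetteEvent] = []
    group: list[tuple] = []
    group_end = -math.inf
    for c in sorted(cands, key=lambda c: (c[0], c[1])):
        if group and c[0] - group_end >= merge_gap:
            events.append(_best(group))
            group = []
            group_end = -math.inf
        group.append(c)
        group_end = max(group_end, c[1])
    if group:
        events.append(_best(group))
    return events


def _best(group: list[tuple]) -> PirouetteEvent:
    # |net_turn| rounded to 1e-6 deg so the winner is stable under
    # rigid-motion float noise; ties break to the earliest candidate
    t0, t1, net, vmean, bmean = max(
        group, key=lambda c: (round(abs(c[2]), 6), -c[0], -c[1]))
    return PirouetteEvent(
        t_start=float(t0), t_end=float(t1), net_turn=float(net),
        baseline_speed=float(bmean), event_speed=float(vmean),
        speed_drop=float(1.0 - vmean / bmean),
    )


def detect_pirouettes(track: Track, window: float = WINDOW,
                      angle_threshold: float = ANGLE_THRESHOLD,
                      drop_threshold: float = DROP_THRESHOLD,
                      baseline: float = BASELINE,
                      min_step: float = MIN_STEP,
                      resample_dt: float | None = RESAMPLE_DT,
                      merge_gap: float = MERGE_GAP,
                      mode: str = "net",
                      min_baseline_frac: float = 0.5) -> list[PirouetteEvent]:
    """Detect pirouette events on one track.

    Scans every sub-interval of contiguous defined-heading spans whose
    duration is at most ``window``; a candidate fires when the cumulative
    turn exceeds ``angle_threshold`` AND its mean speed is at most
    ``(1 - drop_threshold)`` times the mean speed over the ``baseline``
    seconds preceding it.  Candidates whose baseline has fewer than
    ``min_baseline_frac`` of its spans valid (or that start before one
    full baseline has elapsed) are skipped.  Overlapping, abutting, or
    < ``merge_gap``-separated candidates merge into one event carrying
    the maximal-|net_turn| candidate's bounds and statistics.
    """
    if mode not in ("net", "absolute"):
        raise ValueError(f"mode must be 'net' or 'absolute', got {mode!r}")
    step_valid = track.valid[:-1] & track.valid[1:]
    valid_time = float(np.diff(track.times)[step_valid].sum())
    if valid_time < baseline + window:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: {valid_time:.3g}s of valid data "
            f"cannot hold baseline+window = {baseline + window:.3g}s"
        )
    hs = heading_series(track, min_step=min_step, resample_dt=resample_dt)
    m = len(hs)
    ok = ~np.isnan(hs.headings)

    inc = np.where(np.isnan(hs.turn_increments), 0.0, hs.turn_increments)
    inc_cs = np.concatenate([[0.0], np.cumsum(inc)])        # inc_cs[j+1]-inc_cs[i+1] = sum inc[i+1..j]
    abs_cs = np.concatenate([[0.0], np.cumsum(np.abs(inc))])
    ok_cs = np.concatenate([[0], np.cumsum(ok.astype(int))])  # ok in [i..j] <=> ok_cs[j+1]-ok_cs[i] == j-i+1
    sp = np.where(np.isnan(hs.speeds), 0.0, hs.speeds)
    sp_cs = np.concatenate([[0.0], np.cumsum(sp)])
    va_cs = np.concatenate([[0], np.cumsum(hs.valid.astype(int))])

    t0 = hs.times
    t1 = hs.end_times
    first_time = t0[0] if m else 0.0
    cands: list[tuple] = []
    for i in range(m):
        if not ok[i]:
            continue
        bstart = t0[i] - baseline
        if bstart < first_time - 1e-9:
            continue  # no full pre-event baseline inside the track
        lo = int(np.searchsorted(t0, bstart - 1e-9, side="left"))
        hi = i  # baseline spans are [lo, i)
        nb = hi - lo
        if nb == 0:
            continue
        nvalid = va_cs[hi] - va_cs[lo]
        if nvalid == 0 or nvalid < math.ceil(min_baseline_frac * nb):
            logger.debug("track %s: candidate at t=%.3f skipped, baseline "
                         "too sparse (%d/%d valid)", track.animal_id, t0[i],
                         nvalid, nb)
            continue
        bmean = (sp_cs[hi] - sp_cs[lo]) / nvalid
        jmax = int(np.searchsorted(t1, t0[i] + window + 1e-9, side="right")) - 1
        for j in range(i + 1, min(jmax, m - 1) + 1):
            if ok_cs[j + 1] - ok_cs[i] != j - i + 1:
                break  # heading mask breaks contiguity
            if mode == "net":
                turn = inc_cs[j + 1] - inc_cs[i + 1]
            else:
                turn = abs_cs[j + 1] - abs_cs[i + 1]
            if abs(turn) <= angle_threshold:
                continue
            vmean = (sp_cs[j + 1] - sp_cs[i]) / (j - i + 1)
            if vmean <= (1.0 - drop_threshold) * bmean:
                cands.append((t0[i], t1[j], turn, vmean, bmean))
    return _merge_candidates(cands, merge_gap)


def pirouette_rate(track: Track, events: list[PirouetteEvent]) -> PirouetteSummary:
    """Events per minute of valid observation time."""
    step_valid = track.valid[:-1] & track.valid[1:]
    minutes = float(np.diff(track.times)[step_valid].sum()) / 60.0
    if minutes <= 0:
        raise InsufficientDataError(
            f"track {track.animal_id!r}: zero valid observation time"
        )
    return PirouetteSummary(
        animal_id=track.animal_id,
        n_events=len(events),
        observed_minutes=minutes,
        rate=len(events) / minutes,
    )
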