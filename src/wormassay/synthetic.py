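"""Synthetic worm tracks and plate-endpoint assays.

The track generator is a correlated random walk: the centroid moves at a
lognormal AR(1) speed along a heading that integrates Gaussian turning
noise, with sharp reorientation ("pirouette") events injected at a
controlled rate.  The head tip leads the centroid along the heading and
oscillates laterally — the kinematic signature that the head-swinging
index quantifies.  Every stochastic element is driven by one seed, so a
(params, seed) pair fixes the realization bit for bit.

Ground truth (injected event times, nominal speed, head amplitude) rides
on ``Track.meta``; analysis code never reads it, so parameter-recovery
tests are leak-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError
from .trackio import PlateAssay, Track

__all__ = [
    "SpeciesParams", "EndpointModel", "ELEGANS_LIKE", "INOPINATA_LIKE",
    "PRESETS", "simulate_track", "simulate_plate", "simulate_plates",
    "make_two_species_study",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters of one synthetic species.

    Units: mm, s, degrees.  ``heading_diffusion`` is the variance rate of
    baseline turning noise (deg^2/s); ``pirouette_rate`` is in events per
    minute; ``pirouette_speed_factor`` multiplies speed during an event.
    """

    name: str = "synthetic"
    mean_speed: float = 0.3          # mm/s
    speed_cv: float = 0.15           # lognormal coefficient of variation
    speed_ar1: float = 0.8           # per-step autocorrelation of log speed
    heading_diffusion: float = 80.0  # deg^2/s
    head_offset: float = 0.5         # mm, head-tip lead along heading
    head_amp: float = 0.1            # mm, lateral oscillation amplitude
    head_freq: float = 0.5           # Hz
    pirouette_rate: float = 0.0      # events/min
    pirouette_turn: float = 150.0    # deg, mean |net reorientation|
    pirouette_duration: float = 2.0  # s
    pirouette_speed_factor: float = 0.3
    gap_prob: float = 0.0            # per-frame dropout probability
    noise_sd: float = 0.0            # mm, positional jitter

    def __post_init__(self) -> None:
        for f in ("mean_speed", "speed_cv", "heading_diffusion", "head_offset",
                  "head_amp", "head_freq", "pirouette_rate", "pirouette_turn",
                  "pirouette_duration", "noise_sd"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be non-negative")
        if not 0 <= self.speed_ar1 < 1:
            raise ParameterError("speed_ar1 must lie in [0, 1)")
        if not 0 <= self.pirouette_speed_factor < 1:
            raise ParameterError("pirouette_speed_factor must lie in [0, 1)")
        if not 0 <= self.gap_prob < 1:
            raise ParameterError("gap_prob must lie in [0, 1)")


# Shipped presets.  Speeds sit inside the trackable band (0.2, 0.5] mm/s
# implied by the immobility and tracker-ceiling thresholds.  The
# inopinata-like preset is slower, swings its head with larger amplitude
# and higher frequency, and pirouettes only very rarely; the
# elegans-like preset is the converse.
ELEGANS_LIKE = SpeciesParams(
    name="elegans-like",
    mean_speed=0.38, speed_cv=0.15, speed_ar1=0.8,
    heading_diffusion=80.0,
    head_offset=0.5, head_amp=0.08, head_freq=0.5,
    pirouette_rate=0.5, pirouette_turn=150.0, pirouette_duration=2.0,
    pirouette_speed_factor=0.3,
    gap_prob=0.02, noise_sd=0.005,
)

INOPINATA_LIKE = SpeciesParams(
    name="inopinata-like",
    mean_speed=0.24, speed_cv=0.15, speed_ar1=0.8,
    heading_diffusion=60.0,
    head_offset=0.5, head_amp=0.30, head_freq=0.8,
    pirouette_rate=0.02, pirouette_turn=150.0, pirouette_duration=2.0,
    pirouette_speed_factor=0.3,
    gap_prob=0.02, noise_sd=0.005,
)

PRESETS = {p.name: p for p in (ELEGANS_LIKE, INOPINATA_LIKE)}


@dataclass(frozen=True)
class EndpointModel:
    """Multinomial model of one plate's endpoint: each of ``n_worms``
    worms lands in the control, odorant, or central zone independently."""

    p_control: float
    p_odorant: float
    p_central: float
    n_worms: int = 10

    def __post_init__(self) -> None:
        probs = (self.p_control, self.p_odorant, self.p_central)
        if any(not 0 <= p <= 1 for p in probs):
            raise ParameterError("zone probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ParameterError(
                f"zone probabilities must sum to 1 (got {sum(probs)!r})"
            )
        if self.n_worms < 1:
            raise ParameterError("n_worms must be >= 1")


# Injected events are kept clear of the track edges so a full pre-event
# baseline and detection window always exist.
_EVENT_LEAD_IN = 3.0   # s, no event before this time
_EVENT_TAIL = 1.0      # s, event must end this long before the track does
_EVENT_REFRACTORY = 4.0  # s, hard-core gap beyond the event duration


def _draw_event_schedule(rng: np.random.Generator, params: SpeciesParams,
                         duration: float) -> list[tuple[float, float]]:
    """Hard-core renewal schedule of (start_time, signed_turn_deg).

    Inter-event gaps are ``min_gap + Exp(mean_gap - min_gap)`` so the
    long-run rate equals ``pirouette_rate`` exactly while events never
    overlap or crowd within the detector's merge refractory.
    """
    if params.pirouette_rate <= 0:
        return []
    mean_gap = 60.0 / params.pirouette_rate
    min_gap = params.pirouette_duration + _EVENT_REFRACTORY
    if mean_gap <= min_gap:
        raise ParameterError(
            f"pirouette_rate {params.pirouette_rate}/min too high for the "
            f"{min_gap:.1f}s hard-core refractory"
        )
    events = []
    t = _EVENT_LEAD_IN + rng.exponential(mean_gap - min_gap)
    last_end = duration - params.pirouette_duration - _EVENT_TAIL
    while t <= last_end:
        # magnitude ~ N(turn, (0.1 turn)^2) truncated below 130 deg so
        # detection at the 120 deg threshold is never threshold-straddling
        mag = rng.normal(params.pirouette_turn, 0.1 * params.pirouette_turn)
        mag = max(mag, 130.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        events.append((t, sign * mag))
        t += min_gap + rng.exponential(mean_gap - min_gap)
    return events


def simulate_track(params: SpeciesParams, duration: float, dt: float,
                   seed: int, animal_id: str | None = None,
                   condition: str = "control") -> Track:
    """Simulate one worm track of ``duration`` seconds at frame interval
    ``dt``.

    The centroid follows a correlated random walk; heading integrates
    Gaussian noise of variance ``heading_diffusion*dt`` per step plus the
    injected pirouette turns, each spread over ``pirouette_duration``
    while speed is multiplied by ``pirouette_speed_factor``.  Speed is a
    stationary lognormal AR(1) with mean ``mean_speed`` and coefficient
    of variation ``speed_cv``.  The head tip is placed ``head_offset``
    ahead of the centroid along the heading, plus a lateral sinusoid of
    amplitude ``head_amp`` and frequency ``head_freq``.  Positional
    jitter (sd ``noise_sd``) is added independently to centroid and
    head; frames drop out (``valid=False``) iid with ``gap_prob``.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0 (got {dt})")
    if duration < 2 * dt:
        raise ParameterError(
            f"duration {duration}s holds fewer than 2 frames at dt={dt}s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    events = _draw_event_schedule(rng, params, duration)

    # Per-step heading increments (degrees); step k moves frame k -> k+1.
    n_steps = n - 1
    turn = rng.normal(0.0, math.sqrt(params.heading_diffusion * dt),
                      size=n_steps)
    in_event = np.zeros(n_steps, dtype=bool)
    for t0, signed_mag in events:
        sel = (t[:-1] >= t0) & (t[:-1] < t0 + params.pirouette_duration)
        turn[sel] += signed_mag * dt / params.pirouette_duration
        in_event |= sel
    theta0 = rng.uniform(0.0, 360.0)
    theta = np.empty(n)
    theta[0] = theta0
    theta[1:] = theta0 + np.cumsum(turn)

    # Lognormal AR(1) speed, stationary initialization.
    sigma2 = math.log1p(params.speed_cv ** 2)
    mu = math.log(params.mean_speed) - sigma2 / 2 if params.mean_speed > 0 else -np.inf
    eps = rng.normal(size=n_steps)
    logv = np.empty(n_steps)
    if n_steps > 0:
        s = math.sqrt(sigma2)
        logv[0] = mu + s * rng.normal()
        innov = s * math.sqrt(1.0 - params.speed_ar1 ** 2)
        for k in range(1, n_steps):
            logv[k] = mu + params.speed_ar1 * (logv[k - 1] - mu) + innov * eps[k]
    speed = np.exp(logv) if params.mean_speed > 0 else np.zeros(n_steps)
    speed[in_event] *= params.pirouette_speed_factor

    rad = np.deg2rad(theta)
    u = np.column_stack([np.cos(rad), np.sin(rad)])      # heading unit vector
    nvec = np.column_stack([-np.sin(rad), np.cos(rad)])  # left normal
    centroid = np.zeros((n, 2))
    centroid[1:] = np.cumsum(speed[:, None] * dt * u[:-1], axis=0)

    phase = rng.uniform(0.0, 2 * math.pi)
    lateral = params.head_amp * np.sin(2 * math.pi * params.head_freq * t + phase)
    head = centroid + params.head_offset * u + lateral[:, None] * nvec

    if params.noise_sd > 0:
        centroid = centroid + rng.normal(0.0, params.noise_sd, size=(n, 2))
        head = head + rng.normal(0.0, params.noise_sd, size=(n, 2))

    valid = rng.random(n) >= params.gap_prob

    if animal_id is None:
        animal_id = f"{params.name}-s{seed}"
    return Track(
        animal_id=animal_id,
        times=t,
        centroid=centroid,
        head=head,
        valid=valid,
        species="synthetic",
        stage="adult",
        condition=condition,
        nominal_dt=dt,
        meta={
            "true_event_times": np.array([e[0] for e in events]),
            "true_event_turns": np.array([e[1] for e in events]),
            "true_mean_speed": params.mean_speed,
            "true_head_amp": params.head_amp,
            "params": asdict(params),
            "seed": int(seed),
        },
    )


def simulate_plate(model: EndpointModel, seed: int,
                   plate_id: str | None = None, species: str = "synthetic",
                   stage: str = "adult", odorant: str = "ET",
                   dilution: str = "1:1000",
                   odorant_side: str = "left") -> PlateAssay:
    """Draw one plate's endpoint counts from the multinomial model."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(
        model.n_worms, [model.p_control, model.p_odorant, model.p_central]
    )
    return PlateAssay(
        plate_id=plate_id or f"sim-s{seed}",
        species=species, stage=stage, odorant=odorant, dilution=dilution,
        odorant_side=odorant_side,
        count_control=int(counts[0]),
        count_odorant=int(counts[1]),
        count_central=int(counts[2]),
    )


def simulate_plates(model: EndpointModel, n_plates: int, seed: int,
                    **assay_fields) -> list[PlateAssay]:
    """Simulate an ensemble of plates with per-plate RNG streams derived
    from one root seed."""
    seeds = _child_seeds(seed, n_plates)
    return [simulate_plate(model, int(seeds[i]), plate_id=f"sim-{i:04d}",
                           **assay_fields)
            for i in range(n_plates)]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n reproducible per-track seeds from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def make_two_species_study(preset_a: SpeciesParams, preset_b: SpeciesParams,
                           n_per_group: int, duration: float, dt: float,
                           seed: int,
                           condition: str = "control") -> list[Track]:
    """Generate a balanced two-group track ensemble for group comparisons.

    Per-track RNG streams are derived from the root seed by counter
    offset, so the ensemble is reproducible regardless of generation
    order.  Each track's ground truth stays in ``Track.meta``.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    seeds = _child_seeds(seed, 2 * n_per_group)
    tracks: list[Track] = []
    for g, preset in enumerate((preset_a, preset_b)):
        for i in range(n_per_group):
            tr = simulate_track(
                preset, duration, dt, int(seeds[g * n_per_group + i]),
                animal_id=f"{preset.name}-{i:03d}", condition=condition,
            )
            tr.meta["group"] = preset.name
            tracks.append(tr)
    return tracks
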