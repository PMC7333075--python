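"""Synthetic assessment-drive simulator.

Real screening deployments pair each applicant's simulator telemetry with a
road-exam outcome, but such cohorts are rarely shareable.  This module
generates a stand-in cohort with the same statistical shape: a bank of
routes partitioned into behaviour-eliciting *event zones* (crosswalks,
school zones, intersections, a rear-end conflict, ...), drives that execute
one *archetype* — a parametric prototypical behaviour — per zone, and
integer road-exam scores coupled to behaviour through a latent skill
variable and through the infractions actually committed.

Every template is defined over normalised zone progress, so zone-transit
duration varies with the executed speed profile and a per-execution
time-warp jitter; downstream alignment methods therefore face genuinely
unequal-length sequences.  All randomness flows from explicit seeds; a
fixed seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .replay_model import FRAME_COLUMNS, CohortRecord, DriveRecording

__all__ = [
    "MPH",
    "ZONE_TYPES",
    "ZONE_TYPE_SPECS",
    "Waypoint",
    "EventZone",
    "Environment",
    "Archetype",
    "DriverProfile",
    "SimParams",
    "ARCHETYPES",
    "generate_environment_bank",
    "simulate_drive",
    "draw_zone_archetypes",
    "assign_ore_score",
    "generate_cohort",
    "save_environments",
    "load_environments",
]

MPH = 0.44704  # metres per second per mile-per-hour

ZONE_TYPES = (
    "crosswalk",
    "school_zone",
    "construction_zone",
    "playground_zone",
    "banking_curve",
    "intersection_stop",
    "intersection_light",
    "rear_end_event",
)

#: Per zone type: (segment length in metres, posted limit in m/s).
ZONE_TYPE_SPECS: dict[str, tuple[float, float]] = {
    "crosswalk": (40.0, 30 * MPH),
    "school_zone": (150.0, 25 * MPH),
    "construction_zone": (150.0, 25 * MPH),
    "playground_zone": (100.0, 25 * MPH),
    "banking_curve": (120.0, 30 * MPH),
    "intersection_stop": (60.0, 30 * MPH),
    "intersection_light": (60.0, 30 * MPH),
    "rear_end_event": (80.0, 35 * MPH),
}

_CENTERLINE_DS = 5.0  # spacing of route polyline vertices (m)


@dataclass(frozen=True)
class Waypoint:
    """Arc-length position along the route centreline (m, >= 0)."""

    s: float


@dataclass(frozen=True)
class EventZone:
    zone_id: int
    environment_id: int
    zone_type: str
    entry: Waypoint
    exit: Waypoint
    zone_limit: float

    def __post_init__(self) -> None:
        if self.zone_type not in ZONE_TYPES:
            raise ValueError(f"unknown zone_type {self.zone_type!r}")
        if not self.entry.s < self.exit.s:
            raise ValueError("zone entry must precede exit")

    @property
    def length(self) -> float:
        return self.exit.s - self.entry.s


@dataclass
class Environment:
    """One route: centreline polyline plus ordered, non-overlapping zones."""

    environment_id: int
    route_length: float
    zones: list[EventZone]
    base_limit: float
    centerline: np.ndarray  # (n, 2) vertices at _CENTERLINE_DS spacing

    def __post_init__(self) -> None:
        ss = [z.entry.s for z in self.zones]
        if ss != sorted(ss):
            raise ValueError("zones must be sorted by entry waypoint")
        for a, b in zip(self.zones, self.zones[1:]):
            if a.exit.s > b.entry.s:
                raise ValueError(f"zones {a.zone_id} and {b.zone_id} overlap")

    @property
    def centerline_s(self) -> np.ndarray:
        return np.arange(len(self.centerline)) * _CENTERLINE_DS

    def point_at(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centreline point and unit tangent at arc length ``s``."""
        grid = self.centerline_s
        x = np.interp(s, grid, self.centerline[:, 0])
        y = np.interp(s, grid, self.centerline[:, 1])
        # tangent from finite differences of the polyline
        dx = np.gradient(self.centerline[:, 0])
        dy = np.gradient(self.centerline[:, 1])
        tx = np.interp(s, grid, dx)
        ty = np.interp(s, grid, dy)
        norm = np.hypot(tx, ty)
        norm[norm == 0] = 1.0
        return np.column_stack([x, y]), np.column_stack([tx / norm, ty / norm])


@dataclass(frozen=True)
class Archetype:
    """A prototypical zone behaviour.

    Channel templates are knot lists over normalised zone progress
    u in [0, 1], linearly interpolated.  ``speed_knots`` values are relative
    to the zone's posted limit.  ``stop_at`` plants a full stop (zero-speed
    dwell) at that progress point.  ``plants`` names the infraction events a
    clean (noise-free) execution triggers under the detection rules of
    :mod:`zonescreen.variables_features` — simulator ground truth for tests.
    """

    name: str
    zone_type: str
    infraction_weight: float
    speed_knots: tuple[tuple[float, float], ...]
    brake_knots: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 0.0))
    throttle_knots: tuple[tuple[float, float], ...] = ((0.0, 0.3), (1.0, 0.3))
    steering_knots: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 0.0))
    lane_knots: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 0.0))
    stop_at: float | None = None
    stop_duration: tuple[float, float] = (2.0, 3.5)
    signal: bool = False
    scan: bool = False
    plants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.infraction_weight < 0:
            raise ValueError("infraction_weight must be >= 0")

    def profile(self, u: np.ndarray, which: str) -> np.ndarray:
        knots = getattr(self, f"{which}_knots")
        xs = np.array([k[0] for k in knots])
        ys = np.array([k[1] for k in knots])
        return np.interp(u, xs, ys)


@dataclass(frozen=True)
class DriverProfile:
    """Latent skill theta in [0, 1] (1 = fully prepared) plus a seed."""

    theta: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta {self.theta} outside [0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Tunable study conditions for the simulator.

    ``noise_sigma`` is the per-frame Gaussian channel noise as a fraction of
    each channel's range.  ``a``/``b``/``sigma_e`` parameterise the outcome
    model: score = round(max(0, a*(1-theta) + eps) + b * sum of executed
    infraction weights), eps ~ N(0, sigma_e).
    """

    dt: float = 0.1
    noise_sigma: float = 0.05
    cruise_frac: float = 0.9       # cruise speed as fraction of base limit
    jitter: tuple[float, float] = (0.8, 1.25)
    standstill_s: float = 1.5      # standing start before first motion
    a: float = 34.0
    b: float = 0.01
    sigma_e: float = 8.0


def _arch(**kw) -> Archetype:
    return Archetype(**kw)


#: >=3 archetypes per zone type; exactly the zero-weight ones are compliant.
ARCHETYPES: dict[str, tuple[Archetype, ...]] = {
    "crosswalk": (
        _arch(name="full_stop", zone_type="crosswalk", infraction_weight=0.0,
              speed_knots=((0.0, 0.72), (0.35, 0.45), (0.5, 0.08), (0.7, 0.4), (1.0, 0.72)),
              brake_knots=((0.0, 0.0), (0.3, 0.55), (0.5, 0.6), (0.6, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.1), (0.5, 0.0), (0.7, 0.45), (1.0, 0.3)),
              stop_at=0.5, stop_duration=(1.5, 3.0), scan=True),
        _arch(name="slow_yield", zone_type="crosswalk", infraction_weight=0.0,
              speed_knots=((0.0, 0.72), (0.5, 0.3), (1.0, 0.72)),
              brake_knots=((0.0, 0.0), (0.3, 0.3), (0.55, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.2), (0.5, 0.05), (1.0, 0.35))),
        _arch(name="no_yield", zone_type="crosswalk", infraction_weight=3.0,
              speed_knots=((0.0, 1.35), (1.0, 1.35)),
              throttle_knots=((0.0, 0.55), (1.0, 0.55)),
              plants=("missed_yield", "pedestrian_collision")),
    ),
    "school_zone": (
        _arch(name="compliant_slow", zone_type="school_zone", infraction_weight=0.0,
              speed_knots=((0.0, 0.78), (0.2, 0.65), (0.8, 0.65), (1.0, 0.78)),
              brake_knots=((0.0, 0.25), (0.2, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.15), (0.3, 0.3), (1.0, 0.3))),
        _arch(name="moderate_over", zone_type="school_zone", infraction_weight=1.0,
              speed_knots=((0.0, 1.1), (1.0, 1.1)),
              throttle_knots=((0.0, 0.4), (1.0, 0.4))),
        _arch(name="speeding", zone_type="school_zone", infraction_weight=3.0,
              speed_knots=((0.0, 1.45), (1.0, 1.45)),
              throttle_knots=((0.0, 0.6), (1.0, 0.6))),
    ),
    "construction_zone": (
        _arch(name="compliant_slow", zone_type="construction_zone", infraction_weight=0.0,
              speed_knots=((0.0, 0.78), (0.2, 0.65), (0.8, 0.65), (1.0, 0.78)),
              brake_knots=((0.0, 0.25), (0.2, 0.0), (1.0, 0.0)),
              lane_knots=((0.0, 0.0), (0.2, -0.3), (0.8, -0.3), (1.0, 0.0))),
        _arch(name="lane_drift", zone_type="construction_zone", infraction_weight=2.0,
              speed_knots=((0.0, 0.9), (1.0, 0.9)),
              lane_knots=((0.0, 0.0), (0.4, 1.8), (0.6, 1.8), (1.0, 0.0)),
              steering_knots=((0.0, 0.0), (0.3, 0.25), (0.5, -0.25), (1.0, 0.0)),
              plants=("lane_departure",)),
        _arch(name="speeding", zone_type="construction_zone", infraction_weight=3.0,
              speed_knots=((0.0, 1.45), (1.0, 1.45)),
              throttle_knots=((0.0, 0.6), (1.0, 0.6))),
    ),
    "playground_zone": (
        _arch(name="compliant_slow", zone_type="playground_zone", infraction_weight=0.0,
              speed_knots=((0.0, 0.7), (1.0, 0.7)),
              throttle_knots=((0.0, 0.25), (1.0, 0.25))),
        _arch(name="moderate_over", zone_type="playground_zone", infraction_weight=1.0,
              speed_knots=((0.0, 1.1), (1.0, 1.1)),
              throttle_knots=((0.0, 0.4), (1.0, 0.4))),
        _arch(name="speeding", zone_type="playground_zone", infraction_weight=3.0,
              speed_knots=((0.0, 1.45), (1.0, 1.45)),
              throttle_knots=((0.0, 0.6), (1.0, 0.6))),
    ),
    "banking_curve": (
        _arch(name="smooth", zone_type="banking_curve", infraction_weight=0.0,
              speed_knots=((0.0, 0.78), (0.5, 0.7), (1.0, 0.78)),
              steering_knots=((0.0, 0.0), (0.2, 0.35), (0.8, 0.35), (1.0, 0.0)),
              brake_knots=((0.0, 0.2), (0.15, 0.0), (1.0, 0.0))),
        _arch(name="wide_drift", zone_type="banking_curve", infraction_weight=2.0,
              speed_knots=((0.0, 0.95), (1.0, 0.95)),
              steering_knots=((0.0, 0.0), (0.3, 0.2), (0.6, 0.5), (1.0, 0.0)),
              lane_knots=((0.0, 0.0), (0.5, 1.9), (1.0, 0.2)),
              plants=("lane_departure",)),
        _arch(name="too_fast", zone_type="banking_curve", infraction_weight=3.0,
              speed_knots=((0.0, 1.3), (1.0, 1.3)),
              steering_knots=((0.0, 0.0), (0.2, 0.45), (0.8, 0.45), (1.0, 0.0)),
              lane_knots=((0.0, 0.0), (0.5, 1.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.55), (1.0, 0.55))),
    ),
    "intersection_stop": (
        _arch(name="full_stop", zone_type="intersection_stop", infraction_weight=0.0,
              speed_knots=((0.0, 0.7), (0.35, 0.35), (0.5, 0.05), (0.7, 0.45), (1.0, 0.72)),
              brake_knots=((0.0, 0.1), (0.3, 0.5), (0.5, 0.65), (0.6, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.1), (0.5, 0.0), (0.7, 0.5), (1.0, 0.35)),
              stop_at=0.5, stop_duration=(2.0, 3.5), signal=True, scan=True),
        _arch(name="rolling_stop", zone_type="intersection_stop", infraction_weight=1.5,
              speed_knots=((0.0, 0.7), (0.5, 0.15), (1.0, 0.7)),
              brake_knots=((0.0, 0.0), (0.35, 0.4), (0.55, 0.0), (1.0, 0.0)),
              signal=True, plants=("stop_sign_violation",)),
        _arch(name="run_stop", zone_type="intersection_stop", infraction_weight=3.0,
              speed_knots=((0.0, 0.8), (1.0, 0.8)),
              throttle_knots=((0.0, 0.4), (1.0, 0.4)),
              plants=("stop_sign_violation",)),
    ),
    "intersection_light": (
        _arch(name="stop_red", zone_type="intersection_light", infraction_weight=0.0,
              speed_knots=((0.0, 0.7), (0.3, 0.35), (0.45, 0.05), (0.65, 0.45), (1.0, 0.72)),
              brake_knots=((0.0, 0.1), (0.25, 0.5), (0.45, 0.65), (0.55, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.1), (0.45, 0.0), (0.65, 0.5), (1.0, 0.35)),
              stop_at=0.45, stop_duration=(2.0, 5.0), signal=True, scan=True),
        _arch(name="hesitant_stop", zone_type="intersection_light", infraction_weight=0.5,
              speed_knots=((0.0, 0.5), (0.3, 0.25), (0.45, 0.05), (0.7, 0.35), (1.0, 0.6)),
              brake_knots=((0.0, 0.3), (0.45, 0.6), (0.55, 0.1), (1.0, 0.0)),
              stop_at=0.45, stop_duration=(5.0, 9.0), signal=True),
        _arch(name="run_red", zone_type="intersection_light", infraction_weight=3.0,
              speed_knots=((0.0, 0.85), (1.0, 0.85)),
              throttle_knots=((0.0, 0.45), (1.0, 0.45)),
              plants=("red_light_run",)),
    ),
    "rear_end_event": (
        _arch(name="brake_early", zone_type="rear_end_event", infraction_weight=0.0,
              speed_knots=((0.0, 0.72), (0.3, 0.72), (0.5, 0.25), (0.7, 0.35), (1.0, 0.72)),
              brake_knots=((0.0, 0.0), (0.25, 0.0), (0.35, 0.55), (0.55, 0.55), (0.65, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.3), (0.3, 0.0), (0.7, 0.4), (1.0, 0.3))),
        _arch(name="brake_hard_late", zone_type="rear_end_event", infraction_weight=1.0,
              speed_knots=((0.0, 0.78), (0.45, 0.78), (0.55, 0.15), (0.7, 0.3), (1.0, 0.78)),
              brake_knots=((0.0, 0.0), (0.45, 0.0), (0.52, 0.95), (0.62, 0.95), (0.7, 0.0), (1.0, 0.0)),
              throttle_knots=((0.0, 0.35), (0.45, 0.35), (0.5, 0.0), (0.75, 0.4), (1.0, 0.35))),
        _arch(name="no_brake", zone_type="rear_end_event", infraction_weight=3.0,
              speed_knots=((0.0, 0.85), (1.0, 0.85)),
              throttle_knots=((0.0, 0.45), (1.0, 0.45)),
              plants=("vehicle_collision",)),
    ),
}


def compliant_archetypes(zone_type: str) -> list[Archetype]:
    return [a for a in ARCHETYPES[zone_type] if a.infraction_weight == 0.0]


def risky_archetypes(zone_type: str) -> list[Archetype]:
    return [a for a in ARCHETYPES[zone_type] if a.infraction_weight > 0.0]


# ---------------------------------------------------------------------------
# Environment bank

def _make_centerline(route_length: float, rng: np.random.Generator) -> np.ndarray:
    """Gently curving route polyline with vertices every 5 m.

    Curvature is a smoothed random walk capped at |kappa| <= 1/300 m^-1 so
    the nearest-point projection onto the route is unambiguous for any
    trajectory within a few metres of the centreline.
    """
    n = int(math.ceil(route_length / _CENTERLINE_DS)) + 1
    kappa = rng.normal(0.0, 8e-4, size=n)
    # moving-average smoothing, then cap
    kernel = np.ones(25) / 25.0
    kappa = np.convolve(kappa, kernel, mode="same")
    kappa = np.clip(kappa, -1.0 / 300.0, 1.0 / 300.0)
    heading = np.concatenate([[0.0], np.cumsum(kappa[:-1]) * _CENTERLINE_DS])
    x = np.concatenate([[0.0], np.cumsum(np.cos(heading[:-1])) * _CENTERLINE_DS])
    y = np.concatenate([[0.0], np.cumsum(np.sin(heading[:-1])) * _CENTERLINE_DS])
    return np.column_stack([x, y])


def generate_environment_bank(
    n_env: int = 10,
    total_zones: int = 166,
    seed: int = 0,
    route_length: float = 5200.0,
    base_limit: float = 35 * MPH,
    zone_scale: float = 1.0,
) -> list[Environment]:
    """Build a bank of routes with ``total_zones`` zones spread across them.

    Zones are distributed as evenly as possible (16 or 17 each for the
    default 166 over 10), typed by cycling through the eight zone types in a
    per-route shuffled order, and placed along the route with randomised
    gaps.  ``zone_scale`` shrinks zone segment lengths for reduced-scale
    experiments.  Deterministic given ``seed``.
    """
    if total_zones < n_env:
        raise ValueError("total_zones must be >= n_env")
    master = np.random.SeedSequence(seed)
    env_seeds = master.spawn(n_env)
    counts = [total_zones // n_env] * n_env
    for i in range(total_zones % n_env):
        counts[i] += 1
    envs: list[Environment] = []
    next_zone_id = 1
    margin = 60.0 * zone_scale
    min_gap = 25.0 * zone_scale
    for env_idx in range(n_env):
        rng = np.random.default_rng(env_seeds[env_idx])
        n_z = counts[env_idx]
        types = [ZONE_TYPES[(env_idx + j) % len(ZONE_TYPES)] for j in range(n_z)]
        rng.shuffle(types)
        lengths = np.array([ZONE_TYPE_SPECS[t][0] for t in types]) * zone_scale
        free = route_length - lengths.sum() - 2 * margin - (n_z + 1) * min_gap
        if free < 0:
            raise ValueError(
                f"route_length {route_length} too short for {n_z} zones "
                f"at zone_scale {zone_scale}")
        gaps = min_gap + free * rng.dirichlet(np.ones(n_z + 1))
        zones = []
        s = margin + gaps[0]
        for j, (ztype, L) in enumerate(zip(types, lengths)):
            zones.append(EventZone(
                zone_id=next_zone_id,
                environment_id=env_idx + 1,
                zone_type=ztype,
                entry=Waypoint(round(s, 3)),
                exit=Waypoint(round(s + L, 3)),
                zone_limit=ZONE_TYPE_SPECS[ztype][1],
            ))
            next_zone_id += 1
            s += L + gaps[j + 1]
        centerline = _make_centerline(route_length, rng)
        envs.append(Environment(
            environment_id=env_idx + 1,
            route_length=route_length,
            zones=zones,
            base_limit=base_limit,
            centerline=centerline,
        ))
    return envs


# ---------------------------------------------------------------------------
# Drive simulation

def draw_zone_archetypes(
    env: Environment, profile: DriverProfile
) -> list[tuple[EventZone, Archetype]]:
    """Deterministically pick one archetype per zone for this driver.

    With probability (1 - theta) the driver draws uniformly from the risky
    (positive-weight) archetypes of the zone's type, otherwise uniformly
    from the compliant ones; so risky execution frequency is linear and
    decreasing in skill, and a theta = 1 driver is always compliant.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.seed, env.environment_id, 1]))
    out = []
    for zone in env.zones:
        risky = rng.random() < (1.0 - profile.theta)
        pool = risky_archetypes(zone.zone_type) if risky \
            else compliant_archetypes(zone.zone_type)
        out.append((zone, pool[int(rng.integers(len(pool)))]))
    return out


_CHANNEL_RANGE = {"brake": 1.0, "throttle": 1.0, "steering": 2.0,
                  "lane_offset": 4.0}


def _zone_arrays(zone: EventZone, arche: Archetype, rng: np.random.Generator,
                 params: SimParams) -> dict[str, np.ndarray]:
    """Integrate one zone traversal; returns per-frame arrays incl. s."""
    jit = rng.uniform(*params.jitter)          # duration scale
    vf = 1.0 / jit                             # speed scale
    dwell = rng.uniform(*arche.stop_duration) * jit if arche.stop_at is not None else 0.0
    L = zone.length
    dt = params.dt
    s_list: list[float] = []
    v_list: list[float] = []
    stopped_frames = 0
    s = 0.0
    stopped_done = arche.stop_at is None
    n_dwell = int(round(dwell / dt))
    while s < L:
        u = s / L
        if not stopped_done and u >= arche.stop_at:
            for _ in range(n_dwell):
                s_list.append(s)
                v_list.append(0.0)
            stopped_frames = n_dwell
            stopped_done = True
            continue
        v = max(0.3, float(arche.profile(np.array([u]), "speed")[0])
                * zone.zone_limit * vf)
        s_list.append(s)
        v_list.append(v)
        s += v * dt
    s_arr = np.array(s_list)
    v_arr = np.array(v_list)
    u_arr = np.clip(s_arr / L, 0.0, 1.0)
    out = {
        "s": zone.entry.s + s_arr,
        "speed": v_arr,
        "brake": arche.profile(u_arr, "brake"),
        "throttle": arche.profile(u_arr, "throttle"),
        "steering": arche.profile(u_arr, "steering"),
        "lane_offset": arche.profile(u_arr, "lane"),
    }
    if stopped_frames:
        dw = (v_arr == 0.0)
        out["brake"] = np.where(dw, 0.7, out["brake"])
        out["throttle"] = np.where(dw, 0.0, out["throttle"])
    n = len(s_arr)
    sig = np.zeros(n, dtype="<U5")
    sig[:] = "none"
    if arche.signal:
        direction = "left" if zone.zone_id % 2 else "right"
        sig[u_arr <= 0.4] = direction
    scan_l = np.zeros(n, dtype=bool)
    scan_r = np.zeros(n, dtype=bool)
    if arche.scan:
        scan_l[(u_arr >= 0.35) & (u_arr < 0.45)] = True
        scan_r[(u_arr >= 0.45) & (u_arr < 0.55)] = True
    out["turn_signal"] = sig
    out["scan_left"] = scan_l
    out["scan_right"] = scan_r
    out["posted_limit"] = np.full(n, zone.zone_limit)
    return out


def _cruise_arrays(s0: float, s1: float, v: float, params: SimParams,
                   base_limit: float) -> dict[str, np.ndarray]:
    n = max(1, int(math.ceil((s1 - s0) / (v * params.dt))))
    s = s0 + np.arange(n) * v * params.dt
    s = s[s < s1]
    n = len(s)
    zeros = np.zeros(n)
    sig = np.full(n, "none", dtype="<U5")
    return {
        "s": s, "speed": np.full(n, v), "brake": zeros,
        "throttle": np.full(n, 0.35), "steering": zeros,
        "lane_offset": zeros, "turn_signal": sig,
        "scan_left": np.zeros(n, dtype=bool), "scan_right": np.zeros(n, dtype=bool),
        "posted_limit": np.full(n, base_limit),
    }


def simulate_drive(
    env: Environment,
    profile: DriverProfile,
    params: SimParams = SimParams(),
    drive_id: str | None = None,
) -> DriveRecording:
    """Generate one 10 Hz assessment drive through ``env``.

    The vehicle stands still briefly, cruises below the base limit between
    zones, and executes the drawn archetype inside each zone (template +
    per-execution time-warp jitter + Gaussian channel noise).  Position is
    the centreline point at the integrated arc length, displaced laterally
    by the lane offset.
    """
    draws = draw_zone_archetypes(env, profile)
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.seed, env.environment_id, 2]))
    cruise_v = params.cruise_frac * env.base_limit
    segs: list[dict[str, np.ndarray]] = []
    n_still = int(round(params.standstill_s / params.dt))
    if n_still:
        still = _cruise_arrays(0.0, 1.0, cruise_v, params, env.base_limit)
        still = {k: (np.repeat(v[:1], n_still, axis=0) if len(v) else v)
                 for k, v in still.items()}
        still["s"] = np.zeros(n_still)
        still["speed"] = np.zeros(n_still)
        still["throttle"] = np.zeros(n_still)
        segs.append(still)
    s_cursor = 0.0
    for zone, arche in draws:
        if zone.entry.s > s_cursor:
            segs.append(_cruise_arrays(s_cursor, zone.entry.s, cruise_v,
                                       params, env.base_limit))
        segs.append(_zone_arrays(zone, arche, rng, params))
        s_cursor = zone.exit.s
    if s_cursor < env.route_length:
        segs.append(_cruise_arrays(s_cursor, env.route_length, cruise_v,
                                   params, env.base_limit))
    data = {k: np.concatenate([seg[k] for seg in segs])
            for k in segs[0].keys()}
    n = len(data["s"])
    t = np.arange(n) * params.dt
    # channel noise (fraction of range), applied after template evaluation
    if params.noise_sigma > 0:
        moving = data["speed"] > 0
        for ch, rngspan in _CHANNEL_RANGE.items():
            data[ch] = data[ch] + rng.normal(0.0, params.noise_sigma * rngspan, n)
        data["speed"] = np.where(
            moving,
            np.maximum(0.0, data["speed"]
                       + rng.normal(0.0, params.noise_sigma * env.base_limit * 0.5, n)),
            data["speed"])
    data["brake"] = np.clip(data["brake"], 0.0, 1.0)
    data["throttle"] = np.clip(data["throttle"], 0.0, 1.0)
    data["steering"] = np.clip(data["steering"], -1.0, 1.0)
    pos, tang = env.point_at(data["s"])
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    xy = pos + normal * data["lane_offset"][:, None]
    frames = pd.DataFrame({
        "t": t,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "heading": np.arctan2(tang[:, 1], tang[:, 0]),
        "speed": data["speed"],
        "brake": data["brake"],
        "throttle": data["throttle"],
        "steering": data["steering"],
        "lane_offset": data["lane_offset"],
        "turn_signal": data["turn_signal"],
        "scan_left": data["scan_left"],
        "scan_right": data["scan_right"],
        "posted_limit": data["posted_limit"],
    }, columns=list(FRAME_COLUMNS))
    return DriveRecording(
        drive_id=drive_id or f"sim-{profile.seed}",
        environment_id=env.environment_id,
        frames=frames,
        nominal_rate=1.0 / params.dt,
    )


# ---------------------------------------------------------------------------
# Outcome model

def executed_infraction_total(env: Environment, profile: DriverProfile) -> float:
    """Sum of infraction weights of the archetypes this driver executes."""
    return sum(a.infraction_weight for _, a in draw_zone_archetypes(env, profile))


def assign_ore_score(
    profile: DriverProfile,
    a: float = 34.0,
    b: float = 0.01,
    sigma_e: float = 8.0,
    infraction_total: float = 0.0,
) -> int:
    """Integer road-exam score from latent skill plus realised infractions.

    score = round(max(0, a*(1-theta) + eps) + b*infraction_total),
    eps ~ N(0, sigma_e); deterministic given the profile's seed.  A score of
    0 is a perfect exam; >= 26 fails.
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 3]))
    eps = rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0
    return int(round(max(0.0, a * (1.0 - profile.theta) + eps)
                     + b * infraction_total))


# ---------------------------------------------------------------------------
# Cohort generation

def generate_cohort(
    n: int,
    env_bank: Sequence[Environment],
    params: SimParams = SimParams(),
    seed: int = 0,
) -> tuple[list[DriveRecording], list[CohortRecord]]:
    """Simulate ``n`` drivers, each on a uniformly random route.

    Returns aligned lists of recordings and cohort records (all workflow
    flags true — the generated cohort is the analyzable one).  Fully
    reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    thetas = master.uniform(0.0, 1.0, size=n)
    env_idx = master.integers(0, len(env_bank), size=n)
    driver_seeds = master.integers(0, 2**31 - 1, size=n)
    recordings: list[DriveRecording] = []
    records: list[CohortRecord] = []
    for i in range(n):
        env = env_bank[int(env_idx[i])]
        profile = DriverProfile(theta=float(thetas[i]), seed=int(driver_seeds[i]))
        drive_id = f"d{i:05d}"
        rec = simulate_drive(env, profile, params, drive_id=drive_id)
        score = assign_ore_score(
            profile, a=params.a, b=params.b, sigma_e=params.sigma_e,
            infraction_total=executed_infraction_total(env, profile))
        recordings.append(rec)
        records.append(CohortRecord(drive_id=drive_id, ore_score=score))
    return recordings, records


# ---------------------------------------------------------------------------
# Environment bank I/O

def save_environments(envs: Sequence[Environment], path: str | Path) -> None:
    payload = []
    for env in envs:
        payload.append({
            "environment_id": env.environment_id,
            "route_length": env.route_length,
            "base_limit": env.base_limit,
            "zones": [{
                "zone_id": z.zone_id, "zone_type": z.zone_type,
                "entry_s": z.entry.s, "exit_s": z.exit.s,
                "zone_limit": z.zone_limit,
            } for z in env.zones],
            "centerline": np.round(env.centerline, 3).tolist(),
        })
    Path(path).write_text(json.dumps(payload))


def load_environments(path: str | Path) -> list[Environment]:
    payload = json.loads(Path(path).read_text())
    envs = []
    for e in payload:
        zones = [EventZone(
            zone_id=z["zone_id"], environment_id=e["environment_id"],
            zone_type=z["zone_type"], entry=Waypoint(z["entry_s"]),
            exit=Waypoint(z["exit_s"]), zone_limit=z["zone_limit"],
        ) for z in e["zones"]]
        envs.append(Environment(
            environment_id=e["environment_id"],
            route_length=e["route_length"],
            zones=zones,
            base_limit=e["base_limit"],
            centerline=np.asarray(e["centerline"], dtype=float),
        ))
    return envs
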