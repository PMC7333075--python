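"""The standard comparison feature set: 67 engineered per-drive variables.

Summaries of speed management (global and per zone type), posted-limit
adherence, control-input statistics, turn-signal and scan-button usage, and
rule-based infraction counts.  The exact catalog is fixed below; zone-type
blocks are NaN when the drive never visits that zone type.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .replay_model import DriveRecording
from .synthetic_sim import MPH, Environment, EventZone
from .zone_partition import route_progress

__all__ = [
    "VARIABLE_NAMES",
    "INFRACTION_NAMES",
    "build_variables",
    "build_variables_table",
    "count_infractions",
    "detect_zone_events",
    "zone_collision_flags",
]

_STAT_ZONE_TYPES = ("crosswalk", "school_zone", "construction_zone",
                    "playground_zone", "banking_curve")

INFRACTION_NAMES = ("vehicle_collisions", "pedestrian_collisions",
                    "red_light_runs", "stop_sign_violations",
                    "lane_departures", "missed_yields")

_LIMIT_STEPS_MPH = (10, 15, 20)


def _catalog() -> tuple[str, ...]:
    names: list[str] = []
    names += ["vel_max", "vel_mean", "vel_median"]
    names += ["speed_ratio_max", "speed_ratio_mean", "speed_ratio_median"]
    for zt in _STAT_ZONE_TYPES:
        names += [f"{zt}_vel_max", f"{zt}_vel_mean", f"{zt}_vel_median",
                  f"{zt}_speed_ratio_max", f"{zt}_speed_ratio_mean",
                  f"{zt}_speed_ratio_median"]
    for step in _LIMIT_STEPS_MPH:
        names.append(f"pct_above_{step}mph")
    for step in _LIMIT_STEPS_MPH:
        names.append(f"pct_below_{step}mph")
    names += list(INFRACTION_NAMES)
    names += ["steering_reversals", "steering_sd", "steering_max_abs"]
    names += ["brake_mean", "brake_max", "hard_brake_count"]
    names += ["throttle_mean", "throttle_max", "throttle_sd"]
    names += ["lane_offset_mean_abs", "lane_offset_sd", "lane_offset_max_abs"]
    names += ["signal_correct_ratio", "missed_signal_count"]
    names += ["scan_left_count", "scan_right_count"]
    names += ["duration_s", "frac_stopped", "frac_braking"]
    return tuple(names)


#: Fixed name/order of the 67 engineered variables.
VARIABLE_NAMES: tuple[str, ...] = _catalog()
assert len(VARIABLE_NAMES) == 67


# ---------------------------------------------------------------------------
# Rule-based zone event detection

def detect_zone_events(zone: EventZone, speed: np.ndarray, brake: np.ndarray,
                       lane_offset: np.ndarray) -> set[str]:
    """Infraction events for one zone traversal, from channel rules.

    Rules (thresholds in m/s / pedal fraction):
      * crosswalk — ``missed_yield`` when the vehicle never slows below 60%
        of the zone limit; additionally ``pedestrian_collision`` when it
        also exceeds the limit without meaningful braking (max brake < 0.2).
      * intersection_stop — ``stop_sign_violation`` when min speed > 0.7.
      * intersection_light — ``red_light_run`` when min speed > 1.0.
      * rear_end_event — ``vehicle_collision`` when max brake < 0.2 (the
        scripted lead-car stop was never braked for).
    """
    events: set[str] = set()
    vmin = float(np.min(speed))
    vmax = float(np.max(speed))
    bmax = float(np.max(brake)) if len(brake) else 0.0
    if zone.zone_type == "crosswalk":
        if vmin > 0.6 * zone.zone_limit:
            events.add("missed_yield")
            if vmax > zone.zone_limit and bmax < 0.2:
                events.add("pedestrian_collision")
    elif zone.zone_type == "intersection_stop":
        if vmin > 0.7:
            events.add("stop_sign_violation")
    elif zone.zone_type == "intersection_light":
        if vmin > 1.0:
            events.add("red_light_run")
    elif zone.zone_type == "rear_end_event":
        if bmax < 0.2:
            events.add("vehicle_collision")
    return events


def _zone_slices(env: Environment, s: np.ndarray) -> dict[int, slice]:
    out = {}
    for zone in env.zones:
        i0 = int(np.searchsorted(s, zone.entry.s, side="left"))
        i1 = int(np.searchsorted(s, zone.exit.s, side="left"))
        if i1 - i0 >= 2:
            out[zone.zone_id] = slice(i0, i1)
    return out


def _count_episodes(mask: np.ndarray) -> int:
    """Number of maximal runs of True."""
    if mask.size == 0:
        return 0
    m = mask.astype(np.int8)
    return int(m[0] + np.sum(np.diff(m) == 1))


def count_infractions(
    rec: DriveRecording, env: Environment, progress: np.ndarray | None = None
) -> dict[str, int]:
    """Counts of the six catalogued infractions over one drive."""
    s = route_progress(env, rec) if progress is None else np.asarray(progress)
    speed = rec.channel("speed")
    brake = rec.channel("brake")
    lane = rec.channel("lane_offset")
    slices = _zone_slices(env, s)
    zone_by_id = {z.zone_id: z for z in env.zones}
    counts = {name: 0 for name in INFRACTION_NAMES}
    plural = {
        "vehicle_collision": "vehicle_collisions",
        "pedestrian_collision": "pedestrian_collisions",
        "red_light_run": "red_light_runs",
        "stop_sign_violation": "stop_sign_violations",
        "missed_yield": "missed_yields",
    }
    for zone_id, sl in slices.items():
        zone = zone_by_id[zone_id]
        for ev in detect_zone_events(zone, speed[sl], brake[sl], lane[sl]):
            counts[plural[ev]] += 1
    counts["lane_departures"] = _count_episodes(np.abs(lane) > 1.5)
    return counts


def zone_collision_flags(
    rec: DriveRecording, env: Environment, progress: np.ndarray | None = None
) -> dict[int, bool]:
    """Per-zone flag: did this traversal involve a collision event?"""
    s = route_progress(env, rec) if progress is None else np.asarray(progress)
    speed = rec.channel("speed")
    brake = rec.channel("brake")
    lane = rec.channel("lane_offset")
    zone_by_id = {z.zone_id: z for z in env.zones}
    out = {}
    for zone_id, sl in _zone_slices(env, s).items():
        ev = detect_zone_events(zone_by_id[zone_id], speed[sl], brake[sl], lane[sl])
        out[zone_id] = bool(ev & {"vehicle_collision", "pedestrian_collision"})
    return out


# ---------------------------------------------------------------------------
# The 67-variable vector

def build_variables(
    rec: DriveRecording, env: Environment, progress: np.ndarray | None = None
) -> pd.Series:
    """Compute the fixed 67-feature catalog for one preprocessed drive."""
    if len(rec) == 0:
        raise ValueError("empty recording")
    s = route_progress(env, rec) if progress is None else np.asarray(progress)
    speed = rec.channel("speed")
    limit = rec.channel("posted_limit")
    brake = rec.channel("brake")
    throttle = rec.channel("throttle")
    steering = rec.channel("steering")
    lane = rec.channel("lane_offset")
    t = rec.channel("t")
    ratio = speed / limit
    v: dict[str, float] = {}
    v["vel_max"] = speed.max()
    v["vel_mean"] = speed.mean()
    v["vel_median"] = float(np.median(speed))
    v["speed_ratio_max"] = ratio.max()
    v["speed_ratio_mean"] = ratio.mean()
    v["speed_ratio_median"] = float(np.median(ratio))

    slices = _zone_slices(env, s)
    zone_by_id = {z.zone_id: z for z in env.zones}
    for zt in _STAT_ZONE_TYPES:
        idx = np.concatenate([
            np.arange(sl.start, sl.stop)
            for zid, sl in slices.items() if zone_by_id[zid].zone_type == zt
        ]) if any(zone_by_id[zid].zone_type == zt for zid in slices) else None
        if idx is None or idx.size == 0:
            for stat in ("vel_max", "vel_mean", "vel_median",
                         "speed_ratio_max", "speed_ratio_mean",
                         "speed_ratio_median"):
                v[f"{zt}_{stat}"] = np.nan
        else:
            zv, zr = speed[idx], ratio[idx]
            v[f"{zt}_vel_max"] = zv.max()
            v[f"{zt}_vel_mean"] = zv.mean()
            v[f"{zt}_vel_median"] = float(np.median(zv))
            v[f"{zt}_speed_ratio_max"] = zr.max()
            v[f"{zt}_speed_ratio_mean"] = zr.mean()
            v[f"{zt}_speed_ratio_median"] = float(np.median(zr))

    diff = speed - limit
    for step in _LIMIT_STEPS_MPH:
        v[f"pct_above_{step}mph"] = 100.0 * np.mean(diff > step * MPH)
    for step in _LIMIT_STEPS_MPH:
        v[f"pct_below_{step}mph"] = 100.0 * np.mean(diff < -step * MPH)

    v.update(count_infractions(rec, env, progress=s))

    sgn = np.sign(steering) * (np.abs(steering) > 0.02)
    sgn = sgn[sgn != 0]
    v["steering_reversals"] = int(np.sum(np.diff(sgn) != 0)) if sgn.size else 0
    v["steering_sd"] = steering.std()
    v["steering_max_abs"] = np.abs(steering).max()
    v["brake_mean"] = brake.mean()
    v["brake_max"] = brake.max()
    v["hard_brake_count"] = _count_episodes(brake > 0.9)
    v["throttle_mean"] = throttle.mean()
    v["throttle_max"] = throttle.max()
    v["throttle_sd"] = throttle.std()
    v["lane_offset_mean_abs"] = np.abs(lane).mean()
    v["lane_offset_sd"] = lane.std()
    v["lane_offset_max_abs"] = np.abs(lane).max()

    signal = rec.frames["turn_signal"].to_numpy()
    inter_visited = 0
    inter_signalled = 0
    for zid, sl in slices.items():
        if zone_by_id[zid].zone_type in ("intersection_stop", "intersection_light"):
            inter_visited += 1
            if np.any(signal[sl] != "none"):
                inter_signalled += 1
    v["signal_correct_ratio"] = (inter_signalled / inter_visited
                                 if inter_visited else np.nan)
    v["missed_signal_count"] = inter_visited - inter_signalled

    v["scan_left_count"] = _count_episodes(rec.channel("scan_left").astype(bool))
    v["scan_right_count"] = _count_episodes(rec.channel("scan_right").astype(bool))
    v["duration_s"] = t[-1] - t[0]
    v["frac_stopped"] = np.mean(speed < 0.5)
    v["frac_braking"] = np.mean(brake > 0.05)

    out = pd.Series({name: v[name] for name in VARIABLE_NAMES},
                    index=list(VARIABLE_NAMES), dtype=float)
    return out


def build_variables_table(
    recs: Iterable[DriveRecording], envs: Sequence[Environment]
) -> pd.DataFrame:
    """Variables vectors for a cohort; rows indexed by drive id."""
    env_by_id = {e.environment_id: e for e in envs}
    rows = {}
    for rec in recs:
        rows[rec.drive_id] = build_variables(rec, env_by_id[rec.environment_id])
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "drive_id"
    return df[list(VARIABLE_NAMES)]
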