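"""World layout, visual-angle utilities, and the 288-trial schedule.

The paradigm is a cued two-alternative discrimination task in a virtual
environment: a recentering cross 11 m ahead, surrounded by two concentric
rings of 1 m disks at 6 dva (parafoveal) and 20 dva (peripheral)
eccentricity.  One disk is cued per trial; after a 600-1,600 ms stimulus
onset asynchrony the target ("C" facing left or right) appears for 1 s.
Static trials place the cued disk at 13 or 32 m; in Dynamic trials the
observer translates forward at 5 m/s toward disks cued at 32 m, which makes
the cued disk's direction sweep outward and invites smooth pursuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "WorldLayout",
    "TrialSpec",
    "TrialSchedule",
    "CONDITIONS",
    "visual_angle",
    "offset_angle",
    "angle_at_distance",
    "disk_position",
    "disk_label",
    "build_schedule",
]


def disk_label(eccentricity_dva: float, index: int) -> str:
    """Canonical object label for a disk: ``disk:<ring dva>,<index>``."""
    return f"disk:{eccentricity_dva:g},{index}"

#: The three blocked conditions: cue distance 13 m static, 32 m static, dynamic.
CONDITIONS = ("static_13", "static_32", "dynamic")


@dataclass
class WorldLayout:
    """Scene geometry in meters and degrees of visual angle."""

    cross_distance: float = 11.0     # m, recentering cross ahead of observer
    cross_size: float = 0.18         # m (0.94 dva at 11 m)
    disk_diameter: float = 1.0       # m
    ring_eccentricities: tuple = (6.0, 20.0)  # dva from the cross
    disks_per_ring: int = 8
    cue_distances: tuple = (13.0, 32.0)       # m, static condition
    observer_speed: float = 5.0      # m/s, dynamic condition only
    letter_height: float = 0.429     # m; subtends 1.89 dva at 13 m

    def __post_init__(self) -> None:
        for name in ("cross_distance", "cross_size", "disk_diameter",
                     "observer_speed", "letter_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(0 < e < 90 for e in self.ring_eccentricities):
            raise ValueError("eccentricities must lie in (0, 90) dva")


@dataclass
class TrialSpec:
    trial_id: int
    motion: Literal["static", "dynamic"]
    eccentricity: Literal["parafoveal", "peripheral"]
    cue_distance: float             # m at cue time
    cued_disk_index: int
    distractor_disk_index: int      # diametrically opposite
    soa: float                      # s, cue-to-target
    target_dir: Literal["left", "right"]
    block_id: int

    @property
    def condition(self) -> str:
        if self.motion == "dynamic":
            return "dynamic"
        return f"static_{int(self.cue_distance)}"

    @property
    def eccentricity_dva(self) -> float:
        return 20.0 if self.eccentricity == "peripheral" else 6.0


@dataclass
class TrialSchedule:
    trials: list
    seed: int
    block_order: list

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict:
        counts: dict = {}
        for tr in self.trials:
            counts[tr.condition] = counts.get(tr.condition, 0) + 1
        return counts


def visual_angle(extent: float, distance: float) -> float:
    """Angular size (dva) of an extent seen at a distance: 2*atan(e/(2d))."""
    if np.any(np.asarray(distance) <= 0):
        raise ValueError("distance must be positive")
    if np.any(np.asarray(extent) < 0):
        raise ValueError("extent must be non-negative")
    out = 2.0 * np.degrees(np.arctan(np.asarray(extent) / (2.0 * np.asarray(distance))))
    return float(out) if np.ndim(out) == 0 else out


def offset_angle(x: float, y: float, z: float) -> float:
    """Angular offset (dva) of a point from the forward (+z) axis."""
    if z <= 0:
        raise ValueError("z must be positive")
    return math.degrees(math.atan(math.hypot(x, y) / z))


def angle_at_distance(angle_at_d1: float, d1: float, d2: float) -> float:
    """Transfer an angular size from one viewing distance to another.

    Inverts :func:`visual_angle` at ``d1`` to a metric extent and
    re-applies it at ``d2``.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("distances must be positive")
    extent = 2.0 * d1 * math.tan(math.radians(angle_at_d1) / 2.0)
    return visual_angle(extent, d2)


def disk_position(
    layout: WorldLayout,
    ring_eccentricity: float,
    disk_index: int,
    cue_distance: float,
    t_since_cue: float,
    motion: str,
) -> np.ndarray:
    """Observer-relative disk center (m), left-handed y-up z-forward.

    The ring's lateral radius is fixed at cue time so that the disk sits at
    ``ring_eccentricity`` dva from the forward axis when cued.  Static disks
    stay put; in dynamic trials the observer closes at 5 m/s so the forward
    distance shrinks while the lateral offset is constant.
    """
    if not 0 <= disk_index < layout.disks_per_ring:
        raise ValueError("disk_index out of range")
    lateral = cue_distance * math.tan(math.radians(ring_eccentricity))
    phi = 2.0 * math.pi * disk_index / layout.disks_per_ring
    z = cue_distance
    if motion == "dynamic":
        z = cue_distance - layout.observer_speed * t_since_cue
    return np.array([lateral * math.cos(phi), lateral * math.sin(phi), z])


def build_schedule(
    layout: WorldLayout,
    seed: int,
    participant: int = 0,
) -> TrialSchedule:
    """288 trials in 6 counterbalanced blocks of 48, deterministic per seed.

    Two blocks per condition (static 13 m, static 32 m, dynamic); block
    order is a Latin-square rotation keyed by the participant index.  Within
    a block, eccentricity (parafoveal/peripheral) and target direction are
    each balanced 24/24; SOA is uniform on [0.6, 1.6] s; the cued disk index
    is uniform over the ring with the distractor diametrically opposite.
    """
    rng = np.random.default_rng(seed)
    base = list(CONDITIONS)
    rotated = base[participant % 3:] + base[:participant % 3]
    block_order = rotated + rotated[::-1]  # e.g. ABC CBA counterbalancing

    half = layout.disks_per_ring // 2
    trials: list[TrialSpec] = []
    trial_id = 0
    for block_id, condition in enumerate(block_order):
        motion = "dynamic" if condition == "dynamic" else "static"
        cue_distance = 32.0 if condition != "static_13" else 13.0
        ecc = np.array(["parafoveal"] * 24 + ["peripheral"] * 24)
        tdir = np.array(["left"] * 24 + ["right"] * 24)
        rng.shuffle(ecc)
        rng.shuffle(tdir)
        for k in range(48):
            disk = int(rng.integers(layout.disks_per_ring))
            trials.append(TrialSpec(
                trial_id=trial_id,
                motion=motion,
                eccentricity=str(ecc[k]),
                cue_distance=cue_distance,
                cued_disk_index=disk,
                distractor_disk_index=(disk + half) % layout.disks_per_ring,
                soa=float(rng.uniform(0.6, 1.6)),
                target_dir=str(tdir[k]),
                block_id=block_id,
            ))
            trial_id += 1
    return TrialSchedule(trials=trials, seed=seed, block_order=block_order)
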