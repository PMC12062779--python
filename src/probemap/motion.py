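"""Raster sampling-path planning and G-code emission.

The probe is carried by a 3-axis gantry (a converted FDM 3D printer) and
visits a rectangular grid of sampling spots.  At each spot it descends to
the surface, stays in contact for the *sampling time*, retracts to a travel
height, and pauses for the *dwell time* before moving on.  Two descent
strategies exist: ``static`` (one fixed z for every spot, for flat leveled
samples) and ``conductance`` (stepwise descent until the conductance
feedback triggers, for uneven samples).

All coordinates are millimetres in a right-handed frame with z positive
away from the sample bed and z = 0 at the probe's run-start height, so
descending means decreasing z.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass

import yaml

__all__ = [
    "GridOrder",
    "SamplingMode",
    "ActionKind",
    "SamplingPlan",
    "MotionConfig",
    "MotionAction",
    "plan_grid",
    "sequence_run",
    "emit_gcode",
    "GCODE_DIALECT",
]


class GridOrder(str, enum.Enum):
    ROW_MAJOR = "row_major"
    SERPENTINE = "serpentine"


class SamplingMode(str, enum.Enum):
    STATIC = "static"
    CONDUCTANCE = "conductance"


class ActionKind(str, enum.Enum):
    MOVE = "move"
    WAIT = "wait"
    PROBE_STEP = "probe_step"
    SAMPLE = "sample"
    READ_FEEDBACK = "read_feedback"


#: Marlin-style absolute-positioning dialect (Prusa i3-MK3 firmware).
#: Kept as a module constant so an alternative dialect is a config change,
#: not a call-site edit.
GCODE_DIALECT = {
    "absolute": "G90",
    "linear_move": "G1",
    "dwell": "G4",
    "coord_decimals": 3,
}


@dataclass(frozen=True)
class SamplingPlan:
    """An ordered rectangular grid of sampling spots.

    Spots sit at ``origin + i * pitch`` for ``i = 0..floor(extent/pitch)``
    on each axis (endpoints inclusive), enumerated row by row in y;
    serpentine order reverses every other row to minimise travel.
    """

    origin_x: float
    origin_y: float
    extent_x: float
    extent_y: float
    pitch: float
    order: GridOrder
    spots: tuple[tuple[int, float, float], ...]

    @property
    def n_cols(self) -> int:
        return int(math.floor(self.extent_x / self.pitch)) + 1

    @property
    def n_rows(self) -> int:
        return int(math.floor(self.extent_y / self.pitch)) + 1

    def __len__(self) -> int:
        return len(self.spots)

    # -- plain-text persistence -------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "origin": [self.origin_x, self.origin_y],
                "extent": [self.extent_x, self.extent_y],
                "pitch": self.pitch,
                "order": self.order.value,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SamplingPlan":
        d = yaml.safe_load(text)
        return plan_grid(
            tuple(d["origin"]), tuple(d["extent"]), d["pitch"],
            GridOrder(d["order"]),
        )

    def spots_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["index", "x_mm", "y_mm"])
        for i, x, y in self.spots:
            w.writerow([i, f"{x:.3f}", f"{y:.3f}"])
        return buf.getvalue()


@dataclass(frozen=True)
class MotionConfig:
    """Timing and geometry of a sampling run.

    Parameters
    ----------
    sampling_time : float
        Seconds the probe stays in contact with the surface at each spot.
    dwell_time : float
        Seconds the probe pauses above the spot after retracting.
    step_distance : float
        Descent increment in mm for conductance mode (e.g. 0.05 mm).
    travel_clearance : float
        Clearance in mm above the highest contact seen so far; travel
        moves happen at ``highest_contact + travel_clearance``.
    z_start : float
        z at run start (defines z = 0 by convention when 0).
    z_min : float
        Descent floor; conductance descent never goes below this.
    feed_rate : float
        Gantry feed in mm/min for all linear moves.
    mode : SamplingMode
    static_z : float
        Fixed contact height, static mode only.
    """

    sampling_time: float = 3.0
    dwell_time: float = 5.0
    step_distance: float = 0.05
    travel_clearance: float = 2.0
    z_start: float = 0.0
    z_min: float = -5.0
    feed_rate: float = 600.0
    mode: SamplingMode = SamplingMode.CONDUCTANCE
    static_z: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_time < 0 or self.dwell_time < 0:
            raise ValueError("sampling_time and dwell_time must be >= 0")
        if self.step_distance <= 0:
            raise ValueError("step_distance must be > 0")
        if not self.z_min < self.z_start:
            raise ValueError("z_min must lie below z_start")
        if self.feed_rate <= 0:
            raise ValueError("feed_rate must be > 0")


@dataclass(frozen=True)
class MotionAction:
    """One primitive timed action of the planned sequence."""

    kind: ActionKind
    x: float | None = None
    y: float | None = None
    z: float | None = None
    duration: float = 0.0
    t_planned: float = 0.0
    spot_index: int | None = None


def plan_grid(
    origin: tuple[float, float],
    extent: tuple[float, float],
    pitch: float,
    order: GridOrder | str = GridOrder.SERPENTINE,
) -> SamplingPlan:
    """Enumerate the rectangular grid of sampling spots.

    Endpoints are inclusive: ``(floor(extent_x/pitch)+1) *
    (floor(extent_y/pitch)+1)`` spots.  Rows run along x; serpentine
    reverses every other row.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    ex, ey = float(extent[0]), float(extent[1])
    if ex < 0 or ey < 0:
        raise ValueError("extents must be non-negative")
    order = GridOrder(order)
    ox, oy = float(origin[0]), float(origin[1])
    ncx = int(math.floor(ex / pitch)) + 1
    ncy = int(math.floor(ey / pitch)) + 1
    spots: list[tuple[int, float, float]] = []
    idx = 0
    for j in range(ncy):
        cols = range(ncx)
        if order is GridOrder.SERPENTINE and j % 2 == 1:
            cols = reversed(cols)  # type: ignore[assignment]
        for i in cols:
            spots.append((idx, ox + i * pitch, oy + j * pitch))
            idx += 1
    return SamplingPlan(ox, oy, ex, ey, pitch, order, tuple(spots))


def _move_time(dx: float, dy: float, dz: float, feed_rate: float) -> float:
    return math.hypot(dx, math.hypot(dy, dz)) / (feed_rate / 60.0)


def sequence_run(plan: SamplingPlan, cfg: MotionConfig) -> list[MotionAction]:
    """Expand a plan into the ordered primitive action sequence.

    Per spot: lateral move at travel height, descent (static: one move to
    ``static_z``; conductance: probe_step/read_feedback ladder down to
    ``z_min`` — execution stops the ladder at first contact), sample,
    raise back to travel height, dwell.  The raise after sampling doubles
    as the travel raise for the next spot, and planned timestamps assume
    the full ladder (executed times can only be earlier).
    """
    actions: list[MotionAction] = []
    t = 0.0
    # planned travel height: contacts are unknown at plan time, so the plan
    # uses z_start + clearance; the executor re-bases on observed contacts.
    travel_z = cfg.z_start + cfg.travel_clearance if cfg.mode is SamplingMode.CONDUCTANCE \
        else max(cfg.static_z, cfg.z_start) + cfg.travel_clearance
    cx, cy, cz = plan.spots[0][1], plan.spots[0][2], cfg.z_start

    def add(kind: ActionKind, **kw) -> None:
        nonlocal t
        dur = kw.pop("duration", 0.0)
        actions.append(MotionAction(kind=kind, duration=dur, t_planned=t, **kw))
        t += dur

    for spot_idx, sx, sy in plan.spots:
        # lateral move at travel height (absorbs the initial raise on the
        # first spot; for later spots z is already at travel height)
        dt = _move_time(sx - cx, sy - cy, travel_z - cz, cfg.feed_rate)
        add(ActionKind.MOVE, x=sx, y=sy, z=travel_z, duration=dt, spot_index=spot_idx)
        cx, cy, cz = sx, sy, travel_z
        # descent
        if cfg.mode is SamplingMode.STATIC:
            dt = _move_time(0, 0, cfg.static_z - cz, cfg.feed_rate)
            add(ActionKind.MOVE, x=sx, y=sy, z=cfg.static_z, duration=dt,
                spot_index=spot_idx)
            cz = cfg.static_z
        else:
            add(ActionKind.READ_FEEDBACK, x=sx, y=sy, z=cz, spot_index=spot_idx)
            zz = cz
            while zz - cfg.step_distance >= cfg.z_min - 1e-12:
                zz = zz - cfg.step_distance
                dt = _move_time(0, 0, cfg.step_distance, cfg.feed_rate)
                add(ActionKind.PROBE_STEP, x=sx, y=sy, z=zz, duration=dt,
                    spot_index=spot_idx)
                add(ActionKind.READ_FEEDBACK, x=sx, y=sy, z=zz,
                    spot_index=spot_idx)
            cz = zz
        # sample
        add(ActionKind.SAMPLE, x=sx, y=sy, z=cz, duration=cfg.sampling_time,
            spot_index=spot_idx)
        # raise
        dt = _move_time(0, 0, travel_z - cz, cfg.feed_rate)
        add(ActionKind.MOVE, x=sx, y=sy, z=travel_z, duration=dt,
            spot_index=spot_idx)
        cz = travel_z
        # dwell above the spot
        add(ActionKind.WAIT, duration=cfg.dwell_time, spot_index=spot_idx)
    return actions


def emit_gcode(action: MotionAction, cfg: MotionConfig) -> str:
    """Render one action as Marlin-style G-code text.

    Moves and probe steps become absolute ``G1`` linear moves (mm, three
    decimals, feed in mm/min); waits and sampling holds become ``G4``
    dwells in milliseconds.  ``read_feedback`` has no G-code equivalent.
    """
    d = GCODE_DIALECT
    if action.kind in (ActionKind.MOVE, ActionKind.PROBE_STEP):
        nd = d["coord_decimals"]
        return (
            f"{d['linear_move']} X{action.x:.{nd}f} Y{action.y:.{nd}f} "
            f"Z{action.z:.{nd}f} F{cfg.feed_rate:g}"
        )
    if action.kind in (ActionKind.WAIT, ActionKind.SAMPLE):
        return f"{d['dwell']} P{round(action.duration * 1000.0)}"
    raise ValueError(f"no G-code representation for action kind {action.kind.value!r}")
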