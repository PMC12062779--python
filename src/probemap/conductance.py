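"""Conductance-feedback contact sensing.

The sample sits on an electrically conductive bed held at 5 V; the probe
body is grounded.  While the probe hangs in air the full supply voltage is
measured at the bed, and on contact the bed is drawn toward ground.  A
10-bit ADC digitizes the bed voltage into ``sensorValue`` (0 counts = 0 V,
1023 counts = 5 V), and the controller works with the complement

    relativeConductance = 1023 - sensorValue

which is 0 with no contact and rises toward full scale on contact.  A
user-set threshold on relativeConductance declares contact and stops the
stepwise descent.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Protocol

import pandas as pd

__all__ = [
    "FeedbackConfig",
    "ConductanceRecord",
    "ConductanceTrace",
    "ContactEvent",
    "SpotOutcome",
    "Hardware",
    "HardwareError",
    "digitize_voltage",
    "relative_conductance",
    "is_contact",
    "approach_spot",
    "write_trace_csv",
    "read_trace_csv",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "relative_conductance"]


@dataclass(frozen=True)
class FeedbackConfig:
    """ADC and trigger parameters of the feedback loop.

    ``threshold`` is in relativeConductance counts; contact is declared
    strictly above it.  ``poll_settle_time`` is the pause between a step
    and the single ADC read that follows it.
    """

    supply_voltage: float = 5.0
    adc_bits: int = 10
    threshold: int = 100
    step_distance: float = 0.05
    poll_settle_time: float = 0.0

    @property
    def full_scale(self) -> int:
        return (1 << self.adc_bits) - 1

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= self.full_scale):
            raise ValueError("threshold outside ADC range")
        if self.step_distance <= 0:
            raise ValueError("step_distance must be > 0")


@dataclass(frozen=True)
class ConductanceRecord:
    t: float
    x: float
    y: float
    z: float
    relative_conductance: int


class ConductanceTrace(list):
    """Time-ordered list of :class:`ConductanceRecord`."""

    def validate(self, full_scale: int = 1023) -> None:
        prev = float("-inf")
        for i, r in enumerate(self):
            if not (0 <= r.relative_conductance <= full_scale):
                raise ValueError(
                    f"record {i}: relative_conductance {r.relative_conductance} "
                    f"outside [0, {full_scale}]"
                )
            if r.t < prev:
                raise ValueError(f"record {i}: time not ordered")
            prev = r.t


class SpotOutcome(str, enum.Enum):
    CONTACT = "contact"
    MISSED = "missed"


@dataclass(frozen=True)
class ContactEvent:
    """Outcome of one spot approach.

    A miss (descent floor reached without trigger, e.g. a non-conductive
    region) is a recorded outcome, not an error: the run continues.
    """

    spot_index: int
    missed: bool
    contact_time: float | None = None
    contact_z: float | None = None
    peak_relative_conductance: int | None = None


class HardwareError(RuntimeError):
    """A rig/serial read failure; distinct from a missed contact."""


class Hardware(Protocol):
    """Two-method hardware contract, satisfied by a serial byte stream and
    by the virtual rig alike, plus a monotonic clock for trace timestamps."""

    def send(self, command: str) -> None: ...
    def read_feedback(self) -> int: ...
    @property
    def clock(self) -> float: ...


def digitize_voltage(v: float, cfg: FeedbackConfig = FeedbackConfig()) -> int:
    """10-bit ADC model: round(v / supply * full_scale), clamped.

    Rounding is half-away-from-zero (so 2.5 V on the 5 V scale gives 512,
    not banker's 511).
    """
    fs = cfg.full_scale
    ratio = v / cfg.supply_voltage * fs
    code = int(ratio + 0.5) if ratio >= 0 else -int(-ratio + 0.5)
    return min(max(code, 0), fs)


def relative_conductance(sensor_value: int, full_scale: int = 1023) -> int:
    """Complement of the ADC reading: full scale minus sensorValue."""
    if not (0 <= sensor_value <= full_scale):
        raise ValueError(f"sensorValue {sensor_value} outside [0, {full_scale}]")
    return full_scale - sensor_value


def is_contact(rc: int, threshold: int) -> bool:
    """Contact iff relativeConductance strictly exceeds the threshold."""
    return rc > threshold


def approach_spot(
    spot_index: int,
    xy: tuple[float, float],
    start_z: float,
    rig: Hardware,
    fb: FeedbackConfig,
    step_distance: float | None = None,
    z_min: float = -5.0,
    feed_rate: float = 600.0,
    retract_on_miss: bool = True,
) -> tuple[ContactEvent, ConductanceTrace]:
    """Stepwise descent with per-step feedback until contact triggers.

    The probe is assumed positioned above ``xy`` at ``start_z``.  An ADC
    read is taken before the first step (a probe already in contact
    triggers immediately), then the probe descends by ``step_distance``
    per iteration with one read after each step.  Descent stops at the
    first reading strictly above the threshold, and the contact z is the z
    *after* the triggering step — no sub-step back-off or interpolation.
    If ``z_min`` is reached without a trigger the spot is flagged missed
    and the probe retracts to ``start_z``.
    """
    step = fb.step_distance if step_distance is None else step_distance
    x, y = xy
    z = start_z
    trace = ConductanceTrace()
    peak = 0

    def read_once() -> int:
        if fb.poll_settle_time > 0:
            rig.send(f"G4 P{round(fb.poll_settle_time * 1000)}")
        try:
            sv = rig.read_feedback()
        except Exception as exc:  # noqa: BLE001 - any rig failure is hardware
            raise HardwareError(
                f"feedback read failed at spot {spot_index}, z={z:.3f}: {exc}"
            ) from exc
        rc = relative_conductance(sv, fb.full_scale)
        trace.append(ConductanceRecord(rig.clock, x, y, z, rc))
        return rc

    rc = read_once()
    peak = max(peak, rc)
    k = 0
    while not is_contact(rc, fb.threshold):
        # rungs at start_z - k*step (no cumulative float drift)
        if start_z - (k + 1) * step < z_min - 1e-12:
            if retract_on_miss:
                rig.send(f"G1 X{x:.3f} Y{y:.3f} Z{start_z:.3f} F{feed_rate:g}")
            return ContactEvent(spot_index, missed=True), trace
        k += 1
        # commanded positions are mm to 3 decimals; keep the internal rung
        # on a clean sub-nm value so exact-multiple surfaces behave
        z = round(start_z - k * step, 6)
        rig.send(f"G1 X{x:.3f} Y{y:.3f} Z{z:.3f} F{feed_rate:g}")
        rc = read_once()
        peak = max(peak, rc)
    return (
        ContactEvent(
            spot_index,
            missed=False,
            contact_time=trace[-1].t,
            contact_z=z,
            peak_relative_conductance=peak,
        ),
        trace,
    )


def write_trace_csv(trace: ConductanceTrace, path_or_buf) -> None:
    """Write the trace with columns ``t_s,x_mm,y_mm,z_mm,relative_conductance``."""
    if isinstance(trace, ConductanceTrace):
        trace.validate()
    df = pd.DataFrame(
        [(r.t, r.x, r.y, r.z, r.relative_conductance) for r in trace],
        columns=TRACE_COLUMNS,
    )
    df.to_csv(path_or_buf, index=False, float_format="%.6f")


def read_trace_csv(path_or_buf) -> ConductanceTrace:
    """Parse a trace CSV; malformed or out-of-range rows name the line."""
    df = pd.read_csv(path_or_buf)
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(
            f"trace CSV columns {list(df.columns)} != expected {TRACE_COLUMNS}"
        )
    trace = ConductanceTrace()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        try:
            rec = ConductanceRecord(
                float(row.t_s), float(row.x_mm), float(row.y_mm),
                float(row.z_mm), int(row.relative_conductance),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"trace CSV line {line_no}: {exc}") from exc
        if not (0 <= rec.relative_conductance <= 1023):
            raise ValueError(
                f"trace CSV line {line_no}: relative_conductance "
                f"{rec.relative_conductance} outside [0, 1023]"
            )
        trace.append(rec)
    trace.validate()
    return trace
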