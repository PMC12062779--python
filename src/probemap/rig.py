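"""Virtual instrument: printer, sample surface, ADC, and MS stream.

Everything the physical platform produces — the conductance trace CSV and
the mzML spectrum stream — can be generated here from a parametric ground
truth, so the motion, feedback and analysis code is testable without
hardware.  The rig emulates:

* a G-code interpreting gantry with instantaneous kinematics (the clock
  advances by distance/feed on moves and by the dwell time on ``G4``);
* a sample surface ``z(x, y)`` built from a tilted plane plus Gaussian
  bumps, with a binary conductive mask (non-conductive regions never
  trigger the feedback, like dry or insulating patches);
* the 10-bit ADC at the biased sample bed, with optional Gaussian count
  noise;
* a mass-spectral stream: solvent-background centroid spectra on a fixed
  m/z grid, analyte peaks appearing ``t_offset_true`` seconds after each
  contact with intensity proportional to the local concentration, held
  during sampling and then washing out exponentially.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .conductance import (
    ConductanceTrace,
    ContactEvent,
    FeedbackConfig,
    approach_spot,
    digitize_voltage,
)
from .motion import MotionConfig, SamplingMode, SamplingPlan
from .msio import Spectrum, write_mzml

__all__ = [
    "SurfaceModel",
    "GaussianBump",
    "MSStreamConfig",
    "VirtualPrinter",
    "VirtualRig",
    "ContactWindow",
    "RunResult",
    "simulate_ms_stream",
    "run_virtual_experiment",
    "load_surface_yaml",
    "DEFAULT_SOLVENT_BASELINE",
]

#: Background ions always present in the desorption solvent (m/z -> counts).
DEFAULT_SOLVENT_BASELINE = {158.96: 40.0, 210.08: 25.0, 279.16: 15.0, 391.28: 10.0}


@dataclass(frozen=True)
class GaussianBump:
    amplitude: float  # mm
    x0: float
    y0: float
    sigma: float  # mm

    def __call__(self, x, y):
        return self.amplitude * np.exp(
            -((x - self.x0) ** 2 + (y - self.y0) ** 2) / (2.0 * self.sigma**2)
        )


@dataclass
class SurfaceModel:
    """Synthetic ground truth for one specimen.

    ``height(x, y) = a x + b y + c + sum of Gaussian bumps`` (mm, in probe
    coordinates where z = 0 is the run-start height, so specimen surfaces
    sit at negative z).  ``conductive_mask`` returns False where the
    feedback can never trigger.  ``analyte_maps`` holds ``(m/z,
    concentration_fn)`` pairs; concentrations are >= 0 in arbitrary units.
    """

    plane: tuple[float, float, float] = (0.0, 0.0, -2.0)
    bumps: tuple[GaussianBump, ...] = ()
    conductive_mask: Callable[[float, float], bool] = lambda x, y: True
    analyte_maps: tuple[tuple[float, Callable[[float, float], float]], ...] = ()
    noise_sd: float = 0.0  # ADC counts
    dome_offset: float = 0.0  # mm; extra reach of the solvent dome
    seed: int = 0

    def height(self, x: float, y: float) -> float:
        a, b, c = self.plane
        z = a * x + b * y + c
        for bump in self.bumps:
            z += float(bump(x, y))
        if not math.isfinite(z):
            raise ValueError(f"height not finite at ({x}, {y})")
        return z

    def concentration(self, mz: float, x: float, y: float) -> float:
        for m, fn in self.analyte_maps:
            if m == mz:
                c = float(fn(x, y))
                if c < 0:
                    raise ValueError(f"negative concentration at ({x}, {y})")
                return c
        raise KeyError(f"no analyte map at m/z {mz}")


@dataclass
class MSStreamConfig:
    """Timing and response model of the simulated mass spectrometer.

    Defaults: one spectrum every 0.5 s, a 2 s contact-to-detection delay,
    and a 3 s washout time constant — so a +-4 s extraction window
    captures one sampling event cleanly.
    """

    scan_period: float = 0.5
    solvent_baseline: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_SOLVENT_BASELINE)
    )
    t_offset_true: float = 2.0
    washout_tau: float = 3.0
    response_gain: float = 1.0
    intensity_noise_cv: float = 0.0
    mz_bin_width: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_period <= 0:
            raise ValueError("scan_period must be > 0")
        if self.washout_tau <= 0:
            raise ValueError("washout_tau must be > 0")
        if self.t_offset_true < 0:
            raise ValueError("t_offset_true must be >= 0")

    def build_mz_grid(self, analyte_mzs: Sequence[float]) -> np.ndarray:
        """Fixed shared centroid axis: solvent plus analyte m/z values.

        Two analytes closer than one grid bin cannot be distinguished and
        are rejected here rather than silently merged.
        """
        mzs = sorted(set(self.solvent_baseline) | set(float(m) for m in analyte_mzs))
        arr = np.asarray(mzs, dtype=float)
        if arr.size > 1 and np.any(np.diff(arr) < self.mz_bin_width):
            raise ValueError(
                f"analyte/solvent m/z values closer than one grid bin "
                f"({self.mz_bin_width}); merge or re-centre them"
            )
        return arr


# ---------------------------------------------------------------------------
# Virtual printer + rig

_G1_RE = re.compile(r"^G1(\s+[XYZF]-?\d+(\.\d+)?)+\s*$")
_WORD_RE = re.compile(r"([XYZF])(-?\d+(?:\.\d+)?)")


class VirtualPrinter:
    """Marlin-subset G-code interpreter with an internal clock.

    Supports ``G90`` (absolute positioning, the only mode), ``G1`` linear
    moves (clock advances by distance/feed) and ``G4 P<ms>``/``G4 P<s>``
    dwells.  Kinematics are instantaneous-position: no acceleration.
    """

    def __init__(self, x: float = 0.0, y: float = 0.0, z: float = 0.0):
        self.x, self.y, self.z = x, y, z
        self.clock = 0.0
        self.feed_rate = 600.0  # mm/min, sticky like real firmware

    def interpret_gcode(self, command: str) -> None:
        cmd = command.strip()
        if not cmd:
            return
        if cmd == "G90":
            return
        if cmd.startswith("G4"):
            m = re.fullmatch(r"G4\s+(?:P(\d+)|S(\d+(?:\.\d+)?))", cmd)
            if not m:
                raise ValueError(f"unrecognised G-code: {command!r}")
            self.clock += float(m.group(1)) / 1000.0 if m.group(1) else float(m.group(2))
            return
        if cmd.startswith("G1"):
            if not _G1_RE.match(cmd):
                raise ValueError(f"unrecognised G-code: {command!r}")
            words = dict((k, float(v)) for k, v in _WORD_RE.findall(cmd))
            if "F" in words:
                self.feed_rate = words["F"]
            nx = words.get("X", self.x)
            ny = words.get("Y", self.y)
            nz = words.get("Z", self.z)
            dist = math.dist((self.x, self.y, self.z), (nx, ny, nz))
            self.clock += dist / (self.feed_rate / 60.0)
            self.x, self.y, self.z = nx, ny, nz
            return
        raise ValueError(f"unrecognised G-code: {command!r}")


class VirtualRig:
    """Hardware-contract implementation backed by the virtual printer.

    ``send`` feeds G-code to the printer; ``read_feedback`` models the ADC
    at the biased sample bed for the probe's current position: grounded
    (0 V) when the tip is at or below the conductive surface, full supply
    (5 V) otherwise, plus optional Gaussian count noise.
    """

    def __init__(self, surface: SurfaceModel, fb: FeedbackConfig = FeedbackConfig(),
                 printer: VirtualPrinter | None = None):
        self.surface = surface
        self.fb = fb
        self.printer = printer or VirtualPrinter()
        self._rng = np.random.default_rng(surface.seed)

    @property
    def clock(self) -> float:
        return self.printer.clock

    def send(self, command: str) -> None:
        self.printer.interpret_gcode(command)

    def adc_read(self) -> int:
        p = self.printer
        touching = (
            p.z <= self.surface.height(p.x, p.y) + self.surface.dome_offset
            and self.surface.conductive_mask(p.x, p.y)
        )
        ideal = 0 if touching else self.fb.full_scale
        if self.surface.noise_sd > 0:
            ideal = ideal + self._rng.normal(0.0, self.surface.noise_sd)
        v = ideal / self.fb.full_scale * self.fb.supply_voltage
        return digitize_voltage(v, self.fb)

    # Hardware-contract name
    def read_feedback(self) -> int:
        return self.adc_read()


# ---------------------------------------------------------------------------
# MS stream

@dataclass(frozen=True)
class ContactWindow:
    """One sampling event as the mass spectrometer sees it."""

    spot_index: int
    x: float
    y: float
    contact_time: float
    sampling_time: float


def simulate_ms_stream(
    schedule: Sequence[ContactWindow],
    surface: SurfaceModel,
    cfg: MSStreamConfig,
    duration: float | None = None,
) -> list[Spectrum]:
    """Generate the centroid MS1 stream for a run.

    Spectra repeat every ``scan_period`` from t = 0.  The solvent baseline
    is always present.  Each contact adds, for every analyte map,
    ``response_gain * concentration(x, y)`` at the analyte's m/z starting
    at ``contact_time + t_offset_true``, held for the sampling time, then
    decaying with time constant ``washout_tau``.  Multiplicative Gaussian
    noise of relative width ``intensity_noise_cv`` applies to every
    centroid (clipped at zero).
    """
    analyte_mzs = [m for m, _ in surface.analyte_maps]
    grid = cfg.build_mz_grid(analyte_mzs)
    base = np.array([cfg.solvent_baseline.get(m, 0.0) for m in grid])
    a_idx = {m: int(np.searchsorted(grid, m)) for m in analyte_mzs}

    if duration is None:
        last_end = max((c.contact_time + cfg.t_offset_true + c.sampling_time
                        for c in schedule), default=0.0)
        duration = last_end + 4.0 * cfg.washout_tau
    n_scans = int(math.floor(duration / cfg.scan_period)) + 1
    rng = np.random.default_rng(cfg.seed)
    spectra: list[Spectrum] = []
    for k in range(n_scans):
        t = k * cfg.scan_period
        inten = base.copy()
        for c in schedule:
            start = c.contact_time + cfg.t_offset_true
            end = start + c.sampling_time
            if t < start:
                continue
            frac = 1.0 if t <= end else math.exp(-(t - end) / cfg.washout_tau)
            for m, fn in surface.analyte_maps:
                conc = float(fn(c.x, c.y))
                inten[a_idx[m]] += cfg.response_gain * conc * frac
        if cfg.intensity_noise_cv > 0:
            inten = np.clip(
                inten * (1.0 + cfg.intensity_noise_cv * rng.standard_normal(inten.size)),
                0.0, None,
            )
        spectra.append(Spectrum(scan_time=t, mz=grid, intensity=inten,
                                id=f"scan={k}"))
    return spectra


# ---------------------------------------------------------------------------
# End-to-end virtual experiment

@dataclass
class RunResult:
    """Artifacts of one virtual run plus the ground truth for testing."""

    plan: SamplingPlan
    contact_events: list[ContactEvent]
    trace: ConductanceTrace
    spectra: list[Spectrum]
    ground_truth: pd.DataFrame
    mzml_path: Path | None = None
    trace_path: Path | None = None
    ground_truth_path: Path | None = None


def run_virtual_experiment(
    plan: SamplingPlan,
    motion_cfg: MotionConfig,
    fb_cfg: FeedbackConfig,
    surface: SurfaceModel,
    ms_cfg: MSStreamConfig,
    outdir: str | Path | None = None,
) -> RunResult:
    """Execute a full sampling run against the virtual rig.

    Drives the probe through the plan (conductance mode: stepwise approach
    per spot; static mode: fixed z), collecting the conductance trace and
    per-spot contact events, then synthesises the matching MS stream.
    With ``outdir`` set, writes the same two artifacts a real run exports
    (run.mzML, trace.csv) plus ground_truth.csv.
    """
    rig = VirtualRig(surface, fb_cfg)
    rig.printer.z = motion_cfg.z_start
    trace = ConductanceTrace()
    events: list[ContactEvent] = []
    schedule: list[ContactWindow] = []
    travel_z = motion_cfg.z_start
    fr = motion_cfg.feed_rate

    for spot_idx, sx, sy in plan.spots:
        rig.send(f"G1 X{sx:.3f} Y{sy:.3f} Z{travel_z:.3f} F{fr:g}")
        if motion_cfg.mode is SamplingMode.STATIC:
            rig.send(f"G1 X{sx:.3f} Y{sy:.3f} Z{motion_cfg.static_z:.3f} F{fr:g}")
            ev = ContactEvent(spot_idx, missed=False, contact_time=rig.clock,
                              contact_z=motion_cfg.static_z,
                              peak_relative_conductance=None)
            seg = ConductanceTrace()
        else:
            ev, seg = approach_spot(
                spot_idx, (sx, sy), travel_z, rig, fb_cfg,
                step_distance=motion_cfg.step_distance,
                z_min=motion_cfg.z_min, feed_rate=fr,
            )
        events.append(ev)
        trace.extend(seg)
        if not ev.missed:
            schedule.append(ContactWindow(spot_idx, sx, sy, ev.contact_time,
                                          motion_cfg.sampling_time))
            rig.send(f"G4 P{round(motion_cfg.sampling_time * 1000)}")
            travel_z = max(travel_z, ev.contact_z + motion_cfg.travel_clearance)
        rig.send(f"G1 X{sx:.3f} Y{sy:.3f} Z{travel_z:.3f} F{fr:g}")
        rig.send(f"G4 P{round(motion_cfg.dwell_time * 1000)}")

    spectra = simulate_ms_stream(schedule, surface, ms_cfg)

    truth_rows = []
    for spot_idx, sx, sy in plan.spots:
        row = {
            "spot": spot_idx, "x_mm": sx, "y_mm": sy,
            "true_z_mm": surface.height(sx, sy),
            "conductive": bool(surface.conductive_mask(sx, sy)),
        }
        for m, fn in surface.analyte_maps:
            row[f"conc_mz{m:g}"] = float(fn(sx, sy))
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    result = RunResult(plan, events, trace, spectra, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.mzml_path = outdir / "run.mzML"
        result.trace_path = outdir / "trace.csv"
        result.ground_truth_path = outdir / "ground_truth.csv"
        write_mzml(spectra, result.mzml_path)
        from .conductance import write_trace_csv

        write_trace_csv(trace, result.trace_path)
        truth.to_csv(result.ground_truth_path, index=False)
    return result


# ---------------------------------------------------------------------------
# Surface spec files

def _conc_fn(spec) -> Callable[[float, float], float]:
    """Build a concentration function from a YAML-friendly description.

    Supported forms: a bare number (uniform); ``{uniform: c}``;
    ``{plane: [a, b, c]}``; ``{rects: [{rect: [x0, x1, y0, y1], value: v},
    ...], default: d}`` (first matching rectangle wins).
    """
    if isinstance(spec, (int, float)):
        return lambda x, y, c=float(spec): c
    if "uniform" in spec:
        return lambda x, y, c=float(spec["uniform"]): c
    if "plane" in spec:
        a, b, c = (float(v) for v in spec["plane"])
        return lambda x, y: max(a * x + b * y + c, 0.0)
    if "rects" in spec:
        rects = [((float(r["rect"][0]), float(r["rect"][1]),
                   float(r["rect"][2]), float(r["rect"][3])),
                  float(r["value"])) for r in spec["rects"]]
        default = float(spec.get("default", 0.0))

        def fn(x, y):
            for (x0, x1, y0, y1), v in rects:
                if x0 <= x <= x1 and y0 <= y <= y1:
                    return v
            return default

        return fn
    raise ValueError(f"unsupported concentration spec: {spec!r}")


def load_surface_yaml(path_or_text) -> SurfaceModel:
    """Load a surface description from YAML text or a file path."""
    text = path_or_text
    p = Path(str(path_or_text))
    if "\n" not in str(path_or_text) and p.exists():
        text = p.read_text()
    d = yaml.safe_load(text)
    bumps = tuple(
        GaussianBump(float(b["amplitude"]), float(b["x"]), float(b["y"]),
                     float(b["sigma"]))
        for b in d.get("bumps", [])
    )
    off_rects = [tuple(float(v) for v in r)
                 for r in d.get("nonconductive_rects", [])]

    def mask(x, y):
        for x0, x1, y0, y1 in off_rects:
            if x0 <= x <= x1 and y0 <= y <= y1:
                return False
        return True

    analytes = tuple(
        (float(a["mz"]), _conc_fn(a["concentration"]))
        for a in d.get("analytes", [])
    )
    plane = tuple(float(v) for v in d.get("plane", (0.0, 0.0, -2.0)))
    return SurfaceModel(
        plane=plane, bumps=bumps, conductive_mask=mask, analyte_maps=analytes,
        noise_sd=float(d.get("noise_sd", 0.0)),
        dome_offset=float(d.get("dome_offset", 0.0)),
        seed=int(d.get("seed", 0)),
    )
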