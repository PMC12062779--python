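"""Assigning mass spectra to sampling spots.

Most spectra in a run show only the desorption solvent; the spectra of
interest are those acquired while extract from a spot was reaching the
detector.  Two routes identify them:

* **TIC route** — sampling events appear as peaks in the total ion
  current; peak times anchor the extraction windows.  This fails when a
  spot yields little signal (low analyte concentration, narrow m/z range).
* **Conductance route** — the recorded conductance trace gives the exact
  contact times regardless of signal; adding the contact-to-detection
  delay ``t_offset`` extrapolates the detection times.

All spectra inside a +-``half_window`` window around the anchor are
averaged into one spectrum per spot (pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .conductance import ConductanceTrace
from .motion import SamplingPlan
from .msio import Chronogram, Spectrum, tic

__all__ = [
    "AlignmentConfig",
    "SpotSpectrum",
    "AgreementReport",
    "pick_tic_peaks",
    "contact_times",
    "estimate_t_offset",
    "extract_spot_spectra",
    "assign_events_to_spots",
    "align_by_tic_vs_conductance",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Parameters of spectra-of-interest identification.

    ``half_window`` (s) is half the extraction window around an anchor
    time (default 4 s).  ``t_offset`` is the contact-to-detection delay in
    seconds, or ``"auto"`` to estimate it from the data.  The TIC
    peak-picker subtracts a rolling-quantile baseline and keeps local
    maxima rising at least ``tic_peak_min_prominence`` of the
    baseline-to-max span above it.
    """

    half_window: float = 4.0
    t_offset: float | str = "auto"
    tic_baseline_quantile: float = 0.2
    tic_baseline_window: int = 25  # scans
    tic_peak_min_prominence: float = 0.05
    threshold: int = 100
    mz_bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValueError("half_window must be > 0")
        if not (0 <= self.tic_baseline_quantile < 1):
            raise ValueError("tic_baseline_quantile must be in [0, 1)")


@dataclass(frozen=True)
class SpotSpectrum:
    """The averaged spectrum assigned to one sampling spot."""

    spot_index: int
    window: tuple[float, float]
    n_averaged: int
    spectrum: Spectrum | None
    source: str  # "tic_peaks" | "conductance"

    @property
    def empty(self) -> bool:
        return self.spectrum is None


def _rolling_quantile(values: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered rolling quantile with edge shrinkage."""
    n = values.size
    half = max(window // 2, 1)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.quantile(values[lo:hi], q)
    return out


def pick_tic_peaks(chron: Chronogram, cfg: AlignmentConfig = AlignmentConfig()) -> np.ndarray:
    """Locate sampling-event peaks in a TIC (or XIC) chronogram.

    Baseline is a rolling quantile of the trace; a local maximum counts as
    a peak when it rises above its local baseline by at least
    ``min_prominence x (global max - global baseline)``.  Ties — samples
    of a flat plateau, or candidate maxima within one scan period — merge
    to the earlier time, anchoring each peak at its detection onset.
    Returns peak times (s), possibly empty.
    """
    v = np.asarray(chron.values, dtype=float)
    t = np.asarray(chron.times, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 chronogram points")
    baseline = _rolling_quantile(v, cfg.tic_baseline_window,
                                 cfg.tic_baseline_quantile)
    span = float(v.max() - np.median(baseline))
    if span <= 0:
        return np.empty(0)
    min_height = cfg.tic_peak_min_prominence * span
    idx, props = find_peaks(v, prominence=min_height, plateau_size=1)
    # plateau tops tie: take the earliest sample, so the reported time is
    # the detection onset and the contact-to-detection lag stays unbiased
    starts = props["left_edges"].astype(int)
    # a peak must also clear its local baseline by the same margin
    keep = v[starts] - baseline[starts] >= min_height
    starts = starts[keep]
    times = t[starts]
    if times.size == 0:
        return times
    scan_period = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    merged = [times[0]]
    for tt in times[1:]:
        if tt - merged[-1] <= scan_period:
            continue  # tie within one scan period: keep the earlier time
        merged.append(tt)
    return np.asarray(merged)


def contact_times(trace: ConductanceTrace, threshold: int) -> np.ndarray:
    """Contact onset times: rising edges of relativeConductance > threshold.

    One event per contiguous supra-threshold run, at the time of its first
    sample.
    """
    onsets = []
    above = False
    for rec in trace:
        now = rec.relative_conductance > threshold
        if now and not above:
            onsets.append(rec.t)
        above = now
    return np.asarray(onsets)


def estimate_t_offset(contacts: np.ndarray, peak_times: np.ndarray) -> float:
    """Median lag from each contact to the earliest TIC peak at or after it.

    Contacts with no following peak are ignored; the result is >= 0 by
    construction.  Raises when no contact/peak pair exists (supply a
    manual t_offset then).
    """
    contacts = np.asarray(contacts, dtype=float)
    peaks = np.sort(np.asarray(peak_times, dtype=float))
    lags = []
    for c in contacts:
        k = np.searchsorted(peaks, c, side="left")
        if k < peaks.size:
            lags.append(peaks[k] - c)
    if not lags:
        raise ValueError(
            "no contact has a following TIC peak; pass an explicit t_offset"
        )
    return float(np.median(lags))


def _average_spectra(members: list[Spectrum], bin_width: float) -> Spectrum:
    """Point-wise mean on the shared axis, or bin-accumulated mean.

    Consecutive centroid scans from a real instrument need not share m/z
    axes; those are accumulated into fixed-width bins (sum / n_averaged,
    intensity-weighted bin m/z).  Synthetic streams share one grid and
    average directly.
    """
    first = members[0]
    if all(m.mz.size == first.mz.size and np.array_equal(m.mz, first.mz)
           for m in members[1:]):
        mean = np.mean([m.intensity for m in members], axis=0)
        return Spectrum(scan_time=float(np.mean([m.scan_time for m in members])),
                        mz=first.mz.copy(), intensity=mean)
    all_mz = np.concatenate([m.mz for m in members])
    all_in = np.concatenate([m.intensity for m in members])
    bins = np.round(all_mz / bin_width).astype(np.int64)
    uniq, inverse = np.unique(bins, return_inverse=True)
    sums = np.bincount(inverse, weights=all_in)
    wmz = np.bincount(inverse, weights=all_in * all_mz)
    with np.errstate(invalid="ignore"):
        centers = np.where(sums > 0, wmz / np.maximum(sums, 1e-300),
                           uniq * bin_width)
    order = np.argsort(centers)
    return Spectrum(
        scan_time=float(np.mean([m.scan_time for m in members])),
        mz=centers[order], intensity=(sums / len(members))[order],
    )


def extract_spot_spectra(
    spectra: list[Spectrum],
    event_times: np.ndarray,
    t_offset: float,
    cfg: AlignmentConfig,
    plan: SamplingPlan,
    source: str = "conductance",
    missed_spots: set[int] | None = None,
) -> list[SpotSpectrum]:
    """Average the spectra inside each event's extraction window.

    Window anchors: ``event + t_offset`` for the conductance route (events
    are contact onsets), the peak time itself for the TIC route (pass
    ``t_offset = 0``).  The k-th event maps to the k-th non-missed plan
    spot.  Windows are closed; an empty window yields a SpotSpectrum
    flagged empty rather than being dropped.  Overlapping windows are
    possible when spots are closer in time than 2 x half_window and are
    warned about.
    """
    missed_spots = missed_spots or set()
    live_spots = [i for i, _, _ in plan.spots if i not in missed_spots]
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size > len(live_spots):
        raise ValueError(
            f"{event_times.size} events but only {len(live_spots)} non-missed spots"
        )
    scan_times = np.array([s.scan_time for s in spectra])
    out: list[SpotSpectrum] = []
    prev_hi = -np.inf
    for k, ev in enumerate(event_times):
        anchor = ev + (t_offset if source == "conductance" else 0.0)
        lo, hi = anchor - cfg.half_window, anchor + cfg.half_window
        if lo < prev_hi:
            warnings.warn(
                f"extraction windows overlap near t={lo:.1f}s; "
                "spots are closer in time than the window width",
                stacklevel=2,
            )
        prev_hi = hi
        sel = np.nonzero((scan_times >= lo) & (scan_times <= hi))[0]
        members = [spectra[i] for i in sel]
        spot_idx = live_spots[k]
        if not members:
            out.append(SpotSpectrum(spot_idx, (lo, hi), 0, None, source))
        else:
            avg = _average_spectra(members, cfg.mz_bin_width)
            out.append(SpotSpectrum(spot_idx, (lo, hi), len(members), avg, source))
    return out


def assign_events_to_spots(
    trace: ConductanceTrace,
    threshold: int,
    plan: SamplingPlan,
) -> tuple[np.ndarray, set[int]]:
    """Pair contact events with plan spots and flag missed spots.

    Primary mapping is by order (k-th event -> k-th contacted spot), with
    the trace's recorded (x, y) as a cross-check: each event's position is
    snapped to the nearest plan spot, any spot never contacted is missed,
    and a warning is raised when nearest-spot assignment disagrees with
    plan order (e.g. a skipped or duplicated event).
    Returns (event onset times, missed spot indices).
    """
    onsets: list[tuple[float, float, float]] = []
    above = False
    for rec in trace:
        now = rec.relative_conductance > threshold
        if now and not above:
            onsets.append((rec.t, rec.x, rec.y))
        above = now
    xy = np.array([(x, y) for _, x, y in plan.spots])
    nearest = []
    for _, ex, ey in onsets:
        d2 = (xy[:, 0] - ex) ** 2 + (xy[:, 1] - ey) ** 2
        nearest.append(plan.spots[int(np.argmin(d2))][0])
    missed = {i for i, _, _ in plan.spots} - set(nearest)
    by_order = [i for i, _, _ in plan.spots if i not in missed]
    if nearest != by_order:
        warnings.warn(
            "nearest-spot assignment disagrees with plan order; "
            "check the trace for duplicated or out-of-order contacts",
            stacklevel=2,
        )
    return np.asarray([t for t, _, _ in onsets]), missed


@dataclass(frozen=True)
class AgreementReport:
    """Comparison of the TIC and conductance registration routes."""

    n_tic_peaks: int
    n_conductance_events: int
    counts_match: bool
    window_center_diffs: np.ndarray  # s, per paired event
    max_abs_diff: float
    agree: bool  # counts match and every |diff| <= scan_period
    scan_period: float


def align_by_tic_vs_conductance(
    spectra: list[Spectrum],
    trace: ConductanceTrace,
    cfg: AlignmentConfig = AlignmentConfig(),
    tic_mz_range: tuple[float, float] | None = None,
) -> AgreementReport:
    """Check that both identification routes anchor the same windows.

    A count mismatch signals weak-signal spots the TIC route cannot see —
    exactly the case the conductance route exists for.
    """
    if not spectra and not trace:
        return AgreementReport(0, 0, True, np.empty(0), 0.0, True, 0.0)
    chron = tic(spectra) if tic_mz_range is None else tic(spectra, tic_mz_range)
    peaks = pick_tic_peaks(chron, cfg)
    contacts = contact_times(trace, cfg.threshold)
    scan_period = (float(np.median(np.diff(chron.times)))
                   if chron.times.size > 1 else 0.0)
    if cfg.t_offset == "auto":
        t_off = estimate_t_offset(contacts, peaks) if (contacts.size and peaks.size) else 0.0
    else:
        t_off = float(cfg.t_offset)
    n = min(peaks.size, contacts.size)
    diffs = peaks[:n] - (contacts[:n] + t_off)
    counts_match = peaks.size == contacts.size
    max_abs = float(np.max(np.abs(diffs))) if n else 0.0
    return AgreementReport(
        n_tic_peaks=int(peaks.size),
        n_conductance_events=int(contacts.size),
        counts_match=counts_match,
        window_center_diffs=diffs,
        max_abs_diff=max_abs,
        agree=counts_match and max_abs <= scan_period,
        scan_period=scan_period,
    )
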