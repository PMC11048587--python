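"""Voice-onset landmarks and timing measures on a vibrogram.

Three landmarks are detected on the glottal-width series:

* **adduction criterion** — the first frame where the (smoothed) width has
  fallen to one third of the pre-gesture reference width and stays there
  for at least 5 ms;
* **oscillation onset** — the "just noticeable" start of vibration,
  operationalized as the first sustained departure of the width from its
  local baseline exceeding ``k`` (default 3) times the quiet-segment noise
  floor, confirmed by a following detected cycle;
* **steady state** — the first cycle of the earliest run of ``M`` (default
  3) consecutive cycles whose periods and peak-to-peak amplitudes each stay
  within a tolerance (default 10%) of that run's medians.

Pre-phonation time is the adduction-criterion -> oscillation-onset interval;
frames/cycles to steady state count from oscillation onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .edge_tracking import Vibrogram

__all__ = [
    "CycleTable",
    "OnsetReport",
    "detect_cycles",
    "detect_adduction_criterion",
    "detect_oscillation_onset",
    "detect_steady_state",
    "onset_report",
    "smoothed_width",
]


@dataclass
class CycleTable:
    """Detected glottal cycles, ordered and non-overlapping.

    ``peak_time_frames`` holds subpixel-refined peak positions (quadratic
    interpolation around each width maximum), which make period estimates —
    and hence F0 — finer than the frame grid.
    """

    start_frame: np.ndarray
    end_frame: np.ndarray
    period_frames: np.ndarray
    peak_to_peak_amplitude_px: np.ndarray
    max_width_px: np.ndarray
    peak_time_frames: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.start_frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_frame": self.start_frame,
                "end_frame": self.end_frame,
                "period_frames": self.period_frames,
                "peak_to_peak_amplitude_px": self.peak_to_peak_amplitude_px,
                "max_width_px": self.max_width_px,
                "peak_time_frames": self.peak_time_frames,
            }
        )


@dataclass
class OnsetReport:
    """Onset landmarks and derived timing measures (frames are 0-based).

    Any landmark that could not be established — including because a
    whiteout obliterated the view across it — is ``None`` and the derived
    times depending on it are ``None`` as well.
    """

    adduction_criterion_frame: int | None
    oscillation_onset_frame: int | None
    steady_state_frame: int | None
    prephonation_time_ms: float | None
    frames_to_steady: int | None
    cycles_to_steady: int | None
    reached_steady: bool
    reference_width_px: float | None
    fps: float
    settings: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "adduction_criterion_frame": self.adduction_criterion_frame,
            "oscillation_onset_frame": self.oscillation_onset_frame,
            "steady_state_frame": self.steady_state_frame,
            "prephonation_time_ms": self.prephonation_time_ms,
            "frames_to_steady": self.frames_to_steady,
            "cycles_to_steady": self.cycles_to_steady,
            "reached_steady": self.reached_steady,
            "reference_width_px": self.reference_width_px,
            "fps": self.fps,
            "settings": self.settings,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def smoothed_width(vib: Vibrogram, window: int = 3) -> np.ndarray:
    """NaN-aware running-median smoothing of the width series.

    A 3-frame median suppresses single-frame tracking jitter without
    shifting landmarks by more than one frame; invalid rows stay NaN.
    """
    w = vib.masked_width()
    if window <= 1 or len(w) < window:
        return w
    half = window // 2
    padded = np.pad(w, half, mode="edge")
    views = sliding_window_view(padded, window)
    out = _nanmedian_quiet(views)
    out[np.isnan(w)] = np.nan
    return out


def _nanmedian_quiet(views: np.ndarray) -> np.ndarray:
    """Row-wise nanmedian without the all-NaN-slice warning."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(views, axis=1)


def _quiet_reference(w: np.ndarray, fps: float) -> tuple[float, int, float]:
    """Pre-gesture reference width, quiet-segment end, and noise floor SD.

    The quiet segment runs from the start until the smoothed width first
    drops below 90% of the initial median (taken over the first 25 ms).
    The noise floor is the scaled median absolute deviation over the quiet
    segment (0 for a noiseless series).
    """
    n_init = max(5, int(round(0.025 * fps)))
    finite = np.flatnonzero(np.isfinite(w))
    if finite.size == 0:
        raise ValueError("width series has no valid samples")
    initial = float(np.nanmedian(w[: max(n_init, finite[0] + n_init)]))
    below = np.flatnonzero(np.isfinite(w) & (w < 0.9 * initial))
    quiet_end = int(below[0]) if below.size else len(w)
    seg = w[:quiet_end]
    seg = seg[np.isfinite(seg)]
    if seg.size >= 3:
        ref = float(np.median(seg))
        sigma = float(1.4826 * np.median(np.abs(seg - np.median(seg))))
    else:
        ref, sigma = initial, 0.0
    return ref, quiet_end, sigma


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------


def detect_cycles(vib: Vibrogram, min_amplitude_px: float = 1.0) -> CycleTable:
    """Delimit glottal cycles by successive width maxima.

    Maxima must rise at least ``min_amplitude_px`` above the neighbouring
    minima (peak prominence).  An input with no qualifying maxima yields an
    empty table, not an error.
    """
    w = smoothed_width(vib)
    filled = np.where(np.isfinite(w), w, -np.inf)
    peaks, _ = signal.find_peaks(filled, prominence=min_amplitude_px, distance=2)
    peaks = peaks[np.isfinite(w[peaks])]
    # subframe refinement needs rounded (not flat-topped) peaks, so it runs
    # on a short boxcar mean rather than the median-filtered series
    w_box = _boxcar3(vib.masked_width())
    refined = _refine_peaks(w_box, peaks)
    starts, ends, periods, amps, maxima, ptimes = [], [], [], [], [], []
    for i in range(len(peaks) - 1):
        a, b = int(peaks[i]), int(peaks[i + 1])
        seg = w[a : b + 1]
        if not np.all(np.isfinite(seg)):
            continue  # cycle interrupted by untrackable rows
        starts.append(a)
        ends.append(b)
        periods.append(refined[i + 1] - refined[i])
        # conservative peak-to-peak: the cycle's own (starting) peak over its
        # trough, so a growing tail cannot inflate the current cycle
        amps.append(float(min(seg[0], seg[-1]) - np.min(seg)))
        maxima.append(float(np.max(seg)))
        ptimes.append(float(refined[i]))
    return CycleTable(
        start_frame=np.asarray(starts, dtype=int),
        end_frame=np.asarray(ends, dtype=int),
        period_frames=np.asarray(periods, dtype=float),
        peak_to_peak_amplitude_px=np.asarray(amps, dtype=float),
        max_width_px=np.asarray(maxima, dtype=float),
        peak_time_frames=np.asarray(ptimes, dtype=float),
        fps=vib.fps,
    )


def _boxcar3(w: np.ndarray) -> np.ndarray:
    """3-frame NaN-aware moving average (edge-padded)."""
    if len(w) < 3:
        return w
    padded = np.pad(w, 1, mode="edge")
    views = sliding_window_view(padded, 3)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(views, axis=1)
    out[np.isnan(w)] = np.nan
    return out


def _refine_peaks(w: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Quadratic subframe refinement of peak positions."""
    refined = peaks.astype(float).copy()
    for i, p in enumerate(peaks):
        if 0 < p < len(w) - 1 and np.all(np.isfinite(w[p - 1 : p + 2])):
            denom = w[p - 1] - 2 * w[p] + w[p + 1]
            if denom < -1e-12:
                refined[i] = p + 0.5 * (w[p - 1] - w[p + 1]) / denom
    return refined


def detect_adduction_criterion(
    vib: Vibrogram,
    reference_width_px: float | None = None,
    sustain_ms: float = 5.0,
) -> int | None:
    """First frame where the width reaches one third of the reference width.

    The reference defaults to the pre-gesture median width over the initial
    quiet segment.  The crossing must hold for at least ``sustain_ms``.
    Returns ``None`` when the criterion is never met.
    """
    w = smoothed_width(vib)
    if reference_width_px is None:
        reference_width_px, _, _ = _quiet_reference(w, vib.fps)
    if reference_width_px <= 0:
        raise ValueError("reference width must be positive")
    crit = reference_width_px / 3.0
    sustain = max(1, int(round(sustain_ms / 1000.0 * vib.fps)))
    below = np.isfinite(w) & (w <= crit)
    for start, stop in _nan_runs(below):
        if stop - start >= sustain or (stop == len(w) and stop > start):
            return int(start)
    return None


def detect_oscillation_onset(
    vib: Vibrogram,
    cycles: CycleTable,
    noise_floor_sd: float | None = None,
    k: float = 3.0,
    min_threshold_px: float = 0.5,
) -> int | None:
    """Frame of the just-noticeable start of oscillation.

    The first cycle whose peak-to-peak amplitude exceeds ``k`` times the
    noise floor anchors the search; the onset is then the first of 3
    consecutive frames before that cycle's peak where the width's residual
    about a one-period rolling median exceeds the same threshold.  (The
    first width *maximum* lags the true oscillation start by about half a
    period, hence the backtrack.)  Returns ``None`` when no cycle
    qualifies.
    """
    w = smoothed_width(vib)
    if noise_floor_sd is None:
        _, _, noise_floor_sd = _quiet_reference(w, vib.fps)
    threshold = max(k * noise_floor_sd, min_threshold_px)

    if len(cycles) == 0:
        return None
    qualifying = np.flatnonzero(cycles.peak_to_peak_amplitude_px > threshold)
    if qualifying.size == 0:
        return None
    first = int(qualifying[0])
    anchor = int(cycles.start_frame[first])
    period = max(2, int(round(float(np.median(cycles.period_frames)))))

    # residual about a centred one-period rolling median: removes both the
    # flat baseline and the linear adduction ramp, keeps the oscillation
    win = period + (period % 2 == 0)  # odd window
    half = win // 2
    padded = np.pad(w, half, mode="edge")
    baseline = _nanmedian_quiet(sliding_window_view(padded, win))
    resid = np.abs(w - baseline)

    lo = 0
    hi = min(len(w), anchor + 1)
    exceed = np.isfinite(resid[lo:hi]) & (resid[lo:hi] > threshold)
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= 3:
            return lo + i - 2
    return anchor


def detect_steady_state(
    cycles: CycleTable,
    tol_fraction: float = 0.10,
    m: int = 3,
    start_cycle: int = 0,
) -> tuple[int | None, int | None, bool]:
    """Find the first cycle of the earliest stable run of ``m`` cycles.

    A run is stable when every period and every amplitude deviates at most
    ``tol_fraction`` from that run's medians.  Returns ``(steady_frame,
    cycles_to_steady, reached)`` where ``cycles_to_steady`` counts detected
    cycles from ``start_cycle`` up to (excluding) the steady one.
    """
    n = len(cycles)
    if n - start_cycle < m:
        return None, None, False
    periods = cycles.period_frames
    amps = cycles.peak_to_peak_amplitude_px
    for i in range(start_cycle, n - m + 1):
        p = periods[i : i + m]
        a = amps[i : i + m]
        med_p, med_a = np.median(p), np.median(a)
        if med_p <= 0 or med_a <= 0:
            continue
        if (
            np.max(np.abs(p - med_p)) <= tol_fraction * med_p
            and np.max(np.abs(a - med_a)) <= tol_fraction * med_a
        ):
            return int(cycles.start_frame[i]), int(i - start_cycle), True
    return None, None, False


def onset_report(
    vib: Vibrogram,
    reference_width_px: float | None = None,
    k: float = 3.0,
    steady_tol: float = 0.10,
    steady_m: int = 3,
    min_cycle_amplitude_px: float = 1.0,
    max_blind_gap_frames: int = 10,
) -> OnsetReport:
    """Compose the three landmark detectors into a full onset report.

    Long untrackable runs (e.g. whiteout) that overlap the onset region
    invalidate the landmarks they span: those fields come back ``None`` and
    ``reached_steady`` is False, mirroring tokens whose view of the folds
    was obliterated.
    """
    w = smoothed_width(vib)
    ref, quiet_end, sigma = _quiet_reference(w, vib.fps)
    if reference_width_px is not None:
        ref = reference_width_px

    notes = ["adduction criterion interpreted as 1/3 of the pre-gesture gap width"]
    settings = {
        "k": k,
        "steady_tol": steady_tol,
        "steady_m": steady_m,
        "noise_floor_sd_px": sigma,
        "min_cycle_amplitude_px": min_cycle_amplitude_px,
        "max_blind_gap_frames": max_blind_gap_frames,
    }

    blind = [
        (a, b)
        for a, b in _nan_runs(~vib.valid)
        if b - a >= max_blind_gap_frames
    ]

    def blind_overlap(lo: int | None, hi: int | None) -> bool:
        lo = 0 if lo is None else lo
        hi = len(vib) if hi is None else hi
        return any(a < hi and b > lo for a, b in blind)

    crit = detect_adduction_criterion(vib, reference_width_px=ref)
    if crit is not None and blind_overlap(quiet_end, crit):
        crit = None
        notes.append("adduction criterion obscured by untrackable interval")

    min_amp = max(min_cycle_amplitude_px, k * sigma)
    cycles = detect_cycles(vib, min_amplitude_px=min_amp)
    onset = detect_oscillation_onset(vib, cycles, noise_floor_sd=sigma, k=k)
    if onset is not None and blind_overlap(quiet_end, onset):
        onset = None
        notes.append("oscillation onset obscured by untrackable interval")

    steady_frame = cycles_to_steady = None
    reached = False
    if onset is not None:
        start_cycle = int(np.searchsorted(cycles.start_frame, onset))
        # the onset frame precedes the first peak; the cycle beginning at
        # that first peak is cycle 0
        if start_cycle > 0 and cycles.end_frame[start_cycle - 1] > onset:
            start_cycle -= 1
        steady_frame, cycles_to_steady, reached = detect_steady_state(
            cycles, tol_fraction=steady_tol, m=steady_m, start_cycle=start_cycle
        )
        if (
            cycles_to_steady is not None
            and len(cycles)
            and onset < cycles.start_frame[start_cycle]
        ):
            cycles_to_steady += 1  # count the partial cycle before the first peak
        if steady_frame is not None and blind_overlap(onset, steady_frame):
            steady_frame = cycles_to_steady = None
            reached = False
            notes.append("steady state obscured by untrackable interval")

    prephonation = (
        (onset - crit) / vib.fps * 1000.0
        if crit is not None and onset is not None
        else None
    )
    frames_to_steady = (
        steady_frame - onset if steady_frame is not None and onset is not None else None
    )
    return OnsetReport(
        adduction_criterion_frame=crit,
        oscillation_onset_frame=onset,
        steady_state_frame=steady_frame,
        prephonation_time_ms=prephonation,
        frames_to_steady=frames_to_steady,
        cycles_to_steady=cycles_to_steady,
        reached_steady=reached,
        reference_width_px=ref,
        fps=vib.fps,
        settings=settings,
        notes=notes,
    )
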