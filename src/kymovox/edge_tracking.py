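"""Glottal edge tracking: kymogram -> vibrogram waveform.

Each kymogram row is one video frame.  The glottal gap appears as a dark
run between the two bright fold bands; the tracker finds, per row, the
below-threshold run nearest the previous row's gap, then refines both edges
to subpixel precision by linear interpolation between the two pixels
straddling the threshold.  Rows that are saturated (view "whiteout", e.g.
epiglottis retroflexion) or have too little contrast to carry an edge are
flagged invalid rather than tracked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kymography import Kymogram

__all__ = [
    "TrackingSettings",
    "Vibrogram",
    "QCReport",
    "TrackingError",
    "track_edges",
    "fill_gaps",
    "qc",
    "save_vibrogram",
    "load_vibrogram",
]

#: Intensity ceiling used for the whiteout rule on 8-bit input.
_INTENSITY_CEILING = 255.0


@dataclass(frozen=True)
class TrackingSettings:
    """Parameters of the threshold-crossing edge tracker.

    gap_polarity
        ``"dark"`` (default): the glottal gap is darker than the folds.
        ``"bright"``: inverted imagery.
    threshold_mode / threshold_value
        ``"fraction"``: threshold at ``value`` of the row's min->max range
        (default 0.5), which makes the tracked width invariant to global
        intensity gain.  ``"fixed"``: absolute intensity threshold.
    search_window_px
        Lateral window about the previous row's gap centre outside which
        candidate runs are ignored (``None`` = unrestricted).
    saturation_fraction
        A row is whiteout when at least this fraction of its pixels exceeds
        0.9 x the intensity ceiling (255 for 8-bit input).
    min_contrast
        Rows whose min->max range falls below this carry no edge: they are
        a closed glottis if bright, untrackable otherwise.
    """

    gap_polarity: str = "dark"
    threshold_mode: str = "fraction"
    threshold_value: float = 0.5
    search_window_px: float | None = None
    saturation_fraction: float = 0.95
    min_contrast: float = 50.0

    def __post_init__(self) -> None:
        if self.gap_polarity not in ("dark", "bright"):
            raise ValueError("gap_polarity must be 'dark' or 'bright'")
        if self.threshold_mode not in ("fraction", "fixed"):
            raise ValueError("threshold_mode must be 'fraction' or 'fixed'")
        if self.threshold_mode == "fraction" and not 0 < self.threshold_value < 1:
            raise ValueError("fractional threshold must lie in (0, 1)")
        if not 0 < self.saturation_fraction <= 1:
            raise ValueError("saturation_fraction must lie in (0, 1]")


@dataclass
class Vibrogram:
    """Per-frame left/right glottal edge positions and glottal width.

    Positions are subpixel medial--lateral coordinates (pixel centres at
    integer columns).  ``width_px = right - left`` and is exactly 0 during
    the closed phase.  ``valid`` is False for whiteout or untrackable rows;
    ``imputed`` marks rows later filled by :func:`fill_gaps`.
    """

    left_px: np.ndarray
    right_px: np.ndarray
    width_px: np.ndarray
    valid: np.ndarray
    fps: float
    imputed: np.ndarray | None = None
    whiteout: np.ndarray | None = None
    row_contrast: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.width_px)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        if self.whiteout is None:
            self.whiteout = np.zeros(n, dtype=bool)
        if self.row_contrast is None:
            self.row_contrast = np.full(n, np.nan)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(self.width_px[self.valid] < -1e-9):
            raise ValueError("width must be non-negative where valid")

    def __len__(self) -> int:
        return len(self.width_px)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    def masked_width(self) -> np.ndarray:
        """Width series with invalid rows as NaN."""
        w = self.width_px.astype(float).copy()
        w[~self.valid] = np.nan
        return w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.time_s,
                "left_px": self.left_px,
                "right_px": self.right_px,
                "width_px": self.width_px,
                "valid": self.valid,
                "imputed": self.imputed,
                "whiteout": self.whiteout,
            }
        )


@dataclass
class QCReport:
    """Automated stand-in for visual verification of the tracked vibrogram."""

    fraction_valid: float
    mean_row_contrast: float
    whiteout_intervals: list[tuple[int, int]]
    passed: bool
    n_frames: int = 0

    def to_dict(self) -> dict:
        return {
            "fraction_valid": self.fraction_valid,
            "mean_row_contrast": self.mean_row_contrast,
            "whiteout_intervals": [list(iv) for iv in self.whiteout_intervals],
            "passed": self.passed,
            "n_frames": self.n_frames,
        }


class TrackingError(RuntimeError):
    """Raised when no row of the kymogram could be tracked."""

    def __init__(self, message: str, qc_report: QCReport | None = None):
        super().__init__(message)
        self.qc_report = qc_report


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as half-open (start, stop)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _subpixel_edges(
    row: np.ndarray, start: int, stop: int, threshold: float
) -> tuple[float, float]:
    """Refine run boundaries by linear interpolation across the threshold."""
    if start == 0:
        left = -0.5
    else:
        a, b = row[start - 1], row[start]
        left = start - 1 + (a - threshold) / (a - b) if a != b else start - 0.5
    if stop == len(row):
        right = len(row) - 0.5
    else:
        a, b = row[stop - 1], row[stop]
        right = stop - 1 + (threshold - a) / (b - a) if a != b else stop - 0.5
    return float(left), float(right)


def track_edges(kym: Kymogram, settings: TrackingSettings | None = None) -> Vibrogram:
    """Track the glottal gap row by row and return the vibrogram.

    Per row the gap is the below-threshold run nearest the previous row's
    gap centre (first row: nearest the image centre); ties go to the wider
    run, then the more medial one.  Rows with no below-threshold run are a
    closed glottis (width exactly 0, edges placed at the gap centre of the
    nearest open row).  Raises :class:`TrackingError` if every row is
    invalid.
    """
    settings = settings or TrackingSettings()
    img = np.asarray(kym.rows, dtype=np.float64)
    if settings.gap_polarity == "bright":
        img = _INTENSITY_CEILING - img
    n, w = img.shape
    center = (w - 1) / 2.0

    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    width = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    whiteout = np.zeros(n, dtype=bool)
    contrast = img.max(axis=1) - img.min(axis=1)
    row_mean = img.mean(axis=1)
    bright_level = 0.5 * (img.min() + img.max())
    sat_level = 0.9 * _INTENSITY_CEILING
    sat_frac = (np.asarray(kym.rows, dtype=np.float64) >= sat_level).mean(axis=1)

    prev_center = center
    for r in range(n):
        if sat_frac[r] >= settings.saturation_fraction:
            whiteout[r] = True
            continue
        row = img[r]
        if contrast[r] < settings.min_contrast:
            if row_mean[r] >= bright_level:
                # uniformly bright: folds in contact, glottis closed
                width[r] = 0.0
                valid[r] = True
            continue
        if settings.threshold_mode == "fraction":
            lo, hi = row.min(), row.max()
            threshold = lo + settings.threshold_value * (hi - lo)
        else:
            threshold = settings.threshold_value
        runs = _runs(row < threshold)
        if settings.search_window_px is not None:
            runs = [
                (a, b)
                for a, b in runs
                if abs((a + b - 1) / 2.0 - prev_center) <= settings.search_window_px
            ]
        if not runs:
            width[r] = 0.0
            valid[r] = True
            continue
        # nearest to the previous gap centre; ties -> wider -> more medial
        runs.sort(
            key=lambda ab: (
                abs((ab[0] + ab[1] - 1) / 2.0 - prev_center),
                -(ab[1] - ab[0]),
                abs((ab[0] + ab[1] - 1) / 2.0 - center),
            )
        )
        a, b = runs[0]
        l_px, r_px = _subpixel_edges(row, a, b, threshold)
        left[r], right[r] = l_px, r_px
        width[r] = max(0.0, r_px - l_px)
        valid[r] = True
        prev_center = (l_px + r_px) / 2.0

    if not valid.any():
        report = QCReport(
            fraction_valid=0.0,
            mean_row_contrast=float(contrast.mean()),
            whiteout_intervals=_runs(whiteout),
            passed=False,
            n_frames=n,
        )
        raise TrackingError("no trackable rows in kymogram", report)

    # closed rows: place coincident edges at the nearest open row's gap centre
    open_rows = np.flatnonzero(valid & (width > 0))
    closed_rows = np.flatnonzero(valid & (width == 0))
    if open_rows.size and closed_rows.size:
        centers = (left[open_rows] + right[open_rows]) / 2.0
        nearest = np.searchsorted(open_rows, closed_rows)
        nearest = np.clip(nearest, 0, open_rows.size - 1)
        prev_idx = np.clip(nearest - 1, 0, open_rows.size - 1)
        use_prev = np.abs(open_rows[prev_idx] - closed_rows) < np.abs(
            open_rows[nearest] - closed_rows
        )
        pick = np.where(use_prev, prev_idx, nearest)
        left[closed_rows] = right[closed_rows] = centers[pick]
    elif closed_rows.size:
        left[closed_rows] = right[closed_rows] = center

    return Vibrogram(
        left_px=left,
        right_px=right,
        width_px=width,
        valid=valid,
        fps=kym.fps,
        whiteout=whiteout,
        row_contrast=contrast,
        source_id=kym.source_id,
    )


def fill_gaps(vib: Vibrogram, max_gap_frames: int = 5) -> Vibrogram:
    """Linearly interpolate invalid runs no longer than ``max_gap_frames``.

    Interpolated rows are flagged ``imputed`` (and become valid); longer
    runs, or runs touching either end of the record, are left invalid.
    """
    left = vib.left_px.copy()
    right = vib.right_px.copy()
    width = vib.width_px.copy()
    valid = vib.valid.copy()
    imputed = vib.imputed.copy()

    for start, stop in _runs(~vib.valid):
        if stop - start > max_gap_frames or start == 0 or stop == len(vib):
            continue
        lo, hi = start - 1, stop
        frac = (np.arange(start, stop) - lo) / (hi - lo)
        left[start:stop] = left[lo] + frac * (left[hi] - left[lo])
        right[start:stop] = right[lo] + frac * (right[hi] - right[lo])
        width[start:stop] = np.maximum(0.0, right[start:stop] - left[start:stop])
        valid[start:stop] = True
        imputed[start:stop] = True

    return Vibrogram(
        left_px=left,
        right_px=right,
        width_px=width,
        valid=valid,
        fps=vib.fps,
        imputed=imputed,
        whiteout=vib.whiteout.copy(),
        row_contrast=None if vib.row_contrast is None else vib.row_contrast.copy(),
        source_id=vib.source_id,
    )


def qc(
    vib: Vibrogram,
    min_fraction_valid: float = 0.8,
    min_mean_contrast: float = 50.0,
) -> QCReport:
    """Summarize trackability; ``passed`` requires all minima to be met."""
    fraction_valid = float(np.mean(vib.valid))
    contrast = vib.row_contrast
    mean_contrast = float(np.nanmean(contrast)) if contrast is not None else np.nan
    whiteout_intervals = _runs(vib.whiteout)
    passed = fraction_valid >= min_fraction_valid and (
        np.isnan(mean_contrast) or mean_contrast >= min_mean_contrast
    )
    return QCReport(
        fraction_valid=fraction_valid,
        mean_row_contrast=mean_contrast,
        whiteout_intervals=whiteout_intervals,
        passed=bool(passed),
        n_frames=len(vib),
    )


def save_vibrogram(vib: Vibrogram, path) -> None:
    vib.to_frame().to_csv(path, index=False)


def load_vibrogram(path, fps: float | None = None) -> Vibrogram:
    df = pd.read_csv(path)
    if fps is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or dt[0] <= 0:
            raise ValueError("cannot infer fps from vibrogram CSV; pass fps")
        fps = 1.0 / float(np.median(dt))
    return Vibrogram(
        left_px=df["left_px"].to_numpy(float),
        right_px=df["right_px"].to_numpy(float),
        width_px=df["width_px"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        fps=float(fps),
        imputed=df["imputed"].to_numpy(bool) if "imputed" in df else None,
        whiteout=df["whiteout"].to_numpy(bool) if "whiteout" in df else None,
    )
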