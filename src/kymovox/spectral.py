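"""FFT analysis of the vibrogram waveform.

The steady part of the glottal-width series is mean-detrended, Hann
windowed (default) and transformed to a one-sided power spectrum; the
powers of the spectral peak at the fundamental and at the first three
harmonics above it (2f0, 3f0, 4f0) summarize the oscillation: a higher
fundamental peak means larger-amplitude oscillation, and relatively
stronger harmonics mean a longer closed phase with faster opening/closing
of the folds.

Without zero padding the spectrum is Parseval-consistent: the power bins
sum to the energy of the windowed signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .edge_tracking import Vibrogram
from .onset_metrics import CycleTable, detect_cycles, onset_report

__all__ = [
    "VibrogramSpectrum",
    "HarmonicPeaks",
    "F0Estimate",
    "compute_spectrum",
    "estimate_f0",
    "extract_harmonic_peaks",
    "steady_segment",
]

_PHYSIOLOGIC_F0 = (50.0, 600.0)


@dataclass
class VibrogramSpectrum:
    """One-sided power spectrum of a vibrogram segment (units px^2)."""

    frequency_hz: np.ndarray
    power: np.ndarray
    window: str
    segment: tuple[int, int]
    n_signal: int
    n_fft: int
    fps: float

    @property
    def bin_spacing_hz(self) -> float:
        return self.fps / self.n_fft

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.frequency_hz, "power": self.power})


@dataclass
class HarmonicPeaks:
    """Peak powers at the fundamental and first three harmonics above it.

    ``p0`` is the power at f0; ``p1, p2, p3`` are at 2f0, 3f0, 4f0 (``None``
    above Nyquist).  ``r1 = p1/p0`` and ``r2 = p2/p0`` are the harmonic-to-
    fundamental power ratios; ``bandwidth_hz`` holds each peak's half-power
    width.
    """

    f0_hz: float
    p0: float
    p1: float | None
    p2: float | None
    p3: float | None
    r1: float | None
    r2: float | None
    bandwidth_hz: tuple[float | None, ...] = ()

    def to_dict(self) -> dict:
        # both harmonic indexing conventions, to keep the JSON unambiguous
        return {
            "f0_hz": self.f0_hz,
            "power_at_kf0": {"1": self.p0, "2": self.p1, "3": self.p2, "4": self.p3},
            "fundamental_power": self.p0,
            "harmonics_above_fundamental": [self.p1, self.p2, self.p3],
            "r1_p2f0_over_pf0": self.r1,
            "r2_p3f0_over_pf0": self.r2,
            "half_power_bandwidth_hz": list(self.bandwidth_hz),
        }


@dataclass
class F0Estimate:
    f0_hz: float
    spectral_peak_hz: float | None
    discrepant: bool  # cycle-based vs spectral estimate differ by > 10%


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def steady_segment(vib: Vibrogram, f0_nominal: float | None = None) -> tuple[int, int]:
    """Steady-oscillation segment, truncated to whole estimated cycles.

    Runs the onset report to exclude the onset transient; the segment
    spans from the steady-state landmark to the end of the record, cut to
    an integer number of cycles of the cycle-table F0.
    """
    report = onset_report(vib)
    if report.steady_state_frame is None:
        raise ValueError("no steady-state segment found")
    start = report.steady_state_frame
    stop = len(vib)
    cycles = detect_cycles(vib)
    if len(cycles):
        period = float(np.median(cycles.period_frames))
        n_cycles = int((stop - start) / period)
        if n_cycles < 1:
            raise ValueError("steady segment shorter than one cycle")
        stop = start + int(round(n_cycles * period))
    return start, min(stop, len(vib))


def compute_spectrum(
    vib: Vibrogram,
    segment: tuple[int, int] | None = None,
    window: str = "hann",
    zero_pad: bool = True,
    f0_nominal: float | None = None,
) -> VibrogramSpectrum:
    """One-sided power spectrum of the width series over ``segment``.

    The segment (default: the steady segment) must contain only valid (or
    imputed) frames and, when ``f0_nominal`` is given, at least 4 cycles.
    The series is mean-detrended and windowed; with ``zero_pad`` the FFT
    length is the next power of two.  Power is scaled so that, without
    padding, the bins sum to the windowed-signal energy.
    """
    if segment is None:
        segment = steady_segment(vib, f0_nominal)
    start, stop = segment
    if not 0 <= start < stop <= len(vib):
        raise ValueError(f"segment {segment} outside vibrogram of length {len(vib)}")
    if not np.all(vib.valid[start:stop]):
        raise ValueError(
            "segment contains invalid frames; apply fill_gaps or choose another segment"
        )
    x = vib.width_px[start:stop].astype(float)
    n = x.size
    if n < 8:
        raise ValueError("segment too short for spectral analysis")
    if f0_nominal is not None and n < 4 * vib.fps / f0_nominal:
        raise ValueError("segment shorter than 4 nominal cycles")

    x = x - x.mean()
    win = sps.get_window(window, n, fftbins=True)
    xw = x * win
    n_fft = _next_pow2(n) if zero_pad else n
    spec = np.fft.rfft(xw, n_fft)
    power = np.abs(spec) ** 2 / n_fft
    power[1:] *= 2.0
    if n_fft % 2 == 0:
        power[-1] /= 2.0
    freq = np.fft.rfftfreq(n_fft, d=1.0 / vib.fps)
    return VibrogramSpectrum(
        frequency_hz=freq,
        power=power,
        window=window,
        segment=(start, stop),
        n_signal=n,
        n_fft=n_fft,
        fps=vib.fps,
    )


def estimate_f0(
    cycles: CycleTable,
    spectrum: VibrogramSpectrum | None = None,
    f0_range: tuple[float, float] = _PHYSIOLOGIC_F0,
) -> F0Estimate:
    """F0 from the median cycle period, cross-checked against the spectrum.

    Needs at least 3 detected cycles.  When a spectrum is supplied, the
    dominant in-range spectral peak is compared with the cycle-based value;
    a discrepancy above 10% sets ``discrepant``.
    """
    if len(cycles) < 3:
        raise ValueError("need at least 3 cycles to estimate F0")
    periods = cycles.period_frames
    med = float(np.median(periods))
    inliers = periods[np.abs(periods - med) <= 0.10 * med]
    f0 = cycles.fps / float(np.mean(inliers) if inliers.size else med)
    spectral_peak = None
    discrepant = False
    if spectrum is not None:
        lo, hi = f0_range
        mask = (spectrum.frequency_hz >= lo) & (spectrum.frequency_hz <= hi)
        if mask.any():
            idx = np.flatnonzero(mask)[np.argmax(spectrum.power[mask])]
            spectral_peak = float(spectrum.frequency_hz[idx])
            discrepant = abs(spectral_peak - f0) > 0.10 * f0
    return F0Estimate(f0_hz=float(f0), spectral_peak_hz=spectral_peak, discrepant=discrepant)


def _half_power_bandwidth(spec: VibrogramSpectrum, peak_bin: int) -> float | None:
    p = spec.power
    half = p[peak_bin] / 2.0
    lo = peak_bin
    while lo > 0 and p[lo] > half:
        lo -= 1
    hi = peak_bin
    while hi < len(p) - 1 and p[hi] > half:
        hi += 1
    if p[lo] > half or p[hi] > half:
        return None
    df = spec.bin_spacing_hz

    def cross(a: int, b: int) -> float:
        if p[a] == p[b]:
            return float(b)
        return a + (p[a] - half) / (p[a] - p[b])

    return float((cross(hi - 1, hi) - cross(lo + 1, lo)) * df) if hi > lo else None


def extract_harmonic_peaks(
    spec: VibrogramSpectrum,
    f0_hz: float,
    search_bins: int = 2,
    f0_range: tuple[float, float] = _PHYSIOLOGIC_F0,
) -> HarmonicPeaks:
    """Peak power within ``±search_bins`` of k*f0 for k = 1..4.

    The search window tolerates slight F0 drift across the segment.
    Harmonics above Nyquist are absent (``None``).  ``f0`` must sit at
    least 2 bins above DC.
    """
    df = spec.bin_spacing_hz
    if f0_hz < 2 * df:
        raise ValueError("f0 too close to DC for harmonic analysis")
    if not f0_range[0] <= f0_hz <= f0_range[1]:
        raise ValueError(f"f0 {f0_hz:.1f} Hz outside physiologic range {f0_range}")
    nyquist = spec.fps / 2.0
    powers: list[float | None] = []
    bandwidths: list[float | None] = []
    for k in range(1, 5):
        fk = k * f0_hz
        if fk > nyquist:
            powers.append(None)
            bandwidths.append(None)
            continue
        center = int(round(fk / df))
        lo = max(0, center - search_bins)
        hi = min(len(spec.power) - 1, center + search_bins)
        local = int(lo + np.argmax(spec.power[lo : hi + 1]))
        powers.append(float(spec.power[local]))
        bandwidths.append(_half_power_bandwidth(spec, local))
    p0, p1, p2, p3 = powers
    return HarmonicPeaks(
        f0_hz=f0_hz,
        p0=p0,
        p1=p1,
        p2=p2,
        p3=p3,
        r1=None if p1 is None or p0 == 0 else p1 / p0,
        r2=None if p2 is None or p0 == 0 else p2 / p0,
        bandwidth_hz=tuple(bandwidths),
    )
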