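"""Spectrum computation, F0 estimation, and harmonic-peak extraction."""

import numpy as np
import pytest
from scipy.integrate import quad

from kymovox.edge_tracking import Vibrogram, track_edges
from kymovox.onset_metrics import detect_cycles
from kymovox.spectral import (
    compute_spectrum,
    estimate_f0,
    extract_harmonic_peaks,
)
from kymovox.synthetic import GlottisSimParams, generate_kymogram_direct


def _vib_from_width(width, fps=2000.0):
    width = np.asarray(width, dtype=float)
    n = width.size
    return Vibrogram(
        left_px=np.zeros(n),
        right_px=width,
        width_px=width,
        valid=np.ones(n, dtype=bool),
        fps=fps,
    )


def _pure_tone(f0=200.0, fps=2000.0, n=2000, amp=10.0, offset=20.0):
    t = np.arange(n) / fps
    return _vib_from_width(offset + amp * np.sin(2 * np.pi * f0 * t), fps)


def test_pure_tone_dominant_peak_and_harmonic_floor():
    vib = _pure_tone()
    spec = compute_spectrum(vib, segment=(0, len(vib)))
    peak_bin = int(np.argmax(spec.power))
    assert abs(spec.frequency_hz[peak_bin] - 200.0) <= spec.bin_spacing_hz
    peaks = extract_harmonic_peaks(spec, 200.0)
    for p in (peaks.p1, peaks.p2, peaks.p3):
        assert 10 * np.log10(peaks.p0 / p) >= 40.0
    assert peaks.r1 < 0.01


def test_constant_series_has_no_power_after_detrend():
    vib = _vib_from_width(np.full(1024, 12.0))
    spec = compute_spectrum(vib, segment=(0, 1024))
    assert spec.power.max() < 1e-18


def test_parseval_without_zero_padding():
    rng = np.random.default_rng(3)
    vib = _vib_from_width(20.0 + rng.normal(0, 3, 1000))
    spec = compute_spectrum(vib, segment=(0, 1000), zero_pad=False)
    x = vib.width_px - vib.width_px.mean()
    from scipy.signal import get_window

    xw = x * get_window("hann", 1000, fftbins=True)
    energy = float(np.sum(xw**2))
    assert np.sum(spec.power) == pytest.approx(energy, rel=1e-6)


def test_scaling_width_scales_power_quadratically():
    vib = _pure_tone()
    scaled = _vib_from_width(vib.width_px * 3.0)
    a = compute_spectrum(vib, segment=(0, len(vib)))
    b = compute_spectrum(scaled, segment=(0, len(vib)))
    mask = a.power > a.power.max() * 1e-6
    assert np.allclose(b.power[mask] / a.power[mask], 9.0, rtol=1e-6)


def test_segment_with_invalid_frames_rejected():
    vib = _pure_tone()
    vib.valid[500] = False
    with pytest.raises(ValueError, match="invalid frames"):
        compute_spectrum(vib, segment=(0, len(vib)))


def test_too_short_segment_rejected():
    vib = _pure_tone()
    with pytest.raises(ValueError):
        compute_spectrum(vib, segment=(0, 4))


def _analytic_harmonic_ratio(cq: float) -> float:
    """Fourier oracle: power ratio |a2/a1|^2 of w(theta) = max(0, c - cos)
    with c = cos(pi*cq) — the steady-state width waveform shape."""
    c = np.cos(np.pi * cq)

    def f(theta):
        return np.maximum(0.0, c - np.cos(theta))

    def coeff(k):
        re, _ = quad(lambda th: f(th) * np.cos(k * th), 0, 2 * np.pi, limit=200)
        return re / np.pi

    a1, a2 = coeff(1), coeff(2)
    return (a2 / a1) ** 2


@pytest.mark.parametrize("cq", [0.2, 0.4])
def test_clipped_sine_harmonic_ratio_matches_fourier_oracle(cq):
    # 100 Hz at 2000 fps = 20 samples/cycle keeps aliased high harmonics
    # negligible; a whole number of cycles without padding puts f0 exactly
    # on a bin, so the ratio is free of window scalloping
    p = GlottisSimParams(
        noise_sd=0.0,
        duration_s=1.2,
        f0_hz=100.0,
        closed_quotient=cq,
        steady_amplitude_px=12.0,
    )
    _, truth = generate_kymogram_direct(p)
    start = truth.steady_state_frame + 100
    vib = _vib_from_width(truth.true_width_series)
    spec = compute_spectrum(vib, segment=(start, start + 1000), zero_pad=False)
    peaks = extract_harmonic_peaks(spec, p.f0_hz)
    assert peaks.r1 == pytest.approx(_analytic_harmonic_ratio(cq), rel=0.05)


def test_harmonic_ratio_rises_with_closed_quotient():
    ratios = []
    for cq in (0.0, 0.2, 0.4):
        p = GlottisSimParams(
            noise_sd=0.0, duration_s=0.8, closed_quotient=cq, steady_amplitude_px=12.0
        )
        kym, truth = generate_kymogram_direct(p)
        vib = track_edges(kym)
        spec = compute_spectrum(vib)
        est = estimate_f0(detect_cycles(vib), spec)
        ratios.append(extract_harmonic_peaks(spec, est.f0_hz).r1)
    assert ratios[0] < ratios[1] < ratios[2]


def test_loud_config_has_larger_fundamental_and_harmonic_ratio():
    def peaks_for(amp, cq):
        p = GlottisSimParams(
            noise_sd=0.0,
            duration_s=0.8,
            steady_amplitude_px=amp,
            closed_quotient=cq,
            seed=6,
        )
        kym, _ = generate_kymogram_direct(p)
        vib = track_edges(kym)
        spec = compute_spectrum(vib)
        est = estimate_f0(detect_cycles(vib), spec)
        return extract_harmonic_peaks(spec, est.f0_hz)

    soft = peaks_for(8.0, 0.15)
    loud = peaks_for(20.0, 0.45)
    assert loud.p0 > soft.p0
    assert loud.r1 > soft.r1


@pytest.mark.parametrize("f0", [200.0, 119.0])
def test_f0_estimate_recovers_generator_frequency(f0):
    p = GlottisSimParams(duration_s=0.8, f0_hz=f0, seed=12)
    kym, _ = generate_kymogram_direct(p)
    vib = track_edges(kym)
    est = estimate_f0(detect_cycles(vib))
    assert est.f0_hz == pytest.approx(f0, abs=1.0)


def test_f0_cross_check_against_spectrum_not_discrepant():
    p = GlottisSimParams(duration_s=0.8, seed=13)
    kym, _ = generate_kymogram_direct(p)
    vib = track_edges(kym)
    spec = compute_spectrum(vib)
    est = estimate_f0(detect_cycles(vib), spec)
    assert not est.discrepant
    assert est.spectral_peak_hz == pytest.approx(est.f0_hz, rel=0.05)


def test_empty_cycle_table_errors():
    vib = _vib_from_width(np.full(500, 10.0))
    with pytest.raises(ValueError, match="3 cycles"):
        estimate_f0(detect_cycles(vib))


def test_harmonics_above_nyquist_absent():
    vib = _pure_tone(f0=300.0)
    spec = compute_spectrum(vib, segment=(0, len(vib)))
    peaks = extract_harmonic_peaks(spec, 300.0)
    assert peaks.p0 is not None and peaks.p1 is not None and peaks.p2 is not None
    assert peaks.p3 is None  # 4*300 = 1200 Hz > Nyquist (1000 Hz)
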