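"""Diagnostic plots: annotated onset waveform and vibrogram spectrum."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .edge_tracking import Vibrogram
from .onset_metrics import OnsetReport
from .spectral import VibrogramSpectrum

__all__ = ["plot_onset", "plot_spectrum"]


def plot_onset(vib: Vibrogram, report: OnsetReport, path) -> None:
    """Glottal width vs time with the three onset landmarks marked."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    t = vib.time_s * 1000.0
    w = vib.masked_width()
    ax.plot(t, w, lw=0.7, color="k", label="glottal width")
    marks = [
        (report.adduction_criterion_frame, "tab:blue", "adduction 1/3 criterion"),
        (report.oscillation_onset_frame, "tab:red", "oscillation onset"),
        (report.steady_state_frame, "tab:green", "steady state"),
    ]
    for frame, color, label in marks:
        if frame is not None:
            ax.axvline(frame / vib.fps * 1000.0, color=color, ls="--", label=label)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("width (px)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spectrum(spec: VibrogramSpectrum, path, f0_hz: float | None = None) -> None:
    """Power spectrum in dB re max, with harmonic positions marked."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    p = spec.power
    ref = p.max() if p.max() > 0 else 1.0
    db = 10.0 * np.log10(np.maximum(p / ref, 1e-12))
    ax.plot(spec.frequency_hz, db, lw=0.8, color="k")
    if f0_hz is not None:
        for k in range(1, 5):
            if k * f0_hz < spec.fps / 2:
                ax.axvline(k * f0_hz, color="tab:red", ls=":", lw=0.7)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (dB re max)")
    ax.set_ylim(-100, 5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
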