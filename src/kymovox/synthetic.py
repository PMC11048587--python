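"""Synthetic high-speed laryngoscopy and PAS recordings with known ground truth.

No public high-speed recordings of voice onset exist, so every stage of the
pipeline is exercised on simulations with exactly known landmarks.  The
glottis model renders two bright fold bands converging on a dark medial gap.
The per-frame half-gap of each side is

    g(t) = max(0, G(t) - A(t) * cos(2*pi*f0*(t - t_osc)))

where ``G(t)`` is a linear adduction ramp from the resting half-gap to the
final posture half-gap, and ``A(t) = A_inf * (1 - exp(-(t - t_osc)/tau))``
grows exponentially after oscillation start.  The posture half-gap is
coupled to the closed quotient ``cq`` as ``G_final = A_inf * cos(pi*cq)``
(possibly negative: virtual over-adduction), which makes the steady-state
width a cosine clipped at zero whose flat closed phase occupies exactly
``cq`` of each cycle — the analytically known harmonic structure the
spectral stage is validated against.

Oscillation begins a configurable pre-phonation delay after the adduction
ramp crosses the one-third-width criterion, so pre-phonation time is a free
ground-truth parameter.  A whiteout interval (loss of view, e.g. epiglottis
retroflexion) renders frames fully saturated.

The PAS generator emulates [pa:pa:] tokens: bilabial occlusions show an
intraoral pressure plateau at the target subglottic pressure with zero flow,
vowels show the target SPL/F0/flow with near-zero intraoral pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .aerodynamics import PASRecording
from .kymography import FrameStack, Kymogram

__all__ = [
    "GlottisSimParams",
    "GlottisGroundTruth",
    "PASToken",
    "PASSimParams",
    "PASTokenTruth",
    "generate_glottis_frames",
    "generate_kymogram_direct",
    "generate_pas_trace",
    "table1_fixture",
    "table1_printed_derived",
    "pas_params_from_table1",
    "TISSUE_INTENSITY",
    "GAP_INTENSITY",
]

#: Rendering intensities (8-bit): bright fold tissue, dark glottal gap,
#: and the saturated level used for whiteout frames.
TISSUE_INTENSITY = 200.0
GAP_INTENSITY = 25.0
WHITEOUT_INTENSITY = 255


@dataclass(frozen=True)
class GlottisSimParams:
    """Parameters of the synthetic glottis recording.

    Defaults describe a modal female token imaged at 2000 fps in the
    320x240 analysis format.  ``closed_quotient`` is the fraction of each
    steady cycle with zero width (0..0.8); ``asymmetry`` is the left/right
    amplitude ratio; ``prephonation_delay_ms`` separates the adduction
    criterion from oscillation start.  Identical seeds give bit-identical
    output.
    """

    fps: float = 2000.0
    duration_s: float = 1.0
    frame_height: int = 240
    frame_width: int = 320
    fold_length_px: int = 141
    resting_half_gap_px: float = 40.0
    adduction_time_ms: float = 100.0
    prephonation_delay_ms: float = 100.0
    f0_hz: float = 200.0
    steady_amplitude_px: float = 15.0
    growth_tau_cycles: float = 1.5
    closed_quotient: float = 0.3
    asymmetry: float = 1.0
    noise_sd: float = 5.0
    pre_roll_ms: float = 100.0
    whiteout_interval_ms: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ValueError("frame dimensions must be positive")
        if not 0 <= self.closed_quotient <= 0.8:
            raise ValueError("closed_quotient must lie in [0, 0.8]")
        if self.f0_hz <= 0 or self.steady_amplitude_px <= 0:
            raise ValueError("f0 and amplitude must be positive")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.whiteout_interval_ms is not None:
            a, b = self.whiteout_interval_ms
            if not 0 <= a < b <= self.duration_s * 1000.0:
                raise ValueError("whiteout interval must lie within the recording")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def mid_scanline(self) -> int:
        """Row index of the mid-membranous scanline in rendered frames."""
        return self.frame_height // 2

    @property
    def posture_half_gap_px(self) -> float:
        """Final half-gap of the adduction ramp (see module docstring)."""
        return self.steady_amplitude_px * math.cos(math.pi * self.closed_quotient)


@dataclass
class GlottisGroundTruth:
    """Exact landmarks of a simulated token (0-based frame indices)."""

    adduction_start_frame: int
    adduction_criterion_frame: int | None
    oscillation_start_frame: int
    steady_state_frame: int
    true_f0_hz: float
    true_width_series: np.ndarray
    true_prephonation_frames: int | None
    true_cycles_to_steady: int
    whiteout_frames: tuple[int, int] | None = None  # half-open

    def __post_init__(self) -> None:
        seq = [
            self.adduction_start_frame,
            *(
                [self.adduction_criterion_frame]
                if self.adduction_criterion_frame is not None
                else []
            ),
            self.oscillation_start_frame,
            self.steady_state_frame,
        ]
        if any(b < a for a, b in zip(seq[:-1], seq[1:])):
            raise ValueError("landmark ordering violated")

    def to_dict(self) -> dict:
        return {
            "adduction_start_frame": self.adduction_start_frame,
            "adduction_criterion_frame": self.adduction_criterion_frame,
            "oscillation_start_frame": self.oscillation_start_frame,
            "steady_state_frame": self.steady_state_frame,
            "true_f0_hz": self.true_f0_hz,
            "true_prephonation_frames": self.true_prephonation_frames,
            "true_cycles_to_steady": self.true_cycles_to_steady,
            "whiteout_frames": list(self.whiteout_frames)
            if self.whiteout_frames
            else None,
        }


def _frame_at(t: float, fps: float) -> int:
    """First frame whose sample time is at or after ``t`` seconds."""
    return int(math.ceil(t * fps - 1e-9))


def _kinematics(p: GlottisSimParams):
    """Per-frame half-gap of each side plus exact landmark times."""
    n = p.n_frames
    t = np.arange(n) / p.fps
    t0 = p.pre_roll_ms / 1000.0
    t1 = t0 + p.adduction_time_ms / 1000.0
    g_rest = p.resting_half_gap_px
    g_final = p.posture_half_gap_px

    ramp = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    G = g_rest + (g_final - g_rest) * ramp

    crit_level = g_rest / 3.0
    if g_final < crit_level <= g_rest:
        t_crit = t0 + (g_rest - crit_level) / (g_rest - g_final) * (t1 - t0)
    else:
        t_crit = None
    t_osc = (t_crit if t_crit is not None else t1) + p.prephonation_delay_ms / 1000.0
    tau = p.growth_tau_cycles / p.f0_hz
    A = np.where(
        t >= t_osc,
        p.steady_amplitude_px * (1.0 - np.exp(-np.maximum(t - t_osc, 0.0) / tau)),
        0.0,
    )
    theta = 2.0 * np.pi * p.f0_hz * (t - t_osc)
    r = p.asymmetry
    amp_left = 2.0 * r / (1.0 + r)
    amp_right = 2.0 / (1.0 + r)
    osc = A * np.cos(theta)
    g_left = np.maximum(0.0, G - amp_left * osc)
    g_right = np.maximum(0.0, G - amp_right * osc)

    t_steady = t_osc + tau * math.log(10.0)  # amplitude within 10% of A_inf
    truth = GlottisGroundTruth(
        adduction_start_frame=_frame_at(t0, p.fps),
        adduction_criterion_frame=None if t_crit is None else _frame_at(t_crit, p.fps),
        # landmark frames may lie beyond the recording when it ends early
        oscillation_start_frame=_frame_at(t_osc, p.fps),
        steady_state_frame=_frame_at(t_steady, p.fps),
        true_f0_hz=p.f0_hz,
        true_width_series=g_left + g_right,
        true_prephonation_frames=None
        if t_crit is None
        else _frame_at(t_osc, p.fps) - _frame_at(t_crit, p.fps),
        true_cycles_to_steady=int(math.floor(p.growth_tau_cycles * math.log(10.0))),
        whiteout_frames=None
        if p.whiteout_interval_ms is None
        else (
            _frame_at(p.whiteout_interval_ms[0] / 1000.0, p.fps),
            min(_frame_at(p.whiteout_interval_ms[1] / 1000.0, p.fps), n),
        ),
    )
    return g_left, g_right, truth


def _render_rows(
    g_left: np.ndarray, g_right: np.ndarray, width_px: int
) -> np.ndarray:
    """Anti-aliased rendering of dark gaps into (N, W) float rows.

    Pixel ``j`` spans ``[j-0.5, j+0.5)``; its darkness is the fractional
    coverage by the gap ``[center - g_left, center + g_right]``.
    """
    center = (width_px - 1) / 2.0
    cols = np.arange(width_px, dtype=np.float64)
    left = center - np.asarray(g_left)[:, None]
    right = center + np.asarray(g_right)[:, None]
    cov = np.clip(
        np.minimum(cols + 0.5, right) - np.maximum(cols - 0.5, left), 0.0, 1.0
    )
    return TISSUE_INTENSITY - (TISSUE_INTENSITY - GAP_INTENSITY) * cov


def _quantize(rows: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        rows = rows + rng.normal(0.0, noise_sd, size=rows.shape)
    return np.clip(np.rint(rows), 0, 255).astype(np.uint8)


def generate_kymogram_direct(
    params: GlottisSimParams,
) -> tuple[Kymogram, GlottisGroundTruth]:
    """Render the mid-membranous kymogram directly (fast path, no frames)."""
    g_left, g_right, truth = _kinematics(params)
    rows = _render_rows(g_left, g_right, params.frame_width)
    if truth.whiteout_frames is not None:
        a, b = truth.whiteout_frames
        rows[a:b] = WHITEOUT_INTENSITY
    rng = np.random.default_rng(params.seed)
    rows = _quantize(rows, params.noise_sd, rng)
    kym = Kymogram(
        rows=rows,
        scanline_index=params.mid_scanline,
        fps=params.fps,
        source_id=f"synthetic(seed={params.seed})",
    )
    return kym, truth


def generate_glottis_frames(
    params: GlottisSimParams,
) -> tuple[FrameStack, GlottisGroundTruth]:
    """Render the full synthetic frame stack.

    The glottal gap tapers sinusoidally along the anterior--posterior fold
    extent and is widest at the mid-membranous scanline, where the taper is
    exactly 1 so the extracted kymogram matches the direct fast path.
    """
    g_left, g_right, truth = _kinematics(params)
    h, w = params.frame_height, params.frame_width
    fold_len = params.fold_length_px
    if fold_len % 2 == 0:
        fold_len += 1  # odd length puts the taper maximum exactly mid-fold
    fold_len = min(fold_len, h if h % 2 else h - 1)
    mid = params.mid_scanline
    r0 = mid - (fold_len - 1) // 2
    if r0 < 0:
        raise ValueError("fold_length_px too large for frame_height")

    taper = np.zeros(h)
    idx = np.arange(r0, r0 + fold_len)
    taper[idx] = np.sin(np.pi * (idx - r0 + 0.5) / fold_len)

    rng = np.random.default_rng(params.seed)
    frames = np.empty((params.n_frames, h, w), dtype=np.uint8)
    whiteout = truth.whiteout_frames
    for f in range(params.n_frames):
        if whiteout is not None and whiteout[0] <= f < whiteout[1]:
            plane = np.full((h, w), float(WHITEOUT_INTENSITY))
        else:
            plane = _render_rows(taper * g_left[f], taper * g_right[f], w)
        frames[f] = _quantize(plane, params.noise_sd, rng)
    stack = FrameStack(
        frames=frames,
        fps=params.fps,
        source_id=f"synthetic(seed={params.seed})",
    )
    return stack, truth


# ---------------------------------------------------------------------------
# PAS simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PASToken:
    """Targets for one [pa:pa:] token at a given loudness."""

    label: str
    target_spl_db: float
    target_f0_hz: float
    target_flow_ccps: float
    target_psub_cmh2o: float
    n_syllables: int = 4
    syllable_rate_hz: float = 2.5
    occlusion_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.label not in ("soft", "modal", "loud"):
            raise ValueError("label must be soft/modal/loud")
        if min(
            self.target_spl_db,
            self.target_f0_hz,
            self.target_flow_ccps,
            self.target_psub_cmh2o,
        ) <= 0:
            raise ValueError("per-token targets must be positive")
        if not 0 < self.occlusion_fraction < 0.6:
            raise ValueError("occlusion_fraction must lie in (0, 0.6)")
        if self.n_syllables < 2:
            raise ValueError("need at least two syllables per token")


_DEFAULT_TOKENS = (
    PASToken("soft", 74.0, 161.0, 100.0, 4.0),
    PASToken("modal", 84.0, 157.0, 110.0, 5.3),
    PASToken("loud", 87.0, 186.0, 130.0, 10.0),
)


@dataclass(frozen=True)
class PASSimParams:
    """Synthetic PAS recording: ordered tokens with silence gaps between."""

    sample_rate_hz: float = 250.0
    tokens: tuple[PASToken, ...] = _DEFAULT_TOKENS
    lead_s: float = 0.75
    gap_s: float = 1.2
    ambient_spl_db: float = 50.0
    noise_spl_db: float = 0.3
    noise_f0_hz: float = 1.0
    noise_flow_ccps: float = 4.0
    noise_pressure_cmh2o: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.tokens:
            raise ValueError("need at least one token")
        if self.gap_s <= 0:
            raise ValueError("tokens must not overlap: gap_s must be positive")


@dataclass
class PASTokenTruth:
    """Ground truth for one generated token."""

    label: str
    start_s: float  # first occlusion onset
    end_s: float
    voiced_start_s: float  # first vowel onset
    voiced_end_s: float
    targets: PASToken


def generate_pas_trace(
    params: PASSimParams,
) -> tuple[PASRecording, list[PASTokenTruth]]:
    """Render the four PAS channels for the configured token sequence."""
    fs = params.sample_rate_hz
    total = params.lead_s + sum(
        tok.n_syllables / tok.syllable_rate_hz + params.gap_s for tok in params.tokens
    )
    n = int(round(total * fs))
    spl = np.full(n, params.ambient_spl_db)
    f0 = np.zeros(n)
    flow = np.zeros(n)
    pressure = np.zeros(n)

    truths: list[PASTokenTruth] = []
    t_cursor = params.lead_s
    for tok in params.tokens:
        period = 1.0 / tok.syllable_rate_hz
        occ = tok.occlusion_fraction * period
        for k in range(tok.n_syllables):
            t_occ = t_cursor + k * period
            a, b = int(round(t_occ * fs)), int(round((t_occ + occ) * fs))
            pressure[a:b] = tok.target_psub_cmh2o
            a, b = b, int(round((t_occ + period) * fs))
            spl[a:b] = tok.target_spl_db
            f0[a:b] = tok.target_f0_hz
            flow[a:b] = tok.target_flow_ccps
        truths.append(
            PASTokenTruth(
                label=tok.label,
                start_s=t_cursor,
                end_s=t_cursor + tok.n_syllables * period,
                voiced_start_s=t_cursor + occ,
                voiced_end_s=t_cursor + tok.n_syllables * period,
                targets=tok,
            )
        )
        t_cursor += tok.n_syllables * period + params.gap_s

    rng = np.random.default_rng(params.seed)
    if params.noise_spl_db > 0:
        spl = spl + rng.normal(0, params.noise_spl_db, n)
    if params.noise_f0_hz > 0:
        f0 = f0 + rng.normal(0, params.noise_f0_hz, n)
    if params.noise_flow_ccps > 0:
        flow = flow + rng.normal(0, params.noise_flow_ccps, n)
    if params.noise_pressure_cmh2o > 0:
        pressure = pressure + rng.normal(0, params.noise_pressure_cmh2o, n)

    rec = PASRecording(
        sample_rate_hz=fs,
        f0_hz=f0,
        spl_db=spl,
        flow_ccps=flow,
        pressure_cmh2o=pressure,
    )
    return rec, truths


# ---------------------------------------------------------------------------
# Embedded per-token measurement table
# ---------------------------------------------------------------------------


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("kymovox.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def table1_fixture() -> pd.DataFrame:
    """The embedded per-token measurement table: 18 rows (6 subjects x 3
    tokens) of subject, sex, age, token, SPL (dB), F0 (Hz), flow (cc/s) and
    subglottic pressure (cm H2O).  Derived columns are intentionally absent;
    they are recomputed downstream (:func:`kymovox.aerodynamics.derived_table`).
    """
    return _read_packaged_csv("table1.csv")


def table1_printed_derived() -> pd.DataFrame:
    """The published derived columns (resistance, dB change, resistance
    change, resistance change per dB) at their printed precision — used only
    as the cross-check reference for recomputation, never as an input.
    """
    return _read_packaged_csv("table1_printed_derived.csv")


def pas_params_from_table1(
    subject: int,
    sample_rate_hz: float = 250.0,
    noiseless: bool = True,
    seed: int = 0,
) -> PASSimParams:
    """Build PAS simulation targets from one subject's fixture rows."""
    df = table1_fixture()
    sub = df[df["subject"] == subject]
    if sub.empty:
        raise ValueError(f"no such subject: {subject}")
    tokens = tuple(
        PASToken(
            label=row["token"],
            target_spl_db=float(row["spl_db"]),
            target_f0_hz=float(row["f0_hz"]),
            target_flow_ccps=float(row["flow_ccps"]),
            target_psub_cmh2o=float(row["psub_cmh2o"]),
        )
        for _, row in sub.iterrows()
    )
    kwargs = dict(sample_rate_hz=sample_rate_hz, tokens=tokens, seed=seed)
    if noiseless:
        kwargs.update(
            noise_spl_db=0.0,
            noise_f0_hz=0.0,
            noise_flow_ccps=0.0,
            noise_pressure_cmh2o=0.0,
        )
    return PASSimParams(**kwargs)
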