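"""Acoustic--aerodynamic analysis of phonatory aerodynamic (PAS) recordings.

A PAS recording carries four synchronous channels — fundamental frequency
(Hz), sound pressure level (dB), mean airflow (cc/s), and intraoral
pressure (cm H2O) — while the speaker produces [pa:pa:] tokens at soft,
modal (medium) and loud targets.  During each bilabial [p] occlusion the
intraoral pressure equilibrates with the subglottic pressure, so the vowel
subglottic pressure is estimated by interpolating between the flanking
occlusion plateaus.  Glottal (laryngeal airway) resistance is subglottic
pressure over mean flow, scaled to cm H2O per L/s::

    R = (Psub / U) * 1000     [Psub in cm H2O, U in cc/s]

Group summaries reproduce the study-style tables: sex-stratified means/SDs,
per-loudness mean subglottic pressures, the soft->loud SPL rise, and a
paired t contrast of the resistance-change-per-dB between the soft->modal
and modal->loud transitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PASRecording",
    "TokenInterval",
    "TokenMeasures",
    "DerivedMeasures",
    "GroupSummary",
    "LEVELS",
    "segment_tokens",
    "estimate_subglottic_pressure",
    "token_means",
    "average_repetitions",
    "resistance",
    "token_deltas",
    "derived_table",
    "group_summary",
    "paired_t",
    "round_half_up",
]

LEVELS = ("soft", "modal", "loud")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PASRecording:
    """Multichannel phonatory-aerodynamic trace plus subject metadata."""

    sample_rate_hz: float
    f0_hz: np.ndarray
    spl_db: np.ndarray
    flow_ccps: np.ndarray
    pressure_cmh2o: np.ndarray
    subject_id: str = ""
    sex: str = ""
    age: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        lengths = {
            len(self.f0_hz),
            len(self.spl_db),
            len(self.flow_ccps),
            len(self.pressure_cmh2o),
        }
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    def __len__(self) -> int:
        return len(self.spl_db)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "f0_hz": self.f0_hz,
                "spl_db": self.spl_db,
                "flow_ccps": self.flow_ccps,
                "pressure_cmh2o": self.pressure_cmh2o,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "PASRecording":
        df = pd.read_csv(path)
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
        return cls(
            sample_rate_hz=fs,
            f0_hz=df["f0_hz"].to_numpy(float),
            spl_db=df["spl_db"].to_numpy(float),
            flow_ccps=df["flow_ccps"].to_numpy(float),
            pressure_cmh2o=df["pressure_cmh2o"].to_numpy(float),
            **meta,
        )


@dataclass
class TokenInterval:
    label: str
    start_s: float
    end_s: float
    start_idx: int
    end_idx: int  # exclusive


@dataclass
class TokenMeasures:
    """Per-token means of SPL, F0, flow, and subglottic pressure."""

    label: str
    spl_db: float
    f0_hz: float
    flow_ccps: float
    psub_cmh2o: float

    def __post_init__(self) -> None:
        if self.label not in LEVELS:
            raise ValueError(f"label must be one of {LEVELS}")


@dataclass
class DerivedMeasures:
    """Resistance-based quantities for one loudness transition."""

    transition: str  # e.g. "soft->modal"
    resistance_from: float
    resistance_to: float
    db_change: float
    resistance_change: float
    resistance_change_per_db: float | None  # None when db_change == 0


@dataclass
class GroupSummary:
    """Group-level statistics across subjects."""

    sex_stats: pd.DataFrame
    psub_by_level: dict[str, float]
    mean_spl_rise_db: float
    per_db: pd.DataFrame  # one row per subject: soft_modal, modal_loud
    contrast_mean: dict[str, float]
    contrast_sd: dict[str, float]
    t_statistic: float
    t_df: int
    p_two_sided: float
    p_one_sided: float
    n_subjects: int


# ---------------------------------------------------------------------------
# Segmentation and per-token measures
# ---------------------------------------------------------------------------


def segment_tokens(
    rec: PASRecording,
    spl_floor_db: float = 65.0,
    min_duration_ms: float = 300.0,
    merge_gap_ms: float = 400.0,
    label_sequence: tuple[str, ...] | None = None,
) -> list[TokenInterval]:
    """Find voiced token intervals as maximal supra-floor SPL runs.

    Runs of ``spl >= spl_floor_db`` separated by gaps shorter than
    ``merge_gap_ms`` (the brief bilabial occlusions inside a token) are
    merged; merged runs shorter than ``min_duration_ms`` are dropped.
    Labels follow ``label_sequence`` (default ``soft, modal, loud`` for 3
    tokens and ``soft, soft, modal, modal, loud, loud`` for 6, matching the
    fixed recording order); on a count mismatch a warning is issued and
    labels are assigned by rank of mean SPL instead.
    """
    fs = rec.sample_rate_hz
    above = np.asarray(rec.spl_db) >= spl_floor_db
    runs = _bool_runs(above)
    if not runs:
        return []

    merge_gap = merge_gap_ms / 1000.0 * fs
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = min_duration_ms / 1000.0 * fs
    merged = [m for m in merged if m[1] - m[0] >= min_len]

    n = len(merged)
    if label_sequence is None:
        label_sequence = {
            3: ("soft", "modal", "loud"),
            6: ("soft", "soft", "modal", "modal", "loud", "loud"),
        }.get(n, ())
    if len(label_sequence) == n:
        labels = list(label_sequence)
    else:
        if label_sequence:
            warnings.warn(
                f"found {n} tokens but expected {len(label_sequence)}; "
                "labelling by rank of mean SPL",
                stacklevel=2,
            )
        mean_spl = [float(np.mean(rec.spl_db[a:b])) for a, b in merged]
        order = np.argsort(np.argsort(mean_spl))
        labels = [LEVELS[min(2, int(r * 3 / max(n, 1)))] for r in order]

    return [
        TokenInterval(
            label=lab,
            start_s=a / fs,
            end_s=b / fs,
            start_idx=int(a),
            end_idx=int(b),
        )
        for lab, (a, b) in zip(labels, merged)
    ]


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def estimate_subglottic_pressure(
    rec: PASRecording,
    interval: TokenInterval,
    peak_fraction: float = 0.7,
    min_peak_separation_ms: float = 150.0,
    pad_s: float = 0.0,
) -> float:
    """Estimate vowel subglottic pressure from intraoral occlusion plateaus.

    Occlusion peaks are local pressure maxima above ``peak_fraction`` of the
    interval maximum, separated by at least ``min_peak_separation_ms``.
    Each vowel between two consecutive peaks is assigned the linear
    interpolation of the flanking plateau values at the vowel midpoint; the
    token pressure is the mean over those interior vowels.  Fewer than two
    peaks is an error (nothing to interpolate between).
    """
    fs = rec.sample_rate_hz
    pad = int(round(pad_s * fs))
    a = max(0, interval.start_idx - pad)
    b = min(len(rec), interval.end_idx + pad)
    p = np.asarray(rec.pressure_cmh2o[a:b], dtype=float)
    if p.size == 0:
        raise ValueError("empty interval")
    height = peak_fraction * p.max()
    distance = max(1, int(round(min_peak_separation_ms / 1000.0 * fs)))
    peaks, props = signal.find_peaks(p, height=height, distance=distance, plateau_size=1)
    if peaks.size < 2:
        raise ValueError(
            f"need >= 2 occlusion peaks to interpolate, found {peaks.size}"
        )
    # plateau value: median over the flat region around each peak (robust to
    # sample noise, unlike the single maximum sample)
    plateau_vals = np.empty(peaks.size)
    for i, pk in enumerate(peaks):
        lo = max(0, pk - distance // 2)
        hi = min(p.size, pk + distance // 2 + 1)
        region = p[lo:hi]
        flat = region[region >= 0.9 * p[pk]]
        plateau_vals[i] = float(np.median(flat)) if flat.size else float(p[pk])
    # vowel midpoints between consecutive occlusions
    estimates = 0.5 * (plateau_vals[:-1] + plateau_vals[1:])
    return float(np.mean(estimates))


def token_means(
    rec: PASRecording,
    interval: TokenInterval,
    spl_floor_db: float = 65.0,
    psub_kwargs: dict | None = None,
) -> TokenMeasures:
    """Mean SPL/F0/flow over voiced (vowel) samples plus interpolated Psub."""
    a, b = interval.start_idx, interval.end_idx
    voiced = np.asarray(rec.spl_db[a:b]) >= spl_floor_db
    if not voiced.any():
        raise ValueError("no voiced samples in interval")
    psub = estimate_subglottic_pressure(rec, interval, **(psub_kwargs or {}))
    return TokenMeasures(
        label=interval.label,
        spl_db=float(np.mean(np.asarray(rec.spl_db[a:b])[voiced])),
        f0_hz=float(np.mean(np.asarray(rec.f0_hz[a:b])[voiced])),
        flow_ccps=float(np.mean(np.asarray(rec.flow_ccps[a:b])[voiced])),
        psub_cmh2o=psub,
    )


def average_repetitions(measures: list[TokenMeasures]) -> list[TokenMeasures]:
    """Average repeated tokens of the same label into one record per level."""
    out = []
    for level in LEVELS:
        reps = [m for m in measures if m.label == level]
        if not reps:
            continue
        out.append(
            TokenMeasures(
                label=level,
                spl_db=float(np.mean([m.spl_db for m in reps])),
                f0_hz=float(np.mean([m.f0_hz for m in reps])),
                flow_ccps=float(np.mean([m.flow_ccps for m in reps])),
                psub_cmh2o=float(np.mean([m.psub_cmh2o for m in reps])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Derived resistance quantities
# ---------------------------------------------------------------------------


def resistance(psub_cmh2o: float, flow_ccps: float) -> float:
    """Glottal resistance (pressure/flow) x 1000, in cm H2O per L/s."""
    if flow_ccps <= 0:
        raise ValueError("flow must be positive")
    return psub_cmh2o / flow_ccps * 1000.0


def token_deltas(measures: list[TokenMeasures]) -> list[DerivedMeasures]:
    """Per-transition dB change, resistance change, and change per dB.

    ``measures`` must be ordered soft -> modal -> loud (any contiguous
    subsequence of at least two levels is accepted).
    """
    if len(measures) < 2:
        raise ValueError("need at least two ordered tokens")
    order = [LEVELS.index(m.label) for m in measures]
    if order != sorted(order) or len(set(order)) != len(order):
        raise ValueError("tokens must be ordered soft -> modal -> loud")
    out = []
    for prev, cur in zip(measures[:-1], measures[1:]):
        r_prev = resistance(prev.psub_cmh2o, prev.flow_ccps)
        r_cur = resistance(cur.psub_cmh2o, cur.flow_ccps)
        db_change = cur.spl_db - prev.spl_db
        r_change = r_cur - r_prev
        per_db = r_change / db_change if db_change != 0 else None
        out.append(
            DerivedMeasures(
                transition=f"{prev.label}->{cur.label}",
                resistance_from=r_prev,
                resistance_to=r_cur,
                db_change=db_change,
                resistance_change=r_change,
                resistance_change_per_db=per_db,
            )
        )
    return out


def derived_table(tokens: pd.DataFrame) -> pd.DataFrame:
    """Recompute the derived columns for a per-token measurement table.

    ``tokens`` needs columns ``subject, token, spl_db, f0_hz, flow_ccps,
    psub_cmh2o`` with tokens soft/modal/loud per subject.  Returns a copy
    with ``resistance``, ``db_change``, ``resistance_change`` and
    ``resistance_change_per_db`` columns (NaN on each subject's first row),
    subjects in input order and rows ordered soft -> modal -> loud.
    """
    df = tokens.copy()
    df["_level"] = df["token"].map({lev: i for i, lev in enumerate(LEVELS)})
    if df["_level"].isna().any():
        raise ValueError(f"token labels must be in {LEVELS}")
    df = df.sort_values(["subject", "_level"], kind="stable").drop(columns="_level")
    df["resistance"] = df["psub_cmh2o"] / df["flow_ccps"] * 1000.0
    grp = df.groupby("subject", sort=False)
    df["db_change"] = grp["spl_db"].diff()
    df["resistance_change"] = grp["resistance"].diff()
    df["resistance_change_per_db"] = df["resistance_change"] / df["db_change"]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test from its closed form.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = y - x`` and the n-1
    denominator in ``sd``; returns ``(t, df, p_two_sided)``.
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def group_summary(tokens: pd.DataFrame) -> GroupSummary:
    """Group-level tables from per-token measures of all subjects.

    ``tokens`` needs columns ``subject, sex, token, spl_db, f0_hz,
    flow_ccps, psub_cmh2o``.  Subjects with an incomplete soft/modal/loud
    triple are excluded with a warning.  SDs use the n-1 denominator.
    """
    df = derived_table(tokens)
    complete = (
        df.groupby("subject")["token"].apply(lambda s: set(s) == set(LEVELS))
    )
    bad = complete[~complete].index.tolist()
    if bad:
        warnings.warn(f"excluding subjects with incomplete triples: {bad}", stacklevel=2)
        df = df[~df["subject"].isin(bad)]
    if df["subject"].nunique() < 2:
        raise ValueError("need at least two subjects with complete token triples")

    df["sex"] = df["sex"].astype(str).str.lower().str[0].map({"m": "male", "f": "female"})
    sex_stats = (
        df.groupby("sex")[["f0_hz", "flow_ccps", "psub_cmh2o"]]
        .agg(["mean", lambda s: s.std(ddof=1)])
        .rename(columns={"<lambda_0>": "sd"}, level=1)
    )

    psub_by_level = {
        lev: float(df.loc[df["token"] == lev, "psub_cmh2o"].mean()) for lev in LEVELS
    }
    wide_spl = df.pivot(index="subject", columns="token", values="spl_db")
    mean_spl_rise = float((wide_spl["loud"] - wide_spl["soft"]).mean())

    per_db = df.pivot(
        index="subject", columns="token", values="resistance_change_per_db"
    )[["modal", "loud"]].rename(columns={"modal": "soft_modal", "loud": "modal_loud"})
    contrast_mean = {c: float(per_db[c].mean()) for c in per_db.columns}
    contrast_sd = {c: float(per_db[c].std(ddof=1)) for c in per_db.columns}
    t, t_df, p2 = paired_t(per_db["soft_modal"], per_db["modal_loud"])
    p1 = float(stats.t.sf(t, t_df))

    return GroupSummary(
        sex_stats=sex_stats,
        psub_by_level=psub_by_level,
        mean_spl_rise_db=mean_spl_rise,
        per_db=per_db,
        contrast_mean=contrast_mean,
        contrast_sd=contrast_sd,
        t_statistic=t,
        t_df=t_df,
        p_two_sided=p2,
        p_one_sided=p1,
        n_subjects=int(df["subject"].nunique()),
    )
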