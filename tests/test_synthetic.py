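"""Generator properties: determinism, landmark ordering, waveform truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymovox.aerodynamics import segment_tokens
from kymovox.synthetic import (
    GlottisSimParams,
    PASSimParams,
    PASToken,
    generate_glottis_frames,
    generate_kymogram_direct,
    generate_pas_trace,
    table1_fixture,
)


def test_same_seed_gives_identical_frames():
    params = GlottisSimParams(duration_s=0.1, seed=7)
    a, _ = generate_glottis_frames(params)
    b, _ = generate_glottis_frames(params)
    assert np.array_equal(a.frames, b.frames)
    ka, _ = generate_kymogram_direct(params)
    kb, _ = generate_kymogram_direct(params)
    assert np.array_equal(ka.rows, kb.rows)


def test_different_seed_changes_noise():
    a, _ = generate_kymogram_direct(GlottisSimParams(duration_s=0.1, seed=1))
    b, _ = generate_kymogram_direct(GlottisSimParams(duration_s=0.1, seed=2))
    assert not np.array_equal(a.rows, b.rows)


def test_zero_closed_quotient_width_is_sinusoidal():
    """With cq=0 the steady width never clips: a pure sinusoid about the
    posture gap."""
    p = GlottisSimParams(
        noise_sd=0.0, duration_s=0.6, closed_quotient=0.0, steady_amplitude_px=10.0
    )
    _, truth = generate_kymogram_direct(p)
    w = truth.true_width_series[truth.steady_state_frame + 40 :]
    t = np.arange(w.size)
    # least-squares single-tone fit explains essentially all variance
    design = np.column_stack(
        [
            np.cos(2 * np.pi * p.f0_hz / p.fps * t),
            np.sin(2 * np.pi * p.f0_hz / p.fps * t),
            np.ones_like(t, dtype=float),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    resid = w - design @ coef
    assert np.max(np.abs(resid)) < 0.05 * np.ptp(w)
    assert np.min(w) > 0  # never fully closed


def test_oscillation_period_matches_f0_by_zero_crossings():
    """f0=200 at 2000 fps -> 10-frame period, counted via mean crossings."""
    p = GlottisSimParams(
        noise_sd=0.0, duration_s=0.8, f0_hz=200.0, fps=2000.0, growth_tau_cycles=1.0
    )
    _, truth = generate_kymogram_direct(p)
    w = truth.true_width_series[truth.steady_state_frame + 20 :]
    x = w - w.mean()
    crossings = np.flatnonzero(np.diff(np.signbit(x)))
    periods = 2 * np.diff(crossings)
    assert abs(np.mean(periods) - 10.0) < 0.5


@settings(max_examples=20, deadline=None)
@given(
    cq=st.floats(0.0, 0.8),
    amp=st.floats(5.0, 30.0),
    delay=st.floats(20.0, 300.0),
    tau=st.floats(0.5, 3.0),
)
def test_landmark_ordering_invariant(cq, amp, delay, tau):
    p = GlottisSimParams(
        duration_s=0.8,
        closed_quotient=cq,
        steady_amplitude_px=amp,
        prephonation_delay_ms=delay,
        growth_tau_cycles=tau,
        resting_half_gap_px=60.0,
    )
    _, truth = generate_kymogram_direct(p)
    assert truth.adduction_start_frame <= truth.oscillation_start_frame
    if truth.adduction_criterion_frame is not None:
        assert truth.adduction_start_frame <= truth.adduction_criterion_frame
        assert truth.adduction_criterion_frame <= truth.oscillation_start_frame
    assert truth.oscillation_start_frame <= truth.steady_state_frame


def test_whiteout_rows_are_saturated():
    p = GlottisSimParams(duration_s=0.5, whiteout_interval_ms=(200.0, 300.0), seed=3)
    kym, truth = generate_kymogram_direct(p)
    a, b = truth.whiteout_frames
    assert (kym.rows[a:b] >= 230).all()
    assert not (kym.rows[:a] >= 230).all()


def test_whiteout_outside_recording_rejected():
    with pytest.raises(ValueError):
        GlottisSimParams(duration_s=0.2, whiteout_interval_ms=(100.0, 300.0))


def test_symmetric_fold_excursions_mirror_about_midline():
    p = GlottisSimParams(noise_sd=0.0, duration_s=0.5, asymmetry=1.0)
    kym, truth = generate_kymogram_direct(p)
    from kymovox.edge_tracking import track_edges

    vib = track_edges(kym)
    center = (kym.width - 1) / 2.0
    open_enough = vib.valid & (vib.width_px > 4)
    left_exc = center - vib.left_px[open_enough]
    right_exc = vib.right_px[open_enough] - center
    assert np.max(np.abs(left_exc - right_exc)) <= 0.5


def test_invalid_dimensions_rejected():
    with pytest.raises(ValueError):
        GlottisSimParams(frame_width=0)
    with pytest.raises(ValueError):
        GlottisSimParams(closed_quotient=0.9)


# ---------------------------------------------------------------------------
# PAS generator
# ---------------------------------------------------------------------------


def _noiseless_pas(tokens):
    return PASSimParams(
        tokens=tokens,
        noise_spl_db=0.0,
        noise_f0_hz=0.0,
        noise_flow_ccps=0.0,
        noise_pressure_cmh2o=0.0,
    )


def test_noiseless_occlusion_plateau_equals_target():
    tok = PASToken("modal", 84.0, 157.0, 110.0, 9.0)
    rec, truths = generate_pas_trace(_noiseless_pas((tok,)))
    t = truths[0]
    fs = rec.sample_rate_hz
    a = int(round(t.start_s * fs)) + 1
    b = int(round(t.voiced_start_s * fs)) - 1
    assert np.allclose(rec.pressure_cmh2o[a:b], 9.0)
    # and zero flow during the occlusion, target flow during the vowel
    assert np.allclose(rec.flow_ccps[a:b], 0.0)
    v = slice(b + 2, b + 5)
    assert np.allclose(rec.flow_ccps[v], 110.0)


def test_three_token_trace_segments_into_three_intervals():
    rec, truths = generate_pas_trace(PASSimParams(seed=5))
    intervals = segment_tokens(rec)
    assert [iv.label for iv in intervals] == ["soft", "modal", "loud"]
    for iv, t in zip(intervals, truths):
        assert abs(iv.start_s - t.voiced_start_s) <= 0.010
        assert abs(iv.end_s - t.voiced_end_s) <= 0.010


def test_pas_determinism():
    a, _ = generate_pas_trace(PASSimParams(seed=9))
    b, _ = generate_pas_trace(PASSimParams(seed=9))
    assert np.array_equal(a.pressure_cmh2o, b.pressure_cmh2o)
    assert np.array_equal(a.spl_db, b.spl_db)


def test_occlusion_fraction_validated():
    with pytest.raises(ValueError):
        PASToken("soft", 74.0, 110.0, 210.0, 3.0, occlusion_fraction=0.7)


# ---------------------------------------------------------------------------
# Embedded measurement table
# ---------------------------------------------------------------------------


def test_table_has_all_18_rows():
    df = table1_fixture()
    assert len(df) == 18
    assert df.groupby("subject").size().eq(3).all()


@pytest.mark.parametrize(
    "subject, token, expected",
    [
        (1, "soft", (74, 110, 210, 3.0)),
        (5, "loud", (90, 217, 60, 15.0)),
        (4, "modal", (84, 157, 110, 5.3)),
    ],
)
def test_table_rows_match_published_values(subject, token, expected):
    df = table1_fixture()
    row = df[(df["subject"] == subject) & (df["token"] == token)].iloc[0]
    assert (
        row["spl_db"],
        row["f0_hz"],
        row["flow_ccps"],
        row["psub_cmh2o"],
    ) == expected


def test_table_contains_no_derived_columns():
    assert "resistance" not in table1_fixture().columns
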