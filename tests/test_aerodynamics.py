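"""Aerodynamic arithmetic, segmentation, Psub interpolation, group stats."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kymovox.aerodynamics import (
    PASRecording,
    TokenInterval,
    TokenMeasures,
    average_repetitions,
    derived_table,
    estimate_subglottic_pressure,
    group_summary,
    paired_t,
    resistance,
    segment_tokens,
    token_deltas,
    token_means,
)
from kymovox.synthetic import (
    PASSimParams,
    PASToken,
    generate_pas_trace,
    pas_params_from_table1,
    table1_fixture,
    table1_printed_derived,
)


@pytest.mark.parametrize(
    "psub, flow, expected",
    [(3.0, 210.0, 14.28571), (15.0, 60.0, 250.0), (0.0, 100.0, 0.0)],
)
def test_resistance_formula(psub, flow, expected):
    assert resistance(psub, flow) == pytest.approx(expected, abs=5e-5)


def test_resistance_requires_positive_flow():
    with pytest.raises(ValueError):
        resistance(5.0, 0.0)


def test_recomputed_resistance_matches_all_printed_rows():
    computed = derived_table(table1_fixture())
    printed = table1_printed_derived()
    merged = computed.merge(printed, on=["subject", "token"], suffixes=("", "_pub"))
    assert len(merged) == 18
    assert np.max(np.abs(merged["resistance"] - merged["resistance_pub"])) < 5e-5


def test_recomputed_transition_columns_match_printed_rows():
    computed = derived_table(table1_fixture())
    printed = table1_printed_derived()
    merged = computed.merge(printed, on=["subject", "token"], suffixes=("", "_pub"))
    for col in ("db_change", "resistance_change", "resistance_change_per_db"):
        rows = merged[merged[f"{col}_pub"].notna()]
        assert len(rows) == 12
        assert np.max(np.abs(rows[col] - rows[f"{col}_pub"])) < 5e-5


def test_resistance_changes_chain_to_total():
    df = derived_table(table1_fixture())
    for _, sub in df.groupby("subject"):
        total = sub["resistance"].iloc[-1] - sub["resistance"].iloc[0]
        assert sub["resistance_change"].dropna().sum() == pytest.approx(total)


def _measures(spl, f0, flow, psub, labels=("soft", "modal", "loud")):
    return [
        TokenMeasures(lab, s, f, fl, p)
        for lab, s, f, fl, p in zip(labels, spl, f0, flow, psub)
    ]


def test_token_deltas_known_transitions():
    # subject 5 of the embedded table
    ms = _measures([76, 85, 90], [212, 215, 217], [100, 80, 60], [6, 9, 15])
    deltas = token_deltas(ms)
    assert deltas[1].resistance_change_per_db == pytest.approx(27.5)
    # subject 2, soft->modal
    ms2 = _measures([70, 83], [102, 121], [79, 132], [4, 5], labels=("soft", "modal"))
    assert token_deltas(ms2)[0].resistance_change_per_db == pytest.approx(
        -0.98109, abs=5e-5
    )


def test_identical_tokens_have_undefined_per_db():
    ms = _measures([80, 80], [150, 150], [100, 100], [5, 5], labels=("soft", "modal"))
    d = token_deltas(ms)[0]
    assert d.db_change == 0 and d.resistance_change == 0
    assert d.resistance_change_per_db is None


def test_silent_trace_has_no_tokens():
    rec = PASRecording(
        sample_rate_hz=250.0,
        f0_hz=np.zeros(1000),
        spl_db=np.full(1000, 50.0),
        flow_ccps=np.zeros(1000),
        pressure_cmh2o=np.zeros(1000),
    )
    assert segment_tokens(rec) == []


def test_six_token_trace_labels_by_recording_order():
    tokens = tuple(
        PASToken(lab, spl, 180.0, 100.0, 6.0)
        for lab, spl in [
            ("soft", 74.0),
            ("soft", 74.5),
            ("modal", 84.0),
            ("modal", 84.5),
            ("loud", 90.0),
            ("loud", 90.5),
        ]
    )
    rec, _ = generate_pas_trace(PASSimParams(tokens=tokens, seed=2))
    labels = [iv.label for iv in segment_tokens(rec)]
    assert labels == ["soft", "soft", "modal", "modal", "loud", "loud"]


def test_psub_recovery_noiseless():
    tok = PASToken("modal", 84.0, 157.0, 110.0, 9.0)
    params = PASSimParams(
        tokens=(tok,),
        noise_spl_db=0.0,
        noise_f0_hz=0.0,
        noise_flow_ccps=0.0,
        noise_pressure_cmh2o=0.0,
    )
    rec, _ = generate_pas_trace(params)
    (iv,) = segment_tokens(rec)
    assert estimate_subglottic_pressure(rec, iv) == pytest.approx(9.0, abs=0.01)


def test_psub_interpolates_drifting_plateaus():
    """Plateaus drifting 5 -> 7 across three occlusions average to 6."""
    fs = 250.0
    n = int(5 * fs)
    pressure = np.zeros(n)
    for value, start in zip([5.0, 6.0, 7.0], [1.0, 2.0, 3.0]):
        a, b = int(start * fs), int((start + 0.2) * fs)
        pressure[a:b] = value
    rec = PASRecording(
        sample_rate_hz=fs,
        f0_hz=np.zeros(n),
        spl_db=np.full(n, 80.0),
        flow_ccps=np.full(n, 100.0),
        pressure_cmh2o=pressure,
    )
    iv = TokenInterval("modal", 0.5, 4.5, int(0.5 * fs), int(4.5 * fs))
    assert estimate_subglottic_pressure(rec, iv) == pytest.approx(6.0, abs=1e-6)


def test_psub_single_peak_errors():
    fs = 250.0
    n = int(2 * fs)
    pressure = np.zeros(n)
    pressure[100:150] = 8.0
    rec = PASRecording(
        sample_rate_hz=fs,
        f0_hz=np.zeros(n),
        spl_db=np.full(n, 80.0),
        flow_ccps=np.full(n, 100.0),
        pressure_cmh2o=pressure,
    )
    iv = TokenInterval("loud", 0.0, 2.0, 0, n)
    with pytest.raises(ValueError, match="occlusion peaks"):
        estimate_subglottic_pressure(rec, iv)


def test_token_means_recover_targets_within_one_percent():
    params = pas_params_from_table1(1)
    rec, _ = generate_pas_trace(params)
    intervals = segment_tokens(rec)
    targets = table1_fixture().query("subject == 1").set_index("token")
    for iv in intervals:
        m = token_means(rec, iv)
        row = targets.loc[iv.label]
        assert m.spl_db == pytest.approx(row["spl_db"], rel=0.01)
        assert m.f0_hz == pytest.approx(row["f0_hz"], rel=0.01)
        assert m.flow_ccps == pytest.approx(row["flow_ccps"], rel=0.01)
        assert m.psub_cmh2o == pytest.approx(row["psub_cmh2o"], rel=0.01)


def test_average_repetitions_midpoint():
    reps = _measures(
        [74, 76, 84, 84], [110, 110, 109, 109], [210, 210, 170, 170], [3, 3, 5, 5],
        labels=("soft", "soft", "modal", "modal"),
    )
    out = average_repetitions(reps)
    assert [m.label for m in out] == ["soft", "modal"]
    assert out[0].spl_db == 75.0  # two reps differing by 2 dB -> midpoint
    assert out[1].spl_db == 84.0  # identical reps -> either


def test_paired_t_matches_closed_form_and_scipy():
    x = np.array([1.2, 3.4, 2.2])
    y = np.array([2.0, 3.1, 4.0])
    t, df, p = paired_t(x, y)
    d = y - x
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
    assert t == pytest.approx(t_hand, abs=1e-12)
    t_sp, p_sp = stats.ttest_rel(y, x)
    assert t == pytest.approx(t_sp, abs=1e-12)
    assert p == pytest.approx(p_sp, abs=1e-12)
    assert df == 2


def test_paired_t_zero_for_identical_contrasts():
    t, _, p = paired_t([2.0, 5.0], [2.0, 5.0])
    assert t == 0.0
    assert p == 1.0


def test_group_summary_reproduces_published_group_values():
    gs = group_summary(table1_fixture())
    assert gs.psub_by_level["loud"] == pytest.approx(9.7, abs=0.05)
    assert gs.psub_by_level["modal"] == pytest.approx(5.717, abs=0.001)
    assert gs.psub_by_level["soft"] == pytest.approx(3.933, abs=0.001)
    assert gs.mean_spl_rise_db == pytest.approx(15.33, abs=0.01)
    assert gs.sex_stats.loc["male", ("f0_hz", "mean")] == pytest.approx(119.4, abs=0.1)
    assert gs.sex_stats.loc["female", ("f0_hz", "mean")] == pytest.approx(189.4, abs=0.1)
    assert gs.sex_stats.loc["male", ("flow_ccps", "mean")] == pytest.approx(142.2, abs=0.1)
    assert gs.contrast_sd["modal_loud"] == pytest.approx(8.51, abs=0.01)
    assert gs.t_df == 5
    assert gs.p_one_sided < 0.01  # the loud transition demands more resistance


def test_group_summary_excludes_incomplete_triples():
    df = table1_fixture()
    df = df[~((df["subject"] == 6) & (df["token"] == "loud"))]
    with pytest.warns(UserWarning, match="incomplete"):
        gs = group_summary(df)
    assert gs.n_subjects == 5
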