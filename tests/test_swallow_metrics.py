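import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from manodrift import AnalysisParams, analyze_study
from manodrift.swallow_metrics import (
    LandmarksNotFound,
    MetricWindowError,
    SwallowMetrics,
    classify_swallow,
    compute_break_length,
    compute_dci,
    compute_dl,
    compute_irp,
    detect_pressurization,
    fit_deceleration_point,
    locate_landmarks,
    resting_pressures,
    summarize_study,
)
from manodrift.synthetic_cohort import DriftModel, simulate_study


# ---------------------------------------------------------------------- landmarks


def test_landmarks_on_simulator_fixture(nem_study):
    lm = locate_landmarks(nem_study)
    assert lm.ues_band.start <= 3 < lm.ues_band.stop
    assert lm.les_band.start <= 30 < lm.les_band.stop
    assert lm.gastric.start >= lm.les_band.stop


def test_monotone_field_has_no_bands(study_from):
    P = np.tile(np.linspace(0, 50, 36)[:, None], (1, 600))
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    with pytest.raises(LandmarksNotFound):
        locate_landmarks(s)


@pytest.mark.parametrize("seed", range(10))
def test_gastric_sensors_always_distal_to_les(seed):
    s = simulate_study("nem", DriftModel(), seed=seed)
    lm = locate_landmarks(s)
    assert lm.gastric.start >= lm.les_band.stop
    assert lm.gastric.stop <= s.n_sensors


# ---------------------------------------------------------------------- resting


def _banded_study(study_from, les=25.0, gastric=5.0, ues=60.0):
    P = np.zeros((36, 600))
    P[2:5] = ues
    P[29:32] = les
    P[32:] = gastric
    return study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))


def test_resting_pressures_are_gastric_referenced(study_from, toy_landmarks):
    s = _banded_study(study_from)
    uesp, lesp = resting_pressures(s, toy_landmarks)
    assert lesp == pytest.approx(20.0)
    assert uesp == pytest.approx(55.0)


def test_uniform_offset_cancels_in_resting_pressures(study_from, toy_landmarks):
    s = _banded_study(study_from)
    shifted = s.copy(pressure=s.pressure + 7.0)
    assert resting_pressures(shifted, toy_landmarks) == pytest.approx(
        resting_pressures(s, toy_landmarks)
    )


def test_resting_window_may_not_overlap_a_swallow(study_from, toy_landmarks):
    s = _banded_study(study_from)
    with pytest.raises(MetricWindowError):
        resting_pressures(s, toy_landmarks, window=(18.0, 23.0))


def test_simulated_lesp_recovered_within_noise(nem_study):
    a = analyze_study(nem_study)
    # archetype nominal LESP 22 mmHg plus per-study jitter (sd 2)
    assert a.metrics.lesp == pytest.approx(22.0, abs=6.0)
    assert a.metrics.uesp == pytest.approx(80.0, abs=14.0)


# ---------------------------------------------------------------------- IRP


def test_irp_of_constant_signal(study_from, toy_landmarks):
    P = np.zeros((36, 600))
    P[29:32] = 10.0  # sleeve − gastric = 10 throughout
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_irp(s, toy_landmarks, 20.0) == pytest.approx(10.0)


def test_irp_lowest_four_seconds_selection(study_from, toy_landmarks):
    P = np.zeros((36, 600))
    i0 = 200  # onset sample
    P[29:32, i0 + 40:] = 50.0  # zero for exactly 4 s, then 50
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_irp(s, toy_landmarks, 20.0) == pytest.approx(0.0)


def test_irp_window_truncated_by_exit_raises(study_from, toy_landmarks):
    s = study_from(np.zeros((36, 600)), fs=10.0, t_exit=25.0, onsets=(20.0,))
    with pytest.raises(MetricWindowError):
        compute_irp(s, toy_landmarks, 20.0)


@pytest.mark.parametrize("seed", range(100))
def test_irp_equals_sorting_oracle(seed, study_from, toy_landmarks):
    """Efficient lowest-4-of-10-s computation == brute-force sort oracle."""
    rng = np.random.default_rng(seed)
    P = np.zeros((36, 600))
    P[29:32] = rng.normal(10, 8, size=(3, 600))
    P[32:35] = rng.normal(0, 3, size=(3, 600))
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    got = compute_irp(s, toy_landmarks, 20.0)
    sl = s.window(20.0, 30.0)
    rel = P[29:32, sl].min(axis=0) - P[32:35, sl].mean(axis=0)
    oracle = np.sort(rel)[: int(4 * s.fs)].mean()
    assert got == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------- DCI


def test_dci_zero_below_floor(study_from, toy_landmarks):
    P = np.full((36, 600), 20.0)
    P[32:35] = 0.0
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_dci(s, toy_landmarks, 20.0) == 0.0


def test_dci_rectangular_ridge_closed_form(study_from, toy_landmarks):
    P = np.zeros((36, 600))
    P[10:15, 210:250] = 30.0  # 5 sensors (cm) x 4 s at 30 mmHg
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_dci(s, toy_landmarks, 20.0) == pytest.approx((30 - 20) * 5 * 4)


def test_dci_uniform_offset_cancels(study_from, toy_landmarks):
    rng = np.random.default_rng(0)
    P = np.clip(rng.normal(10, 15, size=(36, 600)), 0, None)
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    shifted = s.copy(pressure=s.pressure + 7.0)
    assert compute_dci(shifted, toy_landmarks, 20.0) == pytest.approx(
        compute_dci(s, toy_landmarks, 20.0), rel=1e-12
    )


def test_dci_additive_over_disjoint_ridges_and_linear_in_excess(study_from, toy_landmarks):
    base = np.zeros((36, 600))
    a, b = base.copy(), base.copy()
    a[8:12, 210:230] = 40.0
    b[20:24, 260:290] = 35.0
    both = np.maximum(a, b)
    mk = lambda P: study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    dci = lambda P: compute_dci(mk(P), toy_landmarks, 20.0)
    assert dci(both) == pytest.approx(dci(a) + dci(b))
    doubled = a.copy()
    doubled[8:12, 210:230] = 60.0  # excess over the 20-mmHg floor doubles
    assert dci(doubled) == pytest.approx(2 * dci(a))


# ---------------------------------------------------------------------- DL / CDP


def test_breakpoint_fit_matches_exhaustive_oracle():
    x = np.arange(5.0, 29.0)  # distances, cm
    k_true = 21  # knot index: x = 26 cm (sensor 26)
    y = 0.8 + 0.25 * np.minimum(x, x[k_true]) + 1.0 * np.maximum(x - x[k_true], 0)

    def oracle(x, y):
        best, best_sse = None, np.inf
        for k in range(1, x.size - 2):
            hinge = np.maximum(x - x[k], 0)
            A = np.column_stack([np.ones_like(x), x, hinge])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = ((A @ coef - y) ** 2).sum()
            if sse < best_sse - 1e-12:
                best, best_sse = k, sse
        return best

    assert fit_deceleration_point(x, y) == oracle(x, y) == k_true


def test_dl_matches_programmed_latency(nem_study):
    lm = locate_landmarks(nem_study)
    for onset in nem_study.swallow_onsets[:3]:
        dl = compute_dl(nem_study, lm, onset)
        assert dl == pytest.approx(6.0, abs=0.2)


def test_failed_swallow_has_undefined_dl(toy_landmarks, study_from):
    s = study_from(np.zeros((36, 600)), fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_dl(s, toy_landmarks, 20.0) is None


def test_break_length_measures_contour_gap(study_from, toy_landmarks):
    P = np.zeros((36, 600))
    P[5:12, 210:230] = 40.0
    P[19:29, 240:260] = 40.0  # 7-sensor gap: sensors 12..18
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert compute_break_length(s, toy_landmarks, 20.0) == pytest.approx(7.0)


def test_pressurization_requires_full_column(study_from, toy_landmarks):
    P = np.zeros((36, 600))
    P[5:29, 215:218] = 35.0
    s = study_from(P, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert detect_pressurization(s, toy_landmarks, 20.0)
    P2 = P.copy()
    P2[17, :] = 0.0  # one body sensor never pressurizes
    s2 = study_from(P2, fs=10.0, t_exit=50.0, onsets=(20.0,))
    assert not detect_pressurization(s2, toy_landmarks, 20.0)


# ------------------------------------------------------------ labels & summary


def _m(irp=8.0, dci=1500.0, dl=6.0, brk=0.0, press=False):
    return SwallowMetrics(irp=irp, dci=dci, dl=dl, break_length=brk, pressurization=press)


@pytest.mark.parametrize(
    "dci,dl,brk,strength,pattern",
    [
        (449.0, 6.0, 0.0, "weak", "intact"),      # weak is ineffective, not premature-eligible
        (449.0, 3.0, 0.0, "weak", "intact"),      # premature requires DCI > 450
        (9000.0, 6.0, 0.0, "normal", "intact"),   # hypercontractile-eligible swallow
        (0.0, None, 0.0, "failed", "failed"),
        (1500.0, 3.0, 0.0, "normal", "premature"),
        (1500.0, 6.0, 6.0, "normal", "fragmented"),
        (1500.0, 3.0, 6.0, "normal", "premature"),  # premature outranks fragmented
    ],
)
def test_swallow_labels(dci, dl, brk, strength, pattern):
    m = classify_swallow(_m(dci=dci, dl=dl, brk=brk))
    assert (m.strength_label, m.pattern_label) == (strength, pattern)
    assert m.ineffective == (strength in ("failed", "weak"))


def test_hyper_swallow_counts_toward_study_tally(params):
    swallows = [classify_swallow(_m(dci=9000.0)) for _ in range(2)]
    swallows += [classify_swallow(_m()) for _ in range(8)]
    sm = summarize_study(swallows, uesp=80.0, lesp=20.0)
    assert sm.n_hyper == 2


def test_summary_identical_swallows():
    sm = summarize_study([classify_swallow(_m(irp=8.0)) for _ in range(10)], 80.0, 20.0)
    assert sm.median_irp == 8.0 and sm.pct_intact == 100.0


def test_summary_failed_counts():
    swallows = [classify_swallow(_m(dci=0.0, dl=None)) for _ in range(6)]
    swallows += [classify_swallow(_m()) for _ in range(4)]
    sm = summarize_study(swallows, 80.0, 20.0)
    assert sm.pct_failed == 60.0
    assert sm.pct_ineffective >= 60.0
    assert sm.pct_ineffective == sm.pct_failed + sm.pct_weak


def test_median_matches_sorting_oracle():
    vals = [3.0, 15.0, 27.0]
    sm = summarize_study([classify_swallow(_m(irp=v)) for v in vals], 80.0, 20.0)
    assert sm.median_irp == sorted(vals)[1]


# ------------------------------------------------------------------ properties


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(-20.0, 20.0))
def test_uniform_offset_leaves_study_metrics_unchanged(nem_study, offset):
    base = analyze_study(nem_study).metrics.as_dict()
    shifted = analyze_study(nem_study.copy(pressure=nem_study.pressure + offset)).metrics.as_dict()
    for k, v in base.items():
        assert shifted[k] == pytest.approx(v, abs=1e-9), k


def test_metrics_stable_under_fs_refinement():
    m50 = analyze_study(simulate_study("nem", DriftModel.none(), seed=11, noise_sd=0.0)).metrics
    m100 = analyze_study(simulate_study("nem", DriftModel.none(), seed=11, noise_sd=0.0, fs=100.0)).metrics
    assert m100.median_irp == pytest.approx(m50.median_irp, abs=0.5)
    assert m100.median_dci == pytest.approx(m50.median_dci, rel=0.02)
    assert m100.median_dl == pytest.approx(m50.median_dl, rel=0.02)
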