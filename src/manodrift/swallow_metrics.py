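"""Chicago-style swallow and study metrics from a pressure topography.

Every metric is referenced to intragastric pressure (the mean over a small
set of sensors distal to the LES): the IRP by definition, and the DCI floor,
DL contour, pressurization level and sphincter resting pressures by the same
convention.  Consistent gastric referencing makes a spatially uniform
baseline error provably null, so drift can affect these metrics only through
inter-sensor heterogeneity.

Glossary: IRP — integrated relaxation pressure, the mean of the lowest
(noncontiguous) 4 s of the EGJ eSleeve signal within a 10-s window starting
at UES relaxation; DCI — distal contractile integral, the amplitude ×
duration × length integral of body pressure above 20 mmHg; DL — distal
latency, onset-to-arrival time at the contractile deceleration point (CDP),
found as the knot of a two-segment least-squares fit to the 30-mmHg
wavefront arrival curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .core_model import AnalysisParams, PressureStudy, ValidationError

__all__ = [
    "Landmarks",
    "SwallowMetrics",
    "StudyMetrics",
    "StudyAnalysis",
    "LandmarksNotFound",
    "MetricWindowError",
    "locate_landmarks",
    "resting_pressures",
    "compute_irp",
    "compute_dci",
    "compute_break_length",
    "detect_pressurization",
    "fit_deceleration_point",
    "compute_dl",
    "classify_swallow",
    "summarize_study",
    "analyze_study",
]


class LandmarksNotFound(RuntimeError):
    """Fewer than two distinct high-pressure bands in the resting profile."""


class MetricWindowError(RuntimeError):
    """A metric window is truncated or overlaps a swallow."""


@dataclass(frozen=True)
class Landmarks:
    """Sensor-index geometry of one study (all slices proximal → distal)."""

    ues_band: slice
    les_band: slice
    egj_sleeve: slice
    gastric: slice
    body_span: slice

    def __post_init__(self):
        if not (self.ues_band.stop <= self.body_span.start
                and self.body_span.stop <= self.les_band.start
                and self.les_band.stop <= self.gastric.start):
            raise ValidationError("landmarks", "bands must be ordered proximal→distal and non-overlapping")


def _resting_window(study: PressureStudy, params: AnalysisParams) -> tuple[float, float]:
    """Quiet-baseline window ending 0.5 s before the first swallow."""
    if not study.swallow_onsets:
        raise MetricWindowError("study has no swallow annotations")
    t1 = study.swallow_onsets[0] - 0.5
    t0 = t1 - params.resting_window
    if t0 < 0:
        raise MetricWindowError("insufficient quiet baseline before the first swallow")
    return t0, t1


def locate_landmarks(study: PressureStudy, params: AnalysisParams | None = None) -> Landmarks:
    """Locate UES/LES bands, gastric reference sensors and the body span.

    The two sphincters are the two dominant spatial maxima of the
    time-averaged resting pressure profile (proximal peak = UES, distal =
    LES).  Bands extend from each peak while the profile stays above half
    its height over the esophageal-body level, up to 2 sensors each side.
    The gastric reference is the configured number of sensors immediately
    distal to the LES band.
    """
    params = params or AnalysisParams()
    t0, t1 = _resting_window(study, params)
    profile = study.pressure[:, study.window(t0, t1)].mean(axis=1)

    peaks, props = find_peaks(profile, prominence=8.0, distance=4)
    if len(peaks) < 2:
        raise LandmarksNotFound(
            f"expected two high-pressure bands, found {len(peaks)} "
            "(monotone or featureless resting profile)"
        )
    # two most prominent peaks, reported proximal → distal
    order = np.argsort(props["prominences"])[::-1][:2]
    ues_peak, les_peak = sorted(int(peaks[i]) for i in order)

    body_level = float(np.median(profile))

    def band(peak: int) -> slice:
        half = body_level + 0.5 * (profile[peak] - body_level)
        lo = peak
        while lo > 0 and peak - lo < 2 and profile[lo - 1] >= half:
            lo -= 1
        hi = peak
        while hi < len(profile) - 1 and hi - peak < 2 and profile[hi + 1] >= half:
            hi += 1
        return slice(lo, hi + 1)

    ues_band, les_band = band(ues_peak), band(les_peak)
    gastric = slice(les_band.stop, les_band.stop + params.gastric_sensors)
    if gastric.stop > study.n_sensors:
        raise LandmarksNotFound(
            f"need {params.gastric_sensors} gastric sensors distal to the LES band "
            f"but only {study.n_sensors - les_band.stop} remain"
        )
    return Landmarks(
        ues_band=ues_band,
        les_band=les_band,
        egj_sleeve=les_band,
        gastric=gastric,
        body_span=slice(ues_band.stop, les_band.start),
    )


def _gastric_ref(study: PressureStudy, lm: Landmarks, sl: slice) -> np.ndarray:
    """Intragastric reference pressure per sample over a window slice."""
    return study.pressure[lm.gastric, sl].mean(axis=0)


def resting_pressures(
    study: PressureStudy,
    lm: Landmarks,
    params: AnalysisParams | None = None,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(UESP, LESP): band-maximum pressure averaged over the resting window,
    referenced to the mean gastric pressure in the same window."""
    params = params or AnalysisParams()
    t0, t1 = window if window is not None else _resting_window(study, params)
    if any(t0 <= onset < t1 or onset < t0 < onset + params.irp_window for onset in study.swallow_onsets):
        raise MetricWindowError(f"resting window [{t0:g}, {t1:g}) overlaps a swallow")
    sl = study.window(t0, t1)
    gastric = float(_gastric_ref(study, lm, sl).mean())
    uesp = float(study.pressure[lm.ues_band, sl].max(axis=0).mean()) - gastric
    lesp = float(study.pressure[lm.les_band, sl].max(axis=0).mean()) - gastric
    return uesp, lesp


def compute_irp(
    study: PressureStudy,
    lm: Landmarks,
    onset: float,
    params: AnalysisParams | None = None,
) -> float:
    """Integrated relaxation pressure of one swallow, mmHg.

    eSleeve signal = min across the EGJ sleeve sensors at each sample over
    the 10-s window from UES-relaxation onset; the IRP is the mean of the
    lowest 4 s worth of samples (noncontiguous) of sleeve − gastric.
    """
    params = params or AnalysisParams()
    if onset + params.irp_window > study.t_exit + 1e-9:
        raise MetricWindowError("IRP window truncated by catheter exit")
    sl = study.window(onset, onset + params.irp_window)
    sleeve = study.pressure[lm.egj_sleeve, sl].min(axis=0)
    rel = sleeve - _gastric_ref(study, lm, sl)
    k = int(round(params.irp_relax_span * study.fs))
    k = min(k, rel.size)
    lowest = np.partition(rel, k - 1)[:k]
    return float(lowest.mean())


def _contraction_window(study: PressureStudy, onset: float, params: AnalysisParams) -> slice:
    return study.window(onset, min(onset + params.dci_window, study.t_exit))


def compute_dci(
    study: PressureStudy,
    lm: Landmarks,
    onset: float,
    params: AnalysisParams | None = None,
) -> float:
    """Distal contractile integral, mmHg·s·cm: gastric-referenced pressure in
    excess of the 20-mmHg floor summed over the body span and the contraction
    window (15 s post-onset, clipped to catheter exit)."""
    params = params or AnalysisParams()
    sl = _contraction_window(study, onset, params)
    exc = study.pressure[lm.body_span, sl] - _gastric_ref(study, lm, sl)[None, :] - params.dci_floor
    np.clip(exc, 0.0, None, out=exc)
    return float(exc.sum() * study.spacing / study.fs)


def compute_break_length(
    study: PressureStudy,
    lm: Landmarks,
    onset: float,
    params: AnalysisParams | None = None,
) -> float:
    """Longest gap, cm, in the 20-mmHg isobaric contraction contour along the
    body span (peak referenced pressure per sensor within the window)."""
    params = params or AnalysisParams()
    sl = _contraction_window(study, onset, params)
    peaks = (study.pressure[lm.body_span, sl] - _gastric_ref(study, lm, sl)[None, :]).max(axis=1)
    covered = peaks >= params.dci_floor
    idx = np.flatnonzero(covered)
    if idx.size < 2:
        return 0.0
    gaps = np.diff(idx) - 1
    return float(gaps.max() * study.spacing)


def detect_pressurization(
    study: PressureStudy,
    lm: Landmarks,
    onset: float,
    params: AnalysisParams | None = None,
) -> bool:
    """True if a ≥30 mmHg gastric-referenced isobaric column spans the entire
    body span at any instant of the contraction window (panesophageal
    pressurization)."""
    params = params or AnalysisParams()
    sl = _contraction_window(study, onset, params)
    rel = study.pressure[lm.body_span, sl] - _gastric_ref(study, lm, sl)[None, :]
    return bool(np.any(np.all(rel >= params.pressurization_level, axis=0)))


def fit_deceleration_point(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the knot of the best continuous two-segment linear fit.

    Fits y ≈ a + b·x + c·max(x − x_k, 0) by least squares for every interior
    candidate knot ``x_k`` and returns the index minimizing the residual sum
    of squares (exhaustive search; ties go to the first minimum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for a two-segment fit")
    best_k, best_sse = 1, np.inf
    for k in range(1, n - 2):
        hinge = np.maximum(x - x[k], 0.0)
        design = np.column_stack([np.ones(n), x, hinge])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(((design @ coef - y) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    return best_k


def compute_dl(
    study: PressureStudy,
    lm: Landmarks,
    onset: float,
    params: AnalysisParams | None = None,
) -> float | None:
    """Distal latency, s, or None when undefined (failed propagation).

    Per body sensor, the front arrival time is the first crossing of the
    30-mmHg gastric-referenced contour after onset.  A two-segment line is
    fitted to (distance, arrival) with an exhaustive breakpoint search; the
    knot is the contractile deceleration point (CDP) and DL is the measured
    arrival there minus the swallow onset.  Undefined when fewer than four
    sensors cross the contour or the front never reaches the distal body
    (within 3 sensors of the LES).
    """
    params = params or AnalysisParams()
    sl = _contraction_window(study, onset, params)
    rel = study.pressure[lm.body_span, sl] - _gastric_ref(study, lm, sl)[None, :]
    above = rel >= params.dl_contour
    sensors, arrivals = [], []
    for i in range(above.shape[0]):
        hits = np.flatnonzero(above[i])
        if hits.size:
            sensors.append(lm.body_span.start + i)
            arrivals.append(onset + hits[0] / study.fs)
    if len(sensors) < 4:
        return None
    if sensors[-1] < lm.les_band.start - 3:
        return None  # front never reached the distal body
    x = np.asarray(sensors, dtype=float) * study.spacing
    k = fit_deceleration_point(x, np.asarray(arrivals))
    return float(arrivals[k] - onset)


@dataclass
class SwallowMetrics:
    """Per-swallow derived quantities and labels."""

    irp: float
    dci: float
    dl: float | None
    break_length: float
    pressurization: bool
    strength_label: str = ""   # failed | weak | normal
    pattern_label: str = ""    # failed | premature | fragmented | intact

    @property
    def ineffective(self) -> bool:
        return self.strength_label in ("failed", "weak")


def classify_swallow(m: SwallowMetrics, params: AnalysisParams | None = None) -> SwallowMetrics:
    """Assign strength and pattern labels in place (and return the object).

    Strength: failed (DCI < 100), weak (100 ≤ DCI < 450) or normal.
    Pattern: failed swallows carry only the failed label; otherwise premature
    (DL < 4.5 s with DCI > 450), fragmented (break > 5 cm with DCI > 450),
    else intact.  Weak swallows still receive a pattern label, so intact%
    and weak% may overlap.
    """
    params = params or AnalysisParams()
    if m.dci < params.failed_dci:
        m.strength_label = "failed"
        m.pattern_label = "failed"
        return m
    m.strength_label = "weak" if m.dci < params.weak_dci_upper else "normal"
    vigorous = m.dci > params.weak_dci_upper
    if vigorous and m.dl is not None and m.dl < params.premature_dl:
        m.pattern_label = "premature"
    elif vigorous and m.break_length > params.break_len:
        m.pattern_label = "fragmented"
    else:
        m.pattern_label = "intact"
    return m


@dataclass
class StudyMetrics:
    """Per-study aggregates over the 10 wet swallows."""

    uesp: float
    lesp: float
    median_irp: float
    median_dci: float
    median_dl: float | None
    pct_failed: float
    pct_weak: float
    pct_ineffective: float
    pct_fragmented: float
    pct_premature: float
    pct_intact: float
    pct_pressurization: float
    n_swallows: int
    n_hyper: int  # swallows with DCI > 8000 mmHg·s·cm

    def as_dict(self) -> dict[str, float]:
        d = dict(self.__dict__)
        d["median_dl"] = np.nan if self.median_dl is None else self.median_dl
        return d


def summarize_study(
    swallows: Sequence[SwallowMetrics],
    uesp: float,
    lesp: float,
    params: AnalysisParams | None = None,
) -> StudyMetrics:
    """Aggregate classified swallows: medians over defined values,
    percentages over the number of swallows."""
    params = params or AnalysisParams()
    if not swallows:
        raise ValidationError("swallows", "cannot summarize an empty swallow list")
    n = len(swallows)
    pct = lambda flag: 100.0 * sum(flag(s) for s in swallows) / n
    dls = [s.dl for s in swallows if s.dl is not None and s.strength_label != "failed"]
    pct_failed = pct(lambda s: s.strength_label == "failed")
    pct_weak = pct(lambda s: s.strength_label == "weak")
    return StudyMetrics(
        uesp=uesp,
        lesp=lesp,
        median_irp=float(median(s.irp for s in swallows)),
        median_dci=float(median(s.dci for s in swallows)),
        median_dl=float(median(dls)) if dls else None,
        pct_failed=pct_failed,
        pct_weak=pct_weak,
        pct_ineffective=pct_failed + pct_weak,
        pct_fragmented=pct(lambda s: s.pattern_label == "fragmented"),
        pct_premature=pct(lambda s: s.pattern_label == "premature"),
        pct_intact=pct(lambda s: s.pattern_label == "intact"),
        pct_pressurization=pct(lambda s: s.pressurization),
        n_swallows=n,
        n_hyper=sum(s.dci > params.hyper_dci for s in swallows),
    )


@dataclass
class StudyAnalysis:
    """Everything derived from one (compensated) study."""

    study_id: str
    landmarks: Landmarks
    swallows: list[SwallowMetrics]
    metrics: StudyMetrics


def analyze_study(study: PressureStudy, params: AnalysisParams | None = None) -> StudyAnalysis:
    """Full metric chain for one study: landmarks → resting pressures →
    per-swallow IRP/DCI/DL/break/pressurization → labels → study summary."""
    params = params or AnalysisParams()
    lm = locate_landmarks(study, params)
    uesp, lesp = resting_pressures(study, lm, params)
    swallows = []
    for onset in study.swallow_onsets:
        m = SwallowMetrics(
            irp=compute_irp(study, lm, onset, params),
            dci=compute_dci(study, lm, onset, params),
            dl=compute_dl(study, lm, onset, params),
            break_length=compute_break_length(study, lm, onset, params),
            pressurization=detect_pressurization(study, lm, onset, params),
        )
        swallows.append(classify_swallow(m, params))
    return StudyAnalysis(
        study_id=study.study_id,
        landmarks=lm,
        swallows=swallows,
        metrics=summarize_study(swallows, uesp, lesp, params),
    )
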