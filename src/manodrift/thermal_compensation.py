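"""Per-sensor baseline-offset estimation and drift subtraction.

Solid-state manometry sensors drift as they warm from room to body
temperature, so after the catheter leaves the body they do not return to
atmospheric zero: the residual reading at a chosen post-removal anchor time
is the measured drift.  Compensation subtracts that offset from the whole
recording, accrued linearly in time from zero at recording start to the full
offset at catheter exit (the vendor's accrual model is proprietary; a linear
ramp is the simplest model consistent with a warming process and is the
declared model here — see docs/methods.md).

The five study conditions are: no compensation (``nontc``), compensation
anchored exactly at the end of the waterfall image (``ftc``), and anchors
1, 5 or 10 s later (``tc1``/``tc5``/``tc10``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import AnalysisParams, PressureStudy, TCCondition, ValidationError

__all__ = [
    "OffsetVector",
    "CatheterExitNotDetected",
    "detect_waterfall_end",
    "estimate_offsets",
    "apply_compensation",
    "compensate",
]


class CatheterExitNotDetected(RuntimeError):
    """Pressure never collapses to a narrow spatial range after the last swallow."""


class InsufficientPostRemovalRecording(RuntimeError):
    """The requested anchor window extends beyond the end of the recording."""


@dataclass(frozen=True)
class OffsetVector:
    """Per-sensor baseline offsets (mmHg) measured at one anchor time."""

    o: np.ndarray          # mmHg, one entry per sensor
    anchor_time: float     # s (>= t_exit)
    window: float          # s averaged

    def __post_init__(self):
        object.__setattr__(self, "o", np.asarray(self.o, dtype=float))
        if not np.all(np.isfinite(self.o)):
            raise ValidationError("o", "offsets must be finite")


def detect_waterfall_end(
    study: PressureStudy,
    range_threshold: float | None = None,
    hold: float = 0.5,
    smooth: float = 0.25,
) -> float:
    """Detect the end of the waterfall image: the catheter-exit time.

    Returns the earliest time after the last swallow at which the spatial
    range (max − min across sensors) of time-smoothed pressures stays below
    ``range_threshold`` (default 15 mmHg) for at least ``hold`` seconds —
    the point where anatomical pressure ends and only the (narrow-range)
    residual sensor baselines remain.

    Raises
    ------
    CatheterExitNotDetected
        If the pressures never collapse, e.g. pressure held on the sensors
        after the study (a QC-exclusion scenario).
    """
    if range_threshold is None:
        range_threshold = AnalysisParams().exit_range_threshold
    fs = study.fs
    k = max(1, int(round(smooth * fs)))
    kernel = np.ones(k) / k
    # per-sensor moving average, then spatial range at each sample
    sm = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1, study.pressure)
    spatial_range = sm.max(axis=0) - sm.min(axis=0)
    start = 0
    if study.swallow_onsets:
        start = study.sample_index(study.swallow_onsets[-1])
    below = spatial_range < range_threshold
    need = max(1, int(round(hold * fs)))
    run = 0
    for i in range(start, study.n_samples):
        run = run + 1 if below[i] else 0
        if run >= need:
            return (i - need + 1) / fs
    raise CatheterExitNotDetected(
        "catheter exit not detected: spatial pressure range never stays "
        f"below {range_threshold:g} mmHg for {hold:g} s after the last swallow"
    )


def estimate_offsets(
    study: PressureStudy,
    condition: TCCondition,
    params: AnalysisParams | None = None,
) -> OffsetVector:
    """Measure per-sensor offsets at ``t_exit + anchor_offset``.

    The offset of sensor *i* is the mean of its readings over the half-open
    window ``[anchor, anchor + window)`` (window default 0.5 s, a short mean
    rather than a point sample to suppress measurement noise).

    Raises
    ------
    InsufficientPostRemovalRecording
        If the anchor window runs past the end of the recording — the same
        failure mode that motivates excluding studies with < 10 s of
        post-removal recording.
    """
    params = params or AnalysisParams()
    if condition.mode != "anchored":
        raise ValidationError("condition", "offsets are only defined for anchored compensation")
    anchor = study.t_exit + condition.anchor_offset
    if anchor + params.anchor_window > study.duration + 1e-9:
        raise InsufficientPostRemovalRecording(
            f"anchor window [{anchor:g}, {anchor + params.anchor_window:g}) s "
            f"exceeds the recording length {study.duration:g} s"
        )
    sl = study.window(anchor, anchor + params.anchor_window)
    o = study.pressure[:, sl].mean(axis=1)
    return OffsetVector(o=o, anchor_time=anchor, window=params.anchor_window)


def apply_compensation(study: PressureStudy, offsets: OffsetVector | None) -> PressureStudy:
    """Subtract linearly accrued drift; ``offsets=None`` is the identity (nonTC).

    ``P'[i, t] = P[i, t] − o_i · r(t)`` with ``r(t) = min(t, t_exit)/t_exit``:
    nothing is removed at recording start, exactly the measured offset at
    catheter exit, and post-exit samples are corrected with r = 1 so that
    re-running exit detection on a corrected study is stable.
    """
    if offsets is None:
        return study
    if offsets.o.shape[0] != study.n_sensors:
        raise ValidationError("offsets", f"length {offsets.o.shape[0]} != n_sensors {study.n_sensors}")
    r = np.minimum(study.time, study.t_exit) / study.t_exit
    corrected = study.pressure - offsets.o[:, None] * r[None, :]
    return study.copy(pressure=corrected)


def compensate(
    study: PressureStudy,
    condition: TCCondition,
    params: AnalysisParams | None = None,
) -> PressureStudy:
    """Estimate offsets for ``condition`` and apply them (identity for nonTC)."""
    if condition.mode == "none":
        return study
    return apply_compensation(study, estimate_offsets(study, condition, params))
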