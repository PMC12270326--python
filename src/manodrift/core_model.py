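"""Domain types, unit/coordinate conventions, and study-bundle I/O.

A high-resolution manometry (HRM) study is a space-time pressure topography:
36 solid-state sensors at 1 cm spacing sampled at ``fs`` Hz, pressures in
mmHg relative to atmospheric at calibration.  Sensor 0 is the most proximal
(pharyngeal) sensor; the index increases distally, matching the top-down
reading order of a Clouse plot.  Time is seconds from recording start;
samples are left-closed intervals of width ``1/fs`` and every analysis
window is half-open ``[t0, t0 + w)``.

The on-disk "study bundle" is a CSV matrix (``t,p00..p35``, one row per
sample) plus a JSON sidecar carrying the sampling rate, sensor spacing, the
annotated catheter-exit time (end of the "waterfall image"), swallow onsets
and optional simulator ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PressureStudy",
    "TCCondition",
    "AnalysisParams",
    "read_study",
    "write_study",
    "render_clouse_plot",
]


class ValidationError(ValueError):
    """Structured invariant violation; ``field`` names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class PressureStudy:
    """A validated space-time pressure matrix with its acquisition metadata.

    Attributes
    ----------
    pressure : ndarray, shape (n_sensors, n_samples)
        mmHg relative to atmospheric at calibration.  Baseline drift of the
        solid-state sensors therefore shows up as a nonzero residual reading
        after the catheter has left the body.
    spacing : float
        Distance between adjacent sensors, cm.
    fs : float
        Sampling rate, Hz.
    t_exit : float
        Annotated end of the waterfall image, s: the instant the catheter is
        fully out of the body and anatomical pressure ends.
    swallow_onsets : list of float
        UES-relaxation onset of each wet swallow, s.
    ground_truth : dict or None
        Optional simulator annotations (true diagnosis, true drift offsets);
        carried through serialization, ignored by every analysis stage.
    """

    pressure: np.ndarray
    fs: float
    t_exit: float
    swallow_onsets: list[float] = field(default_factory=list)
    spacing: float = 1.0
    study_id: str = "study"
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure.ndim != 2:
            raise ValidationError("pressure", "must be a 2-D [sensor, sample] matrix")
        if not np.all(np.isfinite(self.pressure)):
            raise ValidationError("pressure", "contains non-finite values")
        if self.fs <= 0:
            raise ValidationError("fs", "sampling rate must be > 0")
        if self.spacing <= 0:
            raise ValidationError("spacing", "sensor spacing must be > 0")
        if not (0 < self.t_exit < self.duration):
            raise ValidationError(
                "t_exit",
                f"must lie strictly inside the recording (0, {self.duration:g}) s; got {self.t_exit:g}",
            )
        self.swallow_onsets = [float(t) for t in self.swallow_onsets]
        if any(t <= 0 or t >= self.t_exit for t in self.swallow_onsets):
            raise ValidationError("swallow_onsets", "every onset must satisfy 0 < onset < t_exit")
        if sorted(self.swallow_onsets) != self.swallow_onsets:
            raise ValidationError("swallow_onsets", "onsets must be nondecreasing")

    @property
    def n_sensors(self) -> int:
        return self.pressure.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pressure.shape[1]

    @property
    def duration(self) -> float:
        """Recording length, s."""
        return self.pressure.shape[1] / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample timestamps (left edge of each sampling interval), s."""
        return np.arange(self.n_samples) / self.fs

    def sample_index(self, t: float) -> int:
        """Index of the sample interval containing time ``t``."""
        return int(np.floor(t * self.fs + 1e-9))

    def window(self, t0: float, t1: float) -> slice:
        """Sample slice for the half-open time window [t0, t1)."""
        return slice(self.sample_index(t0), self.sample_index(t1))

    def copy(self, **changes) -> "PressureStudy":
        out = replace(self, **{"pressure": self.pressure.copy(), **changes})
        return out


#: The five study conditions: formal compensation at catheter exit (fTC),
#: compensation anchored 1/5/10 s later, or no compensation at all.
_NAMED_CONDITIONS = {
    "nontc": ("none", 0.0),
    "ftc": ("anchored", 0.0),
    "tc1": ("anchored", 1.0),
    "tc5": ("anchored", 5.0),
    "tc10": ("anchored", 10.0),
}


@dataclass(frozen=True)
class TCCondition:
    """A thermal-compensation condition: none, or anchored at t_exit + offset."""

    mode: str = "anchored"  # "none" | "anchored"
    anchor_offset: float = 0.0  # s after t_exit; ignored when mode == "none"

    def __post_init__(self):
        if self.mode not in ("none", "anchored"):
            raise ValidationError("mode", f"unknown TC mode {self.mode!r}")
        if self.mode == "anchored" and self.anchor_offset < 0:
            raise ValidationError("anchor_offset", "must be nonnegative")

    @classmethod
    def from_name(cls, name: str) -> "TCCondition":
        """Build one of the five named conditions (nontc/ftc/tc1/tc5/tc10)."""
        key = name.lower()
        if key not in _NAMED_CONDITIONS:
            raise ValidationError("condition", f"unknown condition {name!r}")
        mode, off = _NAMED_CONDITIONS[key]
        return cls(mode=mode, anchor_offset=off)

    @property
    def name(self) -> str:
        if self.mode == "none":
            return "nontc"
        for k, (m, off) in _NAMED_CONDITIONS.items():
            if m == "anchored" and off == self.anchor_offset:
                return k
        return f"tc@{self.anchor_offset:g}s"


STANDARD_CONDITIONS = tuple(TCCondition.from_name(n) for n in ("ftc", "nontc", "tc1", "tc5", "tc10"))


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds and windows of the metric/classification chain.

    Values not fixed by the platform literature follow the Chicago
    conventions; everything is configurable.
    """

    irp_window: float = 10.0          # s, swallow window starting at UES relaxation
    irp_relax_span: float = 4.0       # s of maximal relaxation averaged (noncontiguous)
    dci_floor: float = 20.0           # mmHg above gastric, DCI isobaric floor
    dl_contour: float = 30.0          # mmHg above gastric, DL wavefront contour
    dci_window: float = 15.0          # s after onset integrated for DCI / contour search
    premature_dl: float = 4.5         # s, DL below this = premature swallow
    failed_dci: float = 100.0         # mmHg·s·cm, below = failed
    weak_dci_upper: float = 450.0     # mmHg·s·cm, below = weak
    hyper_dci: float = 8000.0         # mmHg·s·cm, above = hypercontractile swallow
    irp_threshold: float = 15.0       # mmHg, strict: elevated iff median IRP > 15
    borderline_irp: tuple[float, float] = (10.0, 15.0)  # (lo, hi]; hi == irp_threshold
    break_len: float = 5.0            # cm, isobaric-contour break above = fragmented
    pressurization_level: float = 30.0  # mmHg above gastric, panesophageal column
    gastric_sensors: int = 3          # sensors distal to the LES used as reference
    resting_window: float = 5.0       # s of quiet baseline for sphincter resting pressures
    anchor_window: float = 0.5        # s averaged when measuring post-exit offsets
    exit_range_threshold: float = 15.0  # mmHg spatial range defining the waterfall end

    def __post_init__(self):
        for name in (
            "irp_window", "irp_relax_span", "dci_floor", "dl_contour", "dci_window",
            "premature_dl", "failed_dci", "weak_dci_upper", "hyper_dci",
            "irp_threshold", "break_len", "pressurization_level", "resting_window",
            "anchor_window", "exit_range_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(name, "threshold must be strictly positive")
        if self.gastric_sensors < 1:
            raise ValidationError("gastric_sensors", "need at least one gastric reference sensor")
        if self.borderline_irp[1] != self.irp_threshold:
            raise ValidationError("borderline_irp", "upper bound must equal irp_threshold")


# ---------------------------------------------------------------------------
# Study-bundle I/O


def _sensor_columns(n: int) -> list[str]:
    return [f"p{i:02d}" for i in range(n)]


def write_study(study: PressureStudy, path: str | Path) -> Path:
    """Write ``<path>.csv`` + ``<path>.json``; returns the CSV path.

    Floats are written at full precision so a read-back reproduces the
    pressure matrix bit-exactly.
    """
    path = Path(path)
    if path.suffix == ".csv":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(study.pressure.T, columns=_sensor_columns(study.n_sensors))
    df.insert(0, "t", study.time)
    csv_path = path.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    sidecar = {
        "study_id": study.study_id,
        "fs": study.fs,
        "spacing_cm": study.spacing,
        "t_exit_s": study.t_exit,
        "swallow_onsets_s": study.swallow_onsets,
    }
    if study.ground_truth is not None:
        sidecar["ground_truth"] = study.ground_truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def read_study(path: str | Path) -> PressureStudy:
    """Read a study bundle written by :func:`write_study`.

    ``path`` may point at either half of the bundle (or its stem); both the
    CSV matrix and the JSON sidecar must exist and agree on dimensions.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    if not csv_path.exists():
        raise ValidationError("path", f"missing pressure matrix {csv_path}")
    if not json_path.exists():
        raise ValidationError("path", f"missing sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    for key in ("fs", "t_exit_s", "swallow_onsets_s"):
        if key not in meta:
            raise ValidationError(key, "missing from sidecar")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    cols = [c for c in df.columns if c.startswith("p")]
    t = df["t"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValidationError("t", "time axis must be strictly increasing")
    return PressureStudy(
        pressure=df[cols].to_numpy().T,
        fs=float(meta["fs"]),
        spacing=float(meta.get("spacing_cm", 1.0)),
        t_exit=float(meta["t_exit_s"]),
        swallow_onsets=list(meta["swallow_onsets_s"]),
        study_id=str(meta.get("study_id", stem.name)),
        ground_truth=meta.get("ground_truth"),
    )


def _build_clouse_figure(study: PressureStudy, vmax: float | None = None):
    """Build the Clouse-plot figure; the t_exit marker is the last axvline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4.5))
    extent = (0.0, study.duration, (study.n_sensors - 0.5) * study.spacing, -0.5 * study.spacing)
    im = ax.imshow(
        study.pressure, aspect="auto", extent=extent, cmap="jet",
        vmin=-10, vmax=vmax if vmax is not None else max(50.0, np.percentile(study.pressure, 99.5)),
        interpolation="nearest",
    )
    for onset in study.swallow_onsets:
        ax.axvline(onset, color="white", lw=0.6, alpha=0.7)
    ax.axvline(study.t_exit, color="black", lw=1.2, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("distance from proximal sensor (cm)")
    ax.set_title(study.study_id)
    fig.colorbar(im, ax=ax, label="pressure (mmHg)")
    return fig, ax


def render_clouse_plot(study: PressureStudy, path: str | Path, vmax: float | None = None) -> Path:
    """Render the space-time heat map (Clouse plot) to an image file.

    Time runs along x, proximal sensors at the top; swallow onsets and the
    catheter-exit annotation are marked with vertical lines.
    """
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, _ = _build_clouse_figure(study, vmax=vmax)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
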