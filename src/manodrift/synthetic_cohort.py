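"""Synthetic 10-swallow supine HRM studies with disorder archetypes and drift.

Each study emulates the clinical protocol: a quiet baseline, ten sequential
5-mL water swallows, catheter withdrawal (the "waterfall" collapse to
atmospheric pressure) and a post-removal tail.  The anatomy is stylized —
Gaussian high-pressure bands for the UES (sensor 3) and LES (sensor 30),
a gastric baseline on the distal sensors, a peristaltic contraction modeled
as a Gaussian ridge propagating distally with a deceleration point a few cm
above the LES — just rich enough that the Chicago-style metric chain and
decision tree behave as they do on real topographies.

Thermal drift is additive per sensor: an amplitude ``D_i`` drawn from a
truncated normal accrues with a warm-up law while the catheter is in the
body and, after withdrawal, follows a bounded post-exit shape ``g(Δt)``
(mild early overshoot, slow decay).  Post-removal readings equal the drift
term exactly; measurement noise is applied only in-body, so a drift-free
study reads identically zero after catheter exit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import PressureStudy, ValidationError, write_study

__all__ = [
    "DriftModel",
    "ArchetypeSpec",
    "CohortSpec",
    "ARCHETYPES",
    "simulate_study",
    "simulate_cohort",
    "simulate_qc_cohort",
]

# fixed catheter geometry of the simulator
N_SENSORS = 36
UES_CENTER = 3
LES_CENTER = 30
BODY = slice(5, 29)        # body sensors 5..28
CDP_SENSOR = 26            # deceleration point, 3 cm above the LES proximal margin
GASTRIC_LEVEL = 8.0        # mmHg, intragastric baseline (sensors distal to LES)
BAND_SD = 1.0              # spatial sd (sensors) of the sphincter pressure bands

# Generator calibration: the measured IRP sits below the programmed
# relaxation depth because the eSleeve takes the minimum over three noisy
# sensors and the lowest-4-s average prefers noise troughs.  The archetype
# relaxation level is raised by this constant so the *measured* IRP lands on
# the archetype's nominal target at default noise (sd 1 mmHg).
IRP_NOISE_BIAS = 1.55


@dataclass(frozen=True)
class DriftModel:
    """Generative description of per-sensor baseline drift.

    Amplitudes ``D_i`` are truncated-normal(mu_d, sigma_d, floor 0) mmHg.
    In-body the drift accrues as ``D_i·(1 − exp(−t/tau_warm))`` (or linearly
    to the same exit level with ``warmup="linear"``); after catheter exit the
    saturated level is multiplied by the bounded shape ``g(Δt)``.  The
    default g rises to a mild peak near Δt ≈ 2–4 s then decays below 1 by
    10 s — offsets measured at different post-removal instants differ, which
    is the whole phenomenon under study.
    """

    mu_d: float = 6.0          # mmHg, mean drift amplitude
    sigma_d: float = 3.0       # mmHg, inter-sensor heterogeneity
    corr_len: float = 4.0      # sensors, spatial correlation length of D_i
    tau_warm: float = 120.0    # s, in-body warm-up time constant
    warmup: str = "exponential"   # or "linear"
    post_exit_shape: str = "bump"  # or "constant" (g ≡ 1)
    bump_gain: float = 0.16
    bump_gain_sd: float = 0.06  # per-sensor spread of the overshoot gain
    bump_tau: float = 4.0      # s, overshoot timescale
    decay_tau: float = 52.0    # s, slow post-exit decay

    def __post_init__(self):
        if self.mu_d < 0 or self.sigma_d < 0:
            raise ValidationError("drift", "mu_d and sigma_d must be nonnegative")
        if self.warmup not in ("exponential", "linear"):
            raise ValidationError("warmup", f"unknown warm-up law {self.warmup!r}")
        if self.post_exit_shape not in ("bump", "constant"):
            raise ValidationError("post_exit_shape", f"unknown shape {self.post_exit_shape!r}")

    @classmethod
    def none(cls) -> "DriftModel":
        return cls(mu_d=0.0, sigma_d=0.0)

    @classmethod
    def uniform(cls, amplitude: float = 6.0, **kw) -> "DriftModel":
        """All sensors share one drift curve (cancels under gastric referencing)."""
        return cls(mu_d=amplitude, sigma_d=0.0, **kw)

    def draw_amplitudes(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Truncated-normal amplitudes, spatially correlated along the catheter.

        Neighboring sensors share their thermal environment, so D_i is drawn
        from a Gaussian process with exponential correlation over sensor
        distance (``corr_len``); ``corr_len=0`` gives independent sensors.
        Values are floored at 0.
        """
        if self.sigma_d == 0.0:
            return np.full(n, self.mu_d)
        z = rng.normal(size=n)
        if self.corr_len > 0:
            idx = np.arange(n)
            cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / self.corr_len)
            z = np.linalg.cholesky(cov + 1e-12 * np.eye(n)) @ z
        return np.maximum(self.mu_d + self.sigma_d * z, 0.0)

    def draw_gains(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Per-sensor overshoot gains (each sensor has its own electronics);
        clipped to [0, 0.3] so the anchor-window mean stays representative."""
        if self.sigma_d == 0.0 or self.post_exit_shape == "constant" or self.bump_gain_sd == 0.0:
            # sigma_d == 0 means *all* sensors share one drift curve
            return np.full(n, self.bump_gain)
        return np.clip(rng.normal(self.bump_gain, self.bump_gain_sd, size=n), 0.0, 0.30)

    def g(self, dt: np.ndarray | float, gain: np.ndarray | float | None = None) -> np.ndarray:
        """Bounded post-exit shape; g(0) = 1.  ``gain`` may be per sensor, in
        which case the result broadcasts to (n_sensors, n_times)."""
        dt = np.atleast_1d(np.asarray(dt, dtype=float))
        if self.post_exit_shape == "constant":
            return np.ones_like(dt)
        gain = self.bump_gain if gain is None else gain
        gain = np.asarray(gain, dtype=float)
        if gain.ndim == 1:
            gain = gain[:, None]
            dt = dt[None, :]
        bump = 1.0 + gain * (dt / self.bump_tau) * np.exp(1.0 - dt / self.bump_tau)
        return bump * np.exp(-dt / self.decay_tau)

    def curve(
        self,
        t: np.ndarray,
        t_exit: float,
        amplitudes: np.ndarray,
        gains: np.ndarray | None = None,
    ) -> np.ndarray:
        """Drift matrix d_i(t), shape (n_sensors, n_samples)."""
        exit_level = 1.0 - np.exp(-t_exit / self.tau_warm)
        if self.warmup == "exponential":
            in_body = 1.0 - np.exp(-np.minimum(t, t_exit) / self.tau_warm)
        else:
            in_body = exit_level * np.minimum(t, t_exit) / t_exit
        post = exit_level * self.g(np.maximum(t - t_exit, 0.0), gains)
        return amplitudes[:, None] * np.where(t[None, :] <= t_exit, in_body[None, :], post)

    def at_anchor(
        self,
        t_exit: float,
        amplitudes: np.ndarray,
        anchor_offset: float,
        gains: np.ndarray | None = None,
    ) -> np.ndarray:
        """Closed-form drift per sensor at ``t_exit + anchor_offset``."""
        g = self.g(np.array([anchor_offset]), gains).ravel()
        if g.size == 1:
            g = np.full(amplitudes.size, g[0])
        return amplitudes * (1.0 - np.exp(-t_exit / self.tau_warm)) * g


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one disorder archetype.

    ``kind_probs`` gives the per-swallow mixture over contraction kinds
    (intact / weak / failed / premature / fragmented / hyper); the IRP,
    sphincter and vigor targets are chosen so the archetype satisfies its
    diagnostic criteria in expectation.
    """

    label: str                       # expected diagnosis label
    irp_target: float                # mmHg, nominal median IRP
    irp_study_sd: float = 0.8        # between-study spread of the IRP target
    uesp_target: float = 80.0        # mmHg (gastric-referenced)
    lesp_target: float = 22.0        # mmHg (gastric-referenced)
    amp: float = 70.0                # mmHg, peristaltic ridge amplitude (intact)
    weak_amp: float = 40.0           # mmHg, ridge amplitude of weak swallows
    hyper_amp: float = 200.0         # mmHg, hypercontractile ridge amplitude
    amp_rel_sd: float = 0.12         # lognormal per-swallow amplitude spread
    dl_target: float = 6.0           # s, distal latency of normal propagation
    premature_dl: float = 3.2        # s, distal latency of premature swallows
    kind_probs: dict[str, float] = field(default_factory=lambda: {"intact": 1.0})
    pressurization_p: float = 0.0    # per-swallow panesophageal column probability
    fragment_gap: tuple[int, int] = (14, 20)   # sensors silenced in fragmented swallows

    def __post_init__(self):
        for name, v in (("amp", self.amp), ("weak_amp", self.weak_amp), ("hyper_amp", self.hyper_amp)):
            if not 0.0 <= v <= 300.0:
                raise ValidationError(name, "ridge amplitude outside the plausible 0-300 mmHg range")
        if not 0.0 <= self.irp_target <= 60.0:
            raise ValidationError("irp_target", "implausible relaxation pressure")
        if abs(sum(self.kind_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("kind_probs", "mixture must sum to 1")
        if not set(self.kind_probs) <= {"intact", "weak", "failed", "premature", "fragmented", "hyper"}:
            raise ValidationError("kind_probs", f"unknown kind in {set(self.kind_probs)}")


#: Archetype registry.  Targets echo the cohort medians a clinical reader
#: would expect for each subgroup (normal IRP ≈ 8–9 mmHg, obstructed ≈ 21,
#: achalasia ≈ 25–26; DCI ≈ 1.3–1.7k for preserved peristalsis).
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "nem": ArchetypeSpec(label="NEM", irp_target=8.5),
    "iem": ArchetypeSpec(
        label="IEM", irp_target=8.0,
        kind_probs={"failed": 0.45, "weak": 0.45, "intact": 0.10},
    ),
    "egjoo": ArchetypeSpec(
        label="EGJ_OO", irp_target=21.0, lesp_target=40.0,
        kind_probs={"intact": 0.9, "weak": 0.1},
    ),
    "t1a": ArchetypeSpec(
        label="T1A", irp_target=26.0, lesp_target=40.0, kind_probs={"failed": 1.0},
    ),
    "t2a": ArchetypeSpec(
        label="T2A", irp_target=26.0, lesp_target=40.0,
        kind_probs={"failed": 1.0}, pressurization_p=1.0,
    ),
    "t3a": ArchetypeSpec(
        label="T3A", irp_target=25.0, lesp_target=40.0, kind_probs={"premature": 1.0},
    ),
    "ac": ArchetypeSpec(label="AC", irp_target=5.0, lesp_target=12.0, kind_probs={"failed": 1.0}),
    "acr": ArchetypeSpec(
        label="ACR", irp_target=12.5, irp_study_sd=0.4, lesp_target=30.0,
        kind_probs={"failed": 1.0}, pressurization_p=0.6,
    ),
    "des": ArchetypeSpec(
        label="DES", irp_target=8.0, kind_probs={"premature": 0.5, "intact": 0.5},
    ),
    "he": ArchetypeSpec(
        label="HE", irp_target=9.0, kind_probs={"hyper": 0.5, "intact": 0.5},
    ),
    "fp": ArchetypeSpec(
        label="FP", irp_target=8.0, kind_probs={"fragmented": 0.8, "intact": 0.2},
    ),
    # near-threshold variants for studying drift-induced diagnosis flips
    "nem_borderline": ArchetypeSpec(label="NEM", irp_target=13.8, irp_study_sd=0.5),
    "egjoo_borderline": ArchetypeSpec(
        label="EGJ_OO", irp_target=16.3, irp_study_sd=0.5, lesp_target=35.0,
    ),
}


def _trapezoid(tt: np.ndarray, t0: float, t1: float, t2: float, t3: float) -> np.ndarray:
    """0 → 1 over [t0,t1], hold to t2, back to 0 at t3."""
    up = np.clip((tt - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    down = np.clip((t3 - tt) / max(t3 - t2, 1e-9), 0.0, 1.0)
    return np.minimum(up, down)


def simulate_study(
    archetype: ArchetypeSpec | str,
    drift: DriftModel | None = None,
    seed: int = 0,
    *,
    fs: float = 50.0,
    n_swallows: int = 10,
    baseline_lead: float = 18.0,
    swallow_interval: float = 20.0,
    tail_after_last: float = 15.0,
    post_exit_duration: float = 12.0,
    noise_sd: float = 1.0,
    resp_amp: float = 2.0,
    study_id: str | None = None,
    qc_violation: str | None = None,
) -> PressureStudy:
    """Generate one synthetic 10-swallow supine study.

    Deterministic in ``seed``; the anatomy/noise stream is independent of the
    drift stream, so two calls with the same seed and different drift models
    differ only in the additive drift term.  ``qc_violation`` plants one of
    the exclusion scenarios: ``short_tail`` (< 10 s post-removal),
    ``overlong`` (> 15 min), ``residual_pressure`` (pressure held on sensors
    after exit) or ``fold`` (annotation flag only).

    The returned study's ``ground_truth`` records the archetype, its expected
    diagnosis label, the drift amplitudes and the closed-form drift at the
    0/1/5/10-s anchors.
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    drift = drift or DriftModel.none()
    rng = np.random.default_rng([seed, 11])        # anatomy + noise
    rng_drift = np.random.default_rng([seed, 13])  # drift amplitudes

    if qc_violation == "overlong":
        baseline_lead += 690.0
    if qc_violation == "short_tail":
        post_exit_duration = 8.0

    onsets = [baseline_lead + k * swallow_interval for k in range(n_swallows)]
    t_exit = onsets[-1] + tail_after_last
    duration = t_exit + post_exit_duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    in_body = t < t_exit  # anatomical pressure ends at t_exit (waterfall end)

    # --- resting anatomy -------------------------------------------------
    sensors = np.arange(N_SENSORS)
    w_ues = np.exp(-((sensors - UES_CENTER) ** 2) / (2 * BAND_SD**2))
    # LES: flat 3-sensor plateau with steep shoulders, so the eSleeve minimum
    # across the band reads the relaxation level, not a band-margin artifact
    d_les = np.maximum(np.abs(sensors - LES_CENTER) - 1, 0)
    w_les = np.exp(-(d_les**2) / (2 * 0.5**2))
    uesp = archetype.uesp_target + rng.normal(0.0, 4.0)
    lesp = archetype.lesp_target + rng.normal(0.0, 2.0)
    rest = (uesp + GASTRIC_LEVEL) * w_ues + (lesp + GASTRIC_LEVEL) * w_les
    rest[LES_CENTER + 2:] = GASTRIC_LEVEL  # intragastric sensors

    P = np.tile(rest[:, None], (1, n))
    # respiratory modulation of the sphincter high-pressure zones
    resp = resp_amp * np.sin(2 * np.pi * 0.25 * t)
    P += (w_ues + w_les)[:, None] * resp[None, :]

    # --- swallows ---------------------------------------------------------
    irp_depth = max(archetype.irp_target + rng.normal(0.0, archetype.irp_study_sd), 0.5)
    relax_abs = GASTRIC_LEVEL + irp_depth + IRP_NOISE_BIAS
    kinds = list(archetype.kind_probs)
    probs = np.array([archetype.kind_probs[k] for k in kinds])
    body_sensors = np.arange(BODY.start, BODY.stop)
    ridge_sd = 0.9  # s, temporal width of the contraction ridge
    # contraction tapers through the transition zone below the UES and into
    # the EGJ so residual sphincter-shoulder baselines stay under the DCI floor
    ridge_taper = np.ones(body_sensors.size)
    ridge_taper[:2] = (0.3, 0.65)
    ridge_taper[-1] = 0.65

    swallow_truth = []
    for onset in onsets:
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        pressurized = bool(rng.random() < archetype.pressurization_p)
        sl = np.flatnonzero((t >= onset - 1.0) & (t < onset + 16.0))
        tt = t[sl] - onset

        # UES relaxation dip (cosmetic; resting pressures are measured pre-swallow)
        f_ues = _trapezoid(tt, 0.0, 0.15, 0.6, 0.8)
        for i in range(max(UES_CENTER - 1, 0), UES_CENTER + 2):
            P[i, sl] = P[i, sl] * (1 - f_ues) + 5.0 * f_ues

        # LES deglutitive relaxation toward the programmed IRP depth
        f_les = _trapezoid(tt, 0.3, 0.7, 8.1, 8.5)
        for i in range(LES_CENTER - 1, LES_CENTER + 2):
            P[i, sl] = P[i, sl] * (1 - f_les) + relax_abs * f_les

        # peristaltic ridge
        amp = {"intact": archetype.amp, "premature": archetype.amp,
               "fragmented": archetype.amp, "weak": archetype.weak_amp,
               "hyper": archetype.hyper_amp, "failed": 18.0}[kind]
        amp *= float(np.exp(rng.normal(0.0, archetype.amp_rel_sd)))
        amp = min(amp, 290.0)
        sigma = ridge_sd * (1.8 if kind == "hyper" else 1.0)
        dl = archetype.premature_dl if kind == "premature" else archetype.dl_target
        # arrival(s): linear from the proximal body to the CDP, then slow
        arrival = np.where(
            body_sensors <= CDP_SENSOR,
            0.8 + (body_sensors - BODY.start) * (dl - 0.8) / (CDP_SENSOR - BODY.start),
            dl + (body_sensors - CDP_SENSOR) / 1.0,
        )
        crossing_level = 30.0 + GASTRIC_LEVEL  # absolute level of the DL contour
        delta = sigma * np.sqrt(2 * np.log(amp / crossing_level)) if amp > crossing_level else 0.0
        centers = arrival + delta
        ridge = (amp * ridge_taper)[:, None] * np.exp(
            -((tt[None, :] - centers[:, None]) ** 2) / (2 * sigma**2)
        )
        if kind == "fragmented":
            lo, hi = archetype.fragment_gap
            ridge[(body_sensors >= lo) & (body_sensors <= hi), :] = 0.0
        P[BODY, sl] += ridge

        if pressurized:  # brief common-cavity column spanning the whole body
            burst = (tt >= 1.5) & (tt < 1.8)
            P[BODY, sl[burst]] = np.maximum(P[BODY, sl[burst]], GASTRIC_LEVEL + 32.0)

        swallow_truth.append({"kind": kind, "pressurized": pressurized, "dl": float(dl)})

    # --- withdrawal collapse, noise, drift, violations --------------------
    P[:, ~in_body] = 0.0
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=P.shape)
        noise[:, ~in_body] = 0.0
        P += noise
    if qc_violation == "residual_pressure":
        P[15:17, ~in_body] = 40.0

    amplitudes = drift.draw_amplitudes(rng_drift, N_SENSORS)
    gains = drift.draw_gains(rng_drift, N_SENSORS)
    P += drift.curve(t, t_exit, amplitudes, gains)

    ground_truth = {
        "archetype": next((k for k, v in ARCHETYPES.items() if v is archetype), "custom"),
        "label": archetype.label,
        "irp_depth": float(irp_depth),
        "swallows": swallow_truth,
        "drift_amplitudes": amplitudes.tolist(),
        "true_drift_at_anchor": {
            str(a): drift.at_anchor(t_exit, amplitudes, a, gains).tolist() for a in (0, 1, 5, 10)
        },
        "fold_flag": qc_violation == "fold",
        "qc_violation": qc_violation,
    }
    return PressureStudy(
        pressure=P,
        fs=fs,
        t_exit=t_exit,
        swallow_onsets=onsets,
        study_id=study_id or f"{ground_truth['archetype']}-{seed:05d}",
        ground_truth=ground_truth,
    )


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: ``n_per_archetype`` studies of each named archetype."""

    n_per_archetype: dict[str, int] = field(default_factory=lambda: {"nem": 4, "iem": 4, "egjoo": 4, "t2a": 4, "des": 4})
    seed: int = 0
    drift: DriftModel = field(default_factory=DriftModel)
    n_swallows: int = 10
    fs: float = 50.0

    def __post_init__(self):
        if not self.n_per_archetype or sum(self.n_per_archetype.values()) < 1:
            raise ValidationError("n_per_archetype", "cohort must contain at least one study")
        unknown = set(self.n_per_archetype) - set(ARCHETYPES)
        if unknown:
            raise ValidationError("n_per_archetype", f"unknown archetypes {sorted(unknown)}")


def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[PressureStudy], pd.DataFrame]:
    """Generate a deterministic cohort; optionally write study bundles.

    Returns the studies and a manifest (``study_id, true_label, seed`` plus
    ``path`` when bundles are written).  The same spec (same seed) produces a
    byte-identical cohort.
    """
    studies, rows = [], []
    idx = 0
    for name in sorted(spec.n_per_archetype):
        for _ in range(spec.n_per_archetype[name]):
            child_seed = (spec.seed * 1009 + idx) % (2**31)
            study = simulate_study(
                name, spec.drift, seed=child_seed, fs=spec.fs,
                n_swallows=spec.n_swallows,
                study_id=f"{name}-{idx:03d}",
            )
            studies.append(study)
            rows.append({"study_id": study.study_id,
                         "true_label": ARCHETYPES[name].label,
                         "seed": child_seed})
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [str(write_study(s, out_dir / s.study_id)) for s in studies]
        manifest["path"] = paths
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return studies, manifest


def simulate_qc_cohort(
    seed: int = 0,
    n_total: int = 136,
    violations: dict[str, int] | None = None,
    drift: DriftModel | None = None,
) -> list[PressureStudy]:
    """A review-flow cohort with planted protocol violations.

    Generates ``n_total`` studies over a mix of archetypes; the first studies
    of the shuffled order receive the planted violations (default 12: short
    post-removal tails, over-long procedures, residual sensor pressure and
    catheter folds) so the quality screen should include exactly
    ``n_total - sum(violations)`` studies.
    """
    violations = violations if violations is not None else {
        "short_tail": 4, "overlong": 3, "residual_pressure": 3, "fold": 2,
    }
    drift = drift or DriftModel()
    plan: list[str | None] = [v for v, k in violations.items() for _ in range(k)]
    plan += [None] * (n_total - len(plan))
    if len(plan) != n_total:
        raise ValidationError("violations", "more violations than studies")
    rng = np.random.default_rng([seed, 17])
    rng.shuffle(plan)
    mix = ["nem", "nem", "nem", "egjoo", "iem", "iem", "t2a", "nem", "egjoo", "ac"]
    studies = []
    for i, violation in enumerate(plan):
        studies.append(
            simulate_study(
                mix[i % len(mix)], drift,
                seed=(seed * 1013 + i) % (2**31),
                qc_violation=violation,
                study_id=f"qc-{i:03d}",
            )
        )
    return studies
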