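"""Pre-analysis quality screen for HRM recordings.

A study is excluded when the catheter was withdrawn with less than 10 s of
post-removal recording (no reliable drift anchor exists), when the study
runs longer than 15 min (drift grows with procedure duration), when pressure
remained on the sensors after the study ended, or when the catheter folded
during the procedure.  Fold detection is taken from the study annotation
(simulator flag); no heuristic fold recognition is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import PressureStudy

__all__ = ["QCReport", "screen"]

MIN_POST_EXIT_S = 10.0
MAX_STUDY_DURATION_S = 900.0
RESIDUAL_PRESSURE_MMHG = 20.0


@dataclass
class QCReport:
    study_id: str
    post_exit_duration: float
    study_duration: float
    residual_pressure_flag: bool
    fold_flag: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "exclude" if self.reasons else "include"

    @property
    def include(self) -> bool:
        return not self.reasons


def screen(
    study: PressureStudy,
    min_post_exit: float = MIN_POST_EXIT_S,
    max_duration: float = MAX_STUDY_DURATION_S,
    residual_threshold: float = RESIDUAL_PRESSURE_MMHG,
) -> QCReport:
    """Apply the exclusion rules; always returns a report, never raises.

    The residual-pressure rule flags any sensor whose mean reading over the
    final second of the recording exceeds ``residual_threshold`` (20 mmHg by
    default — well above plausible thermal drift but below held anatomical
    pressure).
    """
    post_exit = study.duration - study.t_exit
    reasons: list[str] = []
    if post_exit < min_post_exit:
        reasons.append(f"post-removal recording < {min_post_exit:g} s ({post_exit:.1f} s)")
    if study.duration > max_duration:
        reasons.append(f"study duration exceeds {max_duration / 60:g} min ({study.duration / 60:.1f} min)")

    last_second = study.window(study.duration - 1.0, study.duration)
    residual = study.pressure[:, last_second].mean(axis=1)
    residual_flag = bool((residual > residual_threshold).any())
    if residual_flag:
        reasons.append(f"residual pressure on sensors after study end (max {residual.max():.1f} mmHg)")

    fold_flag = bool((study.ground_truth or {}).get("fold_flag", False))
    if fold_flag:
        reasons.append("catheter folded during the procedure")

    return QCReport(
        study_id=study.study_id,
        post_exit_duration=post_exit,
        study_duration=study.duration,
        residual_pressure_flag=residual_flag,
        fold_flag=fold_flag,
        reasons=reasons,
    )
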