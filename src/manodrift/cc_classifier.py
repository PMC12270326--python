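"""Chicago-style diagnostic decision tree over study-level metrics.

The tree first splits on the median IRP (strictly > 15 mmHg = impaired EGJ
relaxation on this platform, supine), then works through the disorder
definitions in a fixed precedence: achalasia types and outflow obstruction
on the elevated-IRP branch; absent contractility / achalasia-cannot-rule-out,
spasm, hypercontractile esophagus, ineffective motility and fragmented
peristalsis on the normal-IRP branch; anything left is normal esophageal
motility.  The only composite label emitted is DES+IEM (spasm and
ineffective motility firing together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import AnalysisParams
from .swallow_metrics import StudyMetrics

__all__ = ["Diagnosis", "LABELS", "classify", "irp_category"]

#: Every label the tree can emit.
LABELS = ("T1A", "T2A", "T3A", "EGJ_OO", "AC", "ACR", "DES", "HE", "IEM", "FP", "NEM", "DES_IEM")

#: Human-readable names (CLI / report output).
LABEL_NAMES = {
    "T1A": "type 1 achalasia",
    "T2A": "type 2 achalasia",
    "T3A": "type 3 achalasia",
    "EGJ_OO": "EGJ outflow obstruction",
    "AC": "absent contractility",
    "ACR": "achalasia cannot rule out",
    "DES": "distal esophageal spasm",
    "HE": "hypercontractile esophagus",
    "IEM": "ineffective esophageal motility",
    "FP": "fragmented peristalsis",
    "NEM": "normal esophageal motility",
    "DES_IEM": "distal esophageal spasm + ineffective motility",
}


@dataclass(frozen=True)
class Diagnosis:
    label: str
    rule_trace: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown diagnosis label {self.label!r}")
        if not self.rule_trace:
            raise ValueError("rule_trace must record at least one evaluated rule")


def irp_category(sm: StudyMetrics, params: AnalysisParams | None = None) -> str:
    """'elevated' iff median IRP strictly exceeds the 15-mmHg threshold."""
    params = params or AnalysisParams()
    return "elevated" if sm.median_irp > params.irp_threshold else "normal"


def classify(
    sm: StudyMetrics,
    hyper_count: int = 0,
    params: AnalysisParams | None = None,
) -> Diagnosis:
    """Map study metrics to exactly one diagnosis (total function).

    ``hyper_count`` is the number of swallows with DCI > 8000 mmHg·s·cm
    (defaults to ``sm.n_hyper`` when omitted as 0 would under-count).

    Elevated-IRP branch: 100% failed peristalsis → type 2 achalasia when
    panesophageal pressurization occurs in ≥20% of swallows, else type 1;
    otherwise no normal peristalsis with ≥20% premature (DCI > 450) → type 3;
    otherwise EGJ outflow obstruction.

    Normal-IRP branch: 100% failed → achalasia-cannot-rule-out when the IRP
    is borderline (10, 15] with pressurization evidence, else absent
    contractility; then ≥20% premature → DES; ≥2 hypercontractile swallows →
    HE; >50% ineffective → IEM; >50% fragmented → FP; DES and IEM both
    firing give the composite DES+IEM; otherwise normal motility.
    """
    params = params or AnalysisParams()
    hyper_count = hyper_count or sm.n_hyper
    trace: list[str] = []

    def check(desc: str, fired: bool) -> bool:
        trace.append(f"{desc}: {'yes' if fired else 'no'}")
        return fired

    elevated = check(f"median IRP > {params.irp_threshold:g} mmHg ({sm.median_irp:.1f})",
                     sm.median_irp > params.irp_threshold)
    if elevated:
        if check("100% failed peristalsis", sm.pct_failed == 100.0):
            if check("panesophageal pressurization in >=20% of swallows",
                     sm.pct_pressurization >= 20.0):
                return Diagnosis("T2A", tuple(trace))
            return Diagnosis("T1A", tuple(trace))
        if check("no normal peristalsis and >=20% premature contractions",
                 sm.pct_intact == 0.0 and sm.pct_premature >= 20.0):
            return Diagnosis("T3A", tuple(trace))
        trace.append("sufficient evidence of peristalsis: yes")
        return Diagnosis("EGJ_OO", tuple(trace))

    if check("100% failed peristalsis", sm.pct_failed == 100.0):
        lo, hi = params.borderline_irp
        if check(f"borderline IRP ({lo:g}, {hi:g}] with pressurization evidence",
                 lo < sm.median_irp <= hi and sm.pct_pressurization >= 20.0):
            return Diagnosis("ACR", tuple(trace))
        return Diagnosis("AC", tuple(trace))

    des = check(">=20% premature contractions (DCI > 450)", sm.pct_premature >= 20.0)
    iem = check(">50% ineffective swallows", sm.pct_ineffective > 50.0)
    if des and iem:
        return Diagnosis("DES_IEM", tuple(trace))
    if des:
        return Diagnosis("DES", tuple(trace))
    if check(">=2 swallows with DCI > 8000", hyper_count >= 2):
        return Diagnosis("HE", tuple(trace))
    if iem:
        return Diagnosis("IEM", tuple(trace))
    if check(">50% fragmented contractions (DCI > 450)", sm.pct_fragmented > 50.0):
        return Diagnosis("FP", tuple(trace))
    trace.append("no disorder criteria met: normal esophageal motility")
    return Diagnosis("NEM", tuple(trace))
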