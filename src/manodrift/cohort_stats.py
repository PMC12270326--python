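"""Cohort-level comparison of the five compensation conditions.

The same studies are re-analyzed under each thermal-compensation condition
and compared as independent groups (mirroring the clinical analysis
convention; a paired mode would be stronger but is deliberately not the
default).  Continuous metrics are summarized as median (IQR) unless a
two-test Kolmogorov–Smirnov gate declares every group normal; group
differences use Kruskal–Wallis with Mann–Whitney U post hocs summarized as
a compact letter display (letters k, l, m …); diagnosis distributions use
Pearson chi-square with adjusted standardized residuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cc_classifier import classify, irp_category
from .core_model import AnalysisParams, PressureStudy, TCCondition, STANDARD_CONDITIONS
from .qc_screen import screen
from .swallow_metrics import analyze_study
from .thermal_compensation import compensate

__all__ = [
    "kruskal_wallis",
    "mann_whitney",
    "chisq_homogeneity",
    "normality_gate",
    "compact_letters",
    "compare_conditions",
    "build_flip_table",
    "FlipTable",
    "CohortComparison",
    "METRIC_ORDER",
    "DIAGNOSIS_GROUPS",
    "TABLE8_PUBLISHED",
]

#: Report row order (the conventional metric panel).
METRIC_ORDER = [
    "uesp", "lesp", "median_irp", "pct_weak", "pct_failed", "pct_ineffective",
    "pct_pressurization", "pct_premature", "pct_fragmented", "pct_intact",
    "median_dl", "median_dci",
]

#: Grouping of diagnosis labels used in the IRP-flip cross-tabulation.
DIAGNOSIS_GROUPS = {
    "NEM": ("NEM",),
    "IEM": ("IEM",),
    "EGJ-OO": ("EGJ_OO",),
    "Achalasia": ("T1A", "T2A", "T3A"),
    "Other": ("AC", "ACR", "DES", "FP", "HE", "DES_IEM"),
}


def _group_of(label: str) -> str:
    for group, members in DIAGNOSIS_GROUPS.items():
        if label in members:
            return group
    raise KeyError(label)


# ---------------------------------------------------------------------------
# elementary tests


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Degenerate input (every value identical) returns (0, 1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (normal approximation, tie-corrected).

    Returns the U statistic of the first sample (number of (a, b) pairs with
    a > b, ties counting 1/2).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chisq_homogeneity(table) -> tuple[float, float, np.ndarray]:
    """Pearson chi-square for a counts matrix plus adjusted residuals.

    The adjusted standardized residual of cell (i, j) is
    ``(O − E) / sqrt(E · (1 − row_share) · (1 − col_share))``; |r| > 1.96
    marks a cell driving the overall result.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(O < 0) or not np.allclose(O, np.round(O)):
        raise ValueError("table must hold nonnegative counts")
    row, col, n = O.sum(axis=1), O.sum(axis=0), O.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    E = np.outer(row, col) / n
    chi2, p, _, _ = stats.chi2_contingency(O, correction=False)
    denom = np.sqrt(E * (1 - row[:, None] / n) * (1 - col[None, :] / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (O - E) / denom, 0.0)
    return float(chi2), float(p), r


def normality_gate(values: Sequence[float]) -> bool:
    """True when BOTH normality tests accept (p > 0.05): a one-sample KS test
    against the fitted normal and the Lilliefors-corrected KS test.  Small or
    degenerate samples take the nonparametric path."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(values, dtype=float)
    if x.size < 5 or np.std(x) == 0:
        return False
    _, p_ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    try:
        _, p_lf = lilliefors(x, dist="norm")
    except Exception:
        return False
    return p_ks > 0.05 and p_lf > 0.05


def compact_letters(
    names: Sequence[str],
    medians: Sequence[float],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = 0.05,
    alphabet: str = "klmnopq",
) -> dict[str, str]:
    """Compact letter display over groups.

    Groups sharing a letter are not significantly different.  Letters are
    the maximal cliques of the "not significantly different" graph, lettered
    k, l, m … in order of the smallest group median they contain.
    """
    names = list(names)
    sig = {frozenset(k): (p < alpha) for k, p in pairwise_p.items()}

    def compatible(subset: tuple[str, ...]) -> bool:
        return not any(sig.get(frozenset((a, b)), False)
                       for a, b in itertools.combinations(subset, 2))

    cliques = []
    for r in range(len(names), 0, -1):
        for subset in itertools.combinations(names, r):
            if compatible(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    med = dict(zip(names, medians))
    cliques.sort(key=lambda c: min(med[g] for g in c))
    out = {g: "" for g in names}
    for letter, clique in zip(alphabet, cliques):
        for g in clique:
            out[g] += letter
    return out


# ---------------------------------------------------------------------------
# flip cross-tabulation


@dataclass
class FlipTable:
    """Diagnosis × reference-IRP-stratum counts per condition."""

    cross_tab: pd.DataFrame     # rows: condition; cols: (stratum, diagnosis group)
    flips: pd.DataFrame         # per condition: IRP-category flips up / down vs reference
    stratum_sizes: dict[str, int]
    reference: str


def build_flip_table(
    per_study: pd.DataFrame,
    reference: str = "ftc",
    irp_threshold: float = 15.0,
) -> FlipTable:
    """Stratify studies by the reference condition's IRP category and count
    diagnoses (grouped as NEM / IEM / EGJ-OO / Achalasia / Other) per
    condition within each stratum.

    ``per_study`` needs columns ``study_id, condition, label, median_irp``;
    every condition must cover the same study set.  Row sums within a
    stratum equal the stratum size for every condition (a partition), and
    the flip counts record how many studies cross the IRP threshold in each
    direction relative to the reference condition.
    """
    conditions = list(dict.fromkeys(per_study["condition"]))
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    sets = {c: set(g["study_id"]) for c, g in per_study.groupby("condition", sort=False)}
    if any(sets[c] != sets[reference] for c in conditions):
        raise ValueError("all conditions must cover the same studies")

    ref = per_study[per_study["condition"] == reference].set_index("study_id")
    stratum_of = (ref["median_irp"] > irp_threshold).map(
        {False: f"IRP <= {irp_threshold:g}", True: f"IRP > {irp_threshold:g}"}
    )
    strata = [f"IRP <= {irp_threshold:g}", f"IRP > {irp_threshold:g}"]
    groups = list(DIAGNOSIS_GROUPS)

    rows, flip_rows = [], []
    for cond in conditions:
        sub = per_study[per_study["condition"] == cond].set_index("study_id")
        counts = {(s, g): 0 for s in strata for g in groups}
        up = down = 0
        for sid, rec in sub.iterrows():
            stratum = stratum_of[sid]
            counts[(stratum, _group_of(rec["label"]))] += 1
            elevated_now = rec["median_irp"] > irp_threshold
            elevated_ref = ref.loc[sid, "median_irp"] > irp_threshold
            up += (not elevated_ref) and elevated_now
            down += elevated_ref and (not elevated_now)
        rows.append(pd.Series(counts, name=cond))
        flip_rows.append({"condition": cond, "irp_flips_up": up, "irp_flips_down": down})

    cross = pd.DataFrame(rows)
    cross.columns = pd.MultiIndex.from_tuples(cross.columns, names=["stratum", "diagnosis"])
    sizes = stratum_of.value_counts().to_dict()
    return FlipTable(
        cross_tab=cross,
        flips=pd.DataFrame(flip_rows).set_index("condition"),
        stratum_sizes={s: int(sizes.get(s, 0)) for s in strata},
        reference=reference,
    )


# ---------------------------------------------------------------------------
# full comparison


@dataclass
class CohortComparison:
    per_study: pd.DataFrame                 # condition × study metric/label long table
    summaries: pd.DataFrame                 # metric × condition summary strings
    kw: dict[str, tuple[float, float]]      # metric -> (H, p)
    pairwise: dict[str, dict[tuple[str, str], float]]
    letters: dict[str, dict[str, str]]      # metric -> condition -> letters
    diag_counts: pd.DataFrame               # diagnosis × condition counts
    chisq: dict[str, tuple[float, float, np.ndarray]]  # per-diagnosis 2xK test
    flip_table: FlipTable | None
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (study_id, reason)
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.per_study.groupby("condition")["study_id"].nunique().max()


def compare_conditions(
    studies: Sequence[PressureStudy],
    conditions: Sequence[TCCondition] = STANDARD_CONDITIONS,
    params: AnalysisParams | None = None,
    alpha: float = 0.05,
    qc: bool = True,
    reference: str = "ftc",
) -> CohortComparison:
    """Run compensate → metrics → classify for every study under every
    condition and assemble the full comparison report.

    Studies failing the quality screen are excluded up front (with reasons);
    per-study analysis failures are reported in ``failures`` rather than
    silently dropped — a failure under any condition removes the study from
    every condition so the groups stay comparable.
    """
    params = params or AnalysisParams()
    excluded: list[tuple[str, str]] = []
    kept: list[PressureStudy] = []
    for s in studies:
        rep = screen(s) if qc else None
        if rep is not None and not rep.include:
            excluded.append((s.study_id, "; ".join(rep.reasons)))
        else:
            kept.append(s)

    rows, failures = [], []
    failed_ids: set[str] = set()
    for study in kept:
        for cond in conditions:
            try:
                comp = compensate(study, cond, params)
                analysis = analyze_study(comp, params)
                dx = classify(analysis.metrics, analysis.metrics.n_hyper, params)
            except Exception as exc:  # propagate per-study failures as a report
                failures.append((study.study_id, cond.name, str(exc)))
                failed_ids.add(study.study_id)
                continue
            row = {"study_id": study.study_id, "condition": cond.name,
                   "label": dx.label, "irp_category": irp_category(analysis.metrics, params)}
            row.update(analysis.metrics.as_dict())
            rows.append(row)
    per_study = pd.DataFrame(rows)
    if failed_ids and len(per_study):
        per_study = per_study[~per_study["study_id"].isin(failed_ids)].reset_index(drop=True)
    if per_study.empty:
        raise ValueError("no study survived QC and analysis")

    cond_names = [c.name for c in conditions]
    groups = {c: per_study[per_study["condition"] == c] for c in cond_names}

    kw, pairwise, letters = {}, {}, {}
    summary_rows = {}
    for metric in METRIC_ORDER:
        vals = {c: groups[c][metric].dropna().to_numpy() for c in cond_names}
        usable = {c: v for c, v in vals.items() if v.size}
        all_normal = all(normality_gate(v) for v in usable.values())
        cells = {}
        for c in cond_names:
            v = vals[c]
            if v.size == 0:
                cells[c] = "-"
            elif all_normal:
                cells[c] = f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
            else:
                q1, q2, q3 = np.percentile(v, [25, 50, 75])
                cells[c] = f"{q2:.1f} ({q1:.1f}-{q3:.1f})"
        if len(usable) >= 2:
            h, p = kruskal_wallis(list(usable.values()))
            kw[metric] = (h, p)
            if p < alpha:
                pw = {
                    (a, b): mann_whitney(usable[a], usable[b])[1]
                    for a, b in itertools.combinations(usable, 2)
                }
                pairwise[metric] = pw
                letters[metric] = compact_letters(
                    list(usable), [np.median(usable[c]) for c in usable], pw, alpha
                )
        summary_rows[metric] = cells
    summaries = pd.DataFrame(summary_rows).T[cond_names]

    diag_counts = (
        per_study.pivot_table(index="label", columns="condition",
                              values="study_id", aggfunc="count", fill_value=0)
        .reindex(columns=cond_names, fill_value=0)
    )
    n_per_cond = per_study.groupby("condition")["study_id"].nunique()
    chisq = {}
    for label, row in diag_counts.iterrows():
        table = np.array([[row[c], n_per_cond[c] - row[c]] for c in cond_names]).T
        try:
            chisq[label] = chisq_homogeneity(table)
        except ValueError:
            continue  # degenerate marginal (diagnosis absent everywhere)

    flip = None
    if reference in cond_names:
        flip = build_flip_table(per_study, reference=reference, irp_threshold=params.irp_threshold)

    return CohortComparison(
        per_study=per_study,
        summaries=summaries,
        kw=kw,
        pairwise=pairwise,
        letters=letters,
        diag_counts=diag_counts,
        chisq=chisq,
        flip_table=flip,
        excluded=excluded,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# published cross-tabulation fixture


def _table8() -> pd.DataFrame:
    """Verbatim transcription of the published IRP-flip cross-tabulation:
    diagnosis-group counts per condition, stratified by the reference
    (formal-compensation) IRP category of each of the 124 studies.

    Known internal inconsistencies of the source are preserved as printed
    (e.g. the reference-condition NEM count here is 53 while the diagnosis
    table prints 52).
    """
    strata = ["IRP <= 15", "IRP > 15"]
    groups = list(DIAGNOSIS_GROUPS)
    data = {
        "ftc":   [53, 24, 0, 0, 8,    0, 0, 21, 18, 0],
        "nontc": [38, 22, 14, 2, 9,   1, 1, 20, 17, 0],
        "tc1":   [52, 22, 0, 0, 11,   7, 0, 14, 17, 1],
        "tc5":   [52, 21, 3, 1, 8,    6, 1, 14, 18, 0],
        "tc10":  [55, 14, 7, 1, 8,    6, 1, 15, 17, 0],
    }
    cols = pd.MultiIndex.from_product([strata, groups], names=["stratum", "diagnosis"])
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


TABLE8_PUBLISHED: pd.DataFrame = _table8()
TABLE8_STRATUM_SIZES = {"IRP <= 15": 85, "IRP > 15": 39}
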