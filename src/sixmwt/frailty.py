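"""Frailty phenotype scoring and the stride-length × cadence frailty map.

The J-CHS phenotype has five binary items — weight loss, exhaustion, low
physical activity (questionnaire), weak handgrip (< 26 kg men / < 18 kg
women) and slow gait (five-meter walking speed < 1.0 m/s) — and classifies
a total of n ≥ 3 as frail, 1–2 as pre-frail and 0 as non-frail.  The
(SL, SC) plane is cut at 0.6 m/step and 2.0 step/s into four ranges used
as a visual frailty map, and ROC analysis with a Youden-index cutoff
relates single gait parameters to individual frailty items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .types import AnalysisConfig, Gender, SubjectRecord

logger = logging.getLogger(__name__)

FRAIL = "frail"
PRE_FRAIL = "pre-frail"
NON_FRAIL = "non-frail"

HANDGRIP_CUTOFF = {Gender.MALE: 26.0, Gender.FEMALE: 18.0}  # kg
SPEED_CUTOFF = 1.0  # m/s, five-meter walking test


class FrailtyRange(str, Enum):
    """Quadrants of the SC×SL map (I strongest … III weakest)."""

    I = "I"      # SL > cut, SC > cut
    II = "II"    # SL > cut, SC ≤ cut
    III = "III"  # SL ≤ cut, SC ≤ cut
    IV = "IV"    # SL ≤ cut, SC > cut


@dataclass
class JCHSResult:
    """Scored frailty phenotype: five item booleans, total n, and category."""

    weight_loss: bool
    exhaustion: bool
    low_activity: bool
    weak_handgrip: bool
    slow_speed: bool

    @property
    def item_scores(self) -> tuple[bool, bool, bool, bool, bool]:
        return (self.weight_loss, self.exhaustion, self.low_activity,
                self.weak_handgrip, self.slow_speed)

    @property
    def n(self) -> int:
        return sum(self.item_scores)

    @property
    def category(self) -> str:
        if self.n >= 3:
            return FRAIL
        if self.n >= 1:
            return PRE_FRAIL
        return NON_FRAIL


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc {self.auc} outside [0, 1]")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


def jchs_score(subject: SubjectRecord) -> JCHSResult:
    """Score the five-item frailty phenotype for one subject."""
    missing = [
        name for name in
        ("gender", "handgrip", "speed5m", "q_weight_loss", "q_exhaustion", "q_low_activity")
        if getattr(subject, name) is None
    ]
    if missing:
        raise ValueError(f"subject {subject.subject_id}: missing items {missing}")
    return JCHSResult(
        weight_loss=bool(subject.q_weight_loss),
        exhaustion=bool(subject.q_exhaustion),
        low_activity=bool(subject.q_low_activity),
        weak_handgrip=subject.handgrip < HANDGRIP_CUTOFF[subject.gender],
        slow_speed=subject.speed5m < SPEED_CUTOFF,
    )


def roc_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "greater",
) -> RocResult:
    """ROC analysis with the Youden-index optimal cutoff.

    ``direction="greater"`` treats larger scores as predicting the positive
    label; ``"less"`` the reverse (e.g. shorter strides predicting weak
    handgrip).  AUC is the trapezoidal area under the oriented curve; ties
    in Youden's J are broken toward the cutoff nearest the score median.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both label classes must be present")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    oriented = scores if direction == "greater" else -scores
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, oriented)
    auc = float(skmetrics.auc(fpr, tpr))
    j = tpr - fpr
    best = j == j.max()
    # drop the synthetic +inf threshold sklearn prepends unless it is the only optimum
    finite = best & np.isfinite(thresholds)
    candidates = np.flatnonzero(finite if finite.any() else best)
    med = float(np.median(oriented))
    k = candidates[np.argmin(np.abs(thresholds[candidates] - med))]
    cutoff = float(thresholds[k])
    return RocResult(
        auc=auc,
        cutoff=cutoff if direction == "greater" else -cutoff,
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        direction=direction,
    )


def classify_range(
    sl: float, sc: float, config: Optional[AnalysisConfig] = None
) -> FrailtyRange:
    """Assign an (SL, SC) point to one of the four frailty-map ranges.

    Range I requires strictly exceeding both cutoffs; Range III is the
    inclusive complement (both ≤); II and IV are the mixed quadrants.
    """
    config = config or AnalysisConfig()
    if sl < 0 or sc < 0:
        raise ValueError("sl and sc must be non-negative")
    above_sl = sl > config.cut_sl
    above_sc = sc > config.cut_sc
    if above_sl and above_sc:
        return FrailtyRange.I
    if above_sl:
        return FrailtyRange.II
    if above_sc:
        return FrailtyRange.IV
    return FrailtyRange.III


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d: |mean difference| / pooled SD (n−1 weighted pooling)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float(abs(a.mean() - b.mean()) / pooled)


def group_compare(
    df: pd.DataFrame,
    parameters: Sequence[str],
    category_col: str = "category",
    alpha_normal: float = 0.05,
) -> pd.DataFrame:
    """Pairwise group comparison table (mean ± SD, p, Cohen's d) per parameter.

    Each group is screened for normality (Shapiro–Wilk, skipped with a
    warning below n=3); normal pairs use Student's t-test and the rest a
    one-way ANOVA, mirroring the cohort-analysis convention of the study.
    """
    cats = [c for c in df[category_col].unique()]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories to compare")
    order = [c for c in (FRAIL, PRE_FRAIL, NON_FRAIL) if c in cats]
    order += [c for c in cats if c not in order]
    rows = []
    for param in parameters:
        for ca, cb in zip(order, order[1:]):
            a = df.loc[df[category_col] == ca, param].dropna().to_numpy()
            b = df.loc[df[category_col] == cb, param].dropna().to_numpy()
            normal = True
            for name, vals in ((ca, a), (cb, b)):
                if len(vals) < 3:
                    logger.warning(
                        "group %s has n=%d < 3: skipping normality screen", name, len(vals)
                    )
                elif np.ptp(vals) > 0 and stats.shapiro(vals).pvalue < alpha_normal:
                    normal = False
            if normal:
                test = "t-test"
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            else:
                test = "anova"
                p = float(stats.f_oneway(a, b).pvalue)
            try:
                d = cohens_d(a, b)
            except ValueError:
                d = float("nan")
            rows.append({
                "parameter": param, "group_a": ca, "group_b": cb,
                "n_a": len(a), "n_b": len(b),
                "mean_a": float(np.mean(a)), "sd_a": float(np.std(a, ddof=1)),
                "mean_b": float(np.mean(b)), "sd_b": float(np.std(b, ddof=1)),
                "test": test, "p_value": p, "cohens_d": d,
            })
    return pd.DataFrame(rows)


def range_occupancy(
    df: pd.DataFrame,
    sl_col: str = "sl",
    sc_col: str = "sc",
    category_col: str = "category",
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Percentage of each category falling in each frailty-map range.

    Rows are categories, columns the four ranges; each row sums to 100.
    """
    config = config or AnalysisConfig()
    labels = df.apply(
        lambda row: classify_range(row[sl_col], row[sc_col], config).value, axis=1
    )
    table = (
        pd.crosstab(df[category_col], labels, normalize="index") * 100.0
    )
    for r in ("I", "II", "III", "IV"):
        if r not in table.columns:
            table[r] = 0.0
    return table[["I", "II", "III", "IV"]]
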