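"""Delta-index and staged cutoff classification of PH subgroups.

The delta-index relates the homogeneity of the iodine-density distribution
in malperfused lung (ID skewness in PerfDef) to the extent of emphysema:

    delta = (skew_perfdef + 1.36) / (emphysema_pct + 1.0)

with emphysema on the percent (0-100) scale. Both translations make the
quotient well defined: +1.36 shifts skewness just past the smallest value
observed in the defining cohort (-1.35) into the strictly positive range,
and +1.0 guards the divisor. Homogeneous perfusion defects (skewness near 0)
with little emphysema — the CTEPH pattern — give a high delta; homogeneous
defects explained by emphysema (group 3) give a low delta.

The staged classifier mirrors the clinical stepwise read: (1) PH suspicion
when the normally perfused volume fraction is low, (2) groups 3/4 when the
PerfDef ID skewness is near zero (>= -0.335), (3) CTEPH (group 4) when
delta >= 0.502, else group 3. Group 1 and group 2 are pooled as "other" —
their perfusion patterns are not separable by these features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

#: Translation added to PerfDef ID skewness in the delta-index, fixed by the
#: published definition (one more hundredth than the smallest observed
#: skewness, -1.35).
SKEW_TRANSLATION = 1.36

#: Translation added to the emphysema percentage (divisor guard).
EMPHYSEMA_TRANSLATION = 1.0

PRED_PH = "PH"
PRED_NO_PH = "no-PH"
PRED_UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class DeltaIndexResult:
    value: float
    skew_perfdef_in: float
    emphysema_pct_in: float


@dataclass(frozen=True)
class Cutoffs:
    """Operating cutoffs of the staged classifier (published defaults).

    ``v_perfnorm_pct``: below this normally-perfused volume percentage the
    case is flagged PH (weak rule; reported AUC 0.67 clinically).
    ``skew_perfdef``: at or above this PerfDef ID skewness the defect is
    homogeneous (groups 3/4). ``delta_index``: at or above this delta the
    case is called CTEPH (group 4).
    """

    v_perfnorm_pct: float = 71.6
    skew_perfdef: float = -0.335
    delta_index: float = 0.502


DEFAULT_CUTOFFS = Cutoffs()


@dataclass(frozen=True)
class StagedPrediction:
    pred_stage1: str           # PH | no-PH | unevaluable
    pred_group34: bool
    pred_subgroup: str         # g3 | g4 | other | unevaluable
    cutoffs_used: Cutoffs


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_pos: int
    n_neg: int


def delta_index(
    skew_perfdef: float,
    emphysema_pct: float,
    translation: float = SKEW_TRANSLATION,
) -> DeltaIndexResult:
    """(skew_perfdef + 1.36) / (emphysema_pct + 1.0).

    ``emphysema_pct`` must be on the percent (0-100) scale. ``translation``
    overrides the skewness shift for cohort-specific re-derivation; the
    default is the published constant.
    """
    if math.isnan(skew_perfdef) or math.isnan(emphysema_pct):
        raise ValueError("delta_index inputs must not be missing (NaN)")
    if emphysema_pct < 0:
        raise ValueError(f"emphysema_pct must be >= 0, got {emphysema_pct}")
    value = (skew_perfdef + translation) / (emphysema_pct + EMPHYSEMA_TRANSLATION)
    return DeltaIndexResult(value=value, skew_perfdef_in=skew_perfdef,
                            emphysema_pct_in=emphysema_pct)


def classify_stage1_ph(v_perfnorm_pct: float, cutoff: float = DEFAULT_CUTOFFS.v_perfnorm_pct) -> bool:
    """PH iff the normally perfused volume fraction is strictly below the cutoff."""
    if math.isnan(v_perfnorm_pct):
        raise ValueError("v_perfnorm_pct is missing")
    if not 0 <= v_perfnorm_pct <= 100:
        raise ValueError(f"v_perfnorm_pct must be in [0, 100], got {v_perfnorm_pct}")
    return v_perfnorm_pct < cutoff


def classify_group34(skew_perfdef: float, cutoff: float = DEFAULT_CUTOFFS.skew_perfdef) -> bool:
    """Groups 3/4 (homogeneous defects) iff PerfDef ID skewness >= cutoff."""
    if math.isnan(skew_perfdef):
        raise ValueError("skew_perfdef is missing")
    return skew_perfdef >= cutoff


def classify_cteph(delta: float, cutoff: float = DEFAULT_CUTOFFS.delta_index) -> bool:
    """CTEPH (group 4) iff delta-index >= cutoff."""
    if math.isnan(delta):
        raise ValueError("delta_index is missing")
    if delta < 0:
        raise ValueError(f"delta_index must be >= 0, got {delta}")
    return delta >= cutoff


def _get(record, name: str) -> float:
    if isinstance(record, dict):
        v = record.get(name, math.nan)
    else:
        v = getattr(record, name, math.nan)
    try:
        return float(v)
    except (TypeError, ValueError):
        return math.nan


def classify_case(
    record,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
    skip_stage1: bool = False,
) -> StagedPrediction:
    """Apply the staged rules to one feature record.

    ``record`` is a :class:`~sdctperf.features.CaseFeatureRecord`, any object
    with the feature-CSV attribute names, or a dict. With ``skip_stage1``
    the case is treated as known-PH and only the subgroup stages run (the
    volume rule is weak and the subgroup question usually arises in an
    already-diagnosed PH population). A missing required feature yields an
    unevaluable prediction, never a guess.
    """
    if skip_stage1:
        stage1, is_ph = PRED_PH, True
    else:
        v = _get(record, "v_perfnorm_pct")
        if math.isnan(v):
            return StagedPrediction(PRED_UNEVALUABLE, False, PRED_UNEVALUABLE, cutoffs)
        is_ph = classify_stage1_ph(v, cutoffs.v_perfnorm_pct)
        stage1 = PRED_PH if is_ph else PRED_NO_PH
    if not is_ph:
        return StagedPrediction(stage1, False, "other", cutoffs)

    skew = _get(record, "skew_def")
    if math.isnan(skew):
        return StagedPrediction(stage1, False, PRED_UNEVALUABLE, cutoffs)
    if not classify_group34(skew, cutoffs.skew_perfdef):
        return StagedPrediction(stage1, False, "other", cutoffs)

    delta = _get(record, "delta_index")
    if math.isnan(delta):
        return StagedPrediction(stage1, True, PRED_UNEVALUABLE, cutoffs)
    subgroup = "g4" if classify_cteph(delta, cutoffs.delta_index) else "g3"
    return StagedPrediction(stage1, True, subgroup, cutoffs)


def roc_with_youden(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> RocResult:
    """ROC AUC, bootstrap 95% CI, and the Youden-index operating cutoff.

    AUC is the Mann-Whitney pair-counting estimator (ties count one half);
    higher scores are assumed to indicate the positive class. The Youden
    cutoff is the score threshold t (rule: positive iff score >= t)
    maximizing sensitivity + specificity - 1, ties broken toward the
    smallest threshold. The CI is a seeded percentile bootstrap over cases.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"need >= 2 cases per class, got {n_pos} positive / {n_neg} negative")

    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresh = roc_curve(labels, scores)
    j = tpr - fpr
    # thresholds descend; the first is the above-max sentinel. Among equal J,
    # take the smallest threshold (= last index among finite thresholds).
    finite = np.isfinite(thresh)
    j_f, t_f, tpr_f, fpr_f = j[finite], thresh[finite], tpr[finite], fpr[finite]
    best = np.flatnonzero(j_f == j_f.max())[-1]

    rng = np.random.default_rng(seed)
    n = scores.size
    boot = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        boot[kept] = roc_auc_score(lb, scores[idx])
        kept += 1
    if kept == 0:
        ci_low = ci_high = auc
    else:
        ci_low, ci_high = np.percentile(boot[:kept], [2.5, 97.5])
    return RocResult(
        auc=auc, ci_low=float(min(ci_low, auc)), ci_high=float(max(ci_high, auc)),
        youden_cutoff=float(t_f[best]),
        sens_at_cutoff=float(tpr_f[best]), spec_at_cutoff=float(1 - fpr_f[best]),
        n_pos=n_pos, n_neg=n_neg,
    )
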