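"""Wound categorization, depth-score QC, fixed-cutoff classifiers, and ROC.

Categorization is two-stage.  The primary rule reads the burn-creation
protocol: 45 deg C block -> Superficial, 96 deg C -> Full-thickness,
63 deg C with 15-20 s contact -> PT-Superficial, 30-45 s -> PT-Deep.  The
secondary rule confirms partial-thickness wounds by time to heal: complete
re-epithelialization by POD 56 keeps a PT-Superficial wound; incomplete
healing at study end (POD 64) keeps a PT-Deep wound; a partial-thickness
wound satisfying neither is excluded.

Histological depth scores pass per-category QC windows (< 250 um
superficial, <= 680 um PT-Superficial, > 680 um PT-Deep, > 1750 um
full-thickness), with 100 um added when the epidermal layer was missing.

Binary diagnosis at the published operating points uses strict
inequalities: HI > 3.54 calls a partial-thickness burn; HI < 6.58 calls
PT-Deep.  ROC/AUC evaluation uses the Mann-Whitney concordance with ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "WoundRecord",
    "ROCResult",
    "primary_categorize",
    "secondary_categorize",
    "adjust_depth_score",
    "depth_score_qc",
    "classify_hi",
    "roc",
    "youden_cutoff",
    "CUTOFF_PT", "CUTOFF_PT_DEEP",
    "PT_SUPERFICIAL_HEAL_CUTOFF", "STUDY_END",
]

CUTOFF_PT = 3.54        # HI above this calls a partial-thickness burn
CUTOFF_PT_DEEP = 6.58   # HI below this calls a PT-Deep burn
PT_SUPERFICIAL_HEAL_CUTOFF = 56
STUDY_END = 64

DEPTH_QC = {
    "Superficial": lambda d: d < 250.0,
    "PT-Superficial": lambda d: d <= 680.0,   # 680 itself kept (boundary convention)
    "PT-Deep": lambda d: d > 680.0,
    "Full-thickness": lambda d: d > 1750.0,
}


@dataclass
class WoundRecord:
    """Wound metadata plus category assignment and inclusion status."""

    pig: int
    wound_id: int
    block_temp_c: float
    contact_s: float
    heal_pod: int | None = None        # None = unhealed at study end
    depth_um: float | None = None
    epidermis_missing: bool = False
    primary_category: str | None = None
    final_category: str | None = None  # category or "Excluded"
    exclusion_reason: str | None = None

    @property
    def included(self) -> bool:
        return self.final_category is not None and self.final_category != "Excluded"


def primary_categorize(temp_c: float, duration_s: float | None = None) -> str:
    """Category from the burn-creation protocol (block temperature, contact)."""
    if temp_c == 45:
        return "Superficial"
    if temp_c == 96:
        return "Full-thickness"
    if temp_c == 63:
        if duration_s is None or duration_s <= 0:
            raise ValueError("63 deg C burns require a positive contact duration")
        if 15 <= duration_s <= 20:
            return "PT-Superficial"
        if 30 <= duration_s <= 45:
            return "PT-Deep"
        raise ValueError(
            f"contact duration {duration_s} s at 63 deg C is outside the "
            "protocol (15-20 s or 30-45 s)"
        )
    raise ValueError(f"block temperature {temp_c} deg C is not a protocol setting")


def secondary_categorize(
    record: WoundRecord,
    pt_cutoff: int = PT_SUPERFICIAL_HEAL_CUTOFF,
    study_end: int = STUDY_END,
) -> WoundRecord:
    """Confirm partial-thickness categories by time to heal.

    PT-Superficial is retained iff healed by POD ``pt_cutoff``; PT-Deep iff
    unhealed at POD ``study_end``.  Superficial and Full-thickness pass
    through.  Mutates and returns ``record``.
    """
    if record.primary_category is None:
        raise ValueError("primary category must be assigned first")
    cat = record.primary_category
    if cat in ("Superficial", "Full-thickness"):
        record.final_category = cat
        return record
    healed = record.heal_pod is not None
    if cat == "PT-Superficial":
        keep = healed and record.heal_pod <= pt_cutoff
    elif cat == "PT-Deep":
        keep = not healed
    else:
        raise ValueError(f"unknown primary category {cat!r}")
    if keep:
        record.final_category = cat
    else:
        record.final_category = "Excluded"
        record.exclusion_reason = "secondary-criterion"
    return record


def adjust_depth_score(raw_um: float, epidermis_missing: bool) -> float:
    """Add the 100 um average epidermal thickness when the layer is missing."""
    if raw_um < 0:
        raise ValueError(f"depth score must be >= 0, got {raw_um}")
    return raw_um + 100.0 if epidermis_missing else raw_um


def depth_score_qc(category: str, depth_um: float) -> bool:
    """Per-category inclusion window for histological depth scores."""
    if depth_um < 0:
        raise ValueError(f"depth score must be >= 0, got {depth_um}")
    try:
        return bool(DEPTH_QC[category](depth_um))
    except KeyError:
        raise ValueError(f"unknown category {category!r}") from None


def classify_hi(value: float, threshold: float, direction: str) -> bool:
    """Binary call at a fixed HI threshold.

    ``direction`` is ``"greater"`` (positive iff value > threshold, as in
    "HI > 3.54 indicates a partial-thickness burn") or ``"less"`` (positive
    iff value < threshold, as in "HI < 6.58 for PT-Deep").  A value exactly
    at the threshold is the negative class (strict inequality).
    """
    if not np.isfinite(value):
        raise ValueError("HI value must be finite")
    if direction == "greater":
        return value > threshold
    if direction == "less":
        return value < threshold
    raise ValueError("direction must be 'greater' or 'less'")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    p_value: float
    direction: str = "greater"
    n_pos: int = 0
    n_neg: int = 0
    degenerate: bool = field(default=False)


def roc(pos, neg, direction: str = "greater") -> ROCResult:
    """Empirical ROC of positive vs negative HI values.

    AUC is the Mann-Whitney concordance (#concordant + 1/2 #tied) /
    (n_pos * n_neg) in the stated direction; standard error by
    Hanley-McNeil; p-value from the two-sided Mann-Whitney U test.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    sgn = 1.0 if direction == "greater" else -1.0
    p, n = sgn * pos, sgn * neg
    diff = p[:, None] - n[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)
    n_pos, n_neg = pos.size, neg.size
    # Hanley & McNeil (1982) SE of the empirical AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    mw_p = float(stats.mannwhitneyu(p, n, alternative="two-sided").pvalue)
    thresholds = np.unique(np.concatenate([p, n]))
    sens = np.array([(p > t).mean() for t in thresholds])
    spec = np.array([(n <= t).mean() for t in thresholds])
    return ROCResult(
        thresholds=sgn * thresholds, sensitivity=sens, specificity=spec,
        auc=auc, auc_se=se, p_value=mw_p, direction=direction,
        n_pos=n_pos, n_neg=n_neg, degenerate=bool(auc == 0.5),
    )


def youden_cutoff(r: ROCResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the midpoint between the flanking observed
    values, so a perfectly separating cutoff lands mid-gap.
    """
    sgn = 1.0 if r.direction == "greater" else -1.0
    thresholds = sgn * r.thresholds  # back to the internal ascending scale
    j = r.sensitivity + r.specificity - 1.0
    best = float(np.max(j))
    if best <= 0.0:
        # no threshold discriminates (degenerate ROC): return the lowest
        return float(sgn * thresholds[0])
    idx = np.nonzero(j == best)[0]
    i = idx[-1] if len(idx) else 0
    t = thresholds[i]
    if i + 1 < len(thresholds):
        t = (thresholds[i] + thresholds[i + 1]) / 2.0
    return float(sgn * t)
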