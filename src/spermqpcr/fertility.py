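"""Marker-versus-fertility evaluation.

A fertility biomarker study ends with three questions: does transcript
abundance track the phenotype (Pearson correlation / linear regression of
expression on mean litter size); how well does it classify boars against a
fixed litter-size cutoff (ROC curve, AUC, Youden-optimal threshold); and
how consistent are the resulting calls (sensitivity, specificity,
predictive values, overall accuracy).  A reverse operation reconstructs the
integer 2×2 confusion tables compatible with a set of *printed* diagnostic
percentages, which is how reported accuracies can be audited when the raw
per-animal calls are not published.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class FertilityRecord:
    """One boar: mean litter size over its artificial-insemination services."""

    sample_id: str
    litter_size: float
    n_trials: int | None = None

    def __post_init__(self):
        if self.litter_size <= 0:
            raise ValueError("litter_size must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float  # expression per piglet
    intercept: float
    p_value: float  # two-sided, t distribution with n-2 df
    n: int
    n_censored: int


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five reporting percentages; a metric with a zero denominator is
    explicitly undefined (None) rather than 0 or NaN."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    overall_accuracy: float | None
    auc: float | None = None


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_cutoff: float
    direction: str  # orientation actually used
    flipped: bool  # True when auto-orientation negated the scores


# ---------------------------------------------------------------------------

def correlate(expression: dict, fertility) -> CorrelationResult:
    """Pearson correlation and OLS line of expression on litter size.

    ``expression`` maps sample_id to relative expression (None = censored,
    dropped with a count); ``fertility`` is a collection of
    :class:`FertilityRecord`.  Requires >= 3 matched numeric pairs.
    """
    litter = {f.sample_id: f.litter_size for f in fertility}
    pairs = [
        (litter[s], e)
        for s, e in expression.items()
        if s in litter and e is not None
    ]
    n_censored = sum(1 for s, e in expression.items() if s in litter and e is None)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched pairs, have {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    fit = stats.linregress(x, y)  # two-sided p from t with n-2 df
    return CorrelationResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=len(pairs),
        n_censored=n_censored,
    )


def dichotomize(fertility, cutoff: float = 13.0, positive: str = "below") -> dict:
    """Binary fertility labels at a fixed litter-size cutoff.

    The default orientation marks *subfertile* boars (litter size strictly
    below the cutoff) as the positive class; a boar exactly at the cutoff is
    negative.  Returns {sample_id: bool}.
    """
    if positive not in ("below", "above"):
        raise ValueError("positive must be 'below' or 'above'")
    labels = {}
    for f in fertility:
        below = f.litter_size < cutoff
        labels[f.sample_id] = below if positive == "below" else not below
    return labels


def roc(scores, labels, direction: str = "auto") -> RocResult:
    """ROC curve over all distinct score thresholds, ties grouped.

    ``direction`` controls orientation: ``higher_positive`` treats larger
    scores as evidence for the positive class, ``lower_positive`` the
    reverse, and ``auto`` picks whichever yields AUC >= 0.5 (equivalent to
    following the sign of the score–label association) and records the flip.
    AUC is the trapezoid-rule area; the reported cutoff maximises Youden's
    J = TPR − FPR, expressed on the original score scale.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    if direction not in ("auto", "higher_positive", "lower_positive"):
        raise ValueError(f"unknown direction {direction!r}")

    def curve(sc):
        fpr, tpr, thr = _sk_roc_curve(y.astype(int), sc)
        return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))

    flipped = False
    if direction == "lower_positive":
        fpr, tpr, thr, auc = curve(-s)
        flipped = True
    elif direction == "higher_positive":
        fpr, tpr, thr, auc = curve(s)
    else:
        fpr, tpr, thr, auc = curve(s)
        if auc < 0.5:
            fpr, tpr, thr, auc = curve(-s)
            flipped = True
    j = tpr - fpr
    i = int(np.argmax(j))
    cutoff = float(-thr[i] if flipped else thr[i])
    return RocResult(
        thresholds=np.where(np.isinf(thr), thr, -thr if flipped else thr),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        youden_cutoff=cutoff,
        direction="lower_positive" if flipped else "higher_positive",
        flipped=flipped,
    )


def confusion_from_labels(labels, predictions) -> ConfusionTable:
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    return ConfusionTable(
        tp=int((y & p).sum()),
        fn=int((y & ~p).sum()),
        fp=int((~y & p).sum()),
        tn=int((~y & ~p).sum()),
    )


def diagnostics(ct: ConfusionTable, auc: float | None = None) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and overall accuracy as percentages."""

    def pct(num, den):
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=pct(ct.tp, ct.tp + ct.fn),
        specificity=pct(ct.tn, ct.tn + ct.fp),
        ppv=pct(ct.tp, ct.tp + ct.fp),
        npv=pct(ct.tn, ct.tn + ct.fn),
        overall_accuracy=pct(ct.tp + ct.tn, ct.total),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# reconstruction of confusion tables from printed percentages

def _round2_half_up_pct(num: int, den: int) -> float:
    """100*num/den rounded half-up to 2 dp, in exact integer arithmetic."""
    # 100*num/den to 2 dp == round(10000*num/den) with ties away from zero
    q, r = divmod(10000 * num, den)
    if 2 * r >= den:
        q += 1
    return q / 100.0


def reconstruct_confusion(
    sn: float,
    sp: float,
    ppv: float,
    npv: float,
    max_total: int = 100,
    tol: float = 0.005,
) -> list[ConfusionTable]:
    """All integer 2×2 tables whose metrics print as the given percentages.

    Exhaustive search over tables with total <= ``max_total`` whose
    sensitivity, specificity, PPV and NPV — rounded half-up to 2 dp — lie
    within ``tol`` of the four inputs.  Matches are returned sorted by
    total; proportional tables (k·tp, k·fn, …) share identical overall
    accuracy, so a printed accuracy is recoverable even when the absolute
    counts are not unique.  An empty list means no table of that size is
    consistent with the printed values.
    """
    if max_total < 4:
        raise ValueError("max_total must be >= 4")
    for v in (sn, sp, ppv, npv):
        if not 0 <= v <= 100:
            raise ValueError("percentages must lie in [0, 100]")
    matches = []
    for pos in range(0, max_total + 1):  # tp + fn
        # tp consistent with printed sensitivity
        tps = [
            tp for tp in range(pos + 1)
            if pos > 0 and abs(_round2_half_up_pct(tp, pos) - sn) <= tol
        ] if pos > 0 else []
        if pos > 0 and not tps:
            continue
        for neg in range(0, max_total - pos + 1):  # tn + fp
            if pos == 0 and neg == 0:
                continue
            tns = [
                tn for tn in range(neg + 1)
                if neg > 0 and abs(_round2_half_up_pct(tn, neg) - sp) <= tol
            ] if neg > 0 else []
            if neg > 0 and not tns:
                continue
            for tp in (tps or [0]):
                fn = pos - tp
                for tn in (tns or [0]):
                    fp = neg - tn
                    if tp + fp == 0 or tn + fn == 0:
                        continue
                    if abs(_round2_half_up_pct(tp, tp + fp) - ppv) > tol:
                        continue
                    if abs(_round2_half_up_pct(tn, tn + fn) - npv) > tol:
                        continue
                    matches.append(ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn))
    return sorted(matches, key=lambda t: (t.total, t.tp, t.tn))
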