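"""Performance indicators for binary and abstaining classifiers, plus the
length-distribution power-law fit.

Conventions: the positive class is *natively unfolded* throughout, so
Sn = TP/(TP+FN) is the fraction of unfolded proteins correctly recovered,
Sp = TN/(TN+FP) the fraction of folded proteins correctly recovered and
fp = FP/(TN+FP) = 1 - Sp the fraction of folded proteins mis-called as
unfolded.  Abstaining classifiers are handled by excluding unclassified
proteins from the confusion counts and reporting nc (the unclassified
fraction of the whole dataset) split into its folded (nc_f) and unfolded
(nc_u) contributions, so nc = nc_f + nc_u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .seqio import FOLDED, UNCLASSIFIED, UNFOLDED


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    false_positive_fraction: float
    nc: float
    nc_f: float
    nc_u: float
    auc: float | None = None

    @property
    def n_classified(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "Sn": self.sensitivity, "Sp": self.specificity,
            "fp_fraction": self.false_positive_fraction,
            "nc": self.nc, "nc_f": self.nc_f, "nc_u": self.nc_u,
            "AUC": self.auc,
        }


def confusion_metrics(
    calls: Mapping[str, str],
    labels: Mapping[str, str],
    positive_class: str = UNFOLDED,
) -> EvaluationReport:
    """Confusion counts and abstention fractions for per-protein calls.

    ``calls`` maps protein id -> folded/unfolded/unclassified; ``labels``
    maps id -> folded/unfolded ground truth.  Every called protein must be
    labeled.  Unclassified proteins enter only nc/nc_f/nc_u, which are
    normalised by the total number of called proteins.
    """
    if positive_class not in (FOLDED, UNFOLDED):
        raise ValueError("positive_class must be 'folded' or 'unfolded'")
    negative_class = FOLDED if positive_class == UNFOLDED else UNFOLDED
    tp = tn = fp = fn = 0
    n_unc_pos = n_unc_neg = 0
    for pid, call in calls.items():
        if pid not in labels:
            raise ValueError(f"protein {pid!r} has a call but no label")
        truth = labels[pid]
        if truth not in (FOLDED, UNFOLDED):
            raise ValueError(f"protein {pid!r}: label {truth!r} is not binary")
        if call == UNCLASSIFIED:
            if truth == positive_class:
                n_unc_pos += 1
            else:
                n_unc_neg += 1
        elif call == positive_class:
            if truth == positive_class:
                tp += 1
            else:
                fp += 1
        elif call == negative_class:
            if truth == negative_class:
                tn += 1
            else:
                fn += 1
        else:
            raise ValueError(f"protein {pid!r}: unknown call {call!r}")
    total = len(calls)
    if total == 0:
        raise ValueError("no calls to evaluate")
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sn, specificity=sp,
        false_positive_fraction=1.0 - sp if sp == sp else float("nan"),
        nc=(n_unc_pos + n_unc_neg) / total,
        nc_f=(n_unc_neg if positive_class == UNFOLDED else n_unc_pos) / total,
        nc_u=(n_unc_pos if positive_class == UNFOLDED else n_unc_neg) / total,
    )


def roc_points(
    scores: Sequence[float],
    labels: Sequence[str],
    higher_is_unfolded: bool = True,
    positive_class: str = UNFOLDED,
) -> tuple[np.ndarray, np.ndarray]:
    """(false positive rate, true positive rate) of the full ROC sweep."""
    y = np.asarray([lab == positive_class for lab in labels], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC needs at least one positive and one negative")
    s = np.asarray(scores, dtype=float)
    if not higher_is_unfolded:
        s = -s
    fpr, tpr, _ = _roc_curve(y, s)
    return fpr, tpr


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    higher_is_unfolded: bool = True,
    positive_class: str = UNFOLDED,
) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Equal to the pair-counting estimator
    P(score_pos > score_neg) + P(tie)/2.
    """
    fpr, tpr = roc_points(scores, labels, higher_is_unfolded, positive_class)
    return float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    stderr: float
    n_bins: int
    fit_range: tuple[float, float]
    bin_factor: float


def fit_length_exponent(
    lengths: Sequence[int],
    fit_range: tuple[float, float],
    bin_factor: float = 1.25,
) -> PowerLawFit:
    """Power-law exponent of a chain-length distribution.

    Counts are histogrammed in geometric bins (width factor ``bin_factor``)
    restricted to ``fit_range``, converted to a density (count per unit
    length), and the least-squares slope of log density versus log bin
    centre is returned with its standard error.  The fit range must be
    declared explicitly; it is never auto-chosen.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 lengths for a power-law fit")
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not (0 < lo < hi):
        raise ValueError("fit_range must satisfy 0 < lo < hi")
    if lo < x.min() or hi > x.max() * bin_factor:
        raise ValueError("fit_range must lie inside the observed support")
    if bin_factor <= 1.0:
        raise ValueError("bin_factor must exceed 1")
    edges = [lo]
    while edges[-1] < hi:
        edges.append(edges[-1] * bin_factor)
    edges = np.asarray(edges)
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centres = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-empty bins in the fit range")
    density = counts[keep] / (widths[keep] * x.size)
    res = stats.linregress(np.log(centres[keep]), np.log(density))
    return PowerLawFit(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        n_bins=int(keep.sum()),
        fit_range=(lo, hi),
        bin_factor=bin_factor,
    )
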