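"""Per-protein folding indexes and their binary folded/unfolded calls.

Four dichotomic indexes are provided as scikit-learn style estimators plus
thin functional wrappers:

================================  =============================  ==========================
index                             score                          unfolded when
================================  =============================  ==========================
:class:`HQIndex`                  2.785*<H> - |<Q>| - 1.151      score <= 0
:class:`MeanPackingIndex`         mean expected contact number   score < 20.55
:class:`MeanPairwiseEnergyIndex`  mean pairwise contact energy   score > -0.37 a.e.u.
:class:`GlobalDisorderIndex`      mean of a [0,1] disorder       score > 0.5
                                  profile
================================  =============================  ==========================

All smoothing uses truncated sliding-window averaging: the value assigned to
a position is the plain mean over the in-bounds positions within half a
window of it, so termini average over fewer residues and no padding is ever
introduced.  Ties at a threshold follow the strict inequality of each rule
above, i.e. a protein exactly at 20.55 / -0.37 / 0.5 is called folded,
while an HQ of exactly zero is called unfolded.

Thresholds are defaults optimized elsewhere on particular datasets; every
estimator exposes them as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .scales import EnergyMatrix, ResidueScale, load_energy_matrix, load_scale
from .seqio import (
    AA_INDEX,
    AMINO_ACIDS,
    FOLDED,
    MIN_LENGTH,
    RECOMMENDED_MIN_LENGTH,
    UNFOLDED,
    ProteinRecord,
    ResidueProfile,
    as_record,
)


@dataclass(frozen=True)
class WindowSpec:
    """Odd-length sliding window with truncated (no padding) edges."""

    length: int
    edge_rule: str = "truncate"

    def __post_init__(self) -> None:
        if self.length < 1 or self.length % 2 == 0:
            raise ValueError(f"window length must be odd and positive, got {self.length}")
        if self.edge_rule != "truncate":
            raise ValueError(f"unsupported edge rule {self.edge_rule!r}")


@dataclass(frozen=True)
class IndexResult:
    """One index's raw score, threshold and binary call for one protein."""

    protein_id: str
    index_name: str
    score: float
    threshold: float
    call: str  # FOLDED | UNFOLDED


def sliding_window_average(
    values: Sequence[float] | np.ndarray | ResidueProfile,
    window: int | WindowSpec,
) -> np.ndarray:
    """Truncated sliding-window mean: output[p] averages the input over all
    in-bounds positions within (length-1)/2 of p.  Output length equals
    input length; a window of 1 is the identity."""
    if isinstance(window, int):
        window = WindowSpec(window)
    if isinstance(values, ResidueProfile):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if window.length == 1:
        return x.copy()
    half = (window.length - 1) // 2
    n = x.size
    # shift by x[0] before summing: constant profiles come back bit-exact
    # (mean of equal values would otherwise pick up round-off), and the
    # conditioning of the running sums improves for everything else
    ref = x[0]
    csum = np.concatenate(([0.0], np.cumsum(x - ref)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1) + ref


def _shifted_mean(x: np.ndarray) -> float:
    """Mean computed around x[0]; exact for constant arrays."""
    x = np.asarray(x, dtype=float)
    return float(x[0] + np.mean(x - x[0]))


def _sequence_indices(record: ProteinRecord) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in record.sequence), dtype=np.intp,
                       count=record.length)


def _check_length(record: ProteinRecord, warn: bool = True) -> None:
    if record.length < MIN_LENGTH:
        raise ValueError(
            f"record {record.id!r} has {record.length} residues; the indexes "
            f"require at least {MIN_LENGTH}"
        )
    if warn and record.length < RECOMMENDED_MIN_LENGTH:
        warnings.warn(
            f"record {record.id!r} has {record.length} residues; index calls "
            f"below {RECOMMENDED_MIN_LENGTH} residues are unreliable",
            stacklevel=3,
        )


def residue_values(record: ProteinRecord, scale: ResidueScale) -> np.ndarray:
    """Per-residue scale values, in sequence order."""
    return scale.as_array()[_sequence_indices(record)]


def profile_from_scale(record: ProteinRecord, scale: ResidueScale) -> ResidueProfile:
    """Turn a per-residue scale into a ResidueProfile for this protein."""
    return ResidueProfile(record.id, tuple(residue_values(record, scale)))


def mean_hydrophobicity(
    record: ProteinRecord, scale: ResidueScale | None = None, window: int = 5
) -> float:
    """Mean hydrophobicity <H>: window-smoothed per-residue hydrophobicity,
    averaged over the protein (the x-coordinate of the charge/hydrophobicity
    plane)."""
    scale = scale or load_scale("hydrophobicity")
    return _shifted_mean(sliding_window_average(residue_values(record, scale), window))


def mean_net_charge(record: ProteinRecord, scale: ResidueScale | None = None) -> float:
    """Absolute mean net charge <Q> = |sum of residue charges| / length."""
    scale = scale or load_scale("charge")
    return float(abs(residue_values(record, scale).sum()) / record.length)


def pairwise_energy_profile(
    record: ProteinRecord,
    matrix: EnergyMatrix | None = None,
    min_separation: int = 2,
    max_separation: int = 100,
) -> np.ndarray:
    """Estimated per-residue contact energy e(p).

    For residue i at position p the neighbourhood N(p) holds every in-bounds
    position q with ``min_separation <= |q - p| <= max_separation``; e(p) is
    the matrix row of i weighted by the residue frequencies inside N(p):
    e(p) = sum_j P_ij f_j(p).
    """
    matrix = matrix if matrix is not None else load_energy_matrix()
    _check_length(record, warn=False)
    idx = _sequence_indices(record)
    n = idx.size
    onehot = np.zeros((n, 20))
    onehot[np.arange(n), idx] = 1.0
    prefix = np.vstack([np.zeros(20), np.cumsum(onehot, axis=0)])  # (n+1, 20)

    pos = np.arange(n)
    # left band [p - max_sep, p - min_sep], clipped to bounds
    l_lo = np.clip(pos - max_separation, 0, n)
    l_hi = np.clip(pos - min_separation + 1, 0, n)  # exclusive
    # right band [p + min_sep, p + max_sep]
    r_lo = np.clip(pos + min_separation, 0, n)
    r_hi = np.clip(pos + max_separation + 1, 0, n)
    counts = (prefix[np.maximum(l_hi, l_lo)] - prefix[l_lo]) + (
        prefix[np.maximum(r_hi, r_lo)] - prefix[r_lo]
    )
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError(
            f"record {record.id!r}: empty pairwise-energy neighbourhood"
        )
    freqs = counts / totals[:, None]
    return np.einsum("ij,ij->i", freqs, matrix.values[idx])


# ---------------------------------------------------------------------------
# estimators


class FoldingIndex(BaseEstimator, ClassifierMixin):
    """Base class for the dichotomic folding indexes.

    These estimators do not learn from data: ``fit`` validates parameters
    and loads the bundled tables into fitted attributes so the scikit-learn
    fit/predict protocol (cloning, pipelines, ``check_is_fitted``) applies.
    ``score_samples`` returns raw index scores in the index's native units;
    ``decision_function`` orients them so that larger means more disordered
    (positive class = unfolded); ``predict`` applies the index's published
    threshold and tie rule.
    """

    index_name: str = "folding_index"
    #: True when a score exactly at threshold is called unfolded
    _tie_unfolded: bool = False

    def fit(self, X=None, y=None):
        self._load_tables()
        self.classes_ = np.array([FOLDED, UNFOLDED])
        self.n_features_in_ = 1
        return self

    def _load_tables(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def _raw_score(self, record: ProteinRecord) -> float:
        raise NotImplementedError

    def _records(self, X) -> list[ProteinRecord]:
        return [as_record(x, default_id=f"seq{i}") for i, x in enumerate(X)]

    def score_samples(self, X) -> np.ndarray:
        """Raw index scores, one per input sequence."""
        check_is_fitted(self)
        records = self._records(X)
        for r in records:
            _check_length(r)
        return np.array([self._raw_score(r) for r in records])

    def _oriented(self, scores: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def decision_function(self, X) -> np.ndarray:
        """Scores oriented so that positive means unfolded (ties excepted)."""
        return self._oriented(self.score_samples(X))

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        unfolded = d >= 0 if self._tie_unfolded else d > 0
        return np.where(unfolded, UNFOLDED, FOLDED)

    def results(self, X) -> list[IndexResult]:
        """Per-protein :class:`IndexResult` rows (score, threshold, call)."""
        records = self._records(X)
        scores = self.score_samples(records)
        calls = self.predict(records)
        thr = getattr(self, "threshold", 0.0)
        return [
            IndexResult(r.id, self.index_name, float(s), float(thr), c)
            for r, s, c in zip(records, scores, calls)
        ]


class HQIndex(FoldingIndex):
    """Charge/hydrophobicity boundary index.

    HQ = 2.785*<H> - |<Q>| - 1.151 where <H> is the mean of the
    window-smoothed (default 5) unit-interval hydrophobicity profile and
    <Q> the absolute mean net charge.  Negative or zero HQ means natively
    unfolded (the boundary itself counts as unfolded).
    """

    index_name = "hq"
    _tie_unfolded = True

    def __init__(
        self,
        hydrophobicity_coef: float = 2.785,
        intercept: float = -1.151,
        hydrophobicity_window: int = 5,
    ):
        self.hydrophobicity_coef = hydrophobicity_coef
        self.intercept = intercept
        self.hydrophobicity_window = hydrophobicity_window

    def _load_tables(self) -> None:
        self.hydrophobicity_scale_ = load_scale("hydrophobicity")
        self.charge_scale_ = load_scale("charge")

    def _raw_score(self, record: ProteinRecord) -> float:
        h = mean_hydrophobicity(
            record, self.hydrophobicity_scale_, self.hydrophobicity_window
        )
        q = mean_net_charge(record, self.charge_scale_)
        return self.hydrophobicity_coef * h - abs(q) + self.intercept

    def _oriented(self, scores: np.ndarray) -> np.ndarray:
        return -scores

    @property
    def threshold(self) -> float:
        return 0.0


class MeanPackingIndex(FoldingIndex):
    """Mean expected contact number; low packing marks natively unfolded.

    Per-residue packing values are smoothed with a window (default 11)
    assigned to the central residue, then averaged over the protein.
    """

    index_name = "mean_packing"
    _tie_unfolded = False

    def __init__(self, threshold: float = 20.55, window: int = 11):
        self.threshold = threshold
        self.window = window

    def _load_tables(self) -> None:
        self.scale_ = load_scale("packing")

    def _raw_score(self, record: ProteinRecord) -> float:
        vals = residue_values(record, self.scale_)
        return _shifted_mean(sliding_window_average(vals, self.window))

    def _oriented(self, scores: np.ndarray) -> np.ndarray:
        return self.threshold - scores  # lower packing = more disordered


class MeanPairwiseEnergyIndex(FoldingIndex):
    """Mean estimated pairwise contact energy <E_c>.

    The per-residue energy profile (contacts with positions 2..100 apart)
    is smoothed with a window (default 21) and averaged; energies above the
    threshold (default -0.37 a.e.u.) mark natively unfolded proteins —
    an unfavourable estimated contact energy means the chain cannot pay
    for a compact fold.
    """

    index_name = "mean_pairwise_energy"
    _tie_unfolded = False

    def __init__(
        self,
        threshold: float = -0.37,
        window: int = 21,
        min_separation: int = 2,
        max_separation: int = 100,
    ):
        self.threshold = threshold
        self.window = window
        self.min_separation = min_separation
        self.max_separation = max_separation

    def _load_tables(self) -> None:
        self.matrix_ = load_energy_matrix()

    def _raw_score(self, record: ProteinRecord) -> float:
        prof = pairwise_energy_profile(
            record, self.matrix_, self.min_separation, self.max_separation
        )
        return _shifted_mean(sliding_window_average(prof, self.window))

    def _oriented(self, scores: np.ndarray) -> np.ndarray:
        return scores - self.threshold  # higher energy = more disordered


class GlobalDisorderIndex(FoldingIndex):
    """Global mean of a per-residue disorder-probability profile.

    Input samples are [0, 1] residue profiles (from any per-residue
    disorder predictor), not sequences.  The profile is window-smoothed
    (default 11) and averaged; a global score above 0.5 marks the protein
    as natively unfolded.
    """

    index_name = "global_disorder"
    _tie_unfolded = False

    def __init__(self, threshold: float = 0.5, window: int = 11):
        self.threshold = threshold
        self.window = window

    def _load_tables(self) -> None:
        pass

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self)
        scores = []
        for i, prof in enumerate(X):
            pid = prof.protein_id if isinstance(prof, ResidueProfile) else f"profile{i}"
            vals = np.asarray(
                prof.values if isinstance(prof, ResidueProfile) else prof, dtype=float
            )
            if vals.size == 0:
                raise ValueError(f"{pid}: empty disorder profile")
            if vals.min() < 0.0 or vals.max() > 1.0:
                raise ValueError(f"{pid}: disorder profile values outside [0, 1]")
            scores.append(_shifted_mean(sliding_window_average(vals, self.window)))
        return np.array(scores)

    def results(self, X) -> list[IndexResult]:
        scores = self.score_samples(X)
        calls = self.predict(X)
        out = []
        for i, (prof, s, c) in enumerate(zip(X, scores, calls)):
            pid = prof.protein_id if isinstance(prof, ResidueProfile) else f"profile{i}"
            out.append(IndexResult(pid, self.index_name, float(s), self.threshold, c))
        return out

    def _oriented(self, scores: np.ndarray) -> np.ndarray:
        return scores - self.threshold


#: score orientation of each bundled index: True when a larger raw score
#: means more disordered (used for ROC/AUC sweeps).
HIGHER_IS_UNFOLDED = {
    "hq": False,
    "mean_packing": False,
    "mean_pairwise_energy": True,
    "global_disorder": True,
    "mean_flexibility": True,
    "log_odds": False,
}


# ---------------------------------------------------------------------------
# functional wrappers


def hq_index(record: ProteinRecord | str, **params) -> IndexResult:
    return HQIndex(**params).fit().results([record])[0]


def mean_packing(record: ProteinRecord | str, **params) -> IndexResult:
    return MeanPackingIndex(**params).fit().results([record])[0]


def mean_pairwise_energy(record: ProteinRecord | str, **params) -> IndexResult:
    return MeanPairwiseEnergyIndex(**params).fit().results([record])[0]


def global_disorder_score(profile: ResidueProfile | Sequence[float], **params) -> IndexResult:
    return GlobalDisorderIndex(**params).fit().results([profile])[0]


def mean_flexibility(
    record: ProteinRecord | str,
    scale: ResidueScale | None = None,
    window: int = 11,
) -> float:
    """Mean flexibility: per-residue flexibility values smoothed with a
    window (default 11) and averaged.  A descriptor, not a classifier."""
    record = as_record(record)
    _check_length(record)
    scale = scale or load_scale("flexibility")
    vals = residue_values(record, scale)
    return _shifted_mean(sliding_window_average(vals, window))


def score_records(
    records: Iterable[ProteinRecord],
    indexes: Sequence[FoldingIndex] | None = None,
) -> list[IndexResult]:
    """Run several sequence-based indexes over a dataset; rows are grouped
    by index then record, ready for TSV export or consensus building."""
    records = list(records)
    if indexes is None:
        indexes = [HQIndex(), MeanPackingIndex(), MeanPairwiseEnergyIndex()]
    out: list[IndexResult] = []
    for est in indexes:
        est.fit()
        out.extend(est.results(records))
    return out
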