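"""Amino-acid composition statistics and the zero-order log-odds score S.

The composition of a protein class is summarised by per-sequence residue
frequencies f_ij = n_ij / n_j with their binomial variances and by dataset
frequencies F_i = sum_j n_ij / N_aa with the pooled variance propagated from
the per-sequence ones.

The log-odds score of a sequence,

    S = sum_a n_a * ln( pi_a(F) / pi_a(U) ),

compares the likelihood that its composition was drawn i.i.d. (a zero-order
Markov chain) from the residue distribution of folded proteins pi(F) against
that of unfolded proteins pi(U).  Order-promoting residues contribute
positive terms, disorder-promoting residues negative ones, so S near zero
marks a sequence with a balanced, twilight-like composition.  The class
distributions are plug-in estimates with Laplace (add-pseudocount)
smoothing so no log is ever taken of zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .seqio import AA_INDEX, AMINO_ACIDS, FOLDED, UNFOLDED, ProteinRecord, as_record


def _count_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Residue counts, one row per sequence, canonical residue order."""
    counts = np.zeros((len(records), 20), dtype=np.int64)
    for row, rec in enumerate(records):
        for c in rec.sequence:
            counts[row, AA_INDEX[c]] += 1
    return counts


@dataclass(frozen=True)
class CompositionStats:
    """Per-sequence and dataset residue frequencies with variances."""

    ids: tuple[str, ...]
    per_sequence_frequencies: np.ndarray  # (n_seq, 20)
    per_sequence_variances: np.ndarray  # (n_seq, 20)
    dataset_frequencies: np.ndarray  # (20,)
    dataset_variances: np.ndarray  # (20,)
    n_sequences: int
    n_residues: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(AMINO_ACIDS),
                "frequency": self.dataset_frequencies,
                "sd": np.sqrt(self.dataset_variances),
            }
        )


def composition_frequencies(dataset: Sequence[ProteinRecord]) -> CompositionStats:
    """Residue frequencies of a dataset.

    Per sequence j: f_ij = n_ij / n_j with Var = f_ij (1 - f_ij) / n_j.
    Dataset: F_i = sum_j n_ij / N_aa with
    Var(F_i) = sum_j (n_j / N_aa)^2 Var(f_ij).
    """
    if not dataset:
        raise ValueError("composition_frequencies needs a non-empty dataset")
    counts = _count_matrix(dataset)
    lengths = counts.sum(axis=1)
    freqs = counts / lengths[:, None]
    variances = freqs * (1.0 - freqs) / lengths[:, None]
    n_aa = int(lengths.sum())
    dataset_freqs = counts.sum(axis=0) / n_aa
    weights = (lengths / n_aa) ** 2
    dataset_vars = (weights[:, None] * variances).sum(axis=0)
    return CompositionStats(
        ids=tuple(r.id for r in dataset),
        per_sequence_frequencies=freqs,
        per_sequence_variances=variances,
        dataset_frequencies=dataset_freqs,
        dataset_variances=dataset_vars,
        n_sequences=len(dataset),
        n_residues=n_aa,
    )


@dataclass(frozen=True)
class OddsModel:
    """Smoothed residue distributions of the folded and unfolded classes."""

    pi_folded: np.ndarray
    pi_unfolded: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        for name, pi in (("pi_folded", self.pi_folded), ("pi_unfolded", self.pi_unfolded)):
            pi = np.asarray(pi, dtype=float)
            if pi.shape != (20,):
                raise ValueError(f"{name} must have 20 entries")
            if np.any(pi <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if abs(pi.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 within 1e-12")
            object.__setattr__(self, name, pi)

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.pi_folded) - np.log(self.pi_unfolded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(AMINO_ACIDS),
                "pi_folded": self.pi_folded,
                "pi_unfolded": self.pi_unfolded,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_odds_model(path: str | Path, pseudocount: float = float("nan")) -> OddsModel:
    df = pd.read_csv(path, sep="\t")
    order = [list(df["residue"]).index(a) for a in AMINO_ACIDS]
    return OddsModel(
        pi_folded=df["pi_folded"].to_numpy(dtype=float)[order],
        pi_unfolded=df["pi_unfolded"].to_numpy(dtype=float)[order],
        pseudocount=pseudocount,
    )


def _class_pi(records: Sequence[ProteinRecord], pseudocount: float) -> np.ndarray:
    counts = _count_matrix(records).sum(axis=0).astype(float)
    total = counts.sum() + 20.0 * pseudocount
    pi = (counts + pseudocount) / total
    # re-normalise to absorb float round-off so the invariant holds exactly
    return pi / pi.sum()


def fit_odds_model(
    folded: Sequence[ProteinRecord],
    unfolded: Sequence[ProteinRecord],
    pseudocount: float = 1.0,
) -> OddsModel:
    """Plug-in class distributions pi_a = (count_a + k) / (N + 20 k)."""
    if not folded or not unfolded:
        raise ValueError("both the folded and unfolded training sets must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0:
        # zero counts would make a log ratio undefined; fail loudly
        for name, recs in (("folded", folded), ("unfolded", unfolded)):
            counts = _count_matrix(recs).sum(axis=0)
            if np.any(counts == 0):
                missing = [AMINO_ACIDS[i] for i in np.flatnonzero(counts == 0)]
                raise ValueError(
                    f"pseudocount 0 with residues {missing} absent from the "
                    f"{name} sample would produce zero probabilities"
                )
    return OddsModel(
        pi_folded=_class_pi(folded, pseudocount),
        pi_unfolded=_class_pi(unfolded, pseudocount),
        pseudocount=pseudocount,
    )


def log_odds_score(record: ProteinRecord | str, model: OddsModel) -> float:
    """S = sum_a n_a ln(pi_a(F)/pi_a(U)); additive under concatenation."""
    record = as_record(record)
    counts = _count_matrix([record])[0]
    return float(counts @ model.log_ratio)


class Partition(NamedTuple):
    order_promoting: frozenset[str]
    disorder_promoting: frozenset[str]
    neutral: frozenset[str]


def promoting_partition() -> Partition:
    """The order-/disorder-promoting residue partition.

    W,C,F,I,Y,V,L,H,N are enriched in folded proteins; A,R,Q,S,P,E,K in
    disordered ones; M,T,G,D behave similarly in both classes and are
    flagged neutral.  (N also shows near-equal frequencies in some
    datasets, but the explicit order-promoting list is followed here.)
    """
    return Partition(
        order_promoting=frozenset("WCFIYVLHN"),
        disorder_promoting=frozenset("ARQSPEK"),
        neutral=frozenset("MTGD"),
    )


class CompositionLogOdds(BaseEstimator, ClassifierMixin):
    """Zero-order log-odds classifier over amino-acid composition.

    ``fit`` takes sequences with folded/unfolded labels and estimates the
    smoothed class distributions; ``decision_function`` returns S (positive
    = folded-like composition); ``predict`` calls folded when S exceeds
    ``decision_threshold`` (default 0, ties to unfolded).
    """

    def __init__(self, pseudocount: float = 1.0, decision_threshold: float = 0.0):
        self.pseudocount = pseudocount
        self.decision_threshold = decision_threshold

    def fit(self, X, y):
        records = [as_record(x, default_id=f"seq{i}") for i, x in enumerate(X)]
        y = np.asarray(y, dtype=object)
        if len(records) != y.size:
            raise ValueError("X and y must have the same length")
        folded = [r for r, lab in zip(records, y) if lab == FOLDED]
        unfolded = [r for r, lab in zip(records, y) if lab == UNFOLDED]
        unknown = set(y) - {FOLDED, UNFOLDED}
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)!r}")
        self.model_ = fit_odds_model(folded, unfolded, self.pseudocount)
        self.classes_ = np.array([FOLDED, UNFOLDED])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        return np.array(
            [log_odds_score(as_record(x, default_id=f"seq{i}"), self.model_)
             for i, x in enumerate(X)]
        )

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.where(s > self.decision_threshold, FOLDED, UNFOLDED)


def composition_report(
    groups: dict[str, Sequence[ProteinRecord]]
) -> pd.DataFrame:
    """Frequency +/- sd per residue for several protein groups (long form),
    mirroring a per-class composition histogram."""
    frames = []
    for name, records in groups.items():
        frame = composition_frequencies(list(records)).to_frame()
        frame.insert(0, "group", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
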