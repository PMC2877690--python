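"""The strictly-unanimous consensus and the AUC-ranked combination protocol.

A strictly-unanimous consensus classifies a protein as folded only when
every member index calls it folded, as unfolded only when every member
calls it unfolded, and abstains ("unclassified") the moment two members
disagree.  The abstention set is the operational twilight zone: proteins
whose composition supports both verdicts.

``incremental_consensus`` implements the combination protocol: members are
ranked by decreasing AUC and added one at a time; at each step k the
consensus of the top-k members is evaluated on the classified subset while
the unclassified fraction nc grows monotonically.  Members are added until
the false-positive fraction stops improving (absolute improvement below
``fp_tolerance``); the full trace is always returned so any other stopping
rule can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .evaluation import EvaluationReport, confusion_metrics, roc_auc
from .indexes import HIGHER_IS_UNFOLDED, FoldingIndex, IndexResult
from .seqio import FOLDED, UNCLASSIFIED, UNFOLDED, BinaryPredictionTable


@dataclass(frozen=True)
class ConsensusResult:
    protein_id: str
    votes: tuple[tuple[str, str], ...]  # (index name, call)
    verdict: str  # folded | unfolded | unclassified


def _verdict(calls: Sequence[str]) -> str:
    if all(c == FOLDED for c in calls):
        return FOLDED
    if all(c == UNFOLDED for c in calls):
        return UNFOLDED
    return UNCLASSIFIED


def collect_votes(
    index_results: Iterable[IndexResult],
    external: Iterable[BinaryPredictionTable] = (),
) -> dict[str, list[tuple[str, str]]]:
    """Group per-index calls into per-protein vote lists, erroring on any
    protein missing a vote from any member."""
    votes: dict[str, list[tuple[str, str]]] = {}
    members: list[str] = []
    for res in index_results:
        if res.index_name not in members:
            members.append(res.index_name)
        votes.setdefault(res.protein_id, []).append((res.index_name, res.call))
    for table in external:
        members.append(table.source)
        for pid in votes:
            if pid not in table.calls:
                raise ValueError(
                    f"external predictor {table.source!r} has no call for "
                    f"protein {pid!r}"
                )
            votes[pid].append((table.source, table.calls[pid]))
    arity = len(members)
    for pid, v in votes.items():
        if len(v) != arity:
            missing = set(members) - {name for name, _ in v}
            raise ValueError(
                f"protein {pid!r} is missing vote(s) from {sorted(missing)}"
            )
    return votes


def s_su_classify(
    votes: Mapping[str, Sequence[str] | Sequence[tuple[str, str]]],
) -> list[ConsensusResult]:
    """Apply the unanimity rule to per-protein vote lists.

    ``votes`` maps protein id to either bare calls or (member, call) pairs;
    all proteins must carry the same number of votes (>= 1).
    """
    if not votes:
        raise ValueError("no votes supplied")
    arities = {len(v) for v in votes.values()}
    if len(arities) != 1:
        raise ValueError(f"inconsistent vote arity across proteins: {sorted(arities)}")
    if arities == {0}:
        raise ValueError("every protein needs at least one vote")
    results = []
    for pid, raw in votes.items():
        pairs = []
        for k, item in enumerate(raw):
            if isinstance(item, str):
                pairs.append((f"index_{k + 1}", item))
            else:
                pairs.append((str(item[0]), str(item[1])))
        for name, call in pairs:
            if call not in (FOLDED, UNFOLDED):
                raise ValueError(
                    f"protein {pid!r}: vote {call!r} from {name!r} is not a "
                    f"binary call"
                )
        results.append(
            ConsensusResult(pid, tuple(pairs), _verdict([c for _, c in pairs]))
        )
    return results


class UnanimousConsensus(BaseEstimator, ClassifierMixin):
    """Meta-classifier combining folding indexes under strict unanimity.

    Parameters
    ----------
    members : list of (name, estimator)
        Sequence-consuming :class:`~twilightfold.indexes.FoldingIndex`
        estimators.  All members see the same ``X``.
    """

    def __init__(self, members: Sequence[tuple[str, FoldingIndex]] | None = None):
        self.members = members

    def _member_list(self) -> list[tuple[str, FoldingIndex]]:
        if self.members:
            return list(self.members)
        from .indexes import HQIndex, MeanPackingIndex, MeanPairwiseEnergyIndex

        return [
            ("hq", HQIndex()),
            ("mean_packing", MeanPackingIndex()),
            ("mean_pairwise_energy", MeanPairwiseEnergyIndex()),
        ]

    def fit(self, X=None, y=None):
        self.members_ = [
            (name, clone(est).fit(X, y)) for name, est in self._member_list()
        ]
        self.classes_ = np.array([FOLDED, UNCLASSIFIED, UNFOLDED])
        return self

    def predict_votes(self, X) -> pd.DataFrame:
        """Per-member binary calls, one column per member."""
        check_is_fitted(self)
        return pd.DataFrame({name: est.predict(X) for name, est in self.members_})

    def predict(self, X) -> np.ndarray:
        votes = self.predict_votes(X)
        return np.array([_verdict(row) for row in votes.to_numpy()])

    def results(self, X) -> list[ConsensusResult]:
        check_is_fitted(self)
        per_member = [(name, est.results(X)) for name, est in self.members_]
        n = len(per_member[0][1])
        out = []
        for i in range(n):
            pairs = tuple((name, res[i].call) for name, res in per_member)
            pid = per_member[0][1][i].protein_id
            out.append(ConsensusResult(pid, pairs, _verdict([c for _, c in pairs])))
        return out


@dataclass(frozen=True)
class ProtocolStep:
    k: int
    members: tuple[str, ...]
    report: EvaluationReport


@dataclass(frozen=True)
class ProtocolTrace:
    order: tuple[str, ...]  # members by decreasing AUC (externals appended)
    aucs: Mapping[str, float]
    steps: tuple[ProtocolStep, ...]
    stopping_step: int
    fp_tolerance: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            r = s.report
            rows.append(
                {
                    "k": s.k,
                    "members": "+".join(s.members),
                    "Sn": r.sensitivity,
                    "Sp": r.specificity,
                    "fp": r.false_positive_fraction,
                    "nc": r.nc,
                }
            )
        return pd.DataFrame(rows)


def incremental_consensus(
    index_results: Mapping[str, Sequence[IndexResult]],
    labels: Mapping[str, str],
    fp_tolerance: float = 0.01,
    directions: Mapping[str, bool] | None = None,
    external: Sequence[BinaryPredictionTable] = (),
) -> ProtocolTrace:
    """AUC-ranked incremental strictly-unanimous combination.

    ``index_results`` maps member name to that member's per-protein results
    (score + call); ``directions`` maps name to the member's score
    orientation (True when higher means more disordered), defaulting to the
    bundled conventions.  External binary predictors carry no scores, so
    they cannot be AUC-ranked and are appended after the ranked members in
    the order given.

    AUC ties are broken by the member's own false-positive fraction, then
    by name.
    """
    if len(index_results) + len(external) < 1:
        raise ValueError("need at least one member")
    directions = {**HIGHER_IS_UNFOLDED, **(directions or {})}

    aucs: dict[str, float] = {}
    own_fp: dict[str, float] = {}
    for name, results in index_results.items():
        ids = [r.protein_id for r in results]
        scores = [r.score for r in results]
        try:
            higher = directions[name]
        except KeyError:
            raise ValueError(
                f"no score orientation known for member {name!r}; pass it via "
                f"'directions'"
            ) from None
        aucs[name] = roc_auc(scores, [labels[pid] for pid in ids], higher)
        own_fp[name] = confusion_metrics(
            {r.protein_id: r.call for r in results}, labels
        ).false_positive_fraction
    ranked = sorted(aucs, key=lambda n: (-aucs[n], own_fp[n], n))
    order = tuple(ranked) + tuple(t.source for t in external)

    calls: dict[str, dict[str, str]] = {
        name: {r.protein_id: r.call for r in results}
        for name, results in index_results.items()
    }
    for table in external:
        calls[table.source] = dict(table.calls)

    ids = sorted(labels)
    steps: list[ProtocolStep] = []
    for k in range(1, len(order) + 1):
        members = order[:k]
        verdicts = {}
        for pid in ids:
            votes = [calls[m][pid] for m in members]
            verdicts[pid] = _verdict(votes)
        report = confusion_metrics(verdicts, labels)
        steps.append(ProtocolStep(k=k, members=members, report=report))

    stopping = len(steps)
    for prev, step in zip(steps, steps[1:]):
        improvement = (
            prev.report.false_positive_fraction
            - step.report.false_positive_fraction
        )
        if improvement < fp_tolerance:
            stopping = step.k
            break
    return ProtocolTrace(
        order=order,
        aucs=aucs,
        steps=tuple(steps),
        stopping_step=stopping,
        fp_tolerance=fp_tolerance,
    )
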