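"""Twilight-zone delimitation in the hydrophobicity/charge plane.

Each protein is projected to the point (<H>, |<Q>|): the mean smoothed
hydrophobicity and the absolute mean net charge — the same coordinates the
HQ boundary index uses.  The twilight zone is delimited geometrically:

1. For each of the two planes (folded vs unclassified, unfolded vs
   unclassified) every line through a pair of points is evaluated, in both
   labeling orientations, as a separator.  "Sensitivity" here is the
   fraction of unclassified points on the line's unclassified side and the
   false-positive fraction is the fraction of classified points on that
   same side.  Among lines reaching the sensitivity floor (default 0.80,
   inclusive) the one with the lowest false-positive fraction wins
   (ties: higher sensitivity, then lexicographically smallest
   coefficients).
2. The lower-fp line of the two planes becomes the base line; it is
   translated parallel to itself, by the minimal offset, until the band
   between base and translated line holds at least the required coverage
   (default 75%) of the unclassified points.

Lines are stored as (a, b, c) with a*x + b*y + c = 0 and (a, b) unit
length; a point is on the positive ("unclassified") side when
a*x + b*y + c >= -SIDE_TOL, so points on the line count as covered in both
orientations.  The pair search is O(n^3); instances above ``max_points``
are subsampled with a seeded generator and the subsample size is recorded
in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .indexes import mean_hydrophobicity, mean_net_charge
from .scales import load_scale
from .seqio import FOLDED, UNCLASSIFIED, UNFOLDED, ProteinRecord

#: points within this distance of a line count as on its positive side
#: (in both orientations); keeps the search deterministic under round-off.
SIDE_TOL = 1e-9


@dataclass(frozen=True)
class HQPoint:
    protein_id: str
    hydrophobicity: float
    net_charge: float
    group: str  # folded | unfolded | unclassified
    length: int | None = None

    @property
    def xy(self) -> tuple[float, float]:
        return (self.hydrophobicity, self.net_charge)


@dataclass(frozen=True)
class Line:
    """a*x + b*y + c = 0 with (a, b) unit-normalised."""

    a: float
    b: float
    c: float

    def signed_distance(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy[:, 0] * self.a + xy[:, 1] * self.b + self.c

    def translated(self, offset: float) -> "Line":
        """Parallel line through the points at signed distance ``offset``."""
        return Line(self.a, self.b, self.c - offset)


@dataclass(frozen=True)
class LineSearchResult:
    feasible: bool
    line: Line | None
    sensitivity: float
    false_positive_fraction: float
    n_points: tuple[int, int]  # (classified group, unclassified group)
    subsampled: bool = False


@dataclass(frozen=True)
class TwilightZone:
    feasible: bool
    base_line: Line | None
    offset_line: Line | None
    contained_fraction: float
    width: float
    source_group: str | None  # which plane won (folded | unfolded)
    n_unclassified: int
    per_bin: str | None = None  # label when part of a binned analysis

    def contains(self, xy) -> np.ndarray:
        """Boolean mask of points inside the band (inclusive of both lines)."""
        if not self.feasible:
            raise ValueError("infeasible twilight zone has no band")
        d = self.base_line.signed_distance(xy)
        lo, hi = sorted((0.0, self.base_line.c - self.offset_line.c))
        return (d >= lo - SIDE_TOL) & (d <= hi + SIDE_TOL)


def project_to_plane(
    records: Iterable[ProteinRecord],
    groups: Mapping[str, str],
    hydrophobicity_window: int = 5,
) -> list[HQPoint]:
    """One (<H>, |<Q>|) point per protein, tagged with its consensus verdict
    (or experimental label)."""
    h_scale = load_scale("hydrophobicity")
    q_scale = load_scale("charge")
    points = []
    for rec in records:
        if rec.id not in groups:
            raise ValueError(f"protein {rec.id!r} has no group/verdict")
        points.append(
            HQPoint(
                protein_id=rec.id,
                hydrophobicity=mean_hydrophobicity(rec, h_scale, hydrophobicity_window),
                net_charge=mean_net_charge(rec, q_scale),
                group=groups[rec.id],
                length=rec.length,
            )
        )
    return points


def _as_xy(points) -> np.ndarray:
    if len(points) == 0:
        return np.empty((0, 2))
    if isinstance(points[0], HQPoint):
        return np.array([p.xy for p in points], dtype=float)
    return np.atleast_2d(np.asarray(points, dtype=float))


def _pair_lines(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normals and offsets of the lines through all distinct pairs."""
    n = pooled.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = pooled[jj] - pooled[ii]
    normals = np.stack([-d[:, 1], d[:, 0]], axis=1)
    norms = np.linalg.norm(normals, axis=1)
    keep = norms > 0  # skip coincident points
    normals = normals[keep] / norms[keep, None]
    offsets = -np.einsum("ij,ij->i", normals, pooled[ii[keep]])
    return normals, offsets


def _lex_key(a: float, b: float, c: float) -> tuple[float, float, float]:
    return (round(a, 12), round(b, 12), round(c, 12))


def find_discriminative_line(
    group_a,
    group_b,
    min_sensitivity: float = 0.80,
    inclusive: bool = True,
    max_points: int = 500,
    random_state: int | None = 0,
) -> LineSearchResult:
    """Best pair-line separating the unclassified group_b from group_a.

    Exhaustive over the lines through every pair of (pooled) points and
    both orientations.  Returns an explicit infeasible result when no line
    reaches the sensitivity floor.
    """
    A = _as_xy(list(group_a))
    B = _as_xy(list(group_b))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if A.shape[0] + B.shape[0] < 2:
        raise ValueError("need at least two points in total")

    subsampled = False
    total = A.shape[0] + B.shape[0]
    if total > max_points:
        rng = np.random.default_rng(random_state)
        frac = max_points / total
        na = max(1, int(round(A.shape[0] * frac)))
        nb = max(1, min(max_points - na, B.shape[0]))
        A = A[rng.choice(A.shape[0], size=min(na, A.shape[0]), replace=False)]
        B = B[rng.choice(B.shape[0], size=nb, replace=False)]
        subsampled = True

    pooled = np.vstack([A, B])
    normals, offsets = _pair_lines(pooled)
    if normals.shape[0] == 0:
        return LineSearchResult(False, None, 0.0, 1.0, (A.shape[0], B.shape[0]),
                                subsampled)

    floor = min_sensitivity - 1e-12 if inclusive else min_sensitivity + 1e-12
    best = None  # (fp, -sens, lex_key, line, sens)
    chunk = 20000
    for start in range(0, normals.shape[0], chunk):
        N = normals[start : start + chunk]
        C = offsets[start : start + chunk]
        dA = A @ N.T + C  # (na, k)
        dB = B @ N.T + C
        for flip in (1.0, -1.0):
            sens = (flip * dB >= -SIDE_TOL).mean(axis=0)
            fp = (flip * dA >= -SIDE_TOL).mean(axis=0)
            ok = sens >= floor
            if not ok.any():
                continue
            idx = np.flatnonzero(ok)
            # exact ties on (fp, sens) are rationals over the group sizes,
            # so float equality is safe; resolve them lexicographically
            min_fp = fp[idx].min()
            sel = idx[fp[idx] == min_fp]
            max_sens = sens[sel].max()
            sel = sel[sens[sel] == max_sens]
            for j in sel:
                a, b = flip * N[j]
                c = flip * C[j]
                cand = (fp[j], -sens[j], _lex_key(a, b, c))
                if best is None or cand < best[:3]:
                    best = (fp[j], -sens[j], _lex_key(a, b, c), Line(a, b, c), sens[j])
    if best is None:
        return LineSearchResult(False, None, 0.0, 1.0, (A.shape[0], B.shape[0]),
                                subsampled)
    return LineSearchResult(
        feasible=True,
        line=best[3],
        sensitivity=float(best[4]),
        false_positive_fraction=float(best[0]),
        n_points=(A.shape[0], B.shape[0]),
        subsampled=subsampled,
    )


def delimit_twilight_zone(
    folded,
    unfolded,
    unclassified,
    coverage: float = 0.75,
    min_sensitivity: float = 0.80,
    inclusive: bool = True,
    max_points: int = 500,
    random_state: int | None = 0,
) -> TwilightZone:
    """Delimit the twilight band between two parallel lines.

    Runs the pair-line search in both planes, keeps the lower-fp line and
    translates it by the minimal offset so the band holds at least
    ``coverage`` of the unclassified points.  The translation moves toward
    the side holding the majority of the unclassified points; if neither
    side alone can reach the coverage the zone is reported infeasible.
    """
    U = _as_xy(list(unclassified))
    if U.shape[0] == 0:
        raise ValueError("no unclassified points to delimit")
    candidates = []
    for group, name in ((folded, FOLDED), (unfolded, UNFOLDED)):
        res = find_discriminative_line(
            group, unclassified, min_sensitivity, inclusive, max_points, random_state
        )
        if res.feasible:
            candidates.append((res.false_positive_fraction, -res.sensitivity, name, res))
    if not candidates:
        return TwilightZone(False, None, None, 0.0, 0.0, None, U.shape[0])
    candidates.sort(key=lambda t: t[:3])
    _, _, source, best = candidates[0]
    base = best.line

    d = base.signed_distance(U)
    m = U.shape[0]
    need = math.ceil(coverage * m - 1e-12)
    n_pos = int((d >= -SIDE_TOL).sum())
    n_neg = int((d <= SIDE_TOL).sum())
    # direction: side holding the majority of unclassified points
    for side in sorted((("pos", n_pos), ("neg", n_neg)), key=lambda t: -t[1]):
        if side[1] < need:
            return TwilightZone(False, base, None, max(n_pos, n_neg) / m, 0.0,
                                source, m)
        if side[0] == "pos":
            vals = np.sort(np.clip(d[d >= -SIDE_TOL], 0.0, None))
            offset = float(vals[need - 1])
        else:
            vals = np.sort(np.clip(-d[d <= SIDE_TOL], 0.0, None))
            offset = -float(vals[need - 1])
        second = base.translated(offset)
        lo, hi = sorted((0.0, offset))
        contained = float(((d >= lo - SIDE_TOL) & (d <= hi + SIDE_TOL)).mean())
        return TwilightZone(
            feasible=True,
            base_line=base,
            offset_line=second,
            contained_fraction=contained,
            width=abs(offset),
            source_group=source,
            n_unclassified=m,
        )
    raise AssertionError("unreachable")


class TwilightZoneDelimiter:
    """Estimator wrapper around :func:`delimit_twilight_zone`.

    ``fit(X, y)`` takes an (n, 2) array of hydrophobicity/charge points and
    per-point group labels (folded/unfolded/unclassified) and stores the
    delimited band; ``predict(X)`` marks points inside it.  Follows the
    scikit-learn parameter protocol so it clones and grid-searches.
    """

    def __init__(
        self,
        coverage: float = 0.75,
        min_sensitivity: float = 0.80,
        inclusive: bool = True,
        max_points: int = 500,
        random_state: int | None = 0,
    ):
        self.coverage = coverage
        self.min_sensitivity = min_sensitivity
        self.inclusive = inclusive
        self.max_points = max_points
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "coverage": self.coverage,
            "min_sensitivity": self.min_sensitivity,
            "inclusive": self.inclusive,
            "max_points": self.max_points,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "TwilightZoneDelimiter":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "TwilightZoneDelimiter":
        X = _as_xy(list(X))
        y = np.asarray(list(y), dtype=object)
        if X.shape[0] != y.size:
            raise ValueError("X and y must have the same length")
        groups = {
            lab: X[y == lab] for lab in (FOLDED, UNFOLDED, UNCLASSIFIED)
        }
        for lab, pts in groups.items():
            if pts.shape[0] == 0:
                raise ValueError(f"no points labelled {lab!r}")
        self.zone_ = delimit_twilight_zone(
            groups[FOLDED],
            groups[UNFOLDED],
            groups[UNCLASSIFIED],
            coverage=self.coverage,
            min_sensitivity=self.min_sensitivity,
            inclusive=self.inclusive,
            max_points=self.max_points,
            random_state=self.random_state,
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "zone_"):
            raise ValueError("fit the delimiter before calling predict")
        return self.zone_.contains(_as_xy(list(X)))


DEFAULT_BIN_EDGES = (50.0, 100.0, 200.0, 300.0, math.inf)


def binned_twilight_zones(
    points: Sequence[HQPoint],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    **kwargs,
) -> dict[str, TwilightZone | None]:
    """Independent delimitation per chain-length bin.

    Bins are [edge_i, edge_{i+1}); points need a ``length``.  A bin with an
    empty group yields ``None`` (skipped with a notice via the returned
    mapping) rather than an error.
    """
    out: dict[str, TwilightZone | None] = {}
    for lo, hi in zip(bin_edges, bin_edges[1:]):
        label = f"{int(lo)}-{int(hi) - 1}" if math.isfinite(hi) else f">={int(lo)}"
        in_bin = [p for p in points if p.length is not None and lo <= p.length < hi]
        groups = {
            FOLDED: [p for p in in_bin if p.group == FOLDED],
            UNFOLDED: [p for p in in_bin if p.group == UNFOLDED],
            UNCLASSIFIED: [p for p in in_bin if p.group == UNCLASSIFIED],
        }
        if any(len(g) == 0 for g in groups.values()):
            out[label] = None
            continue
        zone = delimit_twilight_zone(
            groups[FOLDED], groups[UNFOLDED], groups[UNCLASSIFIED], **kwargs
        )
        out[label] = TwilightZone(
            feasible=zone.feasible,
            base_line=zone.base_line,
            offset_line=zone.offset_line,
            contained_fraction=zone.contained_fraction,
            width=zone.width,
            source_group=zone.source_group,
            n_unclassified=zone.n_unclassified,
            per_bin=label,
        )
    return out
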