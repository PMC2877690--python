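"""Independent direct-from-definition implementations used as test oracles.

Everything here is deliberately written as plain Python loops over the
definitions, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

SIDE_TOL = 1e-9  # same on-line rule the package documents


def window_average_oracle(values, window):
    half = (window - 1) // 2
    n = len(values)
    out = []
    for p in range(n):
        lo = max(0, p - half)
        hi = min(n - 1, p + half)
        out.append(sum(values[lo:hi + 1]) / (hi - lo + 1))
    return out


def scale_index_oracle(sequence, scale_values, window):
    """Window-smoothed per-residue scale values, averaged over the protein."""
    vals = [scale_values[c] for c in sequence]
    smoothed = window_average_oracle(vals, window)
    return sum(smoothed) / len(smoothed)


def pairwise_profile_oracle(sequence, pair_energy, min_sep=2, max_sep=100):
    """e(p) by the double loop over the 2..100 neighbourhood."""
    n = len(sequence)
    out = []
    for p in range(n):
        counts = {}
        total = 0
        for q in range(n):
            if min_sep <= abs(q - p) <= max_sep:
                counts[sequence[q]] = counts.get(sequence[q], 0) + 1
                total += 1
        e = 0.0
        for res, cnt in counts.items():
            e += pair_energy(sequence[p], res) * (cnt / total)
        out.append(e)
    return out


def mean_pairwise_oracle(sequence, pair_energy, window=21, min_sep=2, max_sep=100):
    prof = pairwise_profile_oracle(sequence, pair_energy, min_sep, max_sep)
    smoothed = window_average_oracle(prof, window)
    return sum(smoothed) / len(smoothed)


def auc_pair_counting(scores, positive_mask):
    """P(score_pos > score_neg) + P(tie)/2 by explicit pair enumeration."""
    pos = [s for s, m in zip(scores, positive_mask) if m]
    neg = [s for s, m in zip(scores, positive_mask) if not m]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def line_search_oracle(A, B, min_sensitivity=0.80, inclusive=True):
    """Exhaustive pair-line separator search by plain loops.

    Returns (feasible, fp, sensitivity) of the optimum under the same
    conventions the package documents: a point at signed distance
    >= -SIDE_TOL is on the positive (unclassified) side in both
    orientations; feasible lines reach the sensitivity floor; among them
    minimal fp wins, then maximal sensitivity.
    """
    pts = [tuple(p) for p in list(A) + list(B)]
    best = None
    floor = min_sensitivity - 1e-12 if inclusive else min_sensitivity + 1e-12
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dx = pts[j][0] - pts[i][0]
            dy = pts[j][1] - pts[i][1]
            norm = (dx * dx + dy * dy) ** 0.5
            if norm == 0:
                continue
            a, b = -dy / norm, dx / norm
            c = -(a * pts[i][0] + b * pts[i][1])
            for flip in (1.0, -1.0):
                fa, fb, fc = flip * a, flip * b, flip * c
                sens = sum(
                    1 for x, y in B if fa * x + fb * y + fc >= -SIDE_TOL
                ) / len(B)
                fp = sum(
                    1 for x, y in A if fa * x + fb * y + fc >= -SIDE_TOL
                ) / len(A)
                if sens >= floor:
                    cand = (fp, -sens)
                    if best is None or cand < best:
                        best = cand
    if best is None:
        return False, None, None
    return True, best[0], -best[1]


def random_sequences(rng, n, min_len, max_len, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = list(alphabet)
    seqs = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seqs.append("".join(rng.choice(letters, size=length)))
    return seqs
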