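"""Seeded generator of folded / twilight / unfolded sequence datasets.

The generator emulates the two structural features the consensus method
rests on, and nothing else:

* compositional separation — the folded class shifts probability mass
  toward the order-promoting residues {W,C,F,I,Y,V,L,H,N}, the unfolded
  class toward the disorder-promoting residues {A,R,Q,S,P,E,K}, and the
  twilight class sits exactly at the elementwise midpoint of the two;
* heavy-tailed chain lengths — each class draws lengths from a truncated
  discrete power law with its own exponent (defaults -2.7 folded,
  -1.2 unfolded, -3.3 twilight, on [50, 2000]).

Residues are sampled i.i.d. within a sequence (a zero-order chain — the
same probabilistic model the log-odds score assumes), so no positional
correlation, domain architecture or actual structural disorder is
simulated.

Class weights follow ``exp(+/- separation)`` on the promoting partition:
``separation=0`` collapses all three compositions to uniform, and at the
default ``separation=0.6`` the order/disorder mass ratio between the two
extreme classes is about e^2.4 ~ 3.3 per residue, enough for the bundled
indexes to separate the extreme classes while leaving the midpoint class
genuinely ambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import promoting_partition
from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta

TWILIGHT = "twilight"

DEFAULT_LENGTH_RANGE = (50, 2000)
DEFAULT_EXPONENTS = {"folded": -2.7, "unfolded": -1.2, TWILIGHT: -3.3}


@dataclass(frozen=True)
class ClassProfile:
    label: str
    composition: np.ndarray  # over AMINO_ACIDS order, sums to 1
    length_exponent: float
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    n: int = 1000

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: composition must be a 20-probability vector")
        object.__setattr__(self, "composition", comp / comp.sum())
        lo, hi = self.length_range
        if not (10 <= lo < hi <= 5000):
            raise ValueError(f"{self.label}: length range must sit inside [10, 5000]")
        if self.length_exponent >= -1:
            raise ValueError(f"{self.label}: length exponent must be < -1")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")


def _biased_composition(separation: float, sign: float) -> np.ndarray:
    part = promoting_partition()
    delta = np.array(
        [
            1.0 if a in part.order_promoting
            else -1.0 if a in part.disorder_promoting
            else 0.0
            for a in AMINO_ACIDS
        ]
    )
    w = np.exp(sign * separation * delta)
    return w / w.sum()


def default_profiles(
    separation: float = 0.6,
    n: int = 1000,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """(folded, twilight, unfolded) class profiles at a given compositional
    separation in [0, 1].  The twilight composition is the elementwise mean
    of the other two."""
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    folded_comp = _biased_composition(separation, +1.0)
    unfolded_comp = _biased_composition(separation, -1.0)
    twilight_comp = (folded_comp + unfolded_comp) / 2.0
    return (
        ClassProfile("folded", folded_comp, DEFAULT_EXPONENTS["folded"],
                     length_range, n),
        ClassProfile(TWILIGHT, twilight_comp, DEFAULT_EXPONENTS[TWILIGHT],
                     length_range, n),
        ClassProfile("unfolded", unfolded_comp, DEFAULT_EXPONENTS["unfolded"],
                     length_range, n),
    )


def sample_power_law_lengths(
    n: int,
    exponent: float,
    length_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw integer lengths from a truncated discrete power law
    P(L) proportional to L**exponent on [lo, hi]."""
    lo, hi = length_range
    support = np.arange(lo, hi + 1)
    pmf = support.astype(float) ** exponent
    pmf /= pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def generate_dataset(
    profiles: Sequence[ClassProfile],
    seed: int,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate labeled records from class profiles, deterministically under
    ``seed``.  Returns (records, id -> class label)."""
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for prof in profiles:
        lengths = sample_power_law_lengths(
            prof.n, prof.length_exponent, prof.length_range, rng
        )
        for k, length in enumerate(lengths):
            seq = "".join(rng.choice(residues, size=int(length), p=prof.composition))
            pid = f"{prof.label}_{k:05d}"
            records.append(ProteinRecord(pid, seq))
            labels[pid] = prof.label
    return records, labels


def write_dataset(
    out_dir: str | Path,
    profiles: Sequence[ClassProfile],
    seed: int,
) -> tuple[Path, Path, Path]:
    """Emit FASTA + labels TSV + a manifest JSON that reproduces the draw."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, labels = generate_dataset(profiles, seed)
    fasta = out_dir / "dataset.fasta"
    label_path = out_dir / "labels.tsv"
    manifest = out_dir / "manifest.json"
    write_fasta(records, fasta)
    with open(label_path, "w") as fh:
        fh.write("protein_id\tclass\n")
        for rec in records:
            fh.write(f"{rec.id}\t{labels[rec.id]}\n")
    manifest.write_text(
        json.dumps(
            {
                "seed": seed,
                "profiles": [
                    {
                        "label": p.label,
                        "composition": {a: p.composition[i]
                                        for i, a in enumerate(AMINO_ACIDS)},
                        "length_exponent": p.length_exponent,
                        "length_range": list(p.length_range),
                        "n": p.n,
                    }
                    for p in profiles
                ],
            },
            indent=2,
        )
        + "\n"
    )
    return fasta, label_path, manifest
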