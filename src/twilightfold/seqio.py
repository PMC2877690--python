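"""Sequence and prediction-table I/O.

Everything downstream assumes the 20-letter canonical amino-acid alphabet;
this module is the single place where that contract is enforced.  Ambiguity
codes are either rejected (``policy="strict"``) or resolved to a canonical
residue (``policy="map"``: B->N, Z->Q, U->C, J->L, O->K, X dropped), with
every edit counted.  Records whose ambiguous fraction exceeds 5% are refused
under ``map`` because the composition statistics would no longer be
trustworthy.

Positions are 1-based in every file format and every reported coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

AMBIGUITY_MAP = {"B": "N", "Z": "Q", "U": "C", "J": "L", "O": "K"}
DROP_CODES = frozenset("X")

FOLDED = "folded"
UNFOLDED = "unfolded"
UNCLASSIFIED = "unclassified"

#: hard mathematical minimum for the indexes (pairwise energy needs
#: positions >= 2 apart); below 50 residues a warning is emitted because the
#: reference datasets used >= 50.
MIN_LENGTH = 10
RECOMMENDED_MIN_LENGTH = 50
MAX_AMBIGUOUS_FRACTION = 0.05


class FastaParseError(ValueError):
    """Malformed FASTA; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RecordError(ValueError):
    """A single sequence record violates the alphabet/length contract."""


class TableError(ValueError):
    """A TSV table (profiles or binary predictions) is inconsistent."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus validated canonical amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise RecordError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise RecordError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise RecordError(
                f"record {self.id!r} contains non-canonical residues "
                f"{sorted(bad)!r}; normalize with an ambiguity policy first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueProfile:
    """Per-residue scores for one protein, 1-based positions, position i at
    ``values[i-1]``."""

    protein_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise TableError(f"profile for {self.protein_id!r} is empty")
        for pos, v in enumerate(self.values, start=1):
            if not (v == v and abs(v) != float("inf")):
                raise TableError(
                    f"profile for {self.protein_id!r} has non-finite score "
                    f"at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BinaryPredictionTable:
    """Per-protein folded/unfolded calls from an external classifier."""

    source: str
    calls: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, call in self.calls.items():
            if call not in (FOLDED, UNFOLDED):
                raise TableError(
                    f"{self.source}: call for {pid!r} is {call!r}; "
                    f"accepted tokens are '{FOLDED}' and '{UNFOLDED}'"
                )

    def __len__(self) -> int:
        return len(self.calls)


def normalize_sequence(raw: str, policy: str = "map") -> tuple[str, int]:
    """Uppercase and resolve ambiguity codes; return (sequence, edit count).

    ``strict`` rejects anything outside the canonical alphabet; ``map``
    substitutes B/Z/U/J/O and drops X, failing if more than 5% of the
    residues needed editing.
    """
    if policy not in ("strict", "map"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    seq = "".join(raw.split()).upper()
    if not seq:
        return "", 0
    if policy == "strict":
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise RecordError(
                f"non-canonical residue(s) {sorted(bad)!r} under strict policy"
            )
        return seq, 0
    out = []
    edits = 0
    for c in seq:
        if c in AA_INDEX:
            out.append(c)
        elif c in AMBIGUITY_MAP:
            out.append(AMBIGUITY_MAP[c])
            edits += 1
        elif c in DROP_CODES:
            edits += 1
        else:
            raise RecordError(f"residue {c!r} is not a canonical or ambiguity code")
    if edits / len(seq) > MAX_AMBIGUOUS_FRACTION:
        raise RecordError(
            f"{edits}/{len(seq)} ambiguous residues exceeds the "
            f"{MAX_AMBIGUOUS_FRACTION:.0%} limit under policy 'map'"
        )
    return "".join(out), edits


def read_fasta(
    path: str | Path,
    policy: str = "map",
    on_error: str = "raise",
) -> list[ProteinRecord]:
    """Read a multi-record FASTA into validated :class:`ProteinRecord` objects.

    ``on_error="skip"`` turns record-level failures (empty sequence, alphabet
    violation, too many ambiguity codes) into warnings and drops the record;
    malformed FASTA structure always raises :class:`FastaParseError`.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        "expected a '>' header before sequence data", line=lineno
                    )
                break
        else:
            raise FastaParseError(f"{path} contains no records")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for raw in SeqIO.parse(str(path), "fasta"):
        try:
            if not raw.id:
                raise RecordError("record with empty id")
            if raw.id in seen:
                raise RecordError(f"duplicate record id {raw.id!r}")
            seq, edits = normalize_sequence(str(raw.seq), policy=policy)
            if not seq:
                raise RecordError(f"record {raw.id!r} has an empty sequence")
            if edits:
                warnings.warn(
                    f"record {raw.id!r}: {edits} ambiguous position(s) edited "
                    f"under policy 'map'",
                    stacklevel=2,
                )
            records.append(ProteinRecord(raw.id, seq))
            seen.add(raw.id)
        except RecordError as exc:
            if on_error == "raise":
                raise
            warnings.warn(f"skipping record: {exc}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_residue_profiles(
    path: str | Path, normalized: bool = False
) -> list[ResidueProfile]:
    """Read a ``protein_id\\tposition\\tscore`` TSV into per-protein profiles.

    Positions must be contiguous from 1 with no duplicates.  With
    ``normalized=True`` every score must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "score"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing column(s) {sorted(missing)}")
    profiles: list[ResidueProfile] = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        dup = pd.Series(positions).duplicated()
        if dup.any():
            pos = int(positions[dup.to_numpy()][0])
            raise TableError(f"{pid}: duplicate position {pos}")
        expected = range(1, len(positions) + 1)
        for want, got in zip(expected, positions):
            if want != got:
                raise TableError(f"{pid}: missing position {want}")
        scores = grp["score"].to_numpy(dtype=float)
        if normalized:
            for pos, s in zip(positions, scores):
                if not 0.0 <= s <= 1.0:
                    raise TableError(
                        f"{pid}: score {s} at position {int(pos)} outside [0, 1] "
                        f"for a normalized profile"
                    )
        profiles.append(ResidueProfile(str(pid), tuple(float(s) for s in scores)))
    return profiles


def check_profile_lengths(
    profiles: Iterable[ResidueProfile], records: Iterable[ProteinRecord]
) -> None:
    """Raise if a profile's length disagrees with its protein's length."""
    lengths = {r.id: r.length for r in records}
    for p in profiles:
        if p.protein_id in lengths and p.length != lengths[p.protein_id]:
            raise TableError(
                f"profile for {p.protein_id!r} has {p.length} positions but the "
                f"sequence has {lengths[p.protein_id]} residues"
            )


def read_binary_predictions(
    path: str | Path, source: str | None = None
) -> BinaryPredictionTable:
    """Read a ``protein_id\\tcall`` TSV; calls are case-folded to
    folded/unfolded."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "call"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing column(s) {sorted(missing)}")
    calls: dict[str, str] = {}
    for pid, call in zip(df["protein_id"], df["call"]):
        token = str(call).strip().lower()
        if token not in (FOLDED, UNFOLDED):
            raise TableError(
                f"{path}: call {call!r} for {pid!r} not recognized; accepted "
                f"tokens are '{FOLDED}' and '{UNFOLDED}' (any case)"
            )
        calls[str(pid)] = token
    return BinaryPredictionTable(source=source or path.stem, calls=calls)


def as_record(seq_or_record, default_id: str = "seq") -> ProteinRecord:
    """Coerce a raw string to a ProteinRecord; pass records through."""
    if isinstance(seq_or_record, ProteinRecord):
        return seq_or_record
    return ProteinRecord(default_id, str(seq_or_record).upper())
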