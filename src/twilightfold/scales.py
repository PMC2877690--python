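"""Bundled per-residue parameter tables and the pairwise contact-energy matrix.

Five scales ship with the package:

``hydrophobicity``
    Kyte-Doolittle hydropathy rescaled to [0, 1] (the charge/hydrophobicity
    boundary convention).
``charge``
    Formal charge at neutral pH: K, R = +1; D, E = -1; H = 0 by convention
    (the simplest assignment consistent with +/-1 formal charges).
``packing``
    Expected number of residues within 8 A of each residue type, averaged
    over structures (transcribed packing scale; see file provenance line).
``flexibility``
    B-factor-derived flexibility parameters (transcribed Smith-type scale).
``disorder_propensity_surrogate``
    TOP-IDP disorder propensity min-max normalized to [0, 1].  A stand-in
    profile source so the global disorder score is testable without an
    external per-residue predictor; it is NOT a VSL2 reimplementation.

The pairwise matrix bundled here is a synthetic calibrated stand-in for a
statistical contact-energy predictor matrix (see the provenance header of
``energy_matrix_synthetic.tsv``): hydrophobic pairs are favourable,
like-charge pairs repulsive, salt bridges attractive, and the overall scale
is set so folded-like compositions fall near -0.6 a.e.u. and disordered-like
ones near -0.35 a.e.u.

Every table is validated at load time and checksummed against
``data/checksums.json``; a mismatch is a hard error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .seqio import AMINO_ACIDS

_SCALE_FILES = {
    "hydrophobicity": "hydrophobicity_kd.tsv",
    "charge": "charge.tsv",
    "packing": "packing_contacts.tsv",
    "flexibility": "flexibility_smith.tsv",
    "disorder_propensity_surrogate": "disorder_propensity_topidp.tsv",
}
_MATRIX_FILE = "energy_matrix_synthetic.tsv"


class ScaleLoadError(ValueError):
    """A bundled data file is missing, corrupt, or has drifted."""


@dataclass(frozen=True)
class ResidueScale:
    name: str
    values: Mapping[str, float]
    provenance: str
    normalization: str  # "raw" | "unit-interval"

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ScaleLoadError(
                f"scale {self.name!r} must define exactly the 20 canonical "
                f"residues"
            )
        arr = np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ScaleLoadError(f"scale {self.name!r} contains non-finite values")
        if self.normalization == "unit-interval" and (
            arr.min() < 0.0 or arr.max() > 1.0
        ):
            raise ScaleLoadError(
                f"unit-interval scale {self.name!r} has values outside [0, 1]"
            )
        if self.normalization not in ("raw", "unit-interval"):
            raise ScaleLoadError(
                f"scale {self.name!r}: unknown normalization "
                f"{self.normalization!r}"
            )

    def value(self, residue: str) -> float:
        return float(self.values[residue])

    def as_array(self) -> np.ndarray:
        """Values in canonical ``AMINO_ACIDS`` order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


@dataclass(frozen=True)
class EnergyMatrix:
    """Symmetric 20x20 pairwise contact-energy table, a.e.u., canonical
    residue order."""

    values: np.ndarray
    provenance: str
    units: str = "a.e.u."

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ScaleLoadError(f"energy matrix must be 20x20, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ScaleLoadError("energy matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-9, rtol=0.0):
            raise ScaleLoadError("energy matrix is not symmetric within 1e-9")
        object.__setattr__(self, "values", v)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)])


def _data_text(fname: str, verify_checksum: bool = True) -> str:
    pkg = resources.files("twilightfold.data")
    try:
        raw = (pkg / fname).read_bytes()
    except FileNotFoundError as exc:
        raise ScaleLoadError(f"bundled data file {fname!r} is missing") from exc
    if verify_checksum:
        checks = json.loads((pkg / "checksums.json").read_text())
        want = checks.get(fname)
        got = hashlib.sha256(raw).hexdigest()
        if want != got:
            raise ScaleLoadError(
                f"bundled data file {fname!r} failed its checksum "
                f"(expected {want}, got {got}); the data has drifted"
            )
    return raw.decode()


def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line.lstrip("# ").partition(":")
        meta[key.strip()] = val.strip()
    return meta


def available_scales() -> tuple[str, ...]:
    return tuple(_SCALE_FILES)


def load_scale(name: str, verify_checksum: bool = True) -> ResidueScale:
    """Load a bundled residue scale by name.

    Raises :class:`ScaleLoadError` for an unknown name (listing the
    available scales) or a corrupt/drifted file.
    """
    if name not in _SCALE_FILES:
        raise ScaleLoadError(
            f"unknown scale {name!r}; available: {', '.join(_SCALE_FILES)}"
        )
    text = _data_text(_SCALE_FILES[name], verify_checksum)
    lines = text.splitlines()
    meta = _parse_metadata(lines)
    values: dict[str, float] = {}
    header_seen = False
    for line in lines:
        if line.startswith("#") or not line.strip():
            continue
        if not header_seen:
            if line.split("\t") != ["residue", "value"]:
                raise ScaleLoadError(f"{name}: bad column header {line!r}")
            header_seen = True
            continue
        residue, val = line.split("\t")
        values[residue] = float(val)
    return ResidueScale(
        name=meta.get("name", name),
        values=values,
        provenance=meta.get("provenance", ""),
        normalization=meta.get("normalization", "raw"),
    )


def load_energy_matrix(verify_checksum: bool = True) -> EnergyMatrix:
    """Load the bundled 20x20 pairwise contact-energy matrix."""
    text = _data_text(_MATRIX_FILE, verify_checksum)
    lines = [l for l in text.splitlines() if l.strip()]
    meta = _parse_metadata(lines)
    body = [l for l in lines if not l.startswith("#")]
    header = body[0].split("\t")
    if header[0] != "residue" or "".join(header[1:]) != AMINO_ACIDS:
        raise ScaleLoadError("energy matrix header does not list the canonical residues")
    rows = {}
    for line in body[1:]:
        parts = line.split("\t")
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if "".join(rows) != AMINO_ACIDS:
        raise ScaleLoadError("energy matrix rows do not list the canonical residues")
    mat = np.array([rows[a] for a in AMINO_ACIDS], dtype=float)
    return EnergyMatrix(
        values=mat,
        provenance=meta.get("provenance", ""),
        units=meta.get("units", "a.e.u."),
    )
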