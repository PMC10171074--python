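"""Domain types and extended-XYZ I/O.

The package works on molecules (or non-interacting supersystems) annotated
with one intensive electronic scalar per structure -- a HOMO energy or an
ionization energy in eV -- plus optional per-atom orbital localization
fractions ``l_i`` and a scalar localization index ``L``.

Energies are in eV, coordinates in Angstrom, atom indexing is 0-based.
Units are never auto-converted.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "OrbpoolError",
    "ParseError",
    "ValidationError",
    "LabeledDataError",
    "ConfigurationError",
    "ContractError",
    "AtomicSystem",
    "ElectronicReference",
    "LabeledDataset",
    "read_extxyz",
    "write_extxyz",
]


class OrbpoolError(Exception):
    """Base class for package errors."""


class ParseError(OrbpoolError):
    """Malformed file content; message names the offending frame."""


class ValidationError(OrbpoolError, ValueError):
    """A domain invariant is violated."""


class LabeledDataError(OrbpoolError):
    """Required labels (target energy, localization fractions) are missing."""


class ConfigurationError(OrbpoolError):
    """Inconsistent or incomplete configuration."""


class ContractError(OrbpoolError, ValueError):
    """A caller violated an operation precondition."""


_MODES = ("max", "min")


@dataclass
class AtomicSystem:
    """One molecule or supersystem: element symbols plus Cartesian coordinates.

    ``fragment_labels`` identify non-interacting subsystems; label 0
    everywhere means a monomer.  Labels gate the tight-binding coupling and
    are assigned by :func:`orbpool.tightbinding.compose_noninteracting`.
    """

    elements: list[str]
    coordinates: np.ndarray
    system_id: str = ""
    fragment_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = [str(e) for e in self.elements]
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValidationError("AtomicSystem needs at least one atom")
        if self.coordinates.shape != (n, 3):
            raise ValidationError(
                f"coordinates shape {self.coordinates.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates must be finite")
        if self.fragment_labels is not None:
            self.fragment_labels = np.asarray(self.fragment_labels, dtype=int)
            if self.fragment_labels.shape != (n,):
                raise ValidationError("fragment_labels length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def fragments(self) -> np.ndarray:
        """Per-atom fragment labels, defaulting to all-zero (monomer)."""
        if self.fragment_labels is None:
            return np.zeros(self.n_atoms, dtype=int)
        return self.fragment_labels


@dataclass
class ElectronicReference:
    """Reference electronic data for one structure.

    ``mode`` records whether the target is governed by the maximum
    (HOMO energy) or the minimum (IE / LUMO energy) over subsystem values
    when structures are composed.
    """

    target_energy: float
    mode: str = "max"
    localization_fractions: np.ndarray | None = None
    localization_index: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.target_energy = float(self.target_energy)
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.localization_fractions is not None:
            l = np.asarray(self.localization_fractions, dtype=float)
            self.localization_fractions = l
            if np.any(l < -1e-6):
                raise ValidationError("localization fractions must be >= 0")
            if abs(float(l.sum()) - 1.0) > 1e-6:
                raise ValidationError(
                    f"localization fractions sum to {l.sum():.8f}, expected 1"
                )
        if self.localization_index is not None:
            L = float(self.localization_index)
            if not (-1e-9 <= L <= 1.0 + 1e-9):
                raise ValidationError(f"localization index {L} outside [0, 1]")
            self.localization_index = L


Record = tuple[AtomicSystem, ElectronicReference]

_SPLITS = ("train", "val", "test")


@dataclass
class LabeledDataset:
    """Ordered records of (structure, reference) with train/val/test tags."""

    records: list[Record]
    split_tags: list[str] | None = None
    provenance: str = ""
    # optional per-record learned weights, populated by pseudoorbital export
    pseudoorbital_weights: list[np.ndarray | None] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if self.split_tags is None:
            self.split_tags = ["train"] * len(self.records)
        if len(self.split_tags) != len(self.records):
            raise ValidationError("split_tags must have one entry per record")
        for tag in self.split_tags:
            if tag not in _SPLITS:
                raise ValidationError(f"unknown split tag {tag!r}")
        modes = {ref.mode for _, ref in self.records}
        if len(modes) > 1:
            raise ValidationError(f"records mix modes {sorted(modes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Record:
        return self.records[i]

    @property
    def mode(self) -> str:
        if not self.records:
            raise ValidationError("empty dataset has no mode")
        return self.records[0][1].mode

    def subset(self, indices: Sequence[int], provenance: str = "") -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            split_tags=[self.split_tags[i] for i in idx],
            provenance=provenance or self.provenance,
        )

    def split(self, tag: str) -> "LabeledDataset":
        """Records carrying a given split tag, order preserved."""
        if tag not in _SPLITS:
            raise ValidationError(f"unknown split tag {tag!r}")
        return self.subset(
            [i for i, t in enumerate(self.split_tags) if t == tag],
            provenance=f"{self.provenance}[{tag}]",
        )


# ---------------------------------------------------------------------------
# extended XYZ
#
# Dialect: integer atom count line; a comment line of space-separated
# key=value pairs including a Properties= column descriptor; per-atom rows
# species x y z [l_frac] [owa_weight].


def _format_comment(
    ref: ElectronicReference,
    system: AtomicSystem,
    split: str,
    has_l: bool,
    has_w: bool,
) -> str:
    cols = "species:S:1:pos:R:3"
    if has_l:
        cols += ":l_frac:R:1"
    if has_w:
        cols += ":owa_weight:R:1"
    parts = [f"Properties={cols}"]
    parts.append(f"target_energy={ref.target_energy:.12e}")
    parts.append(f"mode={ref.mode}")
    if ref.localization_index is not None:
        parts.append(f"L={ref.localization_index:.12e}")
    if system.system_id:
        parts.append(f'system_id="{system.system_id}"')
    if system.fragment_labels is not None:
        parts.append("fragment=" + ",".join(str(x) for x in system.fragment_labels))
    parts.append(f"split={split}")
    return " ".join(parts)


def write_extxyz(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as extended XYZ.

    Output uses fixed float formatting, hence is byte-stable for identical
    inputs.  If ``dataset.pseudoorbital_weights`` is set, an ``owa_weight``
    per-atom column is emitted for records that carry weights.
    """
    path = Path(path)
    weights = dataset.pseudoorbital_weights or [None] * len(dataset)
    lines: list[str] = []
    for (system, ref), split, w in zip(dataset.records, dataset.split_tags, weights):
        l = ref.localization_fractions
        has_l = l is not None
        has_w = w is not None
        lines.append(str(system.n_atoms))
        lines.append(_format_comment(ref, system, split, has_l, has_w))
        for i, (el, xyz) in enumerate(zip(system.elements, system.coordinates)):
            row = f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}"
            if has_l:
                row += f" {l[i]:.12e}"
            if has_w:
                row += f" {w[i]:.12e}"
            lines.append(row)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    fields = spec.split(":")
    if len(fields) % 3 != 0:
        raise ParseError(f"bad Properties descriptor {spec!r}")
    out = []
    for j in range(0, len(fields), 3):
        out.append((fields[j], fields[j + 1], int(fields[j + 2])))
    return out


def read_extxyz(path: str | Path) -> LabeledDataset:
    """Read a dataset written by :func:`write_extxyz` (or compatible).

    Recognized per-structure keys: ``target_energy`` (required), ``mode``,
    ``L``, ``system_id``, ``fragment``, ``split``; recognized optional
    per-atom columns: ``l_frac``, ``owa_weight``.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    pos = 0
    records: list[Record] = []
    tags: list[str] = []
    all_weights: list[np.ndarray | None] = []
    any_weights = False
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"frame {frame}: bad atom count line {lines[pos]!r}") from exc
        if pos + 2 + natoms > len(lines):
            raise ParseError(f"frame {frame}: truncated ({natoms} atoms expected)")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        keys: dict[str, str] = {}
        try:
            for token in shlex.split(comment):
                if "=" in token:
                    k, v = token.split("=", 1)
                    keys[k] = v
        except ValueError as exc:
            raise ParseError(f"frame {frame}: unparseable comment line") from exc
        props = _parse_properties(keys.get("Properties", "species:S:1:pos:R:3"))
        colnames: list[str] = []
        for name, _kind, width in props:
            colnames.extend([name] * width)
        if "target_energy" not in keys:
            raise LabeledDataError(f"frame {frame}: missing target_energy")
        elements: list[str] = []
        coords = np.zeros((natoms, 3))
        lfrac = np.zeros(natoms) if "l_frac" in colnames else None
        wcol = np.zeros(natoms) if "owa_weight" in colnames else None
        for i in range(natoms):
            row = lines[pos + 2 + i].split()
            if len(row) != len(colnames):
                raise ParseError(
                    f"frame {frame}: atom row {i} has {len(row)} fields, "
                    f"expected {len(colnames)}"
                )
            vals = dict()
            xyz = []
            for name, value in zip(colnames, row):
                if name == "pos":
                    xyz.append(float(value))
                else:
                    vals[name] = value
            elements.append(vals["species"])
            coords[i] = xyz
            if lfrac is not None:
                lfrac[i] = float(vals["l_frac"])
            if wcol is not None:
                wcol[i] = float(vals["owa_weight"])
        if lfrac is not None and abs(float(lfrac.sum()) - 1.0) > 1e-6:
            raise ValidationError(
                f"frame {frame}: l_frac sums to {lfrac.sum():.6f}, expected 1"
            )
        fragments = None
        if "fragment" in keys:
            fragments = np.array([int(x) for x in keys["fragment"].split(",")])
        system = AtomicSystem(
            elements=elements,
            coordinates=coords,
            system_id=keys.get("system_id", ""),
            fragment_labels=fragments,
        )
        ref = ElectronicReference(
            target_energy=float(keys["target_energy"]),
            mode=keys.get("mode", "max"),
            localization_fractions=lfrac,
            localization_index=float(keys["L"]) if "L" in keys else None,
        )
        records.append((system, ref))
        tags.append(keys.get("split", "train"))
        all_weights.append(wcol)
        any_weights = any_weights or wcol is not None
        pos += 2 + natoms
        frame += 1
    ds = LabeledDataset(records=records, split_tags=tags, provenance=str(path))
    if any_weights:
        ds.pseudoorbital_weights = all_weights
    return ds
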