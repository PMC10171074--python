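"""Orbital localization mathematics.

Given a normalized molecular orbital expanded in an atom-centered basis,
the Mulliken-style fraction of the orbital residing on atom ``i`` is

    l_i = sum_{mu in i} sum_nu c_mu c_nu S_munu,

where the outer sum runs over basis functions centered on atom ``i`` and
``S`` is the basis overlap matrix (identity for an orthogonal basis, in
which case l_i reduces to the summed squared coefficients).  The fractions
sum to one but individual entries can be slightly negative for non-identity
overlap; they are passed through unclipped for analysis and sanitized only
when used as training labels.

The scalar localization index condenses ``l`` into a single number

    L = (N * sum_i l_i^2 - 1) / (N - 1),

a normalized inverse participation ratio: L = 1 when the orbital sits
entirely on one atom and L = 0 when it is spread evenly over all N atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import LabeledDataset, ValidationError

__all__ = [
    "OrbitalVector",
    "localization_fraction",
    "localization_index",
    "sanitize_fractions",
    "stratify_by_L",
    "Strata",
]

logger = logging.getLogger(__name__)

#: stratification thresholds, following the convention that orbitals with
#: L >= 0.8 count as highly localized and L < 0.4 as highly delocalized
LOCALIZED_CUT = 0.8
DELOCALIZED_CUT = 0.4


@dataclass
class OrbitalVector:
    """A normalized orbital: coefficients, basis-to-atom map, optional overlap.

    ``overlap=None`` means an orthogonal basis (identity overlap).
    Normalization c^T S c = 1 is enforced to 1e-8.
    """

    coefficients: np.ndarray
    basis_to_atom: np.ndarray
    overlap: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        self.coefficients = c
        self.basis_to_atom = np.asarray(self.basis_to_atom, dtype=int)
        m = c.shape[0]
        if self.basis_to_atom.shape != (m,):
            raise ValidationError("basis_to_atom must map every basis function")
        n_atoms = self.basis_to_atom.max() + 1
        covered = np.unique(self.basis_to_atom)
        if covered.min() < 0 or len(covered) != n_atoms:
            raise ValidationError("basis_to_atom must cover atoms 0..N-1")
        if self.overlap is not None:
            S = np.asarray(self.overlap, dtype=float)
            if S.shape != (m, m):
                raise ValidationError("overlap must be M x M")
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValidationError("overlap must be symmetric")
            self.overlap = S
        norm = float(c @ (c if self.overlap is None else self.overlap @ c))
        if abs(norm - 1.0) > 1e-8:
            raise ValidationError(f"orbital norm c^T S c = {norm:.10f}, expected 1")

    @property
    def n_atoms(self) -> int:
        return int(self.basis_to_atom.max()) + 1


def localization_fraction(orbital: OrbitalVector) -> np.ndarray:
    """Per-atom Mulliken fractions l_i of a normalized orbital.

    Returns a length-N vector summing to 1 (to 1e-8).  Entries may be
    slightly negative for non-identity overlap and are returned as-is.
    """
    c = orbital.coefficients
    sc = c if orbital.overlap is None else orbital.overlap @ c
    contrib = c * sc
    return np.bincount(orbital.basis_to_atom, weights=contrib,
                       minlength=orbital.n_atoms)


def localization_index(l: np.ndarray) -> float:
    """Scalar localization index L of a fraction vector.

    L = (N * sum l_i^2 - 1) / (N - 1); 1 for a one-hot vector, 0 for the
    uniform vector.  Undefined for single-atom systems.
    """
    l = np.asarray(l, dtype=float)
    n = l.shape[0]
    if n < 2:
        raise ValidationError("localization index undefined for N = 1")
    if np.any(l < -1e-8):
        raise ValidationError("fractions must be >= -1e-8")
    if abs(float(l.sum()) - 1.0) > 1e-8:
        raise ValidationError(f"fractions sum to {l.sum():.10f}, expected 1")
    return float((n * float(l @ l) - 1.0) / (n - 1))


def sanitize_fractions(l: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip negative Mulliken fractions to 0 and renormalize.

    Used when fractions serve as weight-network training labels, which must
    be a valid probability vector.  Returns (clean vector, number clipped);
    clipping is logged.
    """
    l = np.asarray(l, dtype=float)
    n_clipped = int(np.sum(l < 0))
    if n_clipped:
        logger.info("clipped %d negative localization fractions", n_clipped)
        l = np.clip(l, 0.0, None)
        l = l / l.sum()
    return l, n_clipped


class Strata(NamedTuple):
    """Record-index sets from L-stratification (disjoint, exhaustive)."""

    localized: list[int]
    middle: list[int]
    delocalized: list[int]


def stratify_by_L(
    dataset: LabeledDataset,
    localized_cut: float = LOCALIZED_CUT,
    delocalized_cut: float = DELOCALIZED_CUT,
) -> Strata:
    """Partition record indices into {L >= localized_cut} (inclusive),
    {L < delocalized_cut} (strict), and the middle band."""
    localized: list[int] = []
    middle: list[int] = []
    delocalized: list[int] = []
    for i, (_, ref) in enumerate(dataset):
        if ref.localization_index is None:
            raise ValidationError(f"record {i} carries no localization index")
        L = ref.localization_index
        if L >= localized_cut:
            localized.append(i)
        elif L < delocalized_cut:
            delocalized.append(i)
        else:
            middle.append(i)
    return Strata(localized, middle, delocalized)
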