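"""Per-atom chemical-environment descriptors.

The reference descriptor is a set of element-resolved radial (Gaussian)
symmetry functions with a smooth cosine cutoff: the entry of atom i for
channel (Z, k) is

    sum_{j != i, element_j = Z} exp(-eta (r_ij - mu_k)^2) * f_c(r_ij),
    f_c(r) = 0.5 * (cos(pi r / r_cut) + 1)  for r <= r_cut, else 0.

It is permutation-equivariant, rotation/translation invariant, and strictly
local: atoms beyond the cutoff contribute exactly nothing, which is the
premise that lets intensive pooling extrapolate to non-interacting
supersystems.  Angular terms are deliberately omitted -- pooling behavior
is representation-agnostic -- and external per-atom representations (SOAP,
message passing) can be plugged in through the adapter registry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import AtomicSystem, ConfigurationError, ValidationError

__all__ = [
    "DescriptorConfig",
    "DescriptorMatrix",
    "featurize",
    "locality_check",
    "register_descriptor",
    "get_descriptor",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Radial symmetry-function parameters.

    K Gaussian centers are evenly spaced on [0.5, cutoff) Angstrom; all
    share width eta = 1 / (2 * spacing^2).
    """

    element_channels: tuple[str, ...]
    cutoff_radius: float = 5.0
    n_centers: int = 16

    def __post_init__(self) -> None:
        if self.n_centers < 1:
            raise ValidationError("n_centers must be >= 1")
        if self.cutoff_radius <= 0.5:
            raise ValidationError("cutoff must exceed the first center at 0.5 A")
        channels = tuple(self.element_channels)
        if not channels or len(set(channels)) != len(channels):
            raise ValidationError("element_channels must be non-empty, deduplicated")
        object.__setattr__(self, "element_channels", channels)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.5, self.cutoff_radius, self.n_centers, endpoint=False)

    @property
    def width(self) -> float:
        spacing = (self.cutoff_radius - 0.5) / self.n_centers
        return 1.0 / (2.0 * spacing**2)

    @property
    def n_features(self) -> int:
        return self.n_centers * len(self.element_channels)

    def hash(self) -> str:
        key = f"{self.element_channels}|{self.cutoff_radius}|{self.n_centers}"
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class DescriptorMatrix:
    """N x D per-atom feature matrix with the producing config's hash."""

    values: np.ndarray
    config_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("descriptor entries must be finite and >= 0")


def cutoff_function(r: np.ndarray, r_cut: float) -> np.ndarray:
    """Smooth cosine cutoff; value and first derivative vanish at r_cut."""
    r = np.asarray(r, dtype=float)
    fc = 0.5 * (np.cos(np.pi * r / r_cut) + 1.0)
    return np.where(r <= r_cut, fc, 0.0)


def featurize(system: AtomicSystem, config: DescriptorConfig) -> DescriptorMatrix:
    """Radial symmetry functions for every atom of a system."""
    unknown = set(system.elements) - set(config.element_channels)
    if unknown:
        raise ConfigurationError(
            f"elements {sorted(unknown)} missing from descriptor channels"
        )
    n = system.n_atoms
    coords = system.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    np.fill_diagonal(r, np.inf)  # exclude self-interaction
    rr = np.where(np.isfinite(r), r, 0.0)
    fc = cutoff_function(rr, config.cutoff_radius)
    fc[~np.isfinite(r)] = 0.0
    mu = config.centers
    eta = config.width
    gauss = np.exp(-eta * (rr[:, :, None] - mu[None, None, :]) ** 2)
    pair = gauss * fc[:, :, None]
    elements = np.array(system.elements)
    out = np.zeros((n, config.n_features))
    for zi, z in enumerate(config.element_channels):
        mask = (elements == z).astype(float)
        out[:, zi * config.n_centers:(zi + 1) * config.n_centers] = np.einsum(
            "ijk,j->ik", pair, mask
        )
    return DescriptorMatrix(values=out, config_hash=config.hash())


def locality_check(system: AtomicSystem, config: DescriptorConfig,
                   tol: float = 1e-10) -> bool:
    """True iff every atom's descriptor row equals its isolated-fragment row.

    Holds exactly when all cross-fragment distances are at or beyond the
    cutoff radius.
    """
    labels = system.fragments()
    if len(set(labels.tolist())) < 2:
        raise ValidationError("locality check needs >= 2 fragments")
    full = featurize(system, config).values
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        sub = AtomicSystem(
            elements=[system.elements[i] for i in idx],
            coordinates=system.coordinates[idx],
        )
        iso = featurize(sub, config).values
        if np.max(np.abs(full[idx] - iso)) > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# adapter registry: any callable with featurize's signature returning a
# permutation-equivariant N x D matrix may be registered by name.

_REGISTRY: dict[str, Callable[[AtomicSystem, DescriptorConfig], DescriptorMatrix]] = {
    "radial": featurize,
}


def register_descriptor(
    name: str, fn: Callable[[AtomicSystem, DescriptorConfig], DescriptorMatrix]
) -> None:
    _REGISTRY[name] = fn


def get_descriptor(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"no descriptor registered under {name!r}") from None
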