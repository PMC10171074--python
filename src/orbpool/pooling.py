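"""Permutation-invariant pooling functions for atomistic networks.

A pooling function maps per-atom scalar outputs (eps_1, ..., eps_N) -- and,
for weighted variants, a per-atom weight simplex -- to one molecular
scalar.  Sum pooling is size-extensive (it scales linearly under trivial
replication of a system); every other head here is size-intensive (the
prediction is unchanged when non-interacting copies are concatenated),
which is the correct behavior for orbital and ionization energies.

Heads:

=========  ==================================================================
sum        sum_i eps_i (extensive baseline)
avg        mean of eps
max        max (mode="max", HOMO) or min (mode="min", IE/LUMO) of eps
softmax    Boltzmann-weighted mean, weights softmax(s * eps / T), s = +/-1
wa / owa   weighted average with an externally supplied weight simplex
           (learned by a second network; OWA additionally supervises the
           weights with orbital localization fractions)
coeff      weighted average with exact localization fractions l_i as weights
=========  ==================================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ContractError, ValidationError

__all__ = [
    "HEAD_NAMES",
    "PoolingHead",
    "pool_sum",
    "pool_avg",
    "pool_max",
    "pool_softmax",
    "pool_weighted_average",
    "softmax_weights",
]

HEAD_NAMES = ("sum", "avg", "max", "softmax", "wa", "owa", "coeff")

#: heads whose weight vector is produced by a second (weight) network
WEIGHT_NET_HEADS = ("wa", "owa")


def _check_eps(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 1 or eps.size == 0:
        raise ContractError("eps must be a non-empty 1-D vector")
    if not np.all(np.isfinite(eps)):
        raise ContractError("eps must be finite")
    return eps


def _sign(mode: str) -> float:
    if mode == "max":
        return 1.0
    if mode == "min":
        return -1.0
    raise ValidationError(f"mode must be 'max' or 'min', got {mode!r}")


def pool_sum(eps: np.ndarray) -> float:
    return float(np.sum(_check_eps(eps)))


def pool_avg(eps: np.ndarray) -> float:
    return float(np.mean(_check_eps(eps)))


def pool_max(eps: np.ndarray, mode: str = "max") -> float:
    eps = _check_eps(eps)
    return float(np.max(eps) if _sign(mode) > 0 else np.min(eps))


def softmax_weights(
    eps: np.ndarray, mode: str = "max", temperature: float = 1.0
) -> np.ndarray:
    """Softmax weights exp(s*eps/T) / sum exp(s*eps/T), overflow-safe.

    The inverse temperature defaults to one per eV; the sign s is +1 for
    mode="max" and -1 for mode="min".
    """
    eps = _check_eps(eps)
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    z = _sign(mode) * eps / temperature
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def pool_softmax(
    eps: np.ndarray, mode: str = "max", temperature: float = 1.0
) -> float:
    eps = _check_eps(eps)
    return float(softmax_weights(eps, mode, temperature) @ eps)


def _check_simplex(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError(f"weights shape {w.shape} != ({n},)")
    if np.any(w < -1e-10):
        raise ValidationError("weights must be >= 0")
    if abs(float(w.sum()) - 1.0) > 1e-8:
        raise ValidationError(f"weights sum to {w.sum():.10f}, expected 1")
    return w


def pool_weighted_average(eps: np.ndarray, weights: np.ndarray) -> float:
    """General weighted average sum_i w_i eps_i over a weight simplex.

    Serves WA and OWA (learned weights) as well as coefficient pooling
    (weights = exact localization fractions).
    """
    eps = _check_eps(eps)
    w = _check_simplex(weights, eps.size)
    return float(w @ eps)


@dataclass(frozen=True)
class PoolingHead:
    """A named aggregation rule with a fixed max/min mode.

    wa/owa require an external ``weights`` vector at call time; coeff
    requires reference localization ``fractions``.
    """

    name: str
    mode: str = "max"
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in HEAD_NAMES:
            raise ValidationError(f"unknown pooling head {self.name!r}")
        _sign(self.mode)  # validates mode
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")

    @property
    def softmax_sign(self) -> float:
        return _sign(self.mode)

    @property
    def is_intensive(self) -> bool:
        return self.name != "sum"

    @property
    def uses_weight_net(self) -> bool:
        return self.name in WEIGHT_NET_HEADS

    def __call__(
        self,
        eps: np.ndarray,
        weights: np.ndarray | None = None,
        fractions: np.ndarray | None = None,
    ) -> float:
        if self.name == "sum":
            return pool_sum(eps)
        if self.name == "avg":
            return pool_avg(eps)
        if self.name == "max":
            return pool_max(eps, self.mode)
        if self.name == "softmax":
            return pool_softmax(eps, self.mode, self.temperature)
        if self.name in WEIGHT_NET_HEADS:
            if weights is None:
                raise ContractError(f"{self.name} pooling needs a weight vector")
            return pool_weighted_average(eps, weights)
        # coeff
        if fractions is None:
            raise ContractError("coeff pooling needs reference fractions")
        return pool_weighted_average(eps, fractions)
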