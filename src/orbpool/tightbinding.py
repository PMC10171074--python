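"""Synthetic-data engine: orthogonal tight-binding (Hueckel-like) molecules.

Exact one-electron reference data for benchmarking pooling functions is
generated by building chain molecules as orthogonal tight-binding
Hamiltonians and diagonalizing them exactly:

* on-site energies ``alpha`` per site symbol (eV) on the diagonal,
* distance-decaying hoppings ``t0 * exp(-lambda * (r - r0))`` between
  atoms closer than twice the reference bond length that share a fragment
  label (atoms in different fragments never couple, so non-interaction is
  exact in the Hamiltonian).

Molecules are zig-zag backbones of 2-8 sites decorated with one or two
single-site substituent fragments drawn from a fixed 41-entry on-site
table spanning [-9, -3] eV.  Saturated backbones alternate two on-site
energies, opening a gap at half filling; a substituent level falling
inside that gap produces a HOMO sharply localized on the substituent,
while conjugated (uniform) backbones give delocalized band-like HOMOs.
Together these span the localization index from near 0 to near 1.

The HOMO is the highest occupied orbital at half filling (floor(N/2)
occupied, minimum one).  Localization fractions come from the exact
eigenvector; for an orthogonal basis l_i is the squared coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomicSystem,
    ConfigurationError,
    ContractError,
    ElectronicReference,
    LabeledDataset,
    Record,
    ValidationError,
)
from .localization import OrbitalVector, localization_fraction, localization_index

__all__ = [
    "TBParams",
    "GeneratorConfig",
    "SubstituentTemplate",
    "default_onsite_table",
    "default_substituent_library",
    "build_hamiltonian",
    "solve_orbitals",
    "generate_dataset",
    "compose_noninteracting",
    "toy_monomer_fixtures",
]

logger = logging.getLogger(__name__)

N_SUBSTITUENTS = 41


def default_onsite_table() -> dict[str, float]:
    """On-site energies (eV): conjugated backbone 'C', saturated backbone
    alternating 'Cs1'/'Cs2' (gap-opening), substituents R01..R41 spanning
    [-9, -3] eV."""
    table = {"C": -6.0, "Cs1": -8.0, "Cs2": -4.0}
    for k, alpha in enumerate(np.linspace(-9.0, -3.0, N_SUBSTITUENTS), start=1):
        table[f"R{k:02d}"] = float(alpha)
    return table


@dataclass(frozen=True)
class TBParams:
    """Tight-binding model parameters.

    hopping_scale t0 < 0 (eV) at the reference bond length r0; hoppings
    decay as exp(-hopping_decay * (r - r0)) and are cut off at 2 * r0.
    """

    onsite_table: dict[str, float] = field(default_factory=default_onsite_table)
    hopping_scale: float = -2.5
    hopping_decay: float = 1.8
    reference_bond: float = 1.45
    electron_filling: str = "half"
    degeneracy_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.hopping_scale >= 0:
            raise ValidationError("hopping_scale t0 must be negative")
        if self.hopping_decay <= 0 or self.reference_bond <= 0:
            raise ValidationError("hopping_decay and reference_bond must be > 0")
        if self.electron_filling != "half":
            raise ValidationError("only half filling is supported")

    @property
    def bond_cutoff(self) -> float:
        return 2.0 * self.reference_bond


@dataclass(frozen=True)
class SubstituentTemplate:
    """A fragment template: site symbols plus offsets from the backbone site."""

    symbols: tuple[str, ...]
    offsets: tuple[tuple[float, float, float], ...]


def default_substituent_library(r0: float) -> tuple[SubstituentTemplate, ...]:
    """41 single-site substituents placed 1.7*r0 above their backbone site.

    The long attachment bond keeps the coupling to the backbone weak, so
    in-gap substituent levels stay sharply localized.
    """
    z = 1.7 * r0
    return tuple(
        SubstituentTemplate(symbols=(f"R{k:02d}",), offsets=((0.0, 0.0, z),))
        for k in range(1, N_SUBSTITUENTS + 1)
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset-generation settings.

    Backbone lengths span 2-8 sites; ``backbone_kind`` is 'saturated',
    'conjugated', or 'mixed' (random per molecule).  Substitution sites are
    separated by at least ``min_site_separation`` backbone positions.
    """

    backbone_lengths: tuple[int, int] = (2, 8)
    backbone_kind: str = "mixed"
    substituent_library: tuple[SubstituentTemplate, ...] | None = None
    min_site_separation: int = 3
    geometry_noise_sigma: float = 0.05
    seed: int = 0
    n_molecules: int = 100
    mode: str = "max"

    def __post_init__(self) -> None:
        lo, hi = self.backbone_lengths
        if lo < 2 or hi < lo:
            raise ValidationError("backbone_lengths must satisfy 2 <= lo <= hi")
        if self.backbone_kind not in ("saturated", "conjugated", "mixed"):
            raise ValidationError(f"unknown backbone_kind {self.backbone_kind!r}")
        if self.min_site_separation < 1:
            raise ValidationError("min_site_separation must be >= 1")
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")


def build_hamiltonian(system: AtomicSystem, params: TBParams) -> np.ndarray:
    """Symmetric tight-binding Hamiltonian (eV) of a system.

    Atoms couple when closer than the bond cutoff *and* sharing a fragment
    label; the coupling is t0 * exp(-lambda * (r - r0)).
    """
    try:
        onsite = np.array([params.onsite_table[e] for e in system.elements])
    except KeyError as exc:
        raise ConfigurationError(f"no on-site energy for symbol {exc.args[0]!r}") from exc
    coords = system.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    labels = system.fragments()
    same_frag = labels[:, None] == labels[None, :]
    bonded = (r <= params.bond_cutoff) & same_frag
    np.fill_diagonal(bonded, False)
    H = np.where(
        bonded,
        params.hopping_scale * np.exp(-params.hopping_decay * (r - params.reference_bond)),
        0.0,
    )
    np.fill_diagonal(H, onsite)
    return 0.5 * (H + H.T)


def solve_orbitals(
    H: np.ndarray, params: TBParams, mode: str = "max"
) -> tuple[ElectronicReference, np.ndarray]:
    """Exact eigendecomposition; returns the HOMO reference and eigenvectors.

    Occupation is half filling: floor(N/2) orbitals occupied, minimum one.
    The target energy is the HOMO eigenvalue.  If the HOMO is degenerate
    within ``degeneracy_tol`` the localization fractions are averaged over
    the degenerate subspace and the degeneracy flag is set.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValidationError("Hamiltonian must be square")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValidationError("Hamiltonian must be symmetric")
    if not np.all(np.isfinite(H)):
        raise ValidationError("Hamiltonian must be finite")
    n = H.shape[0]
    w, v = np.linalg.eigh(H)
    nocc = max(1, n // 2)
    e_homo = float(w[nocc - 1])
    degenerate_idx = np.where(np.abs(w - e_homo) < params.degeneracy_tol)[0]
    basis_to_atom = np.arange(n)
    fractions = np.zeros(n)
    for j in degenerate_idx:
        orb = OrbitalVector(coefficients=v[:, j], basis_to_atom=basis_to_atom)
        fractions += localization_fraction(orb)
    fractions /= len(degenerate_idx)
    L = localization_index(fractions) if n >= 2 else None
    ref = ElectronicReference(
        target_energy=e_homo,
        mode=mode,
        localization_fractions=fractions,
        localization_index=L,
        degenerate=len(degenerate_idx) > 1,
    )
    return ref, v


def _zigzag(n: int, r0: float) -> np.ndarray:
    """Planar zig-zag chain with uniform bond length r0 (120-degree angles)."""
    i = np.arange(n)
    coords = np.zeros((n, 3))
    coords[:, 0] = i * r0 * np.cos(np.pi / 6)
    coords[:, 1] = (i % 2) * r0 * np.sin(np.pi / 6)
    return coords


def _backbone_elements(kind: str, n: int) -> list[str]:
    if kind == "conjugated":
        return ["C"] * n
    return ["Cs1" if i % 2 == 0 else "Cs2" for i in range(n)]


def generate_dataset(config: GeneratorConfig, params: TBParams | None = None) -> LabeledDataset:
    """Generate a labeled synthetic dataset, deterministic for a fixed seed.

    Each record carries the exact HOMO energy, localization fractions and
    localization index from direct diagonalization of the constructed
    Hamiltonian.
    """
    params = params or TBParams()
    rng = np.random.default_rng(config.seed)
    library = config.substituent_library or default_substituent_library(
        params.reference_bond
    )
    lo, hi = config.backbone_lengths
    records: list[Record] = []
    for imol in range(config.n_molecules):
        n_bb = int(rng.integers(lo, hi + 1))
        kind = config.backbone_kind
        if kind == "mixed":
            kind = "saturated" if rng.random() < 0.5 else "conjugated"
        elements = _backbone_elements(kind, n_bb)
        coords = _zigzag(n_bb, params.reference_bond)
        # substituent placement: one or two sites, min separation enforced
        n_subs = int(rng.integers(1, 3))
        sites = [int(rng.integers(0, n_bb))]
        if n_subs == 2:
            candidates = [
                s for s in range(n_bb) if abs(s - sites[0]) >= config.min_site_separation
            ]
            if candidates:
                sites.append(int(rng.choice(candidates)))
            else:
                logger.warning(
                    "molecule %d: no site >= %d positions from site %d; "
                    "placing a single substituent",
                    imol, config.min_site_separation, sites[0],
                )
        parts = [coords]
        for s in sites:
            template = library[int(rng.integers(0, len(library)))]
            elements.extend(template.symbols)
            parts.append(coords[s] + np.asarray(template.offsets, dtype=float))
        coords = np.vstack(parts)
        if config.geometry_noise_sigma > 0:
            coords = coords + rng.normal(0.0, config.geometry_noise_sigma, coords.shape)
        system = AtomicSystem(
            elements=elements, coordinates=coords, system_id=f"tb-{imol:05d}"
        )
        H = build_hamiltonian(system, params)
        ref, _ = solve_orbitals(H, params, mode=config.mode)
        records.append((system, ref))
    return LabeledDataset(
        records=records,
        provenance=f"tightbinding(seed={config.seed}, n={config.n_molecules})",
    )


def compose_noninteracting(
    parts: list[Record],
    separation: float,
    descriptor_cutoff: float | None = None,
) -> Record:
    """Concatenate systems into a non-interacting supersystem along +x.

    Fragments are translated so consecutive bounding boxes are
    ``separation`` Angstrom apart and receive distinct fragment labels.
    The supersystem target is the max (mode="max") or min (mode="min") of
    the fragment targets; localization fractions are the winning
    fragment's fractions on its atoms and exactly zero elsewhere (ties
    within 1e-9 eV are averaged across tied fragments).  A fragment
    without stored fractions contributes a uniform distribution over its
    atoms.
    """
    if not parts:
        raise ContractError("need at least one system to compose")
    if descriptor_cutoff is not None and separation <= 2.0 * descriptor_cutoff:
        raise ContractError(
            f"separation {separation} must exceed twice the descriptor "
            f"cutoff ({2 * descriptor_cutoff})"
        )
    if separation <= 0:
        raise ContractError("separation must be positive")
    modes = {ref.mode for _, ref in parts}
    if len(modes) > 1:
        raise ValidationError(f"fragments mix modes {sorted(modes)}")
    mode = parts[0][1].mode

    elements: list[str] = []
    coords_list: list[np.ndarray] = []
    labels: list[int] = []
    x_edge = 0.0
    for k, (system, _) in enumerate(parts):
        c = system.coordinates.copy()
        shift = (x_edge - c[:, 0].min()) if k > 0 else 0.0
        c[:, 0] += shift
        x_edge = c[:, 0].max() + separation
        elements.extend(system.elements)
        coords_list.append(c)
        labels.extend([k] * system.n_atoms)
    coords = np.vstack(coords_list)

    targets = np.array([ref.target_energy for _, ref in parts])
    best = targets.max() if mode == "max" else targets.min()
    winners = np.where(np.abs(targets - best) <= 1e-9)[0]

    n_total = len(elements)
    fractions = np.zeros(n_total)
    offsets = np.cumsum([0] + [s.n_atoms for s, _ in parts])
    for k in winners:
        system, ref = parts[k]
        frag_l = ref.localization_fractions
        if frag_l is None:
            frag_l = np.full(system.n_atoms, 1.0 / system.n_atoms)
        fractions[offsets[k]:offsets[k + 1]] = frag_l / len(winners)

    super_system = AtomicSystem(
        elements=elements,
        coordinates=coords,
        system_id="+".join(s.system_id or f"frag{k}" for k, (s, _) in enumerate(parts)),
        fragment_labels=np.array(labels),
    )
    super_ref = ElectronicReference(
        target_energy=float(best),
        mode=mode,
        localization_fractions=fractions,
        localization_index=localization_index(fractions) if n_total >= 2 else None,
    )
    return super_system, super_ref


def toy_monomer_fixtures() -> LabeledDataset:
    """Water and CO2 monomers with experimental ionization energies.

    Targets (mode="min"): water 12.6 eV, CO2 13.8 eV.  Standard geometries
    (r_OH = 0.96 A, HOH angle 104.5 deg; linear CO2 with r_CO = 1.16 A).
    Monomer localization fractions are uniform: the ionization of an
    isolated molecule belongs to the whole molecule.
    """
    theta = np.deg2rad(104.5 / 2.0)
    r_oh, r_co = 0.96, 1.16
    water = AtomicSystem(
        elements=["O", "H", "H"],
        coordinates=np.array(
            [
                [0.0, 0.0, 0.0],
                [r_oh * np.sin(theta), r_oh * np.cos(theta), 0.0],
                [-r_oh * np.sin(theta), r_oh * np.cos(theta), 0.0],
            ]
        ),
        system_id="water",
    )
    co2 = AtomicSystem(
        elements=["C", "O", "O"],
        coordinates=np.array(
            [[0.0, 0.0, 0.0], [r_co, 0.0, 0.0], [-r_co, 0.0, 0.0]]
        ),
        system_id="co2",
    )
    records: list[Record] = []
    for system, ie in ((water, 12.6), (co2, 13.8)):
        l = np.full(system.n_atoms, 1.0 / system.n_atoms)
        records.append(
            (
                system,
                ElectronicReference(
                    target_energy=ie,
                    mode="min",
                    localization_fractions=l,
                    localization_index=localization_index(l),
                ),
            )
        )
    return LabeledDataset(records=records, provenance="toy monomer fixtures")
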