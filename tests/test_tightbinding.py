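"""Tight-binding generator: Hamiltonians, spectra, composition, fixtures."""

import numpy as np
import pytest

from orbpool.core import (
    AtomicSystem,
    ConfigurationError,
    ContractError,
    ValidationError,
)
from orbpool.localization import localization_index
from orbpool.tightbinding import (
    GeneratorConfig,
    TBParams,
    build_hamiltonian,
    compose_noninteracting,
    default_onsite_table,
    generate_dataset,
    solve_orbitals,
    toy_monomer_fixtures,
)


def charpoly_roots(A):
    """Independent eigenvalue oracle: Faddeev-LeVerrier characteristic
    polynomial coefficients followed by companion-matrix root finding."""
    n = A.shape[0]
    I = np.eye(n)
    M = np.zeros_like(A)
    coeffs = [1.0]
    c = 1.0
    for k in range(1, n + 1):
        M = A @ (M + c * I)
        c = -np.trace(M) / k
        coeffs.append(c)
    return np.sort(np.roots(coeffs).real)


class TestBuildHamiltonian:
    def test_single_atom(self):
        params = TBParams(onsite_table={"X": -6.0})
        system = AtomicSystem(["X"], np.zeros((1, 3)))
        np.testing.assert_allclose(build_hamiltonian(system, params), [[-6.0]])

    def test_dimer_at_reference_bond(self):
        params = TBParams(onsite_table={"X": -6.0}, hopping_scale=-1.0)
        r0 = params.reference_bond
        system = AtomicSystem(["X", "X"], np.array([[0, 0, 0], [r0, 0, 0]]))
        H = build_hamiltonian(system, params)
        np.testing.assert_allclose(H, [[-6.0, -1.0], [-1.0, -6.0]], atol=1e-14)

    def test_different_fragments_never_couple(self):
        params = TBParams(onsite_table={"X": -6.0})
        system = AtomicSystem(
            ["X", "X"],
            np.array([[0, 0, 0], [0.8, 0, 0]]),
            fragment_labels=[0, 1],
        )
        H = build_hamiltonian(system, params)
        assert H[0, 1] == 0.0 and H[1, 0] == 0.0

    def test_unknown_symbol(self):
        with pytest.raises(ConfigurationError):
            build_hamiltonian(
                AtomicSystem(["Zz"], np.zeros((1, 3))), TBParams()
            )


class TestSolveOrbitals:
    def test_two_site_closed_form(self, tb_params):
        H = np.array([[-6.0, -1.0], [-1.0, -6.0]])
        ref, v = solve_orbitals(H, tb_params)
        # eigenvalues alpha -+ |t|; one occupied orbital -> HOMO = -7
        assert ref.target_energy == pytest.approx(-7.0, abs=1e-12)
        np.testing.assert_allclose(ref.localization_fractions, [0.5, 0.5], atol=1e-12)
        w = np.sort(np.linalg.eigvalsh(H))
        np.testing.assert_allclose(w, [-7.0, -5.0], atol=1e-12)

    def test_block_diagonal_spectrum_is_union(self, rng, tb_params):
        A = rng.normal(0, 1, (3, 3))
        A = 0.5 * (A + A.T)
        B = rng.normal(0, 1, (4, 4))
        B = 0.5 * (B + B.T)
        H = np.block([[A, np.zeros((3, 4))], [np.zeros((4, 3)), B]])
        w = np.sort(np.linalg.eigvalsh(H))
        union = np.sort(np.concatenate([np.linalg.eigvalsh(A), np.linalg.eigvalsh(B)]))
        np.testing.assert_allclose(w, union, atol=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_eigenvalues_match_charpoly_oracle(self, trial, tb_params):
        rng = np.random.default_rng(900 + trial)
        n = int(rng.integers(2, 9))
        A = rng.normal(-2, 2, (n, n))
        H = 0.5 * (A + A.T)
        _, v = solve_orbitals(H, tb_params)
        w = np.sort(np.linalg.eigvalsh(H))
        np.testing.assert_allclose(w, charpoly_roots(H), atol=1e-8)
        # orthonormal eigenvectors
        assert np.max(np.abs(v.T @ v - np.eye(n))) <= 1e-8

    def test_non_symmetric_rejected(self, tb_params):
        with pytest.raises(ValidationError):
            solve_orbitals(np.array([[0.0, 1.0], [0.0, 0.0]]), tb_params)

    def test_degenerate_homo_averages_fractions(self, tb_params):
        # two uncoupled identical dimers -> doubly degenerate HOMO
        H = np.kron(np.eye(2), np.array([[-6.0, -1.0], [-1.0, -6.0]]))
        ref, _ = solve_orbitals(H, tb_params)
        assert ref.degenerate
        np.testing.assert_allclose(ref.localization_fractions, np.full(4, 0.25),
                                   atol=1e-10)


class TestGenerator:
    def test_deterministic_given_seed(self, tb_params):
        cfg = GeneratorConfig(n_molecules=20, seed=5)
        a = generate_dataset(cfg, tb_params)
        b = generate_dataset(cfg, tb_params)
        for (sa, ra), (sb, rb) in zip(a, b):
            assert sa.elements == sb.elements
            np.testing.assert_array_equal(sa.coordinates, sb.coordinates)
            assert ra.target_energy == rb.target_energy

    def test_fraction_sums_and_L_range(self, small_dataset):
        for _, ref in small_dataset:
            assert abs(ref.localization_fractions.sum() - 1.0) <= 1e-10
            assert -1e-9 <= ref.localization_index <= 1 + 1e-9

    def test_L_distribution_spans_both_regimes(self, small_dataset):
        L = np.array([ref.localization_index for _, ref in small_dataset])
        assert np.mean(L >= 0.8) >= 0.05
        assert np.mean(L < 0.4) >= 0.20

    def test_in_gap_substituent_localizes_homo(self, tb_params):
        """Substituent levels above the mean backbone on-site energy and
        inside the saturated-backbone gap yield a HOMO on the deeper of the
        two substituents with L >= 0.8 (two substituents on an even backbone
        keep the gap state occupied at half filling); verified by direct
        diagonalization of the constructed Hamiltonian."""
        r0 = tb_params.reference_bond
        n_bb = 6
        i = np.arange(n_bb)
        coords = np.zeros((n_bb + 2, 3))
        coords[:n_bb, 0] = i * r0 * np.cos(np.pi / 6)
        coords[:n_bb, 1] = (i % 2) * r0 * np.sin(np.pi / 6)
        coords[n_bb] = coords[0] + [0, 0, 1.7 * r0]
        coords[n_bb + 1] = coords[4] + [0, 0, 1.7 * r0]
        elements = ["Cs1" if k % 2 == 0 else "Cs2" for k in range(n_bb)]
        elements += ["R22", "R30"]  # on-sites -5.85 / -4.65 eV, inside the gap
        system = AtomicSystem(elements, coords)
        H = build_hamiltonian(system, tb_params)
        ref, _ = solve_orbitals(H, tb_params)
        assert ref.localization_fractions[n_bb] >= 0.8
        assert ref.localization_index >= 0.8

    def test_uniform_conjugated_chain_is_delocalized(self, tb_params):
        cfg = GeneratorConfig(n_molecules=1, seed=0)
        r0 = tb_params.reference_bond
        n = 8
        i = np.arange(n)
        coords = np.zeros((n, 3))
        coords[:, 0] = i * r0 * np.cos(np.pi / 6)
        coords[:, 1] = (i % 2) * r0 * np.sin(np.pi / 6)
        system = AtomicSystem(["C"] * n, coords)
        ref, _ = solve_orbitals(build_hamiltonian(system, tb_params), tb_params)
        assert ref.localization_index < 0.4

    def test_onsite_table_spans_advertised_range(self):
        table = default_onsite_table()
        subs = [v for k, v in table.items() if k.startswith("R")]
        assert len(subs) == 41
        assert min(subs) == -9.0 and max(subs) == -3.0


class TestCompose:
    def test_two_identical_waters_keep_the_ie(self):
        fixtures = toy_monomer_fixtures()
        water = fixtures.records[0]
        sup, ref = compose_noninteracting([water, water], separation=12.0)
        assert ref.target_energy == pytest.approx(12.6)
        # tie between identical fragments: fractions split evenly
        np.testing.assert_allclose(ref.localization_fractions.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            ref.localization_fractions[:3], ref.localization_fractions[3:], atol=1e-12
        )

    def test_water_co2_localizes_on_water(self):
        fixtures = toy_monomer_fixtures()
        water, co2 = fixtures.records
        sup, ref = compose_noninteracting([water, co2], separation=12.0)
        assert ref.target_energy == pytest.approx(12.6)
        assert np.all(ref.localization_fractions[3:] == 0.0)
        assert ref.localization_fractions[:3].sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(sup.fragment_labels, [0, 0, 0, 1, 1, 1])

    def test_k_copies_scale_fractions_by_k(self, small_dataset):
        system, ref = small_dataset[0]
        k = 3
        sup, sref = compose_noninteracting([(system, ref)] * k, separation=15.0)
        assert sref.target_energy == pytest.approx(ref.target_energy, abs=1e-12)
        n = system.n_atoms
        for j in range(k):
            np.testing.assert_allclose(
                sref.localization_fractions[j * n:(j + 1) * n],
                ref.localization_fractions / k,
                atol=1e-12,
            )

    def test_spectrum_of_composed_system_is_union(self, small_dataset, tb_params):
        (s1, r1), (s2, r2) = small_dataset[0], small_dataset[1]
        sup, _ = compose_noninteracting([(s1, r1), (s2, r2)], separation=15.0)
        H = build_hamiltonian(sup, tb_params)
        w = np.sort(np.linalg.eigvalsh(H))
        w1 = np.linalg.eigvalsh(build_hamiltonian(s1, tb_params))
        w2 = np.linalg.eigvalsh(build_hamiltonian(s2, tb_params))
        np.testing.assert_allclose(w, np.sort(np.concatenate([w1, w2])), atol=1e-10)

    def test_separation_contract(self):
        fixtures = toy_monomer_fixtures()
        with pytest.raises(ContractError):
            compose_noninteracting(fixtures.records, separation=6.0,
                                   descriptor_cutoff=5.0)

    def test_mixed_modes_rejected(self):
        fixtures = toy_monomer_fixtures()
        water, co2 = fixtures.records
        bad_ref = type(co2[1])(co2[1].target_energy, mode="max")
        with pytest.raises(ValidationError):
            compose_noninteracting([water, (co2[0], bad_ref)], separation=12.0)


def test_toy_fixture_targets_and_geometry():
    ds = toy_monomer_fixtures()
    (water, wref), (co2, cref) = ds.records
    assert wref.target_energy == 12.6
    assert cref.target_energy == 13.8
    assert ds.mode == "min"
    d_oh = np.linalg.norm(water.coordinates[1] - water.coordinates[0])
    assert d_oh == pytest.approx(0.96, abs=1e-12)
    d_co = np.linalg.norm(co2.coordinates[1] - co2.coordinates[0])
    assert d_co == pytest.approx(1.16, abs=1e-12)
    # linear CO2
    assert np.linalg.norm(co2.coordinates[1] + co2.coordinates[2]) < 1e-12
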