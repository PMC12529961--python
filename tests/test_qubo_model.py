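import itertools

import numpy as np
import pytest

from conftest import (
    all_bitstrings,
    box_grid,
    enumerate_valid_configs,
    line_grid,
    toy_model,
    zero_field,
)
from qubind.decode_refine import chain_physical_energy, decode
from qubind.pocket_lattice import ExternalField
from qubind.qubo_model import (
    QuboModel,
    QuboParams,
    RegistryMismatch,
    VariableRegistry,
    admissible_length_bounds,
    ancilla_term,
    assemble,
    chain_length_term,
    external_term,
    intrachain_term,
    occupancy_term,
    path_term,
    soft_coefficient_mass,
    to_ising,
    variable_count,
    w_from_tolerance,
)
from qubind.solvers import brute_force


def single_site_registry(D=1):
    return VariableRegistry(n_sites=1, n_families=D, edges=())


class TestExternalTerm:
    def test_zero_field_empty(self):
        reg = single_site_registry()
        fld = ExternalField(E=np.zeros((1, 1)), E0=np.zeros(1), Nc=0.0)
        m = external_term(fld, reg)
        assert not m.linear and not m.quadratic and m.offset == 0.0

    def test_offset_subtraction(self):
        reg = single_site_registry()
        fld = ExternalField(E=np.array([[-2.0]]), E0=np.array([-0.5]), Nc=1.0)
        m = external_term(fld, reg)
        assert m.linear[reg.site_var(0, 0)] == pytest.approx(-1.5)

    def test_ablate_E0(self):
        reg = single_site_registry()
        fld = ExternalField(E=np.array([[-2.0]]), E0=np.array([-0.5]), Nc=1.0)
        m = external_term(fld, reg, ablate_E0=True)
        assert m.linear[reg.site_var(0, 0)] == pytest.approx(-2.0)

    def test_shape_mismatch_rejected(self):
        reg = single_site_registry()
        fld = ExternalField(E=np.zeros((2, 1)), E0=np.zeros(1), Nc=0.0)
        with pytest.raises(RegistryMismatch):
            external_term(fld, reg)


class TestIntrachainTerm:
    def test_beyond_cutoff_no_terms(self):
        sites = np.array([[0.0, 0.0, 0.0], [9.0, 0.0, 0.0]])
        from qubind.pocket_lattice import PocketGrid

        grid = PocketGrid.from_points(sites)
        model = toy_model(D=1)
        reg = VariableRegistry.from_grid(grid, 1)
        m = intrachain_term(grid, model, reg)
        assert not m.quadratic

    def test_nonneighbor_pair_single_coefficient(self):
        from qubind.energy_model import pair_potential
        from qubind.pocket_lattice import PocketGrid

        r = 2 * 3.8  # two lattice units apart: no edge, inside cutoff
        sites = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
        grid = PocketGrid.from_points(sites)
        model = toy_model(D=2, eps=np.array([[-1.0, -0.3], [-0.3, 0.5]]))
        reg = VariableRegistry.from_grid(grid, 2)
        m = intrachain_term(grid, model, reg)
        for k in range(2):
            for l in range(2):
                key = tuple(sorted((reg.site_var(0, k), reg.site_var(1, l))))
                assert m.quadratic[key] == pytest.approx(
                    pair_potential(k, l, r, model.params())
                )

    def test_bonded_assignment_cancels(self):
        grid = line_grid(2)
        model = toy_model(D=1)
        reg = VariableRegistry.from_grid(grid, 1)
        m = intrachain_term(grid, model, reg)
        bits = np.zeros(reg.n_variables)
        bits[reg.site_var(0, 0)] = 1
        bits[reg.site_var(1, 0)] = 1
        bits[reg.bond_var(0, 1)] = 1
        bits[reg.anc_var(0, 1, 0)] = 1
        assert m.energy(bits) == pytest.approx(0.0, abs=1e-12)


class TestAncillaTerm:
    @pytest.mark.parametrize("A", [1.0, 10.0])
    def test_truth_table(self, A):
        grid = line_grid(2)
        reg = VariableRegistry.from_grid(grid, 1)
        m = ancilla_term(reg, A)
        for qs, qb, qa in itertools.product((0, 1), repeat=3):
            bits = np.zeros(reg.n_variables)
            bits[reg.site_var(0, 0)] = qs
            bits[reg.bond_var(0, 1)] = qb
            bits[reg.anc_var(0, 1, 0)] = qa
            e = m.energy(bits)
            if qa == qs * qb:
                assert e == pytest.approx(0.0, abs=1e-12)
            else:
                assert e >= A - 1e-12

    def test_specific_penalties(self):
        grid = line_grid(2)
        reg = VariableRegistry.from_grid(grid, 1)
        m = ancilla_term(reg, 1.0)
        bits = np.zeros(reg.n_variables)
        bits[reg.anc_var(0, 1, 0)] = 1  # ancilla on, inputs off
        assert m.energy(bits) == pytest.approx(3.0)
        bits[reg.site_var(0, 0)] = 1
        bits[reg.bond_var(0, 1)] = 1  # fully consistent
        assert m.energy(bits) == pytest.approx(0.0)


class TestOccupancyTerm:
    def test_single_family_per_site_free(self):
        grid = line_grid(3)
        reg = VariableRegistry.from_grid(grid, 3)
        m = occupancy_term(reg, 5.0)
        bits = np.zeros(reg.n_variables)
        for i, k in [(0, 0), (1, 2), (2, 1)]:
            bits[reg.site_var(i, k)] = 1
        assert m.energy(bits) == 0.0

    def test_double_occupancy_costs_A(self):
        grid = line_grid(2)
        reg = VariableRegistry.from_grid(grid, 3)
        m = occupancy_term(reg, 5.0)
        bits = np.zeros(reg.n_variables)
        bits[reg.site_var(0, 0)] = 1
        bits[reg.site_var(0, 2)] = 1
        assert m.energy(bits) == pytest.approx(5.0)

    def test_triple_occupancy_costs_3A(self):
        grid = line_grid(2)
        reg = VariableRegistry.from_grid(grid, 3)
        m = occupancy_term(reg, 5.0)
        bits = np.zeros(reg.n_variables)
        for k in range(3):
            bits[reg.site_var(0, k)] = 1
        assert m.energy(bits) == pytest.approx(15.0)  # C(3,2) pairs


class TestPathTerm:
    def test_empty_configuration(self):
        grid = line_grid(3)
        reg = VariableRegistry.from_grid(grid, 1)
        m = path_term(reg, 0, 2, A=7.0)
        assert m.energy(np.zeros(reg.n_variables)) == pytest.approx(14.0)

    def test_full_path_zero_penalty(self):
        grid = line_grid(3)
        reg = VariableRegistry.from_grid(grid, 1)
        m = path_term(reg, 0, 2, A=7.0)
        bits = np.zeros(reg.n_variables)
        for i in range(3):
            bits[reg.site_var(i, 0)] = 1
        bits[reg.bond_var(0, 1)] = 1
        bits[reg.bond_var(1, 2)] = 1
        assert m.energy(bits) == pytest.approx(0.0, abs=1e-12)

    def test_zero_penalty_set_is_exactly_valid_paths(self):
        """Exhaustive: path+occupancy+ancilla zero set == valid chains."""
        grid = line_grid(3)
        reg = VariableRegistry.from_grid(grid, 1)
        A = 7.0
        m = path_term(reg, 0, 2, A)
        m += occupancy_term(reg, A) if reg.n_families > 1 else QuboModel(
            reg.n_variables
        )
        m += ancilla_term(reg, A)
        bits = all_bitstrings(reg.n_variables)
        zero = {tuple(b) for b in bits[np.abs(m.energies(bits)) < 1e-9]}
        valid = {tuple(b) for _, _, b in enumerate_valid_configs(grid, reg)}
        assert zero == valid


class TestChainLengthTerm:
    def test_exact_length_free(self):
        grid = line_grid(4)
        reg = VariableRegistry.from_grid(grid, 1)
        m = chain_length_term(reg, L0=2, w=3.0)
        bits = np.zeros(reg.n_variables)
        bits[reg.bond_var(0, 1)] = 1
        bits[reg.bond_var(2, 3)] = 1
        assert m.energy(bits) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_bonds,expect", [(1, 3.0), (3, 3.0), (0, 12.0)])
    def test_unit_deviation_costs_w(self, n_bonds, expect):
        grid = line_grid(4)
        reg = VariableRegistry.from_grid(grid, 1)
        m = chain_length_term(reg, L0=2, w=3.0)
        bits = np.zeros(reg.n_variables)
        for e in list(reg.edges)[:n_bonds]:
            bits[reg.bond_var(*e)] = 1
        assert m.energy(bits) == pytest.approx(expect)

    def test_tolerance_scaling(self):
        # w = A / (L0 p)^2 makes an excess of L0*p bonds cost exactly A
        A, L0, p = 10.0, 2, 0.5
        w = w_from_tolerance(A, L0, p)
        grid = line_grid(5)
        reg = VariableRegistry.from_grid(grid, 1)
        m = chain_length_term(reg, L0=L0, w=w)
        bits = np.zeros(reg.n_variables)
        extra = int(L0 * p)
        for e in list(reg.edges)[: L0 + extra]:
            bits[reg.bond_var(*e)] = 1
        assert m.energy(bits) == pytest.approx(A)


class TestToIsing:
    def test_single_linear(self):
        m = QuboModel(1)
        m.add_linear(0, 1.0)
        ising = to_ising(m)
        assert ising.h[0] == pytest.approx(0.5)
        assert ising.offset == pytest.approx(0.5)

    def test_single_quadratic(self):
        m = QuboModel(2)
        m.add_quadratic(0, 1, 1.0)
        ising = to_ising(m)
        assert ising.J[(0, 1)] == pytest.approx(0.25)
        assert ising.h[0] == pytest.approx(0.25)
        assert ising.h[1] == pytest.approx(0.25)
        assert ising.offset == pytest.approx(0.25)

    def test_hypothesis_equivalence_small_models(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=30, deadline=None)
        @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
        def check(seed, n):
            rng = np.random.default_rng(seed)
            m = QuboModel(n)
            m.offset = float(rng.normal())
            for i in range(n):
                m.add_linear(i, float(rng.normal()))
            for i in range(n):
                for j in range(i + 1, n):
                    m.add_quadratic(i, j, float(rng.normal()))
            ising = to_ising(m)
            bits = all_bitstrings(n)
            ei = np.array([ising.energy(2.0 * b - 1.0) for b in bits])
            assert np.allclose(m.energies(bits), ei, atol=1e-9)

        check()

    def test_random_model_equivalence(self):
        rng = np.random.default_rng(5)
        n = 10
        m = QuboModel(n)
        m.offset = float(rng.normal())
        for i in range(n):
            m.add_linear(i, float(rng.normal()))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    m.add_quadratic(i, j, float(rng.normal()))
        ising = to_ising(m)
        bits = all_bitstrings(n)
        eq = m.energies(bits)
        ei = np.array([ising.energy(2.0 * b - 1.0) for b in bits])
        assert np.allclose(eq, ei, atol=1e-9)


class TestVariableCount:
    def test_tiny_box(self):
        exact, estimate = variable_count(1, 1, 2, 1)
        assert exact == 4  # 2 site + 1 bond + 1 ancilla
        assert estimate == 14

    def test_paper_scale_box(self):
        exact, estimate = variable_count(3, 3, 10, 5)
        assert estimate == 2070
        assert exact == 450 + 201 + 1005  # 201 edges: 60 + 60 + 81

    def test_estimate_linear_in_D(self):
        _, e1 = variable_count(4, 4, 4, 2)
        _, e2 = variable_count(4, 4, 4, 4)
        _, e3 = variable_count(4, 4, 4, 6)
        assert e2 - e1 == e3 - e2

    def test_registry_count_matches_formula(self):
        grid = box_grid(2, 3, 2)
        reg = VariableRegistry.from_grid(grid, 3)
        exact, _ = variable_count(2, 3, 2, 3)
        assert reg.n_variables == exact


class TestAdmissibleLength:
    def test_bounds(self):
        assert admissible_length_bounds(10, 0.2) == (8.0, 12.0)
        assert admissible_length_bounds(10, 1.0) == (0.0, 20.0)

    def test_w_formula(self):
        assert w_from_tolerance(10.0, 10, 0.2) == pytest.approx(
            10.0 / (100 * 0.04)
        )


def _tiny_instance(grid, D, seed, L0=None):
    """Seeded tiny assembled model with dominance-safe A."""
    rng = np.random.default_rng(seed)
    eps = -rng.uniform(0.2, 2.0, size=(D, D))
    eps = (eps + eps.T) / 2.0
    model = toy_model(D=D, eps=eps, sigma=float(rng.uniform(2.6, 3.3)))
    E = rng.normal(0.0, 1.0, size=(grid.n_sites, D))
    fld = ExternalField(E=E, E0=np.zeros(D), Nc=0.0)
    if L0 is None:
        L0 = int(rng.integers(1, 4))
    w = float(rng.uniform(0.5, 3.0))
    probe = QuboParams(A=1.0, L0=L0, w=w)
    A = soft_coefficient_mass(grid, fld, model, probe) + 1.0
    H = assemble(grid, fld, model, QuboParams(A=A, L0=L0, w=w))
    return H, fld, model


TINY_GRIDS = [
    lambda: line_grid(3),
    lambda: line_grid(4),
    lambda: box_grid(2, 2, 1, s=0, t=3),
    lambda: box_grid(2, 2, 1, s=0, t=1),
]


class TestAssembledOracle:
    @pytest.mark.parametrize("gi", range(4))
    @pytest.mark.parametrize("D", [1, 2])
    def test_ground_states_are_valid_chains(self, gi, D):
        grid = TINY_GRIDS[gi]()
        H, fld, model = _tiny_instance(grid, D, seed=100 * gi + D)
        states, e0 = brute_force(H)
        valid = enumerate_valid_configs(grid, H.registry)
        valid_bits = {tuple(b) for _, _, b in valid}
        for st in states:
            assert tuple(st) in valid_bits
        # ground energy equals the minimum over the valid-config oracle
        best = min(H.energy(b) for _, _, b in valid)
        assert e0 == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("gi", [0, 2])
    def test_energy_consistency_on_all_valid_configs(self, gi):
        grid = TINY_GRIDS[gi]()
        H, fld, model = _tiny_instance(grid, 2, seed=7 + gi)
        w = H.params["w"]
        L0 = H.params["L0"]
        for path, seq, bits in enumerate_valid_configs(grid, H.registry):
            chain = decode(bits, H.registry, grid)
            assert chain.valid_path
            assert chain.path == path and chain.sequence == seq
            phys = chain_physical_energy(chain, grid, fld, model)
            phys += w * (L0 - chain.length) ** 2
            assert H.energy(bits) == pytest.approx(phys, abs=1e-9)

    def test_violating_states_exceed_best_feasible(self):
        grid = line_grid(3)
        H, _, _ = _tiny_instance(grid, 1, seed=3)
        bits = all_bitstrings(H.n_variables)
        energies = H.energies(bits)
        penalty = np.zeros(len(bits))
        for name in ("ancilla", "occupancy", "path"):
            penalty += H.components[name].energies(bits)
        feasible = np.abs(penalty) < 1e-9
        best_feasible = energies[feasible].min()
        assert np.all(energies[~feasible] > best_feasible + 1e-9)

    def test_ring_configs_reach_zero_penalty_and_are_flagged(self):
        # 2 x 3 box: anchors on one rung, a 4-cycle free on the other four
        grid = box_grid(2, 3, 1, s=0, t=3)
        reg = VariableRegistry.from_grid(grid, 1)
        A = 5.0
        m = path_term(reg, 0, 3, A)
        m += ancilla_term(reg, A)
        bits = np.zeros(reg.n_variables)
        # direct s-t bond
        for i in (0, 3):
            bits[reg.site_var(i, 0)] = 1
        bits[reg.bond_var(0, 3)] = 1
        bits[reg.anc_var(0, 3, 0)] = 1
        # detached ring on sites 1, 2, 4, 5
        ring = [(1, 2), (2, 5), (4, 5), (1, 4)]
        for i in (1, 2, 4, 5):
            bits[reg.site_var(i, 0)] = 1
        for a, b in ring:
            bits[reg.bond_var(a, b)] = 1
            bits[reg.anc_var(a, b, 0)] = 1
        assert m.energy(bits) == pytest.approx(0.0, abs=1e-12)
        chain = decode(bits, reg, grid)
        assert chain.valid_path
        assert chain.path == (0, 3)
        assert chain.had_rings
        assert chain.ring_components == ((1, 2, 4, 5),)


class TestAssembleInterface:
    def test_missing_anchors_rejected(self):
        grid = line_grid(3, anchors=False)
        model = toy_model(D=1)
        with pytest.raises(ValueError, match="anchor"):
            assemble(grid, zero_field(grid, 1), model,
                     QuboParams(A=1.0, L0=2, w=1.0))

    def test_serialization_round_trip(self):
        grid = line_grid(3)
        H, _, _ = _tiny_instance(grid, 2, seed=1)
        back = QuboModel.from_json(H.to_json())
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = rng.integers(0, 2, H.n_variables)
            assert back.energy(b) == pytest.approx(H.energy(b), abs=1e-12)

    def test_coordinate_text_export(self):
        grid = line_grid(3)
        H, _, _ = _tiny_instance(grid, 1, seed=5)
        text = H.to_coordinate_text()
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        total = 0.0
        ones = np.ones(H.n_variables)
        for line in lines:
            i, j, c = line.split()
            total += float(c)
        assert total + H.offset == pytest.approx(H.energy(ones), abs=1e-9)

    def test_energy_matches_componentwise_sum(self):
        grid = box_grid(2, 2, 1, s=0, t=3)
        H, _, _ = _tiny_instance(grid, 2, seed=9)
        rng = np.random.default_rng(2)
        for _ in range(20):
            b = rng.integers(0, 2, H.n_variables)
            total = sum(part.energy(b) for part in H.components.values())
            assert H.energy(b) == pytest.approx(total, abs=1e-9)
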