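"""Absorbing classes, cyclic structure, and spectral/harmonic objects."""

import cmath

import numpy as np
import pytest

from conscious_agents import make_fixture, two_agent_chain
from conscious_agents.asymptotics import (
    eigenfunction,
    eigenvalue,
    find_absorbing_structure,
    harmonic_function,
    indicator,
    spacetime_kernel,
)
from conscious_agents.dynamics import DynamicsChain, _UpdateRule
from conscious_agents.kernels import MarkovKernel, StateSpace


def K(s):
    return tuple(s.strip("|>"))


def chain_from_matrix(m):
    """Wrap a bare stochastic matrix as a single-component chain."""
    m = np.asarray(m, dtype=float)
    space = StateSpace(tuple(f"s{i}" for i in range(m.shape[0])))
    kern = MarkovKernel(space, space, m)
    rules = (_UpdateRule(kern, in_idx=(0,), out_idx=(0,)),)
    return DynamicsChain(E=space, component_spaces=(space,), rules=rules)


def random_chain(n, seed):
    """Seeded random n-state chain with sparse support (transients likely)."""
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n))
    for i in range(n):
        nnz = rng.integers(1, 4)
        cols = rng.choice(n, size=nnz, replace=False)
        w = rng.dirichlet(np.ones(nnz))
        m[i, cols] = w
    return chain_from_matrix(m)


class TestIdentityExample:
    def test_six_classes_with_printed_periods(self, identity_struct):
        assert identity_struct.n_classes == 6
        assert [c.period for c in identity_struct.classes] == [1, 1, 2, 4, 4, 4]
        assert identity_struct.transient_states == ()

    def test_printed_cycle_orders(self, identity_struct):
        listed = {
            1: ["0000"],
            2: ["1111"],
            3: ["0101", "1010"],
            4: ["0001", "1000", "0100", "0010"],
            5: ["0011", "1001", "1100", "0110"],
            6: ["0111", "1011", "1101", "1110"],
        }
        for rho, kets in listed.items():
            assert list(identity_struct.cls(rho).states) == [K(s) for s in kets]

    def test_cyclic_classes_partition_each_class(self, identity_struct):
        for cls in identity_struct.classes:
            flat = [s for cc in cls.cyclic_classes for s in cc]
            assert sorted(flat) == sorted(cls.states)
            assert len(cls.cyclic_classes) == cls.period


class TestSwapExample:
    def test_two_period_eight_classes(self, swap_struct):
        assert swap_struct.n_classes == 2
        assert [c.period for c in swap_struct.classes] == [8, 8]
        assert swap_struct.transient_states == ()

    def test_printed_cycle_orders(self, swap_struct):
        assert list(swap_struct.cls(1).states) == [
            K(s) for s in
            ["0000", "0100", "0110", "0111", "1111", "1011", "1001", "1000"]
        ]
        assert list(swap_struct.cls(2).states) == [
            K(s) for s in
            ["0001", "1100", "0010", "0101", "1110", "0011", "1101", "1010"]
        ]


class TestIndicator:
    def test_printed_indicator_values(self, identity_struct):
        labels = identity_struct.state_labels
        u11 = indicator(identity_struct, 1, 1)
        assert u11[labels.index(K("0000"))] == 1.0 and u11.sum() == 1.0
        u53 = indicator(identity_struct, 5, 3)
        assert u53[labels.index(K("1100"))] == 1.0 and u53.sum() == 1.0

    def test_deltas_partition_class(self, identity_struct):
        for cls in identity_struct.classes:
            total = sum(
                indicator(identity_struct, cls.index, d)
                for d in range(1, cls.period + 1)
            )
            members = set(cls.states)
            expected = np.array(
                [1.0 if lab in members else 0.0 for lab in identity_struct.state_labels]
            )
            assert np.array_equal(total, expected)

    def test_out_of_range_indices(self, identity_struct):
        with pytest.raises(IndexError):
            indicator(identity_struct, 7, 1)
        with pytest.raises(IndexError):
            indicator(identity_struct, 1, 2)


class TestEigen:
    def test_trivial_and_quarter_turn_eigenvalues(self, identity_struct):
        assert eigenvalue(identity_struct, 1, 5) == pytest.approx(1.0)
        lam = eigenvalue(identity_struct, 4, 1)  # period 4, quarter turn
        assert lam == pytest.approx(1j)

    def test_unit_modulus_for_random_modes(self, identity_struct):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rho = int(rng.integers(1, 7))
            k = int(rng.integers(-10, 10))
            assert abs(abs(eigenvalue(identity_struct, rho, k)) - 1.0) < 1e-12

    def test_k0_is_class_indicator(self, identity_struct):
        spec = eigenfunction(identity_struct, 5, 0)
        members = set(identity_struct.cls(5).states)
        for lab, val in zip(identity_struct.state_labels, spec.vector):
            assert val == pytest.approx(1.0 if lab in members else 0.0)

    def test_quarter_turn_eigenrelation_by_matrix_product(self, identity_struct):
        spec = eigenfunction(identity_struct, 4, 1)
        L = identity_struct.L.matrix
        assert np.max(np.abs(L @ spec.vector - 1j * spec.vector)) < 1e-10

    @pytest.mark.parametrize("example", ["identity_pair", "swap_d1_pair"])
    def test_eigenrelation_all_modes_both_examples(self, example):
        chain = two_agent_chain(*make_fixture(example))
        struct = find_absorbing_structure(chain)
        L = struct.L.matrix
        for cls in struct.classes:
            for k in range(cls.period):
                spec = eigenfunction(struct, cls.index, k)
                err = np.max(np.abs(L @ spec.vector - spec.eigenvalue * spec.vector))
                assert err < 1e-10

    def test_support_confined_to_class(self, identity_struct):
        spec = eigenfunction(identity_struct, 6, 2)
        members = set(identity_struct.cls(6).states)
        for lab, val in zip(identity_struct.state_labels, spec.vector):
            if lab not in members:
                assert val == 0.0


class TestSpaceTime:
    def test_operator_matches_direct_sum(self):
        chain = random_chain(4, seed=3)
        q = spacetime_kernel(chain)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 6))

        def h(e, n):
            return vals[chain.E.index(e), n]

        qh = q.apply(h)
        L = chain.L.matrix
        for i, e in enumerate(chain.E.labels):
            for n in range(5):
                direct = sum(L[i, j] * vals[j, n + 1] for j in range(4))
                assert qh(e, n) == pytest.approx(direct, abs=1e-12)

    def test_step_independent_function_reduces_to_L(self):
        chain = random_chain(5, seed=9)
        q = spacetime_kernel(chain)
        v = np.arange(5, dtype=float)
        qh = q.apply(lambda e, n: v[chain.E.index(e)])
        L = chain.L.matrix
        for i, e in enumerate(chain.E.labels):
            assert qh(e, 0) == pytest.approx((L @ v)[i], abs=1e-12)

    def test_mass_off_the_next_step_is_zero(self):
        chain = random_chain(4, seed=5)
        q = spacetime_kernel(chain)
        e = chain.E.labels[0]
        assert q.probability(e, 3, chain.E.labels[1], 5) == 0.0
        assert q.probability(e, 3, chain.E.labels[1], 3) == 0.0


class TestHarmonic:
    def test_k0_constant_in_step(self, identity_struct):
        g0 = harmonic_function(identity_struct, 3, 0, 0)
        g7 = harmonic_function(identity_struct, 3, 0, 7)
        assert np.allclose(g0, g7)
        members = set(identity_struct.cls(3).states)
        for lab, val in zip(identity_struct.state_labels, g0):
            assert val == pytest.approx(1.0 if lab in members else 0.0)

    @pytest.mark.parametrize("example", ["identity_pair", "swap_d1_pair"])
    def test_q_harmonicity_all_modes(self, example):
        chain = two_agent_chain(*make_fixture(example))
        struct = find_absorbing_structure(chain)
        L = struct.L.matrix
        for cls in struct.classes:
            for k in range(cls.period):
                for n in range(2 * cls.period):
                    g_n = harmonic_function(struct, cls.index, k, n)
                    g_n1 = harmonic_function(struct, cls.index, k, n + 1)
                    assert np.max(np.abs(L @ g_n1 - g_n)) < 1e-10

    def test_cis_expansion_matches(self, identity_struct):
        # period-4 class, k = 1: entries are cis(2 pi delta / d - 2 pi n / d)
        rho, k = 4, 1
        cls = identity_struct.cls(rho)
        for n in range(8):
            g = harmonic_function(identity_struct, rho, k, n)
            for delta, cc in enumerate(cls.cyclic_classes, start=1):
                for lab in cc:
                    expected = cmath.exp(1j * (2 * cmath.pi * delta / 4 - 2 * cmath.pi * n / 4))
                    assert g[identity_struct.state_labels.index(lab)] == pytest.approx(expected)


class TestGeneralChains:
    def test_one_state_self_loop(self):
        struct = find_absorbing_structure(chain_from_matrix([[1.0]]))
        assert struct.n_classes == 1
        assert struct.classes[0].period == 1

    def test_transient_states_reported(self):
        # s0 leaks into the closed pair {s1, s2}
        m = [[0.5, 0.5, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
        struct = find_absorbing_structure(chain_from_matrix(m))
        assert struct.transient_states == ("s0",)
        assert struct.n_classes == 1
        assert struct.classes[0].period == 2

    @pytest.mark.parametrize("seed", range(100))
    def test_random_16_state_chains_classes_closed_and_spectral(self, seed):
        chain = random_chain(16, seed=seed)
        struct = find_absorbing_structure(chain)
        L = struct.L.matrix
        labels = struct.state_labels
        assert struct.n_classes >= 1
        recurrent = [labels.index(s) for c in struct.classes for s in c.states]
        for cls in struct.classes:
            members = [labels.index(s) for s in cls.states]
            # closed: no probability mass leaves the class
            outside = np.setdiff1d(np.arange(16), members)
            if outside.size:
                assert np.max(L[np.ix_(members, outside)]) <= 1e-12
            # eigen-relation and harmonicity for every mode, on the recurrent
            # part of the chain (transient states feeding the class pick up
            # mass from f, so the relation is a statement about the
            # restriction to the absorbing sets)
            for k in range(cls.period):
                spec = eigenfunction(struct, cls.index, k)
                resid = L @ spec.vector - spec.eigenvalue * spec.vector
                assert np.max(np.abs(resid[recurrent])) < 1e-10
                g0 = harmonic_function(struct, cls.index, k, 0)
                g1 = harmonic_function(struct, cls.index, k, 1)
                assert np.max(np.abs((L @ g1 - g0)[recurrent])) < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_cesaro_limit_oracle_small_chains(self, seed):
        # independent oracle: classes of an 8-state chain from the support of
        # the Cesaro-averaged powers of L
        chain = random_chain(8, seed=seed)
        struct = find_absorbing_structure(chain)
        L = struct.L.matrix
        # long burn-in so transient mass (geometric decay, possibly slow)
        # is far below the support threshold; averaging window a multiple
        # of every possible period <= 8 removes cyclic oscillation
        n_avg, n_start = 840, 32768
        P = np.linalg.matrix_power(L, n_start)
        acc = np.zeros_like(L)
        cur = P
        for _ in range(n_avg):
            acc += cur
            cur = cur @ L
        A = acc / n_avg
        recurrent = {i for i in range(8) if A[i, i] > 1e-6}
        oracle_classes = set()
        for i in sorted(recurrent):
            support = frozenset(j for j in sorted(recurrent) if A[i, j] > 1e-6)
            oracle_classes.add(support)
        found = {
            frozenset(struct.state_labels.index(s) for s in cls.states)
            for cls in struct.classes
        }
        assert found == oracle_classes
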