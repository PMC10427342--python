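import numpy as np
import pytest

from rsrnsp import (ContractError, NetworkConfig, encode_input, init_network,
                    readout_symbol, step_output, step_recurrent)
from rsrnsp.network import InputMap, NetworkState, WeightMatrices


class TestInitNetwork:
    def test_all_rows_normalized_to_unit_sum(self, tiny_config):
        weights, _, _ = init_network(tiny_config)
        for w in (weights.w_ei, weights.w_ie, weights.w_oe):
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        row_sums = weights.w_ee.sum(axis=1)
        has_conn = weights.c_ee.any(axis=1)
        np.testing.assert_allclose(row_sums[has_conn], 1.0, atol=1e-9)
        np.testing.assert_array_equal(row_sums[~has_conn], 0.0)

    def test_mask_has_no_self_connections(self, tiny_config):
        weights, _, _ = init_network(tiny_config)
        assert not np.any(np.diagonal(weights.c_ee))

    def test_weights_vanish_exactly_off_the_mask(self, tiny_config):
        weights, _, _ = init_network(tiny_config)
        assert np.all(weights.w_ee[~weights.c_ee] == 0.0)
        assert np.all(weights.w_ee[weights.c_ee] > 0.0)

    def test_connection_fraction_matches_p_c_in_expectation(self):
        """Mean realized E-E density over many seeds stays inside the
        binomial 99% confidence band around p_c."""
        p_c, ne, n_seeds = 0.05, 200, 100
        n_pairs = ne * (ne - 1)
        counts = []
        for seed in range(n_seeds):
            cfg = NetworkConfig(n_excitatory=ne, p_c=p_c, seed=seed)
            weights, _, _ = init_network(cfg)
            counts.append(np.count_nonzero(weights.c_ee))
        total = sum(counts)
        mean_frac = total / (n_seeds * n_pairs)
        se = np.sqrt(p_c * (1 - p_c) / (n_seeds * n_pairs))
        assert abs(mean_frac - p_c) < 2.576 * se

    def test_initial_state_is_quiescent(self, tiny_config):
        _, state, _ = init_network(tiny_config)
        assert not state.s_e.any()
        assert not state.s_in.any()
        assert not state.e_ee.any()
        assert state.baseline_b == 0.0
        assert state.t == 0

    def test_thresholds_within_configured_ranges(self, tiny_config):
        _, state, _ = init_network(tiny_config)
        lo, hi = tiny_config.theta_e_range
        assert np.all((state.theta_e >= lo) & (state.theta_e <= hi))
        lo, hi = tiny_config.theta_in_range
        assert np.all((state.theta_in >= lo) & (state.theta_in <= hi))

    def test_same_seed_reproduces_network_bit_exactly(self, tiny_config):
        w1, s1, _ = init_network(tiny_config)
        w2, s2, _ = init_network(tiny_config)
        np.testing.assert_array_equal(w1.w_ee, w2.w_ee)
        np.testing.assert_array_equal(s1.theta_e, s2.theta_e)


class TestEncodeInput:
    def test_drive_has_ones_exactly_on_the_subset(self):
        imap = InputMap(["a", "b", "c"], 10, 100)
        u = encode_input("a", imap)
        assert u.sum() == 10
        assert np.all(u[imap.subsets["a"]] == 1.0)

    def test_distinct_symbols_have_orthogonal_drives(self):
        imap = InputMap(["a", "b", "c"], 10, 100)
        assert np.dot(encode_input("a", imap), encode_input("b", imap)) == 0

    def test_silent_step_is_all_zero(self):
        imap = InputMap(["a", "b"], 5, 50)
        assert not encode_input(None, imap).any()

    def test_unknown_symbol_raises_lookup_error(self):
        imap = InputMap(["a"], 5, 50)
        with pytest.raises(KeyError):
            encode_input("z", imap)


def _manual_state(ne, ni, no, theta_e, theta_in, theta_o):
    return NetworkState(
        s_e=np.zeros(ne), s_in=np.zeros(ni), s_o=np.zeros(no),
        theta_e=np.asarray(theta_e, float),
        theta_in=np.asarray(theta_in, float),
        theta_o=np.asarray(theta_o, float),
        e_ee=np.zeros((ne, ne)), e_oe=np.zeros((no, ne)))


class TestStepRecurrent:
    def test_subthreshold_network_stays_silent(self):
        ne, ni = 4, 1
        weights = WeightMatrices(np.zeros((ne, ne)), np.zeros((ne, ni)),
                                 np.zeros((ni, ne)), np.zeros((1, ne)),
                                 np.zeros((ne, ne), bool))
        state = _manual_state(ne, ni, 1, [0.1] * ne, [0.5], [0.5])
        new = step_recurrent(state, weights, np.zeros(ne))
        assert not new.s_e.any()
        assert new.t == 1

    def test_neuron_at_exact_threshold_fires(self):
        """Heaviside with Theta(0) = 1: drive equal to threshold spikes."""
        weights = WeightMatrices(np.zeros((1, 1)), np.zeros((1, 1)),
                                 np.zeros((1, 1)), np.zeros((1, 1)),
                                 np.zeros((1, 1), bool))
        state = _manual_state(1, 1, 1, [1.0], [2.0], [0.5])
        new = step_recurrent(state, weights, np.ones(1))
        assert new.s_e[0] == 1.0

    def test_hand_built_network_trajectory(self):
        """3 excitatory / 1 inhibitory network followed for 5 steps by a
        pencil-and-paper simulation of the update equations."""
        w_ee = np.array([[0.0, 0.6, 0.0],
                         [0.7, 0.0, 0.0],
                         [0.5, 0.5, 0.0]])
        c_ee = w_ee > 0
        w_ei = np.array([[0.4], [0.4], [1.0]])
        w_ie = np.array([[0.5, 0.5, 0.0]])
        weights = WeightMatrices(w_ee, w_ei, w_ie, np.zeros((1, 3)), c_ee)
        state = _manual_state(3, 1, 1, [0.5, 0.5, 0.9], [0.8], [0.5])
        u = np.array([1.0, 0.0, 0.0])
        # By hand (s_e, s_in after each step, drive u only at step 1):
        #  t1: psi_e = u - theta = (0.5, -0.5, -0.9)          -> s_e 100, s_in 0
        #  t2: psi_e = W.s_e(100) - theta = (-.5, .2, -.4)    -> s_e 010
        #      psi_in = 0.5 - 0.8 < 0                         -> s_in 0
        #  t3: psi_e = (0.6-.5, -.5, .5-.9)                   -> s_e 100
        #      psi_in = 0.5-0.8 < 0                           -> s_in 0
        #  t4: same as t2 with no input                       -> s_e 010
        #  t5: same as t3                                     -> s_e 100
        expected = [[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 1, 0], [1, 0, 0]]
        drives = [u] + [np.zeros(3)] * 4
        for step_u, want in zip(drives, expected):
            state = step_recurrent(state, weights, step_u)
            assert state.s_e.tolist() == want

    def test_agrees_with_dense_double_loop_oracle(self, rng):
        """100 steps of a random small network against an independent
        elementwise reimplementation of the update equations."""
        ne, ni = 8, 2
        w_ee = rng.random((ne, ne)) * (rng.random((ne, ne)) < 0.4)
        np.fill_diagonal(w_ee, 0.0)
        weights = WeightMatrices(w_ee, rng.random((ne, ni)) * 0.3,
                                 rng.random((ni, ne)) * 0.3,
                                 rng.random((2, ne)), w_ee > 0)
        theta_e = rng.uniform(0.05, 0.5, ne)
        theta_in = rng.uniform(0.1, 1.0, ni)
        state = _manual_state(ne, ni, 2, theta_e, theta_in, [0.3, 0.3])
        s_e, s_in = np.zeros(ne), np.zeros(ni)
        for t in range(100):
            u = (rng.random(ne) < 0.2).astype(float)
            state = step_recurrent(state, weights, u)
            ref_e = np.zeros(ne)
            for k in range(ne):
                acc = u[k] - theta_e[k]
                for i in range(ne):
                    acc += w_ee[k, i] * s_e[i]
                for j in range(ni):
                    acc -= weights.w_ei[k, j] * s_in[j]
                ref_e[k] = 1.0 if acc >= 0 else 0.0
            ref_in = np.zeros(ni)
            for k in range(ni):
                acc = -theta_in[k]
                for j in range(ne):
                    acc += weights.w_ie[k, j] * s_e[j]
                ref_in[k] = 1.0 if acc >= 0 else 0.0
            np.testing.assert_array_equal(state.s_e, ref_e)
            np.testing.assert_array_equal(state.s_in, ref_in)
            s_e, s_in = state.s_e, state.s_in

    def test_permuting_neuron_labels_permutes_trajectory(self, rng):
        """Relabeling excitatory neurons (and permuting weights and
        thresholds consistently) permutes every state in the trajectory."""
        ne, ni = 6, 2
        w_ee = rng.random((ne, ne)) * (rng.random((ne, ne)) < 0.5)
        np.fill_diagonal(w_ee, 0.0)
        w_ei = rng.random((ne, ni)) * 0.4
        w_ie = rng.random((ni, ne)) * 0.4
        theta_e = rng.uniform(0.05, 0.6, ne)
        theta_in = rng.uniform(0.1, 0.9, ni)
        perm = rng.permutation(ne)
        weights_a = WeightMatrices(w_ee, w_ei, w_ie, np.zeros((1, ne)),
                                   w_ee > 0)
        weights_b = WeightMatrices(w_ee[np.ix_(perm, perm)], w_ei[perm],
                                   w_ie[:, perm], np.zeros((1, ne)),
                                   (w_ee > 0)[np.ix_(perm, perm)])
        state_a = _manual_state(ne, ni, 1, theta_e, theta_in, [0.5])
        state_b = _manual_state(ne, ni, 1, theta_e[perm], theta_in, [0.5])
        for t in range(30):
            u = (rng.random(ne) < 0.3).astype(float)
            state_a = step_recurrent(state_a, weights_a, u)
            state_b = step_recurrent(state_b, weights_b, u[perm])
            np.testing.assert_array_equal(state_a.s_e[perm], state_b.s_e)

    def test_dimension_mismatch_rejected(self, tiny_config):
        weights, state, _ = init_network(tiny_config)
        with pytest.raises(ContractError):
            step_recurrent(state, weights, np.zeros(5))


class TestStepOutput:
    def test_silent_excitatory_layer_gives_silent_output(self):
        weights = WeightMatrices(np.zeros((3, 3)), np.zeros((3, 1)),
                                 np.zeros((1, 3)), np.full((2, 3), 0.3),
                                 np.zeros((3, 3), bool))
        state = _manual_state(3, 1, 2, [0.5] * 3, [0.5], [0.2, 0.2])
        s_o, psi = step_output(state, weights)
        assert not s_o.any()
        np.testing.assert_allclose(psi, [-0.2, -0.2])

    def test_potential_arithmetic(self):
        weights = WeightMatrices(np.zeros((2, 2)), np.zeros((2, 1)),
                                 np.zeros((1, 2)), np.array([[0.5, 0.5]]),
                                 np.zeros((2, 2), bool))
        state = _manual_state(2, 1, 1, [0.1, 0.1], [0.5], [0.9])
        state.s_e = np.ones(2)
        s_o, psi = step_output(state, weights)
        assert s_o[0] == 1.0
        assert psi[0] == pytest.approx(0.1)

    def test_matches_dense_matvec_oracle(self, rng):
        no, ne = 4, 12
        w_oe = rng.random((no, ne))
        weights = WeightMatrices(np.zeros((ne, ne)), np.zeros((ne, 2)),
                                 np.zeros((2, ne)), w_oe,
                                 np.zeros((ne, ne), bool))
        state = _manual_state(ne, 2, no, [0.5] * ne, [0.5] * 2,
                              rng.uniform(0, 0.5, no))
        state.s_e = (rng.random(ne) < 0.4).astype(float)
        s_o, psi = step_output(state, weights)
        ref = np.array([sum(w_oe[k, j] * state.s_e[j] for j in range(ne))
                        - state.theta_o[k] for k in range(no)])
        np.testing.assert_allclose(psi, ref, atol=1e-12)
        np.testing.assert_array_equal(s_o, (ref >= 0).astype(float))


class TestReadoutSymbol:
    def test_picks_symbol_of_maximal_potential(self):
        assert readout_symbol(np.array([0.2, 0.9, 0.1]), "abc") == "b"

    def test_exact_tie_resolves_to_first_symbol(self):
        assert readout_symbol(np.array([0.5, 0.5]), "ab") == "a"

    def test_readout_follows_permutations_of_the_maximum(self):
        """Exhaustive check over all permutations of a 4-vector."""
        from itertools import permutations
        base = np.array([0.1, 0.4, 0.9, 0.2])
        symbols = ["w", "x", "y", "z"]
        for perm in permutations(range(4)):
            potentials = base[list(perm)]
            expected = symbols[int(np.argmax(potentials))]
            assert readout_symbol(potentials, symbols) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ContractError):
            readout_symbol(np.array([]), [])
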