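import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from disfree import (
    FreeEnergyParams,
    compensation_curve,
    enumerate_terminal,
    exhaustive_search,
    free_energy,
    generate_pair_matrix,
    greedy_internal,
    profile_ensemble,
)
from conftest import attr_matrix, random_attr_matrix, zero_matrix


def brute_force_terminal(matrix, params):
    """Independent (a, b) tail enumeration by direct pair summation."""
    n = matrix.n
    best = None
    best_ab = None
    for a in range(n):
        for b in range(n - a):
            e = 0.0
            for i in range(a, n - b):
                for j in range(i + 1, n - b):
                    e += matrix.total[i, j]
            f = e - params.e_d * (a + b)
            key = (f, a + b, a)
            if best is None or key < best:
                best, best_ab = key, (a, b)
    return best[0], best_ab


class TestFreeEnergyFunction:
    def test_all_ordered_is_pair_sum(self, default_params):
        m = attr_matrix(6, {(1, 3): -2.0, (2, 6): -1.0})
        a = free_energy(m, [True] * 6, default_params)
        assert a.breakdown.F == a.breakdown.E == pytest.approx(-3.0)
        assert a.breakdown.tail_term == a.breakdown.loop_term == 0.0

    def test_terminal_tail_credit(self, default_params):
        # N=10, residues 1-3 disordered on a zero matrix: F = -3 * E_d
        ordered = [False] * 3 + [True] * 7
        a = free_energy(zero_matrix(10), ordered, default_params)
        assert a.breakdown.F == pytest.approx(-6.0)
        assert a.breakdown.tail_term == pytest.approx(6.0)

    def test_internal_loop_credit(self, default_params):
        # N=20, internal run 8-11 (L=4): F = -beta * ln(L / L0)
        ordered = np.ones(20, dtype=bool)
        ordered[7:11] = False
        a = free_energy(zero_matrix(20), ordered, default_params)
        assert a.breakdown.F == pytest.approx(-1.5 * math.log(4 / 0.3))
        assert a.breakdown.F == pytest.approx(-3.8854007, abs=1e-6)

    def test_short_internal_run_rejected(self, default_params):
        ordered = np.ones(12, dtype=bool)
        ordered[5:7] = False
        with pytest.raises(ValueError, match="min_loop_len"):
            free_energy(zero_matrix(12), ordered, default_params)

    def test_breakdown_identity(self, default_params):
        rng = np.random.default_rng(5)
        m = random_attr_matrix(15, rng)
        ordered = np.ones(15, dtype=bool)
        ordered[:3] = False
        ordered[6:11] = False
        b = free_energy(m, ordered, default_params).breakdown
        assert b.F == pytest.approx(b.E - b.tail_term - b.loop_term, abs=1e-12)


class TestEnumerateTerminal:
    def test_zero_matrix_tie_cascade(self, default_params):
        # all a+b = 4 splits tie at F = -8; smaller N tail wins: (0, 4)
        a = enumerate_terminal(zero_matrix(5), default_params)
        assert a.breakdown.F == pytest.approx(-8.0)
        assert (a.n_tail, a.c_tail) == (0, 4)

    def test_strongly_bound_terminus_stays_ordered(self, default_params):
        # residue 1 loses 10 units of attraction but gains only E_d = 2
        m = attr_matrix(6, {(1, 3): -10.0})
        a = enumerate_terminal(m, default_params)
        assert a.n_tail == 0

    def test_never_worse_than_all_ordered(self, default_params):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_attr_matrix(10, rng)
            best = enumerate_terminal(m, default_params)
            all_ordered = free_energy(m, [True] * 10, default_params)
            assert best.breakdown.F <= all_ordered.breakdown.F + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force(self, seed, default_params):
        rng = np.random.default_rng(seed)
        m = random_attr_matrix(9, rng)
        f_ref, ab_ref = brute_force_terminal(m, default_params)
        a = enumerate_terminal(m, default_params)
        assert a.breakdown.F == pytest.approx(f_ref, abs=1e-12)
        assert (a.n_tail, a.c_tail) == ab_ref


class TestGreedyInternal:
    def test_zero_matrix_runs_to_negative_f(self, default_params):
        a = greedy_internal(zero_matrix(16), default_params)
        assert a.breakdown.F < 0
        assert a.n_disordered > 0

    def test_uniform_strong_attraction_stays_ordered(self, default_params):
        # flipping any 4-window loses >= 4 pairs * 5 each, credit is at
        # most 4 * E_d = 8: no move is favorable
        pairs = {(i, j): -5.0 for i in range(1, 13) for j in range(i + 2, 13)}
        m = attr_matrix(12, pairs)
        a = greedy_internal(m, default_params)
        assert a.ordered.all()
        assert a.breakdown.F == pytest.approx(free_energy(
            m, [True] * 12, default_params).breakdown.F)

    def test_planted_isolated_segment_found(self, default_params):
        # residues 13-17 energetically isolated inside a sticky 30-mer
        planted = set(range(13, 18))
        m = generate_pair_matrix(30, planted, attr_core=-5.0,
                                 attr_disordered=0.0, seed=3)
        g = greedy_internal(m, default_params)
        assert set(g.disordered_indices) <= planted
        assert len(g.disordered_indices) >= 4

    def test_trajectory_f_non_increasing(self, default_params):
        rng = np.random.default_rng(11)
        m = random_attr_matrix(20, rng, scale=1.0)
        _, traj = greedy_internal(m, default_params, return_trajectory=True)
        fs = [t.breakdown.F for t in traj]
        assert all(b <= a + 1e-12 for a, b in zip(fs, fs[1:]))


class TestExhaustiveSearch:
    def test_zero_matrix_maximises_entropy_credit(self, default_params):
        a = exhaustive_search(zero_matrix(8), default_params)
        # best admissible state: 7 disordered tail residues, 1 ordered
        assert a.breakdown.F == pytest.approx(-14.0)
        assert a.n_disordered == 7

    def test_sticky_chain_stays_ordered(self, default_params):
        pairs = {(i, j): -5.0 for i in range(1, 11) for j in range(i + 2, 11)}
        m = attr_matrix(10, pairs)
        a = exhaustive_search(m, default_params)
        assert a.ordered.all()

    def test_refuses_large_n(self, default_params):
        with pytest.raises(ValueError, match="max_n"):
            exhaustive_search(zero_matrix(30), default_params, max_n=24)

    def test_matches_terminal_when_loops_inadmissible(self, default_params):
        params = FreeEnergyParams(min_loop_len=12, block=4)
        rng = np.random.default_rng(2)
        for _ in range(5):
            m = random_attr_matrix(8, rng)
            t = enumerate_terminal(m, params)
            x = exhaustive_search(m, params)
            assert x.breakdown.F == pytest.approx(t.breakdown.F, abs=1e-12)
            assert (x.ordered == t.ordered).all()

    def test_greedy_is_upper_bound(self, default_params):
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = random_attr_matrix(18, rng, scale=1.5)
            g = greedy_internal(m, default_params)
            x = exhaustive_search(m, default_params)
            assert g.breakdown.F >= x.breakdown.F - 1e-9


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_f_identity_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        params = FreeEnergyParams()
        m = random_attr_matrix(14, rng)
        for search in (enumerate_terminal, greedy_internal):
            b = search(m, params).breakdown
            assert b.F == pytest.approx(b.E - b.tail_term - b.loop_term,
                                        abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.5, 4.0))
    def test_scaling_covariance(self, seed, c):
        """Scaling the matrix and the entropy credits by c scales F by c
        and leaves the optimal assignment unchanged."""
        rng = np.random.default_rng(seed)
        m = random_attr_matrix(10, rng)
        base = FreeEnergyParams()
        scaled_params = FreeEnergyParams(e_d=c * base.e_d, beta=c * base.beta,
                                         l0=base.l0)
        scaled_matrix = type(m)(n=m.n, e_attr=c * m.e_attr, e_rep=c * m.e_rep)
        a1 = enumerate_terminal(m, base)
        a2 = enumerate_terminal(scaled_matrix, scaled_params)
        assert (a1.ordered == a2.ordered).all()
        assert a2.breakdown.F == pytest.approx(c * a1.breakdown.F, rel=1e-10)

    def test_determinism(self, default_params):
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        m1 = random_attr_matrix(16, rng1)
        m2 = random_attr_matrix(16, rng2)
        a1 = greedy_internal(m1, default_params)
        a2 = greedy_internal(m2, default_params)
        assert (a1.ordered == a2.ordered).all()
        assert a1.breakdown == a2.breakdown


class TestProfileAndCompensation:
    def test_single_model_profile_is_binary(self, tail_ensemble, default_params):
        ens, _, _ = tail_ensemble
        from disfree import Ensemble

        one = Ensemble(sequence=ens.sequence, models=[ens.models[0]])
        p = profile_ensemble(one, default_params, mode="terminal")
        assert set(np.unique(p.freq_disordered)) <= {0.0, 1.0}
        assert p.n_models == 1

    def test_identical_models_give_binary_profile(self, default_params):
        from disfree import Ensemble, SyntheticSpec, generate_ensemble

        spec = SyntheticSpec(n_core=24, n_tail_n=4, n_models=1, seed=5,
                             core_noise=0.0)
        ens, _, _ = generate_ensemble(spec)
        clones = Ensemble(sequence=ens.sequence, models=ens.models * 3)
        p = profile_ensemble(clones, default_params, mode="terminal")
        assert set(np.unique(p.freq_disordered)) <= {0.0, 1.0}

    def test_planted_tails_have_high_frequency(self, tail_ensemble,
                                               default_params):
        ens, truth, _ = tail_ensemble
        p = profile_ensemble(ens, default_params, mode="terminal")
        assert p.freq_disordered[truth].mean() >= 0.9

    def test_compensation_rows(self, default_params):
        rng = np.random.default_rng(21)
        m = random_attr_matrix(20, rng, scale=1.0)
        final, traj = greedy_internal(m, default_params, return_trajectory=True)
        table = compensation_curve(m, default_params, traj)
        assert list(table.columns) == ["n_disordered", "E", "entropy_term", "F"]
        assert (table["n_disordered"].diff().dropna() >= 0).all()
        assert np.allclose(table["F"], table["E"] - table["entropy_term"])
        # all-ordered row: pure energy, no entropy
        first = table.iloc[0]
        assert first["n_disordered"] == 0 and first["entropy_term"] == 0.0
        assert first["F"] == first["E"]

    def test_compensation_e_monotone_on_attractive_matrix(self, default_params):
        rng = np.random.default_rng(22)
        m = random_attr_matrix(20, rng, scale=2.0)
        _, traj = greedy_internal(m, default_params, return_trajectory=True)
        table = compensation_curve(m, default_params, traj)
        # removing residues can only remove attraction: E non-decreasing
        assert (table["E"].diff().dropna() >= -1e-12).all()

    def test_compensation_f_flatter_than_e(self, default_params):
        """Entropy-enthalpy compensation on a planted fixture: the free
        energy varies less along the greedy trajectory than the energy."""
        planted = set(range(9, 17))
        m = generate_pair_matrix(24, planted, attr_core=-5.0,
                                 attr_disordered=-0.04, seed=8)
        _, traj = greedy_internal(m, default_params, return_trajectory=True)
        assert len(traj) >= 2
        table = compensation_curve(m, default_params, traj)
        f_range = table["F"].max() - table["F"].min()
        e_range = table["E"].max() - table["E"].min()
        assert f_range < e_range
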