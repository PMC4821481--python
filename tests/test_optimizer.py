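"""Sequential driver: move enumeration, dependency graph, selection,
execution, oscillation damping."""

import numpy as np
import pytest

from drcseg.core import region_statistics
from drcseg.energy import EnergyParams
from drcseg.optimizer import (Move, OscillationState, build_move_graph,
                              detect_oscillation, enumerate_moves,
                              run_sequential, select_moves)

from conftest import component_counts, random_label_field

P_PC = EnergyParams(model="pc", noise="gaussian", lam=0.0, theta=0.0, r_kappa=2)


def _moves_for(img, lab, p=P_PC):
    return enumerate_moves(img, lab, region_statistics(img, lab), p)


class TestEnumerateMoves:
    def test_perfect_segmentation_has_no_improving_move(self):
        img = np.zeros((6, 6))
        img[2:4, 2:4] = 9.0
        lab = (img > 0).astype(int)
        moves = _moves_for(img, lab)
        assert all(m.delta_e >= 0 for m in moves)

    def test_noise_speck_shrinks_under_length_prior(self):
        img = np.zeros((5, 5))
        lab = np.zeros((5, 5), dtype=int)
        lab[2, 2] = 1
        p = EnergyParams(lam=1.0, r_kappa=2)
        moves = _moves_for(img, lab, p)
        removal = [m for m in moves if m.pixel == (2, 2) and m.l_to == 0]
        assert removal and removal[0].delta_e < 0

    def test_hand_enumeration_single_pixel_region(self):
        img = np.zeros((3, 3))
        img[1, 1] = 5.0
        lab = (img > 0).astype(int)
        moves = _moves_for(img, lab)
        got = {(m.pixel, m.l_from, m.l_to) for m in moves}
        expected = {((1, 1), 1, 0),            # shrink: the particle leaves
                    ((0, 1), 0, 1), ((1, 0), 0, 1),
                    ((1, 2), 0, 1), ((2, 1), 0, 1)}  # growth candidates
        assert got == expected

    def test_forbidden_fusions_pruned(self):
        img = np.array([[9.0, 0.0, 1.0]])
        lab = np.array([[1, 0, 2]])
        p = EnergyParams(theta=0.0, r_kappa=1)  # means differ: no fusion
        moves = _moves_for(img, lab, p)
        # the move claiming the gap pixel for either region would fuse them
        assert not any(m.pixel == (0, 1) for m in moves)


class TestMoveGraph:
    def _mk(self, pixels):
        return [Move(p, 0, 1, -1.0, src=s) for p, s in pixels]

    def test_disjoint_moves_are_separate_subgraphs(self):
        g = build_move_graph(self._mk([((0, 0), (0, 1)), ((5, 5), (5, 6))]),
                             shape=(8, 8))
        assert g.n_components == 2

    def test_moves_sharing_a_pixel_join(self):
        g = build_move_graph(self._mk([((2, 2), (2, 3)), ((2, 3), (2, 4))]),
                             shape=(8, 8))
        assert g.n_components == 1

    def test_matches_generic_component_oracle(self, rng):
        # oracle: connected components of the move/pixel incidence graph
        pix = [(int(a), int(b)) for a, b in rng.integers(0, 6, size=(30, 2))]
        src = [(int(a), int(b)) for a, b in rng.integers(0, 6, size=(30, 2))]
        moves = self._mk(list(zip(pix, src)))
        g = build_move_graph(moves, shape=(6, 6))
        # python-set union find over shared pixels
        groups = []
        for m in moves:
            touched = {m.pixel, m.src}
            merged = [grp for grp in groups if grp["px"] & touched]
            newg = {"px": set(touched), "mv": {id(m)}}
            for grp in merged:
                newg["px"] |= grp["px"]
                newg["mv"] |= grp["mv"]
                groups.remove(grp)
            groups.append(newg)
        oracle_sets = {frozenset(grp["mv"]) for grp in groups}
        got = {}
        for i, c in enumerate(g.comp):
            got.setdefault(int(c), set()).add(id(moves[i]))
        assert {frozenset(v) for v in got.values()} == oracle_sets


class TestSelectMoves:
    def _graph(self, moves):
        return build_move_graph(moves, shape=(10, 10))

    def test_best_move_per_subgraph(self):
        moves = [Move((1, 1), 0, 1, -5.0, src=(1, 2)),
                 Move((1, 2), 0, 1, -2.0, src=(1, 1))]
        sel = select_moves(self._graph(moves))
        assert len(sel) == 1 and sel[0].delta_e == -5.0

    def test_independent_subgraphs_both_selected(self):
        moves = [Move((1, 1), 0, 1, -5.0, src=(1, 2)),
                 Move((7, 7), 0, 1, -2.0, src=(7, 8))]
        sel = select_moves(self._graph(moves))
        assert len(sel) == 2
        assert [m.delta_e for m in sel] == [-5.0, -2.0]  # execution order

    def test_positive_moves_never_selected(self):
        moves = [Move((1, 1), 0, 1, 0.5, src=(1, 2))]
        assert select_moves(self._graph(moves)) == []

    def test_invariant_under_input_permutation(self, rng):
        pix = [(int(a), int(b)) for a, b in rng.integers(0, 9, size=(40, 2))]
        moves = [Move(p, 0, 1, float(rng.normal()), src=(p[0], (p[1] + 1) % 9))
                 for p in pix]
        ref = select_moves(self._graph(moves))
        for _ in range(3):
            perm = list(moves)
            rng.shuffle(perm)
            assert select_moves(self._graph(perm)) == ref

    def test_acceptance_fraction_caps_selection(self):
        moves = [Move((i, 0), 0, 1, -float(10 - i), src=(i, 1))
                 for i in range(0, 10, 2)]
        osc = OscillationState(acceptance_fraction=0.5)
        sel = select_moves(self._graph(moves), osc)
        assert len(sel) == 3  # ceil(0.5 * 5)
        assert sel[0].delta_e == -10.0


class TestOscillation:
    def test_reversal_flags_and_halves_fraction(self):
        osc = OscillationState()
        detect_oscillation(osc, [(10, 1, 0)])
        assert not osc.flagged
        detect_oscillation(osc, [(10, 0, 1)])
        assert osc.flagged
        assert osc.acceptance_fraction == 0.5

    def test_strictly_decreasing_energy_never_flags(self):
        osc = OscillationState()
        trace = list(np.linspace(100, 1, 30))
        for i in range(25):
            detect_oscillation(osc, [(i, 0, 1)], trace[:i + 2])
        assert osc.acceptance_fraction == 1.0

    def test_fraction_never_increases_and_floors(self):
        osc = OscillationState()
        for i in range(10):
            detect_oscillation(osc, [(5, 0, 1)])
            detect_oscillation(osc, [(5, 1, 0)])
        assert osc.acceptance_fraction == osc.f_min

    def test_persistent_two_cycle_gets_blacklisted(self):
        osc = OscillationState()
        for _ in range(4):
            detect_oscillation(osc, [(5, 0, 1)])
            detect_oscillation(osc, [(5, 1, 0)])
        assert (5, 0, 1) in osc.blacklist and (5, 1, 0) in osc.blacklist


class TestRunSequential:
    def test_already_converged_initialization(self):
        img = np.zeros((6, 6))
        img[2:4, 2:4] = 9.0
        init = (img > 0).astype(int)
        res = run_sequential(img, init, P_PC, max_iter=50)
        assert res.converged and res.iterations == 0
        assert len(res.trace) == 1
        assert np.array_equal(res.labels, init)

    def test_two_object_recovery(self):
        from drcseg.synthetic import make_unit_cell
        from drcseg.initializer import init_local_maxima
        from drcseg.io_cli import compare_labelings
        clean, truth, _ = make_unit_cell((48, 48), 2, seed=42, min_gap=6)
        img = clean / 255.0
        init = init_local_maxima(img, 5.0, 3)
        p = EnergyParams(lam=0.04, theta=0.02, r_kappa=4)
        res = run_sequential(img, init, p, max_iter=200)
        assert res.converged
        labs = [l for l in np.unique(res.labels) if l > 0]
        assert len(labs) == 2
        c = compare_labelings(truth, res.labels)
        assert min(c.jaccard.values()) >= 0.95

    def test_trace_non_increasing_without_damping(self):
        from drcseg.synthetic import make_unit_cell
        from drcseg.initializer import init_local_maxima
        clean, _, _ = make_unit_cell((48, 48), 3, seed=9, min_gap=6)
        img = clean / 255.0
        init = init_local_maxima(img, 5.0, 3)
        p = EnergyParams(lam=0.04, theta=0.02, r_kappa=4)
        res = run_sequential(img, init, p, max_iter=200)
        tr = np.asarray(res.trace.energies)
        assert np.all(np.diff(tr) <= 1e-9)

    def test_speck_vanishes_quickly(self):
        img = np.zeros((7, 7))
        init = np.zeros((7, 7), dtype=int)
        init[3, 3] = 1
        p = EnergyParams(lam=1.0, r_kappa=2)
        res = run_sequential(img, init, p, max_iter=10)
        assert res.converged and res.iterations <= 2
        assert not np.any(res.labels)

    def test_fg_labels_stay_connected(self, rng):
        from drcseg.synthetic import make_unit_cell
        from drcseg.initializer import init_local_maxima
        clean, _, _ = make_unit_cell((48, 48), 4, seed=13)
        img = clean / 255.0
        init = init_local_maxima(img, 5.0, 3)
        p = EnergyParams(lam=0.04, theta=0.02, r_kappa=4)
        res = run_sequential(img, init, p, max_iter=200)
        assert all(n == 1 for n in component_counts(res.labels).values())
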