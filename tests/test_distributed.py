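"""Distributed layer: label initialization, checkerboard move selection,
hot-particle re-labeling, and full-run equivalence."""

import numpy as np
import pytest
from scipy import ndimage

from drcseg.core import face_structure
from drcseg.energy import EnergyParams
from drcseg.initializer import init_local_maxima
from drcseg.io_cli import compare_labelings
from drcseg.optimizer import ExecResult, MoveGraph, _pixel_components, \
    run_sequential
from drcseg.distributed import (SimRuntime, _enumerate_local,
                                contour_propagation_step,
                                initial_global_labels, partition_subgraphs,
                                relabel_regions, run_distributed,
                                _stats_copies)
from drcseg.synthetic import add_noise, make_unit_cell

from conftest import (labelings_equal_up_to_bijection, random_label_field)

P_PC = EnergyParams(model="pc", noise="gaussian", lam=0.04, theta=0.02,
                    r_kappa=4)


def _fixture(seed, shape=(48, 48), n=4):
    clean, truth, _ = make_unit_cell(shape, n, seed=seed)
    img = add_noise(clean, "gaussian", 5.0, seed=seed + 100) / 255.0
    init = init_local_maxima(clean / 255.0, 5.0, 3)
    return img, init


class TestInitialGlobalLabels:
    def _run(self, field, dims, img=None):
        img = np.zeros(field.shape) if img is None else img
        rt = SimRuntime(img, field, P_PC, dims, g=1)
        initial_global_labels(rt)
        return rt

    def test_region_inside_one_block_keeps_single_label(self):
        field = np.zeros((12, 12), dtype=int)
        field[1:4, 1:4] = 7
        rt = self._run(field, (2, 2))
        out = rt.gather_labels()
        assert len(np.unique(out[field > 0])) == 1
        assert rt.runstats.init_rounds == 0

    def test_min_label_wins_across_blocks(self):
        field = np.zeros((12, 12), dtype=int)
        field[5:8, 2:10] = 3  # spans both column blocks
        rt = self._run(field, (1, 2))
        out = rt.gather_labels()
        labs = np.unique(out[field > 0])
        assert len(labs) == 1
        assert labs[0] == 1  # rank 0's first local label: 0 + 1 + 0*P

    @pytest.mark.parametrize("ndim,dims", [(2, (3, 3)), (3, (2, 2, 2))])
    def test_matches_flood_fill_oracle(self, rng, ndim, dims):
        shape = (15,) * ndim if ndim == 2 else (8,) * ndim
        for _ in range(20):
            field = random_label_field(rng, shape)
            rt = self._run(field, dims)
            out = rt.gather_labels()
            oracle, _ = ndimage.label(field > 0,
                                      structure=face_structure(ndim))
            assert labelings_equal_up_to_bijection(out, oracle)
            assert rt.runstats.init_rounds <= int(np.prod(dims))


class TestPartitionSubgraphs:
    def _graphs(self, rt):
        rt.stats_global = rt.allreduce_stats()
        _stats_copies(rt)
        out = {}
        for s in rt.states:
            arrays, _ = _enumerate_local(rt, s)
            graph = MoveGraph(arrays, _pixel_components(arrays))
            out[s.rank] = (graph, partition_subgraphs(graph, s))
        return out

    def test_deep_interior_object_is_interior_everywhere(self):
        img = np.full((24, 24), 10 / 255)
        img[4:8, 4:8] = 200 / 255
        init = np.zeros((24, 24), dtype=int)
        init[5:7, 5:7] = 1
        rt = SimRuntime(img, init, P_PC, (2, 2), g=2)
        graphs = self._graphs(rt)
        g0, p0 = graphs[0]
        assert len(p0.boundary) == 0 and len(p0.interior) > 0

    def test_straddling_object_is_boundary_on_both_ranks(self):
        img = np.full((24, 24), 10 / 255)
        img[10:14, 8:16] = 200 / 255  # crosses the row-block boundary at 12
        init = np.zeros((24, 24), dtype=int)
        init[10:14, 8:16] = 1
        rt = SimRuntime(img, init, P_PC, (2, 1), g=2)
        graphs = self._graphs(rt)
        for r in (0, 1):
            _, part = graphs[r]
            assert len(part.boundary) >= 1


class TestContourPropagation:
    def test_black_decision_has_priority_on_shared_subgraph(self):
        # two regions compete for one gap pixel across the block boundary;
        # the black rank decides, the white rank accepts verbatim
        img = np.full((8, 12), 10 / 255.0)
        init = np.zeros((8, 12), dtype=np.int32)
        img[1:3, 4:6] = 200 / 255.0
        init[1:3, 4:6] = 1          # region 1 ends at column 5 (black rank)
        img[1:3, 7:9] = 195 / 255.0
        init[1:3, 7:9] = 2          # region 2 starts at column 7 (white rank)
        img[1:3, 6] = 190 / 255.0   # the contested gap column
        p = EnergyParams(model="pc", noise="gaussian", lam=0.0, theta=1000.0,
                         r_kappa=2)
        rt = SimRuntime(img, init, p, (1, 2), g=3)
        initial_global_labels(rt)
        from drcseg.decomposition import exchange_ghosts
        exchange_ghosts(rt.states, rt.grid, "labels")
        exchange_ghosts(rt.states, rt.grid, "image")
        rt.stats_global = rt.allreduce_stats()
        rt.alloc_base = 2
        rt.scratch["_messages"] = 0
        _stats_copies(rt)
        executed = contour_propagation_step(rt)
        # the white rank received the black decision for its boundary
        # sub-graph and executed it without adding a conflicting move
        assert rt.scratch[1]["received"], "white rank received no decision"
        whites_own = rt.scratch[1]["own_sel"]
        rec_pixels = {d.v for d in rt.scratch[1]["received"]}
        for d in whites_own:
            assert d.v not in rec_pixels

    def test_no_cross_rank_pixel_conflicts(self, rng):
        img, init = _fixture(31)
        rt = SimRuntime(img, init, P_PC, (2, 2))
        initial_global_labels(rt)
        from drcseg.decomposition import exchange_ghosts
        exchange_ghosts(rt.states, rt.grid, "labels")
        exchange_ghosts(rt.states, rt.grid, "image")
        rt.stats_global = rt.allreduce_stats()
        rt.alloc_base = int(rt.gather_labels().max())
        rt.scratch["_messages"] = 0
        _stats_copies(rt)
        executed = contour_propagation_step(rt)
        seen = {}
        for r, decs in executed.items():
            for d in decs:
                assert d.v not in seen, "two ranks executed the same pixel"
                seen[d.v] = r


class TestRelabelRegions:
    def _chain_runtime(self, r_blocks, bar_label=5, other_label=7):
        shape = (6, 8 * r_blocks)
        field = np.zeros(shape, dtype=np.int32)
        field[2:4, :] = bar_label          # spans every block
        field[0, 0:3] = other_label        # untouched region in block 0
        img = np.zeros(shape)
        rt = SimRuntime(img, field, P_PC, (1, r_blocks), g=1)
        for s in rt.states:
            rt.scratch[s.rank] = {
                "shell_pre": s.labels_loc[s.owned].copy(),
                "exec": ExecResult([], [], 0),
            }
        return rt, field

    def test_no_changes_zero_rounds_zero_messages(self):
        rt, _ = self._chain_runtime(3)
        relabel_regions(rt)
        assert rt.scratch["_rounds"] == 0
        assert rt.scratch["_hot"] == 0

    @pytest.mark.parametrize("r_blocks", [2, 3, 4, 5, 6])
    def test_chain_propagates_in_r_minus_one_rounds(self, r_blocks):
        rt, field = self._chain_runtime(r_blocks)
        # a fusion on rank 0 lowered the bar's label from 5 to 2
        s0 = rt.states[0]
        s0.labels_loc[s0.labels_loc == 5] = 2
        rt.scratch[0]["exec"] = ExecResult([], [(5, 2)], 0)
        relabel_regions(rt)
        out = rt.gather_labels()
        assert np.all(out[field == 5] == 2)     # min-label inheritance
        assert np.all(out[field == 7] == 7)     # untouched region keeps label
        assert rt.scratch["_rounds"] == r_blocks - 1

    def test_split_assigns_new_label_to_detached_component_only(self):
        # a region spanning two blocks splits inside block 0; the detached
        # far part must be re-labeled across the boundary, others untouched
        shape = (6, 16)
        field = np.zeros(shape, dtype=np.int32)
        field[2, :] = 5
        field[0, 0:3] = 7
        img = np.zeros(shape)
        rt = SimRuntime(img, field, P_PC, (1, 2), g=1)
        for s in rt.states:
            rt.scratch[s.rank] = {
                "shell_pre": s.labels_loc[s.owned].copy(),
                "exec": ExecResult([], [], 0),
            }
        s0 = rt.states[0]
        # the split: pixel (2, 3) left the region, right part gets label 9
        s0.labels_loc[2, s0.g + 3] = 0
        loc_cols = np.arange(s0.labels_loc.shape[1])
        right = (s0.labels_loc == 5)
        right[:, :s0.g + 4] = False
        s0.labels_loc[right] = 9
        rt.scratch[0]["exec"] = ExecResult([(0, 5, 0)], [(5, 9)], 1)
        relabel_regions(rt)
        out = rt.gather_labels()
        assert np.all(out[2, 4:] == 9)          # detached part renamed
        assert np.all(out[2, :3] == 5)          # kept part unchanged
        assert np.all(out[0, 0:3] == 7)


class TestRunDistributed:
    @pytest.mark.parametrize("seed", [31, 32])
    def test_single_rank_bit_identical_to_sequential(self, seed):
        img, init = _fixture(seed)
        seq = run_sequential(img, init, P_PC, max_iter=300)
        dist = run_distributed(img, init, P_PC, (1, 1), max_iter=300)
        assert np.array_equal(seq.labels, dist.labels)
        assert seq.trace.energies == dist.trace.energies

    def test_four_ranks_agree_with_sequential(self):
        img, init = _fixture(33)
        seq = run_sequential(img, init, P_PC, max_iter=300)
        dist = run_distributed(img, init, P_PC, (2, 2), max_iter=300)
        assert dist.converged
        c = compare_labelings(seq.labels, dist.labels)
        assert c.n_diff_pixels <= 3

    def test_schedule_invariance(self):
        img, init = _fixture(34)
        ref = run_distributed(img, init, P_PC, (2, 2), max_iter=300)
        for order in ([3, 1, 2, 0], [2, 0, 3, 1]):
            alt = run_distributed(img, init, P_PC, (2, 2),
                                  rt_config={"order": order}, max_iter=300)
            assert np.array_equal(ref.labels, alt.labels)
            assert ref.trace.energies == alt.trace.energies

    def test_interior_workload_generates_no_hot_traffic(self):
        # all objects away from block boundaries: after initialization no
        # hot particles should ever be exchanged
        clean, truth, _ = make_unit_cell((48, 48), 2, seed=79, min_gap=6,
                                         semi_axis_range=(4.0, 6.0))
        img = clean / 255.0
        init = init_local_maxima(img, 5.0, 3)
        # the fixture's objects stay clear of the block boundaries at 24
        fg_rows = np.unique(np.nonzero(truth)[0])
        fg_cols = np.unique(np.nonzero(truth)[1])
        assert not np.any(np.abs(fg_rows - 24) < 6)
        assert not np.any(np.abs(fg_cols - 24) < 6)
        dist = run_distributed(img, init, P_PC, (2, 2), max_iter=300)
        assert dist.converged
        assert sum(dist.stats.hot_particles) == 0

    def test_runstats_csv_schema(self, tmp_path):
        img, init = _fixture(35)
        dist = run_distributed(img, init, P_PC, (2, 2), max_iter=300)
        out = tmp_path / "stats.csv"
        dist.stats.to_csv(out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns) == ["iteration", "energy", "accepted_moves",
                                    "messages", "hot_particles",
                                    "relabel_rounds"]
        assert len(df) == dist.iterations
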