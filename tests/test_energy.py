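"""Energy terms and exact single-move energy differences."""

import numpy as np
import pytest

from drcseg.core import RegionStats, region_statistics
from drcseg.energy import (EnergyParams, ball_offsets, delta_energy,
                           delta_length, merge_allowed, total_energy)

from conftest import random_label_field


def _params(model="pc", noise="gaussian", **kw):
    base = dict(model=model, noise=noise, lam=0.0, theta=0.0, r_kappa=2)
    if model == "ps":
        base["radius"] = kw.pop("radius", 2)
    base.update(kw)
    return EnergyParams(**base)


def _random_instance(rng, shape, model):
    img = rng.uniform(0.5, 10.0, size=shape)
    lab = random_label_field(rng, shape)
    return img, lab


def _admissible_moves(lab):
    """All (pixel, l_from, l_to) relabelings toward a face-neighbour label."""
    out = []
    for pt in np.ndindex(*lab.shape):
        nb = set()
        for ax in range(lab.ndim):
            for d in (-1, 1):
                q = list(pt)
                q[ax] += d
                if 0 <= q[ax] < lab.shape[ax]:
                    nb.add(int(lab[tuple(q)]))
        for m in sorted(nb):
            if m != lab[pt] and (lab[pt] > 0 or m > 0):
                out.append((pt, int(lab[pt]), m))
    return out


class TestTotalEnergy:
    def test_perfect_pc_labeling_zero_data(self):
        img = np.zeros((6, 6))
        img[1:3, 1:3] = 7.0
        lab = (img > 0).astype(int)
        p = _params(lam=0.0)
        assert total_energy(img, lab, p) == pytest.approx(0.0, abs=1e-12)

    def test_length_prior_counts_pairs(self):
        # 2x2 foreground square: 8 face pairs against other labels
        img = np.zeros((4, 4))
        img[1:3, 1:3] = 7.0
        lab = (img > 0).astype(int)
        p = _params(lam=0.5)
        assert total_energy(img, lab, p) == pytest.approx(0.5 * 8)

    @pytest.mark.parametrize("noise", ["gaussian", "poisson"])
    def test_truth_beats_random_perturbations(self, rng, noise):
        img = np.full((8, 8), 2.0)
        img[2:6, 2:6] = 9.0
        truth = (img > 5).astype(int)
        p = _params(noise=noise)
        e_truth = total_energy(img, truth, p)
        fg = np.argwhere(truth > 0)
        for k in range(10):
            pert = truth.copy()
            i = rng.integers(len(fg))
            pert[tuple(fg[i])] = 0
            assert total_energy(img, pert, p) > e_truth

    def test_label_permutation_invariance(self, rng):
        img, lab = _random_instance(rng, (8, 8), "pc")
        p = _params()
        perm = lab.copy()
        labs = [l for l in np.unique(lab) if l > 0]
        for i, l in enumerate(labs):
            perm[lab == l] = labs[(i + 1) % len(labs)]
        assert total_energy(img, lab, p) == pytest.approx(
            total_energy(img, perm, p), rel=1e-12)

    def test_level_set_partition_is_global_optimum(self):
        # exhaustive over all 2-level labelings of a 3x3 two-level image
        img = np.array([[1.0, 1.0, 9.0],
                        [1.0, 9.0, 9.0],
                        [1.0, 1.0, 9.0]])
        truth = (img > 5).astype(int)
        p = _params()
        best = min(range(512), key=lambda b: total_energy(
            img, np.array([(b >> i) & 1 for i in range(9)]).reshape(3, 3), p))
        best_lab = np.array([(best >> i) & 1 for i in range(9)]).reshape(3, 3)
        assert (np.array_equal(best_lab, truth)
                or np.array_equal(best_lab, 1 - truth))


class TestDeltaEnergy:
    def test_fixing_mislabeled_pixel_improves(self):
        img = np.zeros((5, 5))
        img[1:4, 1:4] = 8.0
        lab = (img > 0).astype(int)
        lab[2, 2] = 0  # mislabel one interior pixel as background
        st = region_statistics(img, lab)
        d = delta_energy(img, lab, st, (2, 2), 0, 1, _params())
        assert d < 0

    def test_four_pixel_example_matches_oracle(self):
        img = np.array([[10.0, 10.0, 0.0, 0.0]])
        lab = np.array([[1, 1, 1, 0]])
        p = _params()
        st = region_statistics(img, lab)
        d = delta_energy(img, lab, st, (0, 2), 1, 0, p)
        after = lab.copy()
        after[0, 2] = 0
        oracle = total_energy(img, after, p) - total_energy(img, lab, p)
        assert d == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("model,noise", [("pc", "gaussian"),
                                             ("pc", "poisson"),
                                             ("ps", "gaussian"),
                                             ("ps", "poisson")])
    @pytest.mark.parametrize("ndim", [2, 3])
    def test_matches_total_energy_difference(self, rng, model, noise, ndim):
        shape = (8,) * ndim if ndim == 2 else (5,) * ndim
        p = _params(model, noise, lam=0.3, beta=0.1 if model == "ps" else 0.0)
        for _ in range(6):
            img, lab = _random_instance(rng, shape, model)
            st = region_statistics(img, lab)
            moves = _admissible_moves(lab)
            rng.shuffle(moves)
            for (pt, lf, lt) in moves[:6]:
                d = delta_energy(img, lab, st, pt, lf, lt, p)
                after = lab.copy()
                after[pt] = lt
                oracle = (total_energy(img, after, p)
                          - total_energy(img, lab, p))
                assert d == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_reversibility(self, rng):
        img, lab = _random_instance(rng, (7, 7), "pc")
        st = region_statistics(img, lab)
        p = _params(lam=0.2)
        for (pt, lf, lt) in _admissible_moves(lab)[:10]:
            d1 = delta_energy(img, lab, st, pt, lf, lt, p)
            after = lab.copy()
            after[pt] = lt
            st2 = region_statistics(img, after)
            d2 = delta_energy(img, after, st2, pt, lt, lf, p)
            assert d1 + d2 == pytest.approx(0.0, abs=1e-9)

    def test_rejects_invalid_moves(self):
        img = np.zeros((3, 3))
        lab = np.zeros((3, 3), dtype=int)
        lab[1, 1] = 1
        st = region_statistics(img, lab)
        with pytest.raises(ValueError):
            delta_energy(img, lab, st, (1, 1), 1, 1, _params())
        with pytest.raises(ValueError):
            delta_energy(img, lab, st, (0, 0), 0, 1, _params())  # not adjacent


class TestDeltaLength:
    def test_ball_size_at_radius_one(self):
        assert len(ball_offsets(1, 2)) == 5  # center + 4 face neighbours

    def test_straight_edge_is_neutral(self):
        lab = np.zeros((11, 11), dtype=int)
        lab[:, :5] = 1  # half plane
        # grow the half-plane by one pixel at the middle of the edge
        v = delta_length(lab, (5, 5), 0, 1, 3)
        # neutral up to the discretization bias of the center column
        assert abs(v) <= (2 * 3 + 1) / len(ball_offsets(3, 2))

    def test_protrusion_is_penalized(self):
        lab = np.zeros((11, 11), dtype=int)
        lab[:, :5] = 1
        lab[5, 5] = 1  # one-pixel protrusion
        # growing the protrusion further sharpens the contour
        v = delta_length(lab, (5, 6), 0, 1, 3)
        assert v > 0

    def test_filling_concavity_is_favored(self):
        lab = np.zeros((11, 11), dtype=int)
        lab[:, :5] = 1
        lab[5, 4] = 0  # one-pixel pit in the edge
        v = delta_length(lab, (5, 4), 0, 1, 3)
        assert v < 0


class TestMergeAllowed:
    def _stats(self, mu_a, mu_b):
        st = RegionStats(2)
        st.n[1], st.s[1] = 10, mu_a * 10
        st.n[2], st.s[2] = 10, mu_b * 10
        return st

    def test_equal_means_always_allowed(self):
        st = self._stats(4.0, 4.0)
        assert merge_allowed(st, 1, 2, _params(theta=0.0))

    def test_zero_threshold_strict(self):
        st = self._stats(4.0, 4.1)
        assert not merge_allowed(st, 1, 2, _params(theta=0.0))

    def test_threshold_boundary_inclusive(self):
        p = EnergyParams(theta=0.5)
        for dmu in np.linspace(0.0, 1.0, 21):
            st = self._stats(4.0, 4.0 + dmu)
            assert merge_allowed(st, 1, 2, p) == (dmu <= 0.5 + 1e-12)

    def test_unknown_label_raises(self):
        st = self._stats(1.0, 2.0)
        with pytest.raises(KeyError):
            merge_allowed(st, 1, 7, _params())


class TestParamValidation:
    def test_ps_requires_radius(self):
        with pytest.raises(ValueError):
            EnergyParams(model="ps", radius=0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(lam=-0.1)
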