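"""Component labeling, mixture-model thresholding, Dice, pairing, partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovasc.decompose import ICADecomposition
from neurovasc.identify import (
    BinaryMask,
    dice_coefficient,
    find_neural_components,
    mixture_model_threshold,
    pair_components,
    partition_voxels,
)
from neurovasc.paradigm import Regressor, ValidationError
from neurovasc.preprocess import BOLDDataset

GRID = (12, 12, 8)
NVOX = int(np.prod(GRID))
T = 60


def make_decomp(ts_cols, maps=None, seed=0):
    """ICADecomposition with given timecourse columns and optional maps."""
    rng = np.random.default_rng(seed)
    n = len(ts_cols)
    ts = np.column_stack(ts_cols)
    if maps is None:
        maps = rng.standard_normal((n, NVOX))
    return ICADecomposition(maps=np.asarray(maps, float), timeseries=ts,
                            mask=np.ones(GRID, bool), tr_s=2.0, n_comp=n)


def blob_map(center, width=120, amp=6.0, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal(NVOX)
    idx = (center + np.arange(width)) % NVOX
    m[idx] += amp
    return m


@pytest.fixture
def regs():
    rng = np.random.default_rng(42)
    wm = np.sin(2 * np.pi * np.arange(T) / 20)
    vis = np.cos(2 * np.pi * np.arange(T) / 14)
    return (Regressor("working_memory", wm, 2.0),
            Regressor("visual", vis, 2.0), rng)


class TestFindNeuralComponents:
    def test_extreme_correlations_win(self, regs):
        wm, vis, rng = regs
        noise = [rng.standard_normal(T) for _ in range(2)]
        decomp = make_decomp([noise[0], -wm.values, wm.values, vis.values,
                              noise[1]])
        labels = find_neural_components(decomp, wm, vis)
        assert labels["DMN"][0] == 1 and labels["DMN"][1] == pytest.approx(-1)
        assert labels["TPN"][0] == 2 and labels["TPN"][1] == pytest.approx(1)
        assert labels["VN"][0] == 3 and labels["VN"][1] == pytest.approx(1)

    def test_collision_reports_correlations(self, regs):
        wm, vis, rng = regs
        # one component maximally correlated with both stimuli
        both = wm.values + vis.values
        decomp = make_decomp([both, -wm.values, rng.standard_normal(T)])
        # make vis's argmax collide with TPN's argmax
        with pytest.raises(ValidationError, match="collision"):
            find_neural_components(decomp, wm, Regressor("visual", both, 2.0))

    def test_length_mismatch_rejected(self, regs):
        wm, vis, rng = regs
        decomp = make_decomp([rng.standard_normal(T)])
        short = Regressor("working_memory", wm.values[:-5], 2.0)
        with pytest.raises(ValidationError):
            find_neural_components(decomp, short, vis)


class TestMixtureModelThreshold:
    def test_pure_null_map_selects_almost_nothing(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        sel, _ = mixture_model_threshold(x)
        assert sel.sum() < 0.02 * x.size

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        planted = np.zeros(5000, bool)
        planted[rng.choice(5000, 500, replace=False)] = True
        x[planted] += 4.0
        sel, info = mixture_model_threshold(x)
        jac = (sel & planted).sum() / (sel | planted).sum()
        assert jac >= 0.8
        assert info["method"] == "mixture"

    def test_level_one_gives_empty_mask(self):
        rng = np.random.default_rng(2)
        sel, _ = mixture_model_threshold(rng.standard_normal(2000), level=1.0)
        assert not sel.any()

    def test_subgaussian_map_falls_back(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 5000)   # flat map: no separable tail class
        sel, info = mixture_model_threshold(x)
        assert sel.sum() < 0.05 * x.size

    def test_small_map_rejected(self):
        with pytest.raises(ValidationError):
            mixture_model_threshold(np.zeros(100))


class TestDice:
    def _mask(self, flat):
        return BinaryMask.from_flat(np.asarray(flat, bool), np.ones(GRID, bool))

    def test_identical_nonempty_is_one(self):
        a = np.zeros(NVOX, bool)
        a[:50] = True
        assert dice_coefficient(self._mask(a), self._mask(a)) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros(NVOX, bool); a[:50] = True
        b = np.zeros(NVOX, bool); b[50:100] = True
        assert dice_coefficient(self._mask(a), self._mask(b)) == 0.0

    def test_two_two_one_case(self):
        a = np.zeros(NVOX, bool); a[[0, 1]] = True
        b = np.zeros(NVOX, bool); b[[1, 2]] = True
        assert dice_coefficient(self._mask(a), self._mask(b)) == 0.5

    def test_both_empty_defined_as_zero(self):
        z = np.zeros(NVOX, bool)
        assert dice_coefficient(self._mask(z), self._mask(z)) == 0.0

    def test_grid_mismatch_rejected(self):
        a = BinaryMask(grid=np.zeros((2, 2, 2), bool))
        b = BinaryMask(grid=np.zeros((3, 2, 2), bool))
        with pytest.raises(ValidationError):
            dice_coefficient(a, b)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = self._mask(rng.random(NVOX) < 0.2)
        b = self._mask(rng.random(NVOX) < 0.2)
        d1, d2 = dice_coefficient(a, b), dice_coefficient(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


class TestPairComponents:
    def _setup(self, regs, extra_maps=None, seed=0):
        wm, vis, _ = regs
        rng = np.random.default_rng(seed)
        maps = [blob_map(0, seed=1), blob_map(200, seed=2), blob_map(400, seed=3)]
        ts = [-wm.values, wm.values, vis.values]
        if extra_maps is not None:
            maps += extra_maps
            ts += [rng.standard_normal(T) for _ in extra_maps]
        return make_decomp(ts, maps=np.stack(maps)), wm, vis

    def test_duplicate_mask_pairs_with_dice_one(self, regs):
        decomp, wm, vis = self._setup(regs, extra_maps=[blob_map(0, seed=1)])
        labels = find_neural_components(decomp, wm, vis)
        pairs, masks = pair_components(decomp, labels)
        dmn = next(p for p in pairs if p.label == "DMN")
        assert dmn.vascular_idx == 3
        assert dmn.dice == pytest.approx(1.0)

    def test_all_disjoint_flags_unmatched(self, regs):
        decomp, wm, vis = self._setup(regs)
        labels = find_neural_components(decomp, wm, vis)
        pairs, masks = pair_components(decomp, labels, exclude_neural=True)
        assert all(not p.matched and p.vascular_idx is None for p in pairs)

    def test_pairing_invariant_to_component_permutation(self, regs):
        decomp, wm, vis = self._setup(
            regs, extra_maps=[blob_map(10, seed=1), blob_map(210, seed=2)])
        labels = find_neural_components(decomp, wm, vis)
        pairs, _ = pair_components(decomp, labels)
        perm = np.array([4, 2, 0, 1, 3])
        permuted = ICADecomposition(
            maps=decomp.maps[perm], timeseries=decomp.timeseries[:, perm],
            mask=decomp.mask, tr_s=2.0, n_comp=decomp.n_comp)
        labels_p = find_neural_components(permuted, wm, vis)
        pairs_p, _ = pair_components(permuted, labels_p)
        inv = np.argsort(perm)
        for p, q in zip(sorted(pairs, key=lambda x: x.label),
                        sorted(pairs_p, key=lambda x: x.label)):
            assert q.neural_idx == inv[p.neural_idx]
            if p.vascular_idx is None:
                assert q.vascular_idx is None
            else:
                assert q.vascular_idx == inv[p.vascular_idx]
            assert q.dice == pytest.approx(p.dice)


class TestPartitionVoxels:
    def _pair_and_masks(self, a, b):
        from neurovasc.identify import ComponentPair
        masks = [BinaryMask.from_flat(a, np.ones(GRID, bool)),
                 BinaryMask.from_flat(b, np.ones(GRID, bool))]
        pair = ComponentPair(label="VN", neural_idx=0, vascular_idx=1,
                             dice=0.0, neural_corr=1.0)
        return pair, masks

    def test_identical_masks_all_common(self):
        a = np.zeros(NVOX, bool); a[:60] = True
        pair, masks = self._pair_and_masks(a, a.copy())
        regions, _ = partition_voxels(pair, masks)
        assert regions["unique_neural"].count == 0
        assert regions["unique_vascular"].count == 0
        assert regions["common"].count == 60

    def test_disjoint_masks_no_common(self):
        a = np.zeros(NVOX, bool); a[:60] = True
        b = np.zeros(NVOX, bool); b[60:120] = True
        pair, masks = self._pair_and_masks(a, b)
        regions, _ = partition_voxels(pair, masks)
        assert regions["common"].count == 0
        assert regions["unique_neural"].count == 60

    def test_region_timeseries_extracted_and_empty_flagged(self):
        a = np.zeros(NVOX, bool); a[:60] = True
        pair, masks = self._pair_and_masks(a, a.copy())
        data = np.zeros(GRID + (20,), np.float32)
        data[masks[0].grid] = 1.5
        ds = BOLDDataset(data=data, tr_s=2.0, units="percent_bold")
        regions, ts = partition_voxels(pair, masks, dataset=ds)
        assert np.allclose(ts["common"], 1.5)
        assert "unique_neural" not in ts  # empty region omitted
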