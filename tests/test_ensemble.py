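import numpy as np
import pytest

from interpsplit import metrics, phantom, tiling
from interpsplit.ensemble import (
    EnsembleConfig,
    TrainingConfig,
    binarize,
    ensemble_union,
    largest_connected_component,
    predict_volume,
    run_interpolation_split,
    threshold_opening_backend,
    trainable_backend,
    SegmenterBackend,
)


class TestEnsembleConfig:
    def test_defaults(self):
        cfg = EnsembleConfig()
        assert cfg.irs == (1, 2, 4, 8)
        assert cfg.binarize_threshold == 0.5
        assert cfg.connectivity == 26

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"irs": ()},
            {"irs": (0, 1)},
            {"binarize_threshold": 0.0},
            {"binarize_threshold": 1.0},
            {"connectivity": 4},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            EnsembleConfig(**kwargs)


class TestThresholdOpeningBackend:
    def test_all_bright_tile_empty(self):
        be = threshold_opening_backend(tau=80, opening_radius=1)
        out = be.predict(np.full((64, 64), 200.0))
        assert out.shape == (64, 64)
        assert out.sum() == 0

    def test_two_pixel_line_removed(self):
        tile = np.full((64, 64), 200.0)
        tile[:, 30:32] = 0.0  # 2 px wide dark line
        be = threshold_opening_backend(tau=128, opening_radius=1)
        assert be.predict(tile).sum() == 0

    def test_upsampled_line_retained(self):
        tile = np.full((64, 64), 200.0)
        tile[:, 30:32] = 0.0
        up = tiling.upsample_image(tile, 2)  # line now ~4 px wide
        be = threshold_opening_backend(tau=128, opening_radius=1)
        assert be.predict(up).sum() > 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            threshold_opening_backend(tau=300, opening_radius=1)

    def test_output_is_binary_probability(self, rng):
        be = threshold_opening_backend(tau=128, opening_radius=0)
        out = be.predict(rng.random((16, 16)) * 255)
        assert set(np.unique(out)) <= {0.0, 1.0}


@pytest.fixture(scope="module")
def tile_pairs():
    spec = phantom.PhantomSpec(grid_shape=(28, 32, 32), generations=1,
                               root_radius=4.0, length_root=12.0, seed=5)
    vol = phantom.generate_phantom(spec)
    from interpsplit.io import Volume, window_level_normalize

    norm = window_level_normalize(Volume(vol.image)).data
    return [(norm[k], vol.lumen_mask[k]) for k in (4, 6, 8, 10)]


class TestTrainableBackend:
    def test_smoke_train_checkpoint(self, tile_pairs, tmp_path):
        ckpt = tmp_path / "weights.npz"
        be = trainable_backend(tile_pairs, TrainingConfig(epochs=1), checkpoint_path=ckpt)
        assert ckpt.exists()
        assert np.isfinite(be.predict.best_loss)

    def test_overfit_small_set(self, tile_pairs):
        be = trainable_backend(tile_pairs, TrainingConfig(epochs=50, learning_rate=0.5))
        assert be.predict.best_loss < 0.1

    def test_determinism(self, tile_pairs):
        cfg = TrainingConfig(epochs=10, seed=3)
        b1 = trainable_backend(tile_pairs, cfg)
        b2 = trainable_backend(tile_pairs, cfg)
        assert b1.predict.history == b2.predict.history

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            trainable_backend([])

    def test_invalid_learning_rate(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)


class TestPredictVolume:
    def test_identity_backend_ir1(self, rng):
        vol = rng.random((3, 32, 32)) * 255
        be = SegmenterBackend("identity", lambda t: np.asarray(t) / 255.0)
        out = predict_volume(vol, be, ir=1, tile_size=32)
        np.testing.assert_allclose(out, vol / 255.0)

    def test_constant_zero_backend(self, rng):
        vol = rng.random((2, 16, 16)) * 255
        be = SegmenterBackend("zero", lambda t: np.zeros_like(np.asarray(t)))
        assert predict_volume(vol, be, ir=2, tile_size=16).sum() == 0

    def test_out_of_range_backend_rejected(self, rng):
        vol = rng.random((1, 16, 16))
        be = SegmenterBackend("bad", lambda t: np.full_like(np.asarray(t), 2.0))
        with pytest.raises(ValueError):
            predict_volume(vol, be, ir=1, tile_size=16)

    def test_terminal_branches_found_only_when_magnified(
        self, desk_phantom, desk_spec, normalized_phantom
    ):
        max_gen = max(b.generation for b in desk_phantom.branches)
        terminal = [b for b in desk_phantom.branches if b.generation == max_gen]
        terminal_mask = phantom.rasterize(terminal, desk_spec).lumen_mask
        be = threshold_opening_backend(tau=60, opening_radius=2)
        hits = {}
        for ir in (1, 4):
            mask = binarize(predict_volume(normalized_phantom, be, ir, 64), 0.5)
            hits[ir] = int((mask & terminal_mask).sum())
        assert hits[4] > hits[1]


class TestBinarize:
    def test_ties_go_to_background(self):
        out = binarize(np.full((2, 2, 2), 0.5), 0.5)
        assert out.sum() == 0

    def test_hard_probabilities_unchanged(self, rng):
        p = (rng.random((2, 4, 4)) > 0.5).astype(float)
        for theta in (0.1, 0.5, 0.9):
            np.testing.assert_array_equal(binarize(p, theta), p.astype(np.uint8))

    def test_monotone_in_threshold(self, rng):
        p = rng.random((3, 8, 8))
        low = binarize(p, 0.3)
        high = binarize(p, 0.7)
        assert ((high == 1) <= (low == 1)).all()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((1, 1, 1)), 1.0)


class TestEnsembleUnion:
    def test_single_mask(self, rng):
        m = (rng.random((2, 4, 4)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(ensemble_union([m]), m)

    def test_disjoint_counts(self):
        a = np.zeros((2, 4, 4), dtype=np.uint8)
        b = np.zeros((2, 4, 4), dtype=np.uint8)
        a.ravel()[:5] = 1
        b.ravel()[10:13] = 1
        assert ensemble_union([a, b]).sum() == 8

    def test_superset_property(self, rng):
        masks = [(rng.random((2, 6, 6)) > 0.6).astype(np.uint8) for _ in range(3)]
        u = ensemble_union(masks)
        for m in masks:
            assert ((m == 1) <= (u == 1)).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ensemble_union([np.zeros((2, 2, 2)), np.zeros((2, 2, 3))])


class TestLargestConnectedComponent:
    def test_keeps_larger(self):
        m = np.zeros((3, 8, 8), dtype=np.uint8)
        m[0, 0:5, 0] = 1  # 5 voxels
        m[2, 0:3, 7] = 1  # 3 voxels
        out = largest_connected_component(m)
        assert out.sum() == 5
        assert out[0, 0, 0] == 1 and out[2, 0, 7] == 0

    def test_single_component_identity(self):
        m = np.zeros((2, 4, 4), dtype=np.uint8)
        m[:, 1:3, 1:3] = 1
        np.testing.assert_array_equal(largest_connected_component(m), m)

    def test_output_connected(self, rng):
        from scipy import ndimage as ndi

        m = (rng.random((6, 10, 10)) > 0.7).astype(np.uint8)
        out = largest_connected_component(m, connectivity=26)
        _, n = ndi.label(out, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = largest_connected_component(np.zeros((2, 2, 2), dtype=np.uint8))
        assert out.sum() == 0
        assert "empty" in caplog.text

    def test_tie_broken_by_raster_order(self):
        m = np.zeros((1, 5, 5), dtype=np.uint8)
        m[0, 0, 0:2] = 1
        m[0, 4, 3:5] = 1
        out = largest_connected_component(m)
        assert out[0, 0, 0] == 1 and out[0, 4, 3] == 0

    def test_connectivity_6_vs_26(self):
        m = np.zeros((2, 2, 2), dtype=np.uint8)
        m[0, 0, 0] = 1
        m[1, 1, 1] = 1  # diagonal touch: one component at 26, two at 6
        assert largest_connected_component(m, 26).sum() == 2
        assert largest_connected_component(m, 6).sum() == 1


class TestRunInterpolationSplit:
    def test_degenerate_single_ratio(self, normalized_phantom, desk_phantom):
        be = threshold_opening_backend(tau=60, opening_radius=2)
        cfg = EnsembleConfig(irs=(1,), tile_size=64)
        res = run_interpolation_split(normalized_phantom, be, cfg,
                                      gt_mask=desk_phantom.lumen_mask)
        direct = binarize(predict_volume(normalized_phantom, be, 1, 64), 0.5)
        np.testing.assert_array_equal(
            res.final_mask, largest_connected_component(direct)
        )
        assert res.case_result.dsc_per_config["ensemble"] == pytest.approx(
            res.case_result.dsc_per_config["ir1"]
        )

    def test_ensemble_beats_baseline_on_phantom(self, normalized_phantom, desk_phantom):
        be = threshold_opening_backend(tau=60, opening_radius=2)
        cfg = EnsembleConfig(irs=(1, 2, 4, 8), tile_size=64)
        res = run_interpolation_split(normalized_phantom, be, cfg,
                                      gt_mask=desk_phantom.lumen_mask)
        assert res.case_result.dsc_per_config["ensemble"] > res.case_result.dsc_per_config["ir1"]
        assert res.case_result.gain("ensemble") > 0

    def test_union_recall_monotonicity(self, normalized_phantom, desk_phantom):
        be = threshold_opening_backend(tau=60, opening_radius=2)
        cfg = EnsembleConfig(irs=(1, 2, 4), tile_size=64)
        res = run_interpolation_split(normalized_phantom, be, cfg,
                                      gt_mask=desk_phantom.lumen_mask)
        gt = desk_phantom.lumen_mask.astype(bool)
        tp_union = int((res.union_mask.astype(bool) & gt).sum())
        for m in res.per_ir_masks.values():
            assert tp_union >= int((m.astype(bool) & gt).sum())

    def test_final_mask_is_single_component_or_empty(self, normalized_phantom):
        from scipy import ndimage as ndi

        be = threshold_opening_backend(tau=60, opening_radius=2)
        cfg = EnsembleConfig(irs=(1, 2), tile_size=64)
        res = run_interpolation_split(normalized_phantom, be, cfg)
        _, n = ndi.label(res.final_mask, structure=np.ones((3, 3, 3)))
        assert n <= 1

    def test_bit_reproducible(self, normalized_phantom):
        be = threshold_opening_backend(tau=60, opening_radius=2)
        cfg = EnsembleConfig(irs=(1, 2), tile_size=64)
        r1 = run_interpolation_split(normalized_phantom, be, cfg)
        r2 = run_interpolation_split(normalized_phantom, be, cfg)
        np.testing.assert_array_equal(r1.final_mask, r2.final_mask)
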