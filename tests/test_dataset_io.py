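import numpy as np
import pandas as pd
import pytest

from radialpolarity import (
    ChannelNaming,
    DatasetError,
    FieldPair,
    ImageRaster,
    RunConfig,
    SimulationConfig,
    analyze_dataset,
    analyze_field,
    discover_dataset,
    read_raster,
    render_overlay,
    simulate_field,
    write_blind_manifest,
    write_raster,
    write_simulated_dataset,
)


class TestRasterRoundTrip:
    @pytest.mark.parametrize("dtype,depth", [(np.uint8, 8), (np.uint16, 16)])
    def test_tiff_bit_identical(self, tmp_path, dtype, depth):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, np.iinfo(dtype).max, size=(32, 40)).astype(dtype)
        path = tmp_path / "img.tif"
        write_raster(ImageRaster(arr, bit_depth=depth), path)
        back = read_raster(path)
        assert back.bit_depth == depth
        np.testing.assert_array_equal(back.pixels, arr)

    def test_png_roundtrip_uint8(self, tmp_path):
        arr = np.arange(64, dtype=np.uint8).reshape(8, 8)
        path = tmp_path / "img.png"
        write_raster(ImageRaster(arr, bit_depth=8), path)
        np.testing.assert_array_equal(read_raster(path).pixels, arr)

    def test_invalid_rasters_rejected(self):
        with pytest.raises(ValueError):
            ImageRaster(np.full((4, 4), -1.0))
        with pytest.raises(ValueError):
            ImageRaster(np.full((4, 4), np.nan))
        with pytest.raises(ValueError):
            ImageRaster(np.zeros((4, 4, 3)))


def _write_pair(folder, field_id, shape=(32, 32), suffixes=("_dapi", "_pol")):
    folder.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(abs(hash(field_id)) % 2**31)
    for suffix in suffixes:
        arr = rng.integers(0, 1000, size=shape).astype(np.uint16)
        write_raster(ImageRaster(arr, bit_depth=16), folder / f"{field_id}{suffix}.tif")


class TestDiscoverDataset:
    def test_counts_and_grouping(self, tmp_path):
        for cond in ("ctrl", "treated"):
            for i in range(3):
                _write_pair(tmp_path / cond, f"f{i}")
        pairs = discover_dataset(tmp_path)
        assert len(pairs) == 6
        assert sorted({p.condition for p in pairs}) == ["ctrl", "treated"]

    def test_orphan_file_reported(self, tmp_path):
        _write_pair(tmp_path / "ctrl", "f0")
        lonely = tmp_path / "ctrl" / "f9_dapi.tif"
        write_raster(ImageRaster(np.zeros((16, 16), dtype=np.uint8), bit_depth=8), lonely)
        with pytest.raises(DatasetError, match="f9_dapi"):
            discover_dataset(tmp_path)

    def test_deterministic_ordering(self, tmp_path):
        for cond in ("b_cond", "a_cond"):
            for fid in ("f2", "f0", "f1"):
                _write_pair(tmp_path / cond, fid)
        order1 = [(p.condition, p.field_id) for p in discover_dataset(tmp_path)]
        order2 = [(p.condition, p.field_id) for p in discover_dataset(tmp_path)]
        assert order1 == order2 == sorted(order1)

    def test_dimension_mismatch_rejected(self, tmp_path):
        folder = tmp_path / "ctrl"
        folder.mkdir()
        write_raster(ImageRaster(np.zeros((16, 16), dtype=np.uint8), bit_depth=8), folder / "f0_dapi.tif")
        write_raster(ImageRaster(np.zeros((16, 20), dtype=np.uint8), bit_depth=8), folder / "f0_pol.tif")
        with pytest.raises(DatasetError, match="shape"):
            discover_dataset(tmp_path)

    def test_custom_suffixes(self, tmp_path):
        _write_pair(tmp_path / "c", "f0", suffixes=("_nuc", "_marker"))
        pairs = discover_dataset(tmp_path, ChannelNaming("_nuc", "_marker"))
        assert len(pairs) == 1

    def test_simulated_dataset_is_valid_input(self, tmp_path):
        cfg = SimulationConfig(n_acini=3, image_size=(160, 160), seed=1)
        write_simulated_dataset(tmp_path / "ds", {"sim": cfg}, n_fields=2)
        pairs = discover_dataset(tmp_path / "ds")
        assert len(pairs) == 2
        assert pairs[0].nuclear.bit_depth == 16


class TestOverlay:
    def make_analysis(self):
        pair, _ = simulate_field(SimulationConfig(n_acini=4, seed=21, phenotype_mix={"apical": 1.0}))
        return pair, analyze_field(pair, RunConfig(wavr_cutoff=0.0))

    def test_retained_acini_get_contours_and_labels(self):
        pair, fa = self.make_analysis()
        rgb = render_overlay(pair, fa.rois, fa.results)
        assert rgb.shape == (*pair.polarity.shape, 3)
        # contour pixels are green; numeric labels change pixels vs. a
        # render without results
        assert (rgb == (80, 220, 80)).all(axis=-1).sum() > 0
        no_text = render_overlay(pair, fa.rois, [])
        assert (rgb != no_text).any()

    def test_empty_field_renders_plain_image(self):
        pair, _ = simulate_field(SimulationConfig(n_acini=2, seed=22))
        rgb = render_overlay(pair, [], [])
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_excluded_acinus_in_distinct_style_without_number(self):
        pair, fa = self.make_analysis()
        # force-exclude everything: red contours and no text vs. plain render
        for roi in fa.rois:
            roi.excluded_reason = "blur"
        results = fa.results
        rgb = render_overlay(pair, fa.rois, results)
        assert (rgb == (230, 70, 70)).all(axis=-1).sum() > 0
        # no numbers rendered for excluded acini: identical to a no-results render
        np.testing.assert_array_equal(rgb, render_overlay(pair, fa.rois, []))


class TestBlindManifest:
    def make_analyses(self):
        analyses = []
        for cond, seed in (("ctrl", 31), ("treated", 32)):
            pair, _ = simulate_field(
                SimulationConfig(n_acini=4, seed=seed, phenotype_mix={"apical": 1.0}), condition=cond
            )
            analyses.append(analyze_field(pair, RunConfig(wavr_cutoff=0.0)))
        return analyses

    def test_same_seed_same_order(self, tmp_path):
        analyses = self.make_analyses()
        m1, k1 = write_blind_manifest(analyses, seed=1, out_dir=tmp_path / "a")
        m2, k2 = write_blind_manifest(analyses, seed=1, out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(k1, k2)

    def test_different_seed_permutes_same_membership(self, tmp_path):
        analyses = self.make_analyses()
        _, k1 = write_blind_manifest(analyses, seed=1, out_dir=tmp_path / "a")
        _, k2 = write_blind_manifest(analyses, seed=2, out_dir=tmp_path / "b")
        key1 = list(zip(k1.condition, k1.field_id, k1.acinus_id))
        key2 = list(zip(k2.condition, k2.field_id, k2.acinus_id))
        assert key1 != key2 and sorted(key1) == sorted(key2)

    def test_manifest_withholds_condition(self, tmp_path):
        analyses = self.make_analyses()
        manifest, key = write_blind_manifest(analyses, seed=3, out_dir=tmp_path)
        assert "condition" not in manifest.columns
        text = manifest.to_csv(index=False)
        for cond in ("ctrl", "treated"):
            assert cond not in text
        assert set(key.condition) == {"ctrl", "treated"}

    def test_no_retained_acini_rejected(self, tmp_path):
        analyses = self.make_analyses()
        for fa in analyses:
            for roi in fa.rois:
                roi.excluded_reason = "blur"
            fa.results.clear()
        with pytest.raises(ValueError):
            write_blind_manifest(analyses, seed=1, out_dir=tmp_path)
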