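"""File formats, pipeline configuration and orchestration, CLI wiring."""

import json

import numpy as np
import pytest
from scipy import ndimage

from opmkit import io as opmio
from opmkit.geometry import AcquisitionGeometry, ObliqueStack, OrthoVolume
from opmkit.pipeline import PipelineConfig, PipelineError, run_pipeline
from opmkit.synthesis import ScenePhantom, _blob_template, make_two_view_scene

from conftest import two_view_geometries


@pytest.fixture
def geometry():
    return AcquisitionGeometry(scan_step_um=0.8, pixel_size_um=0.4,
                               frame_shape=(12, 16), view_id=2)


class TestTiffRoundTrip:
    def test_uint16_stack_round_trips_bitwise(self, tmp_path, geometry):
        data = np.random.default_rng(0).integers(0, 2**16, (5, 12, 16)).astype(np.uint16)
        stack = ObliqueStack(data, geometry)
        opmio.write_stack(tmp_path / "s.tif", stack)
        back = opmio.read_stack(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.data, data)
        assert back.geometry == geometry

    def test_float_volume_quantized_within_one_count(self, tmp_path):
        vol = OrthoVolume(
            np.random.default_rng(1).uniform(0.0, 4000.0, (6, 8, 10)),
            (0.9, 0.44, 1.0), origin_um=(0.0, 0.0, -3.5),
        )
        opmio.write_volume(tmp_path / "v.tif", vol)
        back = opmio.read_volume(tmp_path / "v.tif")
        scale = 4000.0 / 65535.0
        assert np.abs(back.data - vol.data).max() <= scale
        assert back.voxel_size_um == pytest.approx(vol.voxel_size_um)
        assert back.origin_um == pytest.approx(vol.origin_um)

    def test_missing_sidecar_rejected(self, tmp_path, geometry):
        stack = ObliqueStack(np.zeros((2, 12, 16), dtype=np.uint16), geometry)
        opmio.write_stack(tmp_path / "s.tif", stack)
        (tmp_path / "s.tif.json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            opmio.read_stack(tmp_path / "s.tif")

    def test_malformed_sidecar_rejected(self, tmp_path, geometry):
        stack = ObliqueStack(np.zeros((2, 12, 16), dtype=np.uint16), geometry)
        opmio.write_stack(tmp_path / "s.tif", stack)
        (tmp_path / "s.tif.json").write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            opmio.read_stack(tmp_path / "s.tif")

    def test_wrong_kind_rejected(self, tmp_path, geometry):
        stack = ObliqueStack(np.zeros((2, 12, 16), dtype=np.uint16), geometry)
        opmio.write_stack(tmp_path / "s.tif", stack)
        with pytest.raises(ValueError, match="kind"):
            opmio.read_volume(tmp_path / "s.tif")


class TestZarrStore:
    def test_round_trips_bitwise(self, tmp_path):
        data = np.random.default_rng(2).integers(0, 2**16, (32, 40, 48)).astype(np.uint16)
        opmio.to_zarr(tmp_path / "a.zarr", data)
        np.testing.assert_array_equal(opmio.from_zarr(tmp_path / "a.zarr"), data)

    def test_float_stored_as_32bit(self, tmp_path):
        data = np.random.default_rng(3).uniform(0, 1, (8, 8, 8))
        opmio.to_zarr(tmp_path / "f.zarr", data)
        back = opmio.from_zarr(tmp_path / "f.zarr")
        assert back.dtype == np.float32
        np.testing.assert_array_equal(back, data.astype(np.float32))

    def test_lossless_compression_near_or_above_unity(self, tmp_path):
        """Incompressible data stays near 1:1 (header overhead only)."""
        data = np.random.default_rng(4).integers(0, 2**16, (64, 64, 64)).astype(np.uint16)
        opmio.to_zarr(tmp_path / "r.zarr", data)
        assert opmio.zarr_compression_ratio(tmp_path / "r.zarr", data) > 0.95

    def test_structured_data_compresses(self, tmp_path):
        """Sparse specimen-like content achieves a real compression gain."""
        zz, yy, xx = np.indices((64, 64, 64))
        blob = 4000 * np.exp(-((zz - 32) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2) / 50)
        data = blob.astype(np.uint16)
        opmio.to_zarr(tmp_path / "s.zarr", data)
        assert opmio.zarr_compression_ratio(tmp_path / "s.zarr", data) > 1.5


class TestPipelineConfig:
    def _base(self, tmp_path, stages):
        return {
            "input": {"view1": ["a.tif"], "view2": ["b.tif"]},
            "output_dir": str(tmp_path / "out"),
            "stages": stages,
        }

    def test_valid_config_accepted(self, tmp_path):
        cfg = PipelineConfig.from_dict(self._base(tmp_path, [
            {"name": "deskew"}, {"name": "register"}, {"name": "fuse"},
        ]))
        assert [s["name"] for s in cfg.stages] == ["deskew", "register", "fuse"]

    def test_illegal_order_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="order"):
            PipelineConfig.from_dict(self._base(tmp_path, [
                {"name": "deskew"}, {"name": "fuse"}, {"name": "register"},
            ]))

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown stage"):
            PipelineConfig.from_dict(self._base(tmp_path, [{"name": "sharpen"}]))

    def test_unknown_top_level_key_rejected(self, tmp_path):
        cfg = self._base(tmp_path, [{"name": "deskew"}])
        cfg["gpu"] = True
        with pytest.raises(ValueError, match="unknown config keys"):
            PipelineConfig.from_dict(cfg)

    def test_two_view_stage_requires_second_view(self, tmp_path):
        cfg = self._base(tmp_path, [{"name": "deskew"}, {"name": "fuse"}])
        cfg["input"] = {"view1": ["a.tif"]}
        with pytest.raises(ValueError, match="view2"):
            PipelineConfig.from_dict(cfg)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(self._base(tmp_path, [{"name": "deskew"}])))
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.stages[0]["name"] == "deskew"


@pytest.fixture
def scene_on_disk(tmp_path):
    """Three drifting time points of a two-view scene written as raw stacks."""
    shape = (40, 48, 64)
    base = _blob_template(shape, np.random.default_rng(0))
    g1, g2 = two_view_geometries(shape)
    v1_paths, v2_paths = [], []
    true_drift = []
    for t in range(3):
        drift = np.array([0.0, 0.8 * t, -0.5 * t])
        true_drift.append(drift)
        vol = OrthoVolume(ndimage.shift(base, drift, order=1), (1.0, 1.0, 1.0))
        phantom = ScenePhantom(truth=vol, attenuation_mu_per_um=0.01)
        s1, s2, _ = make_two_view_scene(phantom, g1, g2)
        p1 = tmp_path / f"v1_{t}.tif"
        p2 = tmp_path / f"v2_{t}.tif"
        opmio.write_stack(p1, s1)
        opmio.write_stack(p2, s2)
        v1_paths.append(str(p1))
        v2_paths.append(str(p2))
    return v1_paths, v2_paths, np.array(true_drift)


class TestRunPipeline:
    def _config(self, tmp_path, v1, v2, out="out"):
        return PipelineConfig.from_dict({
            "input": {"view1": v1, "view2": v2},
            "output_dir": str(tmp_path / out),
            "stages": [
                {"name": "deskew"},
                {"name": "dehaze", "scale_voxels": 20},
                {"name": "register", "max_iterations": 1, "min_chunk_voxels": 16},
                {"name": "fuse"},
                {"name": "stabilize", "n": 2},
            ],
        })

    def test_full_run_recovers_drift_and_fuses(self, tmp_path, scene_on_disk):
        v1, v2, true_drift = scene_on_disk
        cfg = self._config(tmp_path, v1, v2)
        log = run_pipeline(cfg)
        assert len(log["outputs"]) == 4  # 3 volumes + trajectory
        traj = json.loads((tmp_path / "out" / "trajectory.json").read_text())
        recovered = np.array(traj["A"])
        assert np.abs(recovered - true_drift).max() < 0.1

    def test_identical_config_reproduces_checksums(self, tmp_path, scene_on_disk):
        v1, v2, _ = scene_on_disk
        log_a = run_pipeline(self._config(tmp_path, v1, v2, "out_a"))
        log_b = run_pipeline(self._config(tmp_path, v1, v2, "out_b"))
        for name, digest in log_a["outputs"].items():
            assert log_b["outputs"][name] == digest

    def test_failing_stage_named_and_marked(self, tmp_path, scene_on_disk):
        v1, v2, _ = scene_on_disk
        cfg = PipelineConfig.from_dict({
            "input": {"view1": v1, "view2": v2},
            "output_dir": str(tmp_path / "fail"),
            "stages": [{"name": "deskew"}, {"name": "dehaze", "scale_voxels": -5}],
        })
        with pytest.raises(PipelineError, match="dehaze"):
            run_pipeline(cfg)
        assert (tmp_path / "fail" / "FAILED_dehaze").exists()


class TestCli:
    def test_ls3_prints_schedule(self):
        from click.testing import CliRunner

        from opmkit.cli import main

        result = CliRunner().invoke(main, ["ls3", "--scan-range-um", "2000",
                                           "--stage-speed", "180.6"])
        assert result.exit_code == 0
        assert "frames per volume" in result.output

    def test_simulate_and_deskew_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from opmkit.cli import main

        runner = CliRunner()
        beads = tmp_path / "beads.tif"
        r = runner.invoke(main, [
            "simulate", "beads", str(beads), "--n-beads", "3",
            "--shape", "64", "64", "64", "--fwhm-um", "0.4", "0.4", "0.8",
            "--seed", "1",
        ])
        assert r.exit_code == 0, r.output
        assert beads.exists()
        manifest = json.loads((tmp_path / "beads.tif.truth.json").read_text())
        assert len(manifest["positions_voxel_zyx"]) == 3
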