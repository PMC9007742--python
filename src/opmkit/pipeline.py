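"""Pipeline configuration and orchestration.

One time point of a dual-view acquisition travels through the stages in a
fixed order: per-view deskew, per-view dehaze, warp registration of view 2
onto view 1, content-aware fusion, illumination correction of the fused
volume; after all time points are processed the series is temporally
stabilized.  A :class:`PipelineConfig` selects a contiguous-in-order subset
of these stages with parameters; :func:`run_pipeline` executes it on disk,
logging parameters and output checksums so identical configs reproduce
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from opmkit import io as opmio
from opmkit.fusion import compute_blend_map, fuse_views
from opmkit.geometry import OrthoVolume, deskew, overlap_crop
from opmkit.registration import RegistrationConfig, apply_warp, multiscale_warp_register
from opmkit.restoration import correct_illumination, dehaze
from opmkit.stabilization import pairwise_shifts, solve_trajectory, stabilize
from opmkit.synthesis import LightSheetProfile

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = [
    "deskew",
    "dehaze",
    "register",
    "fuse",
    "illumination_correct",
    "stabilize",
]

_KNOWN_TOP_KEYS = {"input", "output_dir", "stages", "seed", "log_level"}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the failing stage is named."""


@dataclass
class PipelineConfig:
    """Validated pipeline description.

    ``stages`` is an ordered list of ``{"name": ..., **params}`` mappings
    whose names must appear in the canonical order (fusion cannot precede
    registration, and so on).  ``input`` maps ``view1``/``view2`` to lists of
    TIFF paths, one per time point.
    """

    input: dict
    output_dir: Path
    stages: list[dict]
    seed: int = 0
    log_level: str = "info"

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        unknown = set(cfg) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("input", "output_dir", "stages"):
            if key not in cfg:
                raise ValueError(f"config missing required key {key!r}")
        stages = [dict(s) for s in cfg["stages"]]
        names = []
        for s in stages:
            if "name" not in s:
                raise ValueError("every stage needs a 'name'")
            if s["name"] not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s['name']!r}")
            names.append(s["name"])
        order = [STAGE_ORDER.index(n) for n in names]
        if order != sorted(order) or len(set(names)) != len(names):
            raise ValueError(
                f"stages {names} violate the canonical order {STAGE_ORDER}"
            )
        inp = dict(cfg["input"])
        if "view1" not in inp:
            raise ValueError("input must define at least 'view1'")
        needs_two = {"register", "fuse"} & set(names)
        if needs_two and "view2" not in inp:
            raise ValueError("register/fuse stages require input 'view2'")
        return cls(
            input=inp,
            output_dir=Path(cfg["output_dir"]),
            stages=stages,
            seed=int(cfg.get("seed", 0)),
            log_level=str(cfg.get("log_level", "info")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_params(self, name: str) -> dict | None:
        for s in self.stages:
            if s["name"] == name:
                return {k: v for k, v in s.items() if k != "name"}
        return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the structured log.

    Outputs (fused/stabilized volumes as TIFF, the drift trajectory as JSON)
    and a ``pipeline_log.json`` with per-stage parameters and output
    checksums land in ``output_dir``.  On stage failure a
    ``FAILED_<stage>`` marker is written next to any partial outputs and a
    :class:`PipelineError` names the stage.
    """
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": [], "outputs": {}, "seed": config.seed}

    view1_paths = [Path(p) for p in config.input["view1"]]
    view2_paths = [Path(p) for p in config.input.get("view2", [])]
    n_t = len(view1_paths)
    stage = "load"
    try:
        volumes: list[OrthoVolume] = []
        for t in range(n_t):
            stage = "deskew"
            params = config.stage_params("deskew")
            s1 = opmio.read_stack(view1_paths[t])
            v1 = deskew(s1) if params is not None else None
            if v1 is None:
                raise PipelineError("pipeline currently starts at the deskew stage")
            v2 = None
            if view2_paths:
                s2 = opmio.read_stack(view2_paths[t])
                # the view-2 deskew transform restores the common
                # orientation; the views then share only an overlap window
                v1, v2 = overlap_crop(v1, deskew(s2))
            if t == 0:
                log["stages"].append({"name": "deskew", "params": params or {}})

            params = config.stage_params("dehaze")
            if params is not None:
                stage = "dehaze"
                v1 = dehaze(v1, **params)
                if v2 is not None:
                    v2 = dehaze(v2, **params)
                if t == 0:
                    log["stages"].append({"name": "dehaze", "params": params})

            params = config.stage_params("register")
            if params is not None and v2 is not None:
                stage = "register"
                reg_cfg = RegistrationConfig(**params)
                warp = multiscale_warp_register(v1, v2, reg_cfg)
                v2 = apply_warp(v2, warp)
                if t == 0:
                    log["stages"].append({"name": "register", "params": params})

            params = config.stage_params("fuse")
            if params is not None and v2 is not None:
                stage = "fuse"
                blend = compute_blend_map(v1, v2, **params)
                v1 = fuse_views(v1, v2, blend)
                if t == 0:
                    log["stages"].append({"name": "fuse", "params": params})

            params = config.stage_params("illumination_correct")
            if params is not None:
                stage = "illumination_correct"
                profile = LightSheetProfile(
                    sigma_y_um=params["sigma_y_um"],
                    center_y_um=params.get("center_y_um", 0.0),
                )
                epsilon = params.get("epsilon", 0.05)
                v1 = correct_illumination(v1, profile, epsilon)
                if t == 0:
                    log["stages"].append({"name": "illumination_correct", "params": params})
            volumes.append(v1)

        params = config.stage_params("stabilize")
        if params is not None and n_t >= 2:
            stage = "stabilize"
            series = np.stack([v.data for v in volumes])
            shifts = pairwise_shifts(series, n=int(params.get("n", 7)))
            traj = solve_trajectory(shifts, method=params.get("method", "l1"))
            series = stabilize(series, traj)
            volumes = [
                OrthoVolume(series[t], volumes[t].voxel_size_um, volumes[t].origin_um)
                for t in range(n_t)
            ]
            traj_path = out_dir / "trajectory.json"
            traj_path.write_text(
                json.dumps(
                    {
                        "A": traj.A.tolist(),
                        "gauge": traj.gauge,
                        "n": int(params.get("n", 7)),
                    },
                    indent=2,
                )
            )
            log["outputs"]["trajectory.json"] = _sha256(traj_path)
            log["stages"].append({"name": "stabilize", "params": params})

        stage = "write"
        for t, vol in enumerate(volumes):
            name = f"output_t{t:04d}.tif"
            opmio.write_volume(out_dir / name, vol)
            log["outputs"][name] = _sha256(out_dir / name)
    except PipelineError:
        (out_dir / f"FAILED_{stage}").write_text(stage)
        raise
    except Exception as exc:
        (out_dir / f"FAILED_{stage}").write_text(f"{stage}: {exc}")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    log_path = out_dir / "pipeline_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
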