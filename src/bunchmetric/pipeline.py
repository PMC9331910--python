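"""End-to-end pipeline: per-view segmentation -> merge -> downsample -> MLS
-> size + five volume estimators, with a structured stage log.

The configuration object round-trips losslessly through JSON/TOML and
rejects unknown keys, so a config file cannot silently misspell a
parameter.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .errors import ArgumentError
from .geometry import PointCloud
from .measurement import MeasureConfig, VolumeReport, measure_all
from .poisson import PoissonParams
from .registration import (
    ICPParams,
    MERGE_ICP_PARAMS,
    MLSParams,
    downsample,
    merge_views,
    mls_smooth,
)
from .segmentation import CropBox, RegionGrowingParams, segment_bunch

__all__ = ["PipelineConfig", "run_pipeline"]


def _from_dict(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ArgumentError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, as one serializable object."""

    unit_scale: float = 1.0        # multiply input coordinates into cm
    segment: bool = False          # run per-view segmentation first
    crop: dict = field(default_factory=dict)      # CropBox kwargs
    region_growing: dict = field(default_factory=dict)  # RegionGrowingParams kwargs
    icp: dict = field(default_factory=dict)       # ICPParams kwargs
    mls: dict = field(default_factory=dict)       # MLSParams kwargs
    downsample_edge: float = 0.25  # cm; 0 disables
    alpha: float = 1.75
    voxel_edge: float = 0.2
    poisson: dict = field(default_factory=dict)   # PoissonParams kwargs
    methods: tuple = ("gm", "ch", "as", "vb", "pb")
    size_frame: str = "pca"
    seed: int = 0
    verbosity: int = 1

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data)
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return _from_dict(PipelineConfig, data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(d["methods"])
        return d

    def crop_box(self) -> CropBox:
        kw = {k: tuple(v) if v is not None else None for k, v in self.crop.items()}
        return _from_dict(CropBox, kw)

    def region_params(self) -> RegionGrowingParams:
        return _from_dict(RegionGrowingParams, self.region_growing)

    def icp_params(self) -> ICPParams:
        # start from the robust merge defaults; config keys override fields
        from dataclasses import replace

        names = {f.name for f in fields(ICPParams)}
        unknown = set(self.icp) - names
        if unknown:
            raise ArgumentError(f"unknown ICPParams keys: {sorted(unknown)}")
        return replace(MERGE_ICP_PARAMS, **self.icp)

    def mls_params(self) -> MLSParams:
        return _from_dict(MLSParams, self.mls)

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            alpha=self.alpha,
            voxel_edge=self.voxel_edge,
            poisson=_from_dict(PoissonParams, self.poisson),
            methods=self.methods,
            size_frame=self.size_frame,
        )


def orient_normals_outward(cloud: PointCloud) -> PointCloud:
    """Flip per-point normals to point away from the cloud centroid.

    MLS leaves each normal's sign tied to its (arbitrary) input reference;
    volumetry wants a consistent outward field.
    """
    outward = cloud.points - cloud.points.mean(axis=0)
    normals = cloud.normals.copy()
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] = -normals[flip]
    return PointCloud(cloud.points, normals, cloud.curvatures)


def run_pipeline(views: list[PointCloud], config: PipelineConfig,
                 v_true: float | None = None,
                 sample_id: str = "sample") -> tuple[VolumeReport, list[dict]]:
    """Run the full measurement chain on a list of view clouds.

    Returns the volume report and a JSON-serializable stage log (one record
    per stage with timings, point counts and registration RMSEs).
    """
    log: list[dict] = []

    def record(stage: str, t0: float, **extra):
        log.append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **extra})

    if config.unit_scale != 1.0:
        views = [PointCloud(v.points * config.unit_scale) for v in views]

    if config.segment:
        t0 = time.perf_counter()
        box = config.crop_box()
        params = config.region_params()
        views = [segment_bunch(v, box, params) for v in views]
        record("segment", t0, points_per_view=[len(v) for v in views])

    if len(views) > 1:
        t0 = time.perf_counter()
        merged = merge_views(views, config.icp_params())
        cloud = merged.cloud
        record("merge", t0, points=len(cloud), pairs=merged.log)
    else:
        cloud = views[0]

    if config.downsample_edge > 0:
        t0 = time.perf_counter()
        cloud = downsample(cloud, config.downsample_edge)
        record("downsample", t0, points=len(cloud))

    t0 = time.perf_counter()
    cloud = mls_smooth(cloud, config.mls_params())
    record("mls_smooth", t0, points=len(cloud))

    cloud = orient_normals_outward(cloud)

    t0 = time.perf_counter()
    report = measure_all(cloud, config.measure_config(), v_true=v_true, sample_id=sample_id)
    record("measure", t0, warnings=report.warnings)
    return report, log


def write_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
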