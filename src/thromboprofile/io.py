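"""Configuration, file formats and provenance for the pipeline.

Formats handled here:

* single-channel 8-bit TIFF frames (16-bit input is rejected unless an
  explicit downcast is requested) and PNG/TIFF masks;
* long-form run-profile CSV (``run_id, group, age_group, microspot,
  parameter, value``) with lossless round-tripping;
* kinetic-series CSV (``time_min, sac_percent``);
* YAML pipeline configuration and JSON summaries.

Every table written by the pipeline carries a provenance header
(``# key: value`` comment lines) embedding the package version, the seed
and a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .image_quant import BandpassSpec, BinaryMask, ImageFrame, MorphologySpec
from .thrombus_params import (DEFAULT_FIBRIN_THRESHOLD, DEFAULT_SLOPE_WINDOW,
                              FlowRunProfile, KineticSeries)

__all__ = [
    "PipelineConfig",
    "read_tiff_frame",
    "write_tiff_frame",
    "write_mask",
    "profiles_to_frame",
    "frame_to_profiles",
    "write_table",
    "read_table",
    "write_kinetic_series",
    "read_kinetic_series",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, YAML round-trippable."""

    # image quantification
    bandpass_large_cutoff_px: float = 120.0
    bandpass_small_cutoff_px: float | None = None
    morphology_diamond_close_radius: int = 5
    morphology_disk_close_radius: int = 3
    morphology_disk_dilate_radius: int = 1
    threshold_method: str = "otsu"
    threshold_manual_offset: float = 0.0
    brightfield_dark_objects: bool = True
    # fibrin kinetics
    fibrin_threshold_sac: float = DEFAULT_FIBRIN_THRESHOLD
    slope_window_min: tuple[float, float] = DEFAULT_SLOPE_WINDOW
    fibrin_log_base: float = 10.0
    # group statistics
    alpha: float = 0.05
    correction: str | None = "bh"
    min_effect_r: float = 0.3
    effect_mode: str = "signed_r"
    pool_age_groups: bool = True
    # proteome
    fold_threshold: float = 1.5
    proteome_equal_var: bool = True
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fold_threshold <= 1.0:
            raise ValueError("fold_threshold must exceed 1")
        lo, hi = self.slope_window_min
        if not lo < hi:
            raise ValueError("slope window must be an increasing interval")
        if self.correction not in ("bh", None):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        # fail early on invalid spec combinations
        self.bandpass_spec()
        self.morphology_spec()

    def bandpass_spec(self) -> BandpassSpec:
        return BandpassSpec(self.bandpass_large_cutoff_px, self.bandpass_small_cutoff_px)

    def morphology_spec(self) -> MorphologySpec:
        return MorphologySpec(self.morphology_diamond_close_radius,
                              self.morphology_disk_close_radius,
                              self.morphology_disk_dilate_radius)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slope_window_min"] = list(self.slope_window_min)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "slope_window_min" in data:
            data["slope_window_min"] = tuple(data["slope_window_min"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Short stable digest of the configuration, for provenance lines."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig | None, extra: dict | None = None) -> dict:
    prov = {"version": __version__}
    if config is not None:
        prov["config_hash"] = config.hash()
        prov["seed"] = config.seed
    if extra:
        prov.update(extra)
    return prov


def read_tiff_frame(path: str | Path, channel: str = "brightfield",
                    allow_16bit: bool = False) -> ImageFrame:
    """Read a single-channel TIFF frame.

    16-bit input raises unless ``allow_16bit=True``, in which case it is
    downcast to 8-bit by dropping the low byte.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        if not allow_16bit:
            raise ValueError(f"{path}: 16-bit TIFF; pass allow_16bit to downcast")
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8")
    return ImageFrame(arr, channel=channel, frame_id=Path(path).stem)


def write_tiff_frame(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as 8-bit grayscale TIFF (floats are rounded)."""
    tifffile.imwrite(str(path),
                     np.clip(np.round(frame.pixels), 0, 255).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG or TIFF (0 / 255)."""
    img = (mask.pixels.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), img)
    else:
        iio.imwrite(path, img)


def write_table(df: pd.DataFrame, path: str | Path,
                config: PipelineConfig | None = None,
                extra_provenance: dict | None = None,
                index: bool = False, sep: str = ",") -> None:
    """Write a CSV/TSV with ``# key: value`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in _provenance(config, extra_provenance).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=index, sep=sep)


def read_table(path: str | Path, sep: str = ",", **kwargs) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, skipping provenance."""
    return pd.read_csv(path, comment="#", sep=sep, **kwargs)


_PROFILE_COLUMNS = ["run_id", "group", "age_group", "microspot", "parameter", "value"]


def profiles_to_frame(profiles: Sequence[FlowRunProfile]) -> pd.DataFrame:
    """Long-form table of run profiles: one row per run x parameter."""
    rows = []
    for p in profiles:
        for key, value in p.values.items():
            rows.append({"run_id": p.run_id, "group": p.group_label,
                         "age_group": p.age_group, "microspot": p.microspot,
                         "parameter": key, "value": value})
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def frame_to_profiles(df: pd.DataFrame) -> list[FlowRunProfile]:
    """Rebuild run profiles from a long-form table (inverse of the writer)."""
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    profiles = []
    for (run_id, group, microspot), sub in df.groupby(
            ["run_id", "group", "microspot"], sort=False):
        age = sub["age_group"].iloc[0]
        profiles.append(FlowRunProfile(
            run_id=run_id, group_label=group,
            values=dict(zip(sub["parameter"], sub["value"])),
            microspot=microspot,
            age_group=None if pd.isna(age) else age,
        ))
    return profiles


def wide_profile_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a long profile table to runs x parameters plus a group series."""
    wide = df.pivot_table(index="run_id", columns="parameter", values="value",
                          sort=False)
    groups = df.drop_duplicates("run_id").set_index("run_id")["group"]
    return wide, groups.loc[wide.index]


def write_kinetic_series(series: KineticSeries, path: str | Path,
                         config: PipelineConfig | None = None) -> None:
    df = pd.DataFrame({"time_min": series.times_min,
                       "sac_percent": series.sac_percent})
    write_table(df, path, config,
                extra_provenance={"fibrin_threshold": series.fibrin_threshold,
                                  "duration_min": series.duration_min})


def read_kinetic_series(path: str | Path,
                        fibrin_threshold: float = DEFAULT_FIBRIN_THRESHOLD,
                        duration_min: float = 10.0) -> KineticSeries:
    df = read_table(path)
    return KineticSeries(df["time_min"].to_numpy(), df["sac_percent"].to_numpy(),
                         fibrin_threshold=fibrin_threshold, duration_min=duration_min)
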