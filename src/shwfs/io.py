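"""File I/O helpers: frames as TIFF, centroids as CSV, sensor config as
YAML, coefficients as JSON (see :meth:`ZernikeCoefficients.to_json`)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .centroid import CentroidSet
from .forward_model import LensletGeometry, SensorConfig, SpotFrame

__all__ = [
    "save_frame",
    "load_frame",
    "centroids_to_csv",
    "centroids_from_csv",
    "config_to_yaml",
    "config_from_yaml",
]


def save_frame(path, frame: SpotFrame) -> None:
    """Write a frame as a 32-bit float TIFF."""
    tifffile.imwrite(path, frame.intensity.astype(np.float32))


def load_frame(path, geometry: LensletGeometry) -> SpotFrame:
    """Read a frame image (TIFF) back onto a known geometry."""
    intensity = np.asarray(tifffile.imread(path), dtype=float)
    if intensity.shape != geometry.frame_shape:
        raise ValueError(
            f"frame shape {intensity.shape} does not match geometry "
            f"{geometry.frame_shape}"
        )
    return SpotFrame(intensity=intensity, geometry=geometry)


def centroids_to_csv(path, centroids: CentroidSet) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(len(centroids)),
            "x_px": centroids.points[:, 0],
            "y_px": centroids.points[:, 1],
            "peak_response": (
                centroids.peak_response
                if centroids.peak_response is not None
                else np.full(len(centroids), np.nan)
            ),
        }
    )
    df.to_csv(path, index=False)


def centroids_from_csv(path, source: str = "autocorrelation") -> CentroidSet:
    df = pd.read_csv(path)
    return CentroidSet(
        points=df[["x_px", "y_px"]].to_numpy(),
        source=source,
        peak_response=df["peak_response"].to_numpy()
        if "peak_response" in df
        else None,
    )


def config_to_yaml(path, config: SensorConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.__dict__, sort_keys=False))


def config_from_yaml(path) -> SensorConfig:
    return SensorConfig(**yaml.safe_load(Path(path).read_text()))
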