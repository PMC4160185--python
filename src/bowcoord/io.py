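"""Plain-text I/O for bowing time series and feature tables.

Time series are CSV files with a commented (``#``) YAML metadata header
and the columns time, velocity, inclination, force_total, band_halfwidth,
band_center.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import BowingTimeSeries

SERIES_COLUMNS = [
    "time", "velocity", "inclination", "force_total", "band_halfwidth",
    "band_center",
]


def write_series_csv(series: BowingTimeSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": series.time,
            "velocity": series.velocity,
            "inclination": series.inclination,
            "force_total": series.force_total,
            "band_halfwidth": series.band_halfwidth,
            "band_center": np.full(series.n_samples, series.band_center),
        }
    )
    meta_yaml = yaml.safe_dump(_plain(series.metadata), sort_keys=False)
    with path.open("w") as fh:
        for line in meta_yaml.rstrip("\n").split("\n"):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_series_csv(path: str | Path) -> BowingTimeSeries:
    path = Path(path)
    meta_lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line[1:].lstrip(" "))
            else:
                break
    metadata = yaml.safe_load("".join(meta_lines)) or {}
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series file {path} lacks columns {missing}")
    return BowingTimeSeries(
        time=df["time"].to_numpy(),
        velocity=df["velocity"].to_numpy(),
        inclination=df["inclination"].to_numpy(),
        force_total=df["force_total"].to_numpy(),
        band_halfwidth=df["band_halfwidth"].to_numpy(),
        band_center=float(df["band_center"].iloc[0]),
        metadata=metadata,
    )


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
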