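"""Shared I/O: TIFF stacks with metadata sidecars, result tables, configs.

Every run writes its fully resolved configuration next to its outputs and a
manifest listing the written files, so any result table is reproducible from
seed + config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ResultsTable",
    "read_stack",
    "write_stack",
    "write_results",
    "load_config",
    "resolve_config",
    "compare_conditions",
]

RESULT_COLUMNS = ["larva_id", "segment", "roi_type", "metric", "value", "units"]

METRIC_VOCABULARY = {
    "pr",
    "quantal_density",
    "velocity",
    "stride_length",
    "reorient_duration",
    "crawl_duration",
    "turning_angle",
    "bout_duration",
    "time_to_max",
    "mean_amplitude",
    "peak_amplitude",
    "integral",
    "fraction_time_active",
    "intersegmental_delay",
    "overlap_time",
    "contraction_displacement",
    "waves_per_10min",
    "bouts_per_10min",
    "relative_distance",
    "relative_amplitude",
    "relative_duration",
    "fwhm",
    "sigma",
    "center",
    "amplitude",
    "offset",
}


@dataclass
class ResultsTable:
    """Tidy measurements: one row per (larva, roi, metric) value."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RESULT_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"results table missing columns: {sorted(missing)}")
        self.rows = self.rows[RESULT_COLUMNS].reset_index(drop=True)
        if len(self.rows):
            if self.rows["units"].astype(str).str.len().min() == 0:
                raise ValueError("units must be non-empty")
            unknown = set(self.rows["metric"]) - METRIC_VOCABULARY
            if unknown:
                raise ValueError(f"unknown metric names: {sorted(unknown)}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "ResultsTable":
        return cls(pd.DataFrame(records, columns=RESULT_COLUMNS))


def read_stack(path: str | Path, sidecar: str | Path) -> tuple[np.ndarray, dict]:
    """Load a multi-page TIFF and its JSON metadata sidecar.

    The sidecar must declare ``pixel_size`` (um/px) and ``frame_period`` (s);
    missing metadata is an error, never silently defaulted.
    """
    path, sidecar = Path(path), Path(sidecar)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("pixel_size", "frame_period"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    data = tifffile.imread(path)
    if "shape" in meta and tuple(meta["shape"]) != data.shape:
        raise ValueError(
            f"stack shape {data.shape} does not match sidecar shape {tuple(meta['shape'])}"
        )
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3-D or 4-D stack, got {data.ndim} axes")
    return np.asarray(data), meta


def write_stack(data: np.ndarray, meta: dict, path: str | Path, sidecar: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    tifffile.imwrite(Path(path), np.asarray(data, dtype=np.float32))
    meta = dict(meta)
    meta["shape"] = list(np.asarray(data).shape)
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: dict[str, ResultsTable | pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Write result tables as CSV with a manifest JSON.

    The manifest records every file, a schema version, and a hash of the
    resolved config; the resolved config itself is written alongside.
    Output bytes depend only on the tables and config (no timestamps), so
    identical runs produce identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": 1, "files": []}
    for name, table in tables.items():
        df = table.rows if isinstance(table, ResultsTable) else table
        fn = out_dir / f"{name}.csv"
        df.to_csv(fn, index=False)
        manifest["files"].append(fn.name)
    if config is not None:
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        manifest["config_hash"] = _config_hash(config)
        manifest["files"].append("resolved_config.yaml")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def resolve_config(user: dict, defaults: dict) -> dict:
    """Overlay user config on defaults, rejecting unknown keys."""
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = dict(defaults)
    out.update(user)
    return out


def compare_conditions(
    values_a, values_b, metric: str = ""
) -> dict:
    """Two-group comparison: medians, median difference, rank-sum p-value.

    Uses the standard two-sided Mann-Whitney U test; this is a reporting
    harness, not a re-derivation of the statistic.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "metric": metric,
        "n_a": len(a),
        "n_b": len(b),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "median_difference": float(np.median(b) - np.median(a)),
        "u_statistic": float(stat),
        "p_value": float(p),
    }
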