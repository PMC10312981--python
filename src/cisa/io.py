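"""Reading and writing the standard file contract.

Marker images are multipage TIFFs with one 2D plane per channel; label masks
are integer TIFF/PNG; cell tables and results are flat CSV with a JSON
run-metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    AnalysisConfig,
    CellTable,
    LabelMask,
    MarkerImage,
    types_to_str,
)

__all__ = [
    "read_marker_image",
    "write_marker_image",
    "imc_preprocess",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
    "write_results",
    "read_config",
    "write_config",
    "write_run_manifest",
]


def read_marker_image(
    path,
    channel_names: Sequence[str],
    pixel_size_um: float,
    modality: str = "fluorescence",
) -> MarkerImage:
    """Load a single- or multi-page TIFF, one plane per listed channel."""
    planes = tifffile.imread(path)
    planes = np.asarray(planes)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.ndim != 3:
        raise ValueError(f"expected 2D planes in {path}, got shape {planes.shape}")
    if planes.shape[0] != len(channel_names):
        raise ValueError(
            f"channel count mismatch: {planes.shape[0]} planes for "
            f"{len(channel_names)} names"
        )
    if planes.min() < 0:
        raise ValueError("negative pixel values in marker image")
    channels = {name: planes[i] for i, name in enumerate(channel_names)}
    return MarkerImage(channels, pixel_size_um=pixel_size_um, modality=modality)


def write_marker_image(image: MarkerImage, path) -> None:
    stack = np.stack([image.channels[n] for n in image.names])
    tifffile.imwrite(path, stack.astype(np.float32))


def imc_preprocess(image: MarkerImage) -> MarkerImage:
    """log2(x+1)-transform every channel of an IMC image.

    Strong isolated pixels dominate raw ion counts, so channels are
    log-transformed before synapse analysis; low-intensity pixels are kept
    (no noise floor is subtracted or thresholded away).
    """
    if image.modality != "imc":
        raise ValueError("imc_preprocess applies to modality='imc' images")
    if image.log_transformed:
        raise ValueError("image already log-transformed")
    channels = {n: np.log2(a + 1.0) for n, a in image.channels.items()}
    return MarkerImage(
        channels,
        pixel_size_um=image.pixel_size_um,
        modality=image.modality,
        log_transformed=True,
    )


def read_label_mask(path) -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(arr)


def write_label_mask(mask: LabelMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


_BOOL_COLS = ("ki67", "loaded", "multi_label")


def read_cell_table(path, mask: Optional[LabelMask] = None) -> CellTable:
    """Read a cell-annotation CSV; optionally check ids against a mask."""
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    table = CellTable(df)
    if mask is not None:
        table.validate_against(mask)
    return table


def write_cell_table(table: CellTable, path) -> None:
    df = table.df.copy()
    df["types"] = df["types"].map(types_to_str)
    df.to_csv(path, index=False)


def write_results(records, path, config=None, seed=None, extra_meta=None) -> None:
    """Write result dataclasses as a flat CSV plus a JSON metadata sidecar.

    ``records`` is a sequence of dataclass instances (e.g. SynapseScore);
    full float precision is kept via ``repr`` formatting.
    """
    records = list(records)
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for k, v in list(d.items()):
            if isinstance(v, frozenset):
                d[k] = types_to_str(v)
            elif isinstance(v, np.ndarray):
                d[k] = json.dumps(v.tolist())
        rows.append(d)
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    write_run_manifest(
        path.with_suffix(".meta.json"),
        command="write_results",
        config=config,
        seed=seed,
        inputs=[],
        extra=extra_meta,
    )


def read_results(path) -> pd.DataFrame:
    """Read a results CSV back losslessly (round-trip float parsing)."""
    return pd.read_csv(path, float_precision="round_trip")


def read_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config fields: {sorted(bad)}")
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["reference_types"] = list(config.reference_types)
    data["target_types"] = list(config.target_types)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path, command, config=None, seed=None, inputs=(), extra=None):
    """Persist the effective configuration and input digests for a run."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "rng_seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
        "inputs": {str(p): _digest(p) for p in inputs},
    }
    if manifest["config"]:
        for key in ("reference_types", "target_types"):
            if key in manifest["config"]:
                manifest["config"][key] = list(manifest["config"][key])
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
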