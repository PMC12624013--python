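"""Serialisation: layouts, traces, snapshots, run manifests.

All tabular outputs are plain CSV with a header row; rasters are lossless
greyscale PNG; manifests and layout metadata are plain structured text.
Everything written under a fixed seed is byte-identical across runs except
the manifest's timestamp line.
"""

from __future__ import annotations

import dataclasses
import hashlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .arrangements import ArrangementSpec, ConfigurationError, PillarLayout, _rasterize
from .simulator import Ensemble, SimulationTrace

__all__ = [
    "save_layout",
    "load_layout",
    "write_trace_csv",
    "write_ensemble_csv",
    "render_snapshot",
    "read_snapshot",
    "write_manifest",
    "read_manifest",
]

_LAYOUT_PNG = "layout.png"
_LAYOUT_META = "layout.meta.txt"
_LAYOUT_CENTERS = "centers.csv"

#: PNG grey levels for occupancy snapshots.
SNAPSHOT_TONES = {"empty": 0, "pillar": 128, "bacterium": 255}


def save_layout(layout: PillarLayout, out_dir: str | Path) -> Path:
    """Write a layout as PNG mask + key=value metadata + centres CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = (layout.obstacle_mask.astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(out / _LAYOUT_PNG)
    with open(out / _LAYOUT_META, "w") as fh:
        for k, v in dataclasses.asdict(layout.spec).items():
            fh.write(f"{k}={'' if v is None else v}\n")
    pd.DataFrame(
        {
            "row": layout.centers[:, 0] if len(layout.centers) else [],
            "col": layout.centers[:, 1] if len(layout.centers) else [],
            "radius": [layout.spec.pillar_radius] * len(layout.centers),
        }
    ).to_csv(out / _LAYOUT_CENTERS, index=False)
    return out


def load_layout(in_dir: str | Path) -> PillarLayout:
    """Reconstruct a layout saved by :func:`save_layout` (lossless)."""
    src = Path(in_dir)
    meta: dict[str, str] = {}
    for line in (src / _LAYOUT_META).read_text().splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            meta[k] = v
    spec = ArrangementSpec(
        kind=meta["kind"],
        field_size=int(meta["field_size"]),
        pillar_radius=int(meta["pillar_radius"]),
        block_n=int(meta["block_n"]) if meta.get("block_n") else None,
        intra_block_gap=int(meta["intra_block_gap"]) if meta.get("intra_block_gap") else None,
        array_gap=int(meta["array_gap"]),
        fractal_min_gap=int(meta["fractal_min_gap"]),
        seed=int(meta["seed"]),
    )
    mask = np.asarray(Image.open(src / _LAYOUT_PNG)) > 127
    df = pd.read_csv(src / _LAYOUT_CENTERS)
    centers = df[["row", "col"]].to_numpy(dtype=np.int64).reshape(-1, 2)
    expected = _rasterize(centers, spec.field_size, spec.pillar_radius)
    if not np.array_equal(mask, expected):
        raise ConfigurationError(f"layout mask in {src} is inconsistent with its centres")
    return PillarLayout(mask, centers, spec)


def write_trace_csv(trace: SimulationTrace, path: str | Path, replicate: int = 0) -> Path:
    path = Path(path)
    df = trace.to_dataframe()
    df.insert(0, "replicate", replicate)
    df.to_csv(path, index=False)
    return path


def write_ensemble_csv(ensemble: Ensemble, path: str | Path) -> Path:
    path = Path(path)
    ensemble.to_dataframe().to_csv(path, index=False)
    return path


def render_snapshot(occupancy: np.ndarray, layout: PillarLayout, out_path: str | Path) -> Path:
    """Write a 3-tone PNG (0 empty, 128 pillar, 255 bacterium) of an occupancy grid.

    ``occupancy`` is either a boolean agent mask or an int8 code grid
    (0/1/2) as produced by simulation snapshots.
    """
    occupancy = np.asarray(occupancy)
    if occupancy.shape != layout.obstacle_mask.shape:
        raise ConfigurationError("occupancy shape does not match the layout")
    if occupancy.dtype == bool:
        agents = occupancy
    else:
        agents = occupancy == 2
    if (agents & layout.obstacle_mask).any():
        raise ConfigurationError("occupancy marks bacteria on pillar pixels")
    img = np.zeros(occupancy.shape, dtype=np.uint8)
    img[layout.obstacle_mask] = SNAPSHOT_TONES["pillar"]
    img[agents] = SNAPSHOT_TONES["bacterium"]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="L").save(out_path)
    return out_path


def read_snapshot(path: str | Path) -> np.ndarray:
    """Read a snapshot PNG back into a 0/1/2 code grid."""
    img = np.asarray(Image.open(path))
    grid = np.zeros(img.shape, dtype=np.int8)
    grid[img == SNAPSHOT_TONES["pillar"]] = 1
    grid[img == SNAPSHOT_TONES["bacterium"]] = 2
    return grid


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Write the run manifest: resolved config, package version, file checksums."""
    from . import __version__

    out = Path(out_dir)
    manifest_path = out / "manifest.yaml"
    inventory = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.yaml"
    }
    doc = {
        "package": "pillarsim",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "outputs": inventory,
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest_path


def read_manifest(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)
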