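"""File I/O for rasters, scenes, phenotype tables and layouts."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .layout import PlotLayout
from .simulate import CanopyScene

__all__ = [
    "read_raster",
    "write_raster",
    "write_scene",
    "read_scene",
    "read_phenotypes",
    "write_phenotypes",
    "layout_from_json",
    "layout_to_json",
]


def read_raster(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as a numpy array."""
    return np.asarray(iio.imread(path))


def write_raster(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image))


def write_scene(scene: CanopyScene, stem: str | Path) -> None:
    """Write a scene as ``<stem>.png`` (image), ``<stem>_mask.png``
    (0/255 mask) and ``<stem>.json`` (truth_vf, spread, seed)."""
    stem = Path(stem)
    iio.imwrite(stem.with_suffix(".png"), scene.image)
    iio.imwrite(stem.parent / f"{stem.name}_mask.png", (scene.truth_mask * 255).astype(np.uint8))
    meta = {"truth_vf": scene.truth_vf, "spread": scene.spread, "seed": scene.seed}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_scene(stem: str | Path) -> CanopyScene:
    stem = Path(stem)
    image = iio.imread(stem.with_suffix(".png"))
    mask = (iio.imread(stem.parent / f"{stem.name}_mask.png") > 127).astype(np.uint8)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return CanopyScene(
        image=np.asarray(image),
        truth_mask=mask,
        truth_vf=float(mask.mean()),
        spread=float(meta["spread"]),
        seed=int(meta["seed"]),
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"line_id", "trait", "environment", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV lacks columns {sorted(missing)}")
    return df


def write_phenotypes(tables: List[pd.DataFrame] | pd.DataFrame, path: str | Path) -> None:
    df = pd.concat(tables, ignore_index=True) if isinstance(tables, list) else tables
    df.to_csv(path, index=False)


def layout_to_json(layout: PlotLayout, path: str | Path) -> None:
    d = asdict(layout)
    d["grid"] = {k: list(v) for k, v in d["grid"].items()}
    d["origin"] = list(d["origin"])
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def layout_from_json(path: str | Path) -> PlotLayout:
    d = json.loads(Path(path).read_text())
    d["grid"] = {k: tuple(v) for k, v in d["grid"].items()}
    d["origin"] = tuple(d["origin"])
    return PlotLayout(**d)
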