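"""Readers and writers for the package's external formats.

Cell maps and tabular outputs are comma-separated with a header and
empty fields for missing values; tissue masks are single-channel 8-bit
PNG rasters with a JSON sidecar carrying the label->class map and the
pixel size in µm.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import TissueMask

CELL_MAP_COLUMNS = ["case_id", "x_um", "y_um", "cell_type"]


def write_cell_map(cells: pd.DataFrame, path: str | Path) -> None:
    cells[CELL_MAP_COLUMNS].to_csv(path, index=False)


def read_cell_map(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, dtype={"case_id": str, "cell_type": str})
    missing = set(CELL_MAP_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell map {path} lacks columns {sorted(missing)}")
    return cells


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mask(mask: TissueMask, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(path, mask.labels.astype(np.uint8))
    meta = {
        "um_per_pixel": mask.um_per_pixel,
        "classes": {str(k): v for k, v in mask.class_map.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_mask(path: str | Path) -> TissueMask:
    path = Path(path)
    labels = np.asarray(iio.imread(path))
    meta = json.loads(_sidecar(path).read_text())
    class_map = {int(k): v for k, v in meta["classes"].items()}
    return TissueMask(labels=labels, class_map=class_map,
                      um_per_pixel=float(meta["um_per_pixel"]))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Delimiter-separated table; NaN written as empty fields."""
    table.to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    """Plain key=value config file; '#' starts a comment."""
    config: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line {line!r}: expected key=value")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
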