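"""Per-case tissue phenotypic signatures.

Each case is summarised by: the ratio of the area of each
connection-frequency (CF) phenotype to the total tissue area; the
appearance-based (AP) smooth-muscle and inflammation ratios; the
stroma-tumor and necrosis-tumor ratios; and the Morisita-Horn index of
spatial coexistence between inflammatory and malignant epithelial
cells.  Tissue area always excludes normal mucosa, fat and non-tissue
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MASK_CLASSES

logger = logging.getLogger(__name__)

#: Mask classes that never count as tissue.
NON_TISSUE_CLASSES = ("background", "normal", "fat")

DEFAULT_QUADRAT_UM = 200.0


@dataclass
class TissueMask:
    """Categorical tissue raster with its label->class map and pixel size."""

    labels: np.ndarray  # uint8 raster, [row, col]
    class_map: dict[int, str]
    um_per_pixel: float

    def __post_init__(self):
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in self.class_map]
        if unknown:
            raise ValueError(f"mask labels {unknown} missing from the class map")
        missing = set(self.class_map.values()) - set(MASK_CLASSES)
        if missing:
            raise ValueError(f"unknown tissue classes {sorted(missing)}")

    @classmethod
    def from_labels(cls, labels: np.ndarray, um_per_pixel: float) -> "TissueMask":
        """Mask using the default label order of :data:`MASK_CLASSES`."""
        return cls(labels, dict(enumerate(MASK_CLASSES)), um_per_pixel)

    def class_area_um2(self, class_name: str) -> float:
        values = [v for v, c in self.class_map.items() if c == class_name]
        count = int(np.isin(self.labels, values).sum())
        return count * self.um_per_pixel**2


def tissue_area(mask: TissueMask) -> float:
    """Total tissue area in µm²: all classes except normal, fat, background."""
    return float(
        sum(
            mask.class_area_um2(c)
            for c in MASK_CLASSES
            if c not in NON_TISSUE_CLASSES
        )
    )


def _tissue_pixels(mask: TissueMask) -> np.ndarray:
    non_tissue = [v for v, c in mask.class_map.items() if c in NON_TISSUE_CLASSES]
    return ~np.isin(mask.labels, non_tissue)


def cf_phenotype_ratios(
    tile_table: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    mask: TissueMask | None = None,
    tile_size_um: float = 200.0,
) -> dict[int, float]:
    """Area ratio of each CF phenotype to the total tissue area of one case.

    ``tile_table`` holds the case's phenotyped tile rows (columns ``row``,
    ``col``) aligned with ``labels`` (1..k).  With a mask, the numerator
    for a phenotype is the tissue-pixel area inside its tiles and the
    denominator is the mask's tissue area; without a mask, tile counts
    over the phenotyped-tile count are used (ratios then sum to 1).
    A zero denominator yields missing ratios with a logged warning.
    """
    if len(tile_table) != len(labels):
        raise ValueError("labels must align with tile_table rows")
    ratios: dict[int, float] = {}
    if mask is None:
        total = len(labels)
        if total == 0:
            logger.warning("no phenotyped tiles: CF ratios undefined")
            return {p: np.nan for p in range(1, k + 1)}
        for p in range(1, k + 1):
            ratios[p] = float(np.sum(labels == p) / total)
        return ratios
    tissue = _tissue_pixels(mask)
    denom = tissue.sum() * mask.um_per_pixel**2
    if denom == 0:
        logger.warning("zero tissue area: CF ratios undefined")
        return {p: np.nan for p in range(1, k + 1)}
    px_per_tile = tile_size_um / mask.um_per_pixel
    areas = np.zeros(k + 1)
    for (r, c), label in zip(
        tile_table[["row", "col"]].to_numpy(dtype=int), labels
    ):
        r0 = int(round(r * px_per_tile))
        c0 = int(round(c * px_per_tile))
        r1 = min(int(round((r + 1) * px_per_tile)), tissue.shape[0])
        c1 = min(int(round((c + 1) * px_per_tile)), tissue.shape[1])
        areas[label] += tissue[r0:r1, c0:c1].sum() * mask.um_per_pixel**2
    for p in range(1, k + 1):
        ratios[p] = float(areas[p] / denom)
    return ratios


def ap_ratios(mask: TissueMask) -> dict[str, float]:
    """Appearance-based smooth-muscle and inflammation area ratios."""
    denom = tissue_area(mask)
    if denom == 0:
        return {"ap_smooth_muscle_ratio": np.nan, "ap_inflammation_ratio": np.nan}
    return {
        "ap_smooth_muscle_ratio": mask.class_area_um2("smooth_muscle") / denom,
        "ap_inflammation_ratio": mask.class_area_um2("inflammation") / denom,
    }


def stroma_tumor_ratio(mask: TissueMask) -> float:
    """stroma area / (stroma area + tumor area); missing when both are zero."""
    stroma = mask.class_area_um2("stroma")
    tumor = mask.class_area_um2("tumor")
    if stroma + tumor == 0:
        return np.nan
    return stroma / (stroma + tumor)


def necrosis_tumor_ratio(mask: TissueMask) -> float:
    """necrosis area / (necrosis area + tumor area); missing when both are zero."""
    necrosis = mask.class_area_um2("necrosis")
    tumor = mask.class_area_um2("tumor")
    if necrosis + tumor == 0:
        return np.nan
    return necrosis / (necrosis + tumor)


def morisita_index(
    cells: pd.DataFrame, quadrat_size_um: float = DEFAULT_QUADRAT_UM
) -> float:
    """Morisita-Horn overlap of inflammatory and malignant cells over quadrats.

    Counts inflammatory (x) and malignant epithelial (y) cells in square
    quadrats aligned with the tile grid and evaluates

        MH = 2 sum_q x_q y_q / ((sum x_q^2 / X^2 + sum y_q^2 / Y^2) X Y)

    with X = sum x_q and Y = sum y_q.  MH is 1 for proportionally
    identical quadrat profiles, 0 for disjoint occupancy, and missing
    when either population is absent.
    """
    if quadrat_size_um <= 0:
        raise ValueError("quadrat_size_um must be positive")
    sub = cells[cells["cell_type"].isin(["I", "M"])]
    if len(sub) == 0:
        return np.nan
    col = np.floor(sub["x_um"].to_numpy(dtype=float) / quadrat_size_um).astype(int)
    row = np.floor(sub["y_um"].to_numpy(dtype=float) / quadrat_size_um).astype(int)
    quad_key = row * (col.max() + 1) + col  # flat quadrat index
    quad = pd.DataFrame({"q": quad_key, "t": sub["cell_type"].to_numpy()})
    counts = pd.crosstab(quad["q"], quad["t"]).reindex(columns=["I", "M"], fill_value=0)
    x = counts["I"].to_numpy(dtype=float)
    y = counts["M"].to_numpy(dtype=float)
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        return np.nan
    denom = (np.sum(x**2) / X**2 + np.sum(y**2) / Y**2) * X * Y
    return float(2.0 * np.sum(x * y) / denom)


def case_features(
    case_id: str,
    tile_table: pd.DataFrame,
    labels: np.ndarray,
    k: int,
    cells: pd.DataFrame,
    mask: TissueMask | None = None,
    phenotype_names: list[str] | None = None,
    tile_size_um: float = 200.0,
) -> dict:
    """Assemble one case's full feature record."""
    cf = cf_phenotype_ratios(tile_table, labels, k, mask, tile_size_um)
    if phenotype_names is None:
        cf_cols = {f"cf_phenotype_{p}_ratio": v for p, v in cf.items()}
    else:
        cf_cols = {f"cf_{phenotype_names[p - 1]}_ratio": v for p, v in cf.items()}
    rec: dict = {"case_id": case_id, **cf_cols}
    if mask is not None:
        rec.update(ap_ratios(mask))
        rec["stroma_tumor_ratio"] = stroma_tumor_ratio(mask)
        rec["necrosis_tumor_ratio"] = necrosis_tumor_ratio(mask)
        rec["tissue_area_um2"] = tissue_area(mask)
    rec["morisita_index"] = morisita_index(cells)
    return rec


def build_feature_table(case_records: list[dict]) -> pd.DataFrame:
    """Per-case feature table with a stable column order.

    One row per case; missing features stay NaN (written as empty fields
    on export).  Duplicate case ids are rejected.
    """
    if not case_records:
        return pd.DataFrame(columns=["case_id"])
    table = pd.DataFrame(case_records)
    if table["case_id"].duplicated().any():
        dupes = table.loc[table["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids {dupes}")
    ordered = ["case_id"] + [c for c in table.columns if c != "case_id"]
    return table[ordered]
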