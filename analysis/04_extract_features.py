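"""Compute per-case tissue phenotypic signatures.

Joins the phenotype assignments with the tissue masks to produce one
feature row per case: CF phenotype area ratios (denominator = tissue
area excluding normal/fat/background), AP smooth-muscle and
inflammation ratios, stroma-tumor and necrosis-tumor ratios, and the
Morisita-Horn coexistence index of inflammatory and malignant cells.
"""

import sys
from pathlib import Path

from phenonet.features import build_feature_table, case_features
from phenonet.io import read_cell_map, read_mask, read_table, write_table
from phenonet.phenotyping import PhenotypeModel

OUT = Path("results/analysis")


def main():
    cells = read_cell_map(OUT / "cells.csv")
    assignments = read_table(OUT / "assignments.csv")
    model = PhenotypeModel.from_json(OUT / "phenotype_model.json")

    records = []
    for case_id, case_assign in assignments.groupby("case_id", sort=True):
        records.append(
            case_features(
                case_id=str(case_id),
                tile_table=case_assign,
                labels=case_assign["phenotype"].to_numpy(),
                k=model.k,
                cells=cells[cells["case_id"] == case_id],
                mask=read_mask(OUT / "masks" / f"{case_id}.png"),
                phenotype_names=model.names,
            )
        )
    features = build_feature_table(records)
    write_table(features, OUT / "features.csv")

    print(f"{len(features)} cases x {len(features.columns) - 1} features")
    summary = features.drop(columns=["case_id", "tissue_area_um2"]).describe()
    print(summary.loc[["mean", "50%"]].round(3).to_string())
    print(f"wrote {OUT / 'features.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
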