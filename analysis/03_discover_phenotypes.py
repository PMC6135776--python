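"""Discover tissue phenotypes by chi-squared k-medoids and choose k.

Pools every phenotyped tile of the cohort, scans k = 2..8 with the
medoid-distance (>= 0.2) and feature-correlation (<= 0.8) admissibility
criteria (on a 1000-tile subsample to keep the scan quick), fits the
final model on all tiles at the selected k with the 100-restart
protocol, names the phenotypes by the dominant-pair heuristic, and
assigns every tile to its nearest medoid.
"""

import sys
from pathlib import Path

import numpy as np

from phenonet.cellgraph import N_PAIRS
from phenonet.io import read_table, write_table
from phenonet.phenotyping import assign_phenotypes, kmedoids, name_phenotypes, select_k

OUT = Path("results/analysis")
SEED = 404
SCAN_SUBSAMPLE = 1000


def main():
    tiles = read_table(OUT / "tiles.csv")
    phen = tiles[tiles["phenotyped"]].reset_index(drop=True)
    vectors = phen[[f"h_{i + 1}" for i in range(N_PAIRS)]].to_numpy()

    rng = np.random.default_rng(SEED)
    sub = rng.choice(len(vectors), min(SCAN_SUBSAMPLE, len(vectors)), replace=False)
    selection = select_k(
        vectors[sub], phen["case_id"].to_numpy()[sub], k_range=range(2, 9),
        n_restarts=20, seed=SEED,
    )
    write_table(selection.diagnostics, OUT / "k_selection.csv")
    print(selection.diagnostics.round(3).to_string(index=False))
    if selection.selected_k is None:
        print("no admissible k in range; stopping")
        return 1
    k = selection.selected_k

    model = kmedoids(vectors, k, n_restarts=100, seed=SEED)
    names = name_phenotypes(model)
    model.to_json(OUT / "phenotype_model.json")
    phen = phen.assign(phenotype=assign_phenotypes(model, vectors))
    write_table(
        phen[["case_id", "row", "col", "phenotype"]], OUT / "assignments.csv"
    )

    print(f"\nselected k = {k}; phenotypes: {names}")
    print(f"total cost {model.cost:.2f} "
          f"(best of {len(model.replicate_costs)} restarts)")
    print(f"wrote {OUT / 'phenotype_model.json'} and assignments")
    return 0


if __name__ == "__main__":
    sys.exit(main())
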