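"""Simulate the study cohort's slides: typed cell maps and tissue masks.

Each of 30 cases gets a 1600x1600 µm slide laid out as a grid of
200 µm blocks, each block drawn from one of the six tissue archetypes
according to a case-specific composition, so cases differ in their
phenotypic make-up the way real tumor sections do.  Writes the pooled
cell map, per-case masks, and the true per-case compositions (kept for
comparison in later steps, never used by the pipeline itself).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from phenonet.features import TissueMask
from phenonet.io import write_cell_map, write_mask, write_table
from phenonet.pipeline import RunConfig, random_case_layout
from phenonet.synthetic import default_archetypes, generate_slide

OUT = Path("results/analysis")
SEED = 20260920
N_CASES = 30

def main():
    (OUT / "masks").mkdir(parents=True, exist_ok=True)
    config = RunConfig(n_cases=N_CASES, slide_um=1600.0, seed=SEED)
    rng = np.random.default_rng(SEED)
    archetypes = default_archetypes()
    names = [a.name for a in archetypes]
    all_cells, truth = [], []
    for i in range(N_CASES):
        case_id = f"case_{i:04d}"
        composition = rng.dirichlet(np.ones(len(archetypes)))
        layout = random_case_layout(config, composition, names, rng)
        cells, mask = generate_slide(
            layout, seed=int(rng.integers(2**31)), archetypes=archetypes,
            case_id=case_id,
        )
        all_cells.append(cells)
        write_mask(
            TissueMask.from_labels(mask, config.mask_resolution_um),
            OUT / "masks" / f"{case_id}.png",
        )
        truth.append({"case_id": case_id, **dict(zip(names, composition))})
    cells = pd.concat(all_cells, ignore_index=True)
    write_cell_map(cells, OUT / "cells.csv")
    write_table(pd.DataFrame(truth), OUT / "true_compositions.csv")

    print(f"simulated {N_CASES} slides, {len(cells):,} cells total")
    print("cell-type mix:", cells["cell_type"].value_counts(normalize=True)
          .round(3).to_dict())
    print(f"wrote {OUT / 'cells.csv'} and {N_CASES} masks")
    return 0


if __name__ == "__main__":
    sys.exit(main())
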