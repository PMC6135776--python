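"""End-to-end orchestration: simulate -> network -> phenotype -> features -> stats.

A run is fully determined by a :class:`RunConfig`; all randomness flows
from its single root seed, split per stage, and the resolved config is
written beside the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellgraph import N_PAIRS, tile_frequency_table
from .features import TissueMask, build_feature_table, case_features
from .io import write_cell_map, write_mask, write_table
from .phenotyping import assign_phenotypes, kmedoids, name_phenotypes, select_k
from .stats import (
    FitFailure,
    cox_iqr_effect,
    km_table,
    logistic_iqr_effect,
    minp_cutoff,
)
from .synthetic import (
    CohortConfig,
    SlideLayout,
    default_archetypes,
    generate_cohort,
    generate_slide,
)

logger = logging.getLogger(__name__)

CLINICAL_ADJUSTERS = ("differentiation", "histological_type", "t_stage")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the analysis constants: 200 µm tiles, 100 clustering
    restarts, k-selection thresholds 0.2 (medoid distance) and 0.8
    (feature correlation), a 10-90% cutoff scan window, and 100
    bootstrap replicates / imputations where those stages run at full
    scale.
    """

    out_dir: str = "results/run"
    n_cases: int = 20
    slide_um: float = 1600.0
    block_um: float = 200.0
    mask_resolution_um: float = 2.2
    tile_size_um: float = 200.0
    min_cells: int = 5
    k: int | None = 6
    k_range: tuple[int, int] = (2, 8)
    restarts: int = 100
    dist_threshold: float = 0.2
    corr_threshold: float = 0.8
    quantile_window: tuple[float, float] = (0.1, 0.9)
    n_boot: int = 100
    m_imputations: int = 100
    seed: int = 0
    # planted outcome model over computed feature columns (missing columns
    # are dropped with a warning, so runs stay robust to phenotype naming)
    beta: dict = field(
        default_factory=lambda: {
            "cf_smooth_muscle_ratio": 6.0,
            "cf_inflammation_ratio": -8.0,
        }
    )
    log_hazard: dict = field(
        default_factory=lambda: {
            "cf_smooth_muscle_ratio": 6.0,
            "cf_inflammation_ratio": -8.0,
        }
    )


def random_case_layout(
    config: RunConfig, composition: np.ndarray, archetype_names: list[str],
    rng: np.random.Generator,
) -> SlideLayout:
    """Block-grid slide layout with archetypes drawn from a case composition."""
    n_blocks = int(config.slide_um // config.block_um)
    regions = []
    for r in range(n_blocks):
        for c in range(n_blocks):
            name = archetype_names[rng.choice(len(archetype_names), p=composition)]
            x0, y0 = c * config.block_um, r * config.block_um
            regions.append(((x0, y0, x0 + config.block_um, y0 + config.block_um), name))
    return SlideLayout(
        width_um=config.slide_um,
        height_um=config.slide_um,
        regions=regions,
        mask_resolution_um=config.mask_resolution_um,
    )


def _stage_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated cohort and write all outputs.

    Returns a dict of the main in-memory results (tile table, phenotype
    model, feature table, cohort table, effect tables).
    """
    out = Path(config.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    seed_sim, seed_phen, seed_cohort, seed_stats = _stage_seeds(config.seed, 4)

    # --- stage 1: simulate slides -------------------------------------
    rng = np.random.default_rng(seed_sim)
    archetypes = default_archetypes()
    names = [a.name for a in archetypes]
    all_cells, masks = [], {}
    for i in range(config.n_cases):
        case_id = f"case_{i:04d}"
        composition = rng.dirichlet(np.ones(len(archetypes)))
        layout = random_case_layout(config, composition, names, rng)
        cells, mask_labels = generate_slide(
            layout, seed=int(rng.integers(2**31)), archetypes=archetypes,
            case_id=case_id,
        )
        all_cells.append(cells)
        masks[case_id] = TissueMask.from_labels(mask_labels, config.mask_resolution_um)
        write_mask(masks[case_id], out / "masks" / f"{case_id}.png")
    cells = pd.concat(all_cells, ignore_index=True)
    write_cell_map(cells, out / "cells.csv")

    # --- stage 2: tile networks and frequency vectors -----------------
    tiles = tile_frequency_table(cells, config.tile_size_um, config.min_cells)
    write_table(tiles, out / "tiles.csv")
    phenotyped = tiles[tiles["phenotyped"]].reset_index(drop=True)
    h_cols = [f"h_{i + 1}" for i in range(N_PAIRS)]
    vectors = phenotyped[h_cols].to_numpy()

    # --- stage 3: phenotyping -----------------------------------------
    if config.k is None:
        selection = select_k(
            vectors,
            phenotyped["case_id"].to_numpy(),
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            dist_threshold=config.dist_threshold,
            corr_threshold=config.corr_threshold,
            n_restarts=config.restarts,
            seed=seed_phen,
        )
        write_table(selection.diagnostics, out / "k_selection.csv")
        if selection.selected_k is None:
            raise RuntimeError("phenotyping failed: no admissible k in range")
        k = selection.selected_k
    else:
        k = config.k
    model = kmedoids(vectors, k, n_restarts=config.restarts, seed=seed_phen)
    phen_names = name_phenotypes(model)
    model.to_json(out / "phenotype_model.json")
    labels = assign_phenotypes(model, vectors)

    # --- stage 4: per-case features -----------------------------------
    records = []
    for case_id, case_tiles in phenotyped.groupby("case_id", sort=True):
        idx = case_tiles.index.to_numpy()
        records.append(
            case_features(
                case_id=str(case_id),
                tile_table=case_tiles,
                labels=labels[idx],
                k=k,
                cells=cells[cells["case_id"] == case_id],
                mask=masks.get(str(case_id)),
                phenotype_names=phen_names,
                tile_size_um=config.tile_size_um,
            )
        )
    features = build_feature_table(records)
    write_table(features, out / "features.csv")

    # --- stage 5: cohort outcomes and prognostic statistics -----------
    feature_cols = [
        c for c in features.columns if c not in ("case_id", "tissue_area_um2")
    ]
    beta = {k_: v for k_, v in config.beta.items() if k_ in feature_cols}
    log_hazard = {
        k_: v for k_, v in config.log_hazard.items() if k_ in feature_cols
    }
    for missing in set(config.beta) - set(beta):
        logger.warning("planted logistic effect on absent feature %r dropped", missing)
    for missing in set(config.log_hazard) - set(log_hazard):
        logger.warning("planted hazard effect on absent feature %r dropped", missing)
    cohort_config = CohortConfig(
        n_cases=len(features), beta=beta, log_hazard=log_hazard, seed=seed_cohort
    )
    cohort = generate_cohort(
        cohort_config, features[feature_cols].reset_index(drop=True)
    )
    cohort["case_id"] = features["case_id"].to_numpy()
    write_table(cohort, out / "cohort.csv")

    logistic_rows, cox_rows = [], []
    adjusters = tuple(CLINICAL_ADJUSTERS) + ("cohort",)
    for feat in feature_cols:
        if cohort[feat].isna().all():
            continue
        for adj in ((), adjusters):
            try:
                logistic_rows.append(
                    logistic_iqr_effect(cohort, feat, adjusters=adj).as_row()
                )
            except (FitFailure, ValueError) as err:
                logger.warning("logistic %s (%s) failed: %s",
                               feat, "multi" if adj else "uni", err)
        for adj in ((), tuple(CLINICAL_ADJUSTERS)):
            try:
                cox_rows.append(
                    cox_iqr_effect(
                        cohort, feat, adjusters=adj,
                        n_boot=config.n_boot, seed=seed_stats,
                    ).as_row()
                )
            except (FitFailure, ValueError) as err:
                logger.warning("cox %s (%s) failed: %s",
                               feat, "multi" if adj else "uni", err)
    logistic_table = pd.DataFrame(logistic_rows)
    cox_table = pd.DataFrame(cox_rows)
    write_table(logistic_table, out / "logistic_effects.csv")
    write_table(cox_table, out / "cox_effects.csv")

    cutoff_rows = []
    for feat in feature_cols:
        values = cohort[feat]
        if values.isna().all() or values.nunique() < 4:
            continue
        try:
            res = minp_cutoff(
                values, cohort["dmfs_time_years"], cohort["dmfs_event"],
                quantile_window=config.quantile_window,
            )
        except ValueError:
            continue
        cutoff_rows.append(
            {
                "feature": feat,
                "cutoff": res.cutoff,
                "n_low": res.n_low,
                "n_high": res.n_high,
                "p_min": res.p_min,
                "p_corrected": res.p_corrected,
            }
        )
        groups = np.where(cohort[feat] > res.cutoff, "high", "low")
        km = km_table(cohort["dmfs_time_years"], cohort["dmfs_event"], groups)
        km.insert(0, "feature", feat)
        mode = "a" if (out / "km_curves.csv").exists() and cutoff_rows[:-1] else "w"
        km.to_csv(out / "km_curves.csv", mode=mode, header=mode == "w", index=False)
    write_table(pd.DataFrame(cutoff_rows), out / "cutoffs.csv")

    manifest = {
        "phenonet_version": __version__,
        "config": asdict(config),
        "stage_seeds": {
            "simulate": seed_sim,
            "phenotype": seed_phen,
            "cohort": seed_cohort,
            "stats": seed_stats,
        },
        "k": k,
        "phenotype_names": phen_names,
        "digests": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ("cells.csv", "tiles.csv", "features.csv", "cohort.csv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "tiles": tiles,
        "model": model,
        "features": features,
        "cohort": cohort,
        "logistic": logistic_table,
        "cox": cox_table,
    }
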