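"""Tissue phenotyping by chi-squared k-medoids over connection-frequency vectors.

All tiles of a cohort are pooled and clustered into k phenotypes with a
partition-around-medoids search under the chi-squared histogram distance

    d(h, m) = sum_k (h_k - m_k)^2 / (h_k + m_k),

which is bounded by 2 on the simplex.  The clustering is restarted from
random medoids (100 restarts by default) and the replicate with the
smallest total within-cluster distance is kept.  The number of
phenotypes is chosen as the largest k for which (a) every pair of
medoids stays at chi-squared distance >= 0.2 of each other and (b) no
pair of per-case phenotype-ratio features exceeds absolute Spearman
correlation 0.8 — closer medoids or more correlated features mean a
redundant phenotype was split off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "chi_squared_distance",
    "pairwise_chi_squared",
    "kmedoids",
    "assign_phenotypes",
    "select_k",
    "name_phenotypes",
    "PhenotypeModel",
    "SelectKResult",
]


def chi_squared_distance(h: np.ndarray, m: np.ndarray) -> float:
    """Chi-squared histogram distance between two nonnegative vectors.

    Components where h_k + m_k = 0 contribute nothing.  Symmetric, zero
    iff h == m, and at most 2 when both arguments lie on the simplex.
    """
    h = np.asarray(h, dtype=float)
    m = np.asarray(m, dtype=float)
    if h.shape != m.shape:
        raise ValueError("vectors must have equal length")
    if (h < 0).any() or (m < 0).any():
        raise ValueError("chi-squared distance requires nonnegative components")
    s = h + m
    diff2 = (h - m) ** 2
    nz = s > 0
    return float(np.sum(diff2[nz] / s[nz]))


def pairwise_chi_squared(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Chi-squared distance matrix between the rows of x and y (or x and x)."""
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("chi-squared distance requires nonnegative components")
    s = x[:, None, :] + y[None, :, :]
    d = (x[:, None, :] - y[None, :, :]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, d / np.where(s > 0, s, 1.0), 0.0)
    return terms.sum(axis=2)


@dataclass
class PhenotypeModel:
    """Fitted k-medoids phenotype model.

    Medoids are members of the training set (``medoid_indices`` indexes
    the input vectors).  ``replicate_costs`` records the total cost of
    every restart; the stored model is the minimum-cost replicate.
    """

    k: int
    medoids: np.ndarray
    medoid_indices: np.ndarray
    cost: float
    replicate_costs: np.ndarray
    seed: int | None = None
    names: list[str] | None = field(default=None)

    def medoid_distances(self) -> np.ndarray:
        """Pairwise chi-squared distances between the medoids."""
        return pairwise_chi_squared(self.medoids)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "k": self.k,
            "medoids": self.medoids.tolist(),
            "medoid_indices": self.medoid_indices.tolist(),
            "cost": self.cost,
            "replicate_costs": self.replicate_costs.tolist(),
            "seed": self.seed,
            "names": self.names,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhenotypeModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            k=doc["k"],
            medoids=np.asarray(doc["medoids"], dtype=float),
            medoid_indices=np.asarray(doc["medoid_indices"], dtype=int),
            cost=float(doc["cost"]),
            replicate_costs=np.asarray(doc["replicate_costs"], dtype=float),
            seed=doc.get("seed"),
            names=doc.get("names"),
        )


def _pam(dist: np.ndarray, init: np.ndarray, max_iter: int = 200):
    """Greedy swap descent from an initial medoid set to a local optimum.

    Each iteration evaluates every (medoid, non-medoid) swap and applies
    the single best strictly improving one, so the total cost is
    non-increasing and the search terminates at a local optimum.  The
    swap deltas decompose as delta(i, j) = A(j) + B(i, j) with A the
    cost change from adding candidate j (independent of which medoid
    leaves) and B the correction for points whose nearest medoid i is
    removed, so one iteration costs O(n^2) element operations.
    """
    n = dist.shape[0]
    medoids = np.array(init, dtype=int)
    k = len(medoids)
    rows = np.arange(n)
    for _ in range(max_iter):
        dm = dist[:, medoids]  # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[rows, nearest]
        d2 = dm[rows, order[:, 1]] if k > 1 else np.full(n, np.inf)
        min_d1 = np.minimum(dist, d1[:, None])  # (point p, candidate j)
        add_gain = min_d1.sum(axis=0) - d1.sum()  # A(j)
        removal = np.minimum(dist, d2[:, None]) - min_d1  # per-point B term
        delta = np.empty((k, n))
        for i in range(k):
            delta[i] = add_gain + removal[nearest == i].sum(axis=0)
        delta[:, medoids] = np.inf
        best = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[best] >= -1e-12:
            break
        medoids[best[0]] = int(best[1])
    dm = dist[:, medoids]
    return np.sort(medoids), float(dm[rows, np.argmin(dm, axis=1)].sum())


def kmedoids(
    vectors: np.ndarray,
    k: int,
    n_restarts: int = 100,
    seed: int | None = None,
    init: str = "random",
) -> PhenotypeModel:
    """Chi-squared k-medoids with restart-and-best-cost selection.

    Parameters
    ----------
    vectors
        (n, p) nonnegative frequency vectors (rows on the simplex for
        connection-frequency data, though only nonnegativity is required).
    k
        Number of phenotypes; must not exceed the number of *distinct*
        vectors.
    n_restarts
        Number of uniformly random initialisations (default 100); the
        replicate with the smallest total distance is returned.
    init
        ``"random"`` (default) or ``"exhaustive"``, which starts one
        replicate from every k-subset of the data (small n only) and is
        guaranteed to contain the global optimum among its starts.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("vectors must be a non-empty 2-D array")
    n = len(x)
    n_distinct = len(np.unique(x, axis=0))
    if not 1 <= k <= n_distinct:
        raise ValueError(f"k={k} must be in [1, {n_distinct}] (distinct vectors)")
    dist = pairwise_chi_squared(x)
    if init == "exhaustive":
        starts = [np.array(c) for c in combinations(range(n), k)]
    elif init == "random":
        rng = np.random.default_rng(seed)
        starts = [rng.choice(n, size=k, replace=False) for _ in range(n_restarts)]
    else:
        raise ValueError(f"unknown init {init!r}")
    costs = np.empty(len(starts))
    results = []
    for r, start in enumerate(starts):
        medoids, cost = _pam(dist, start)
        costs[r] = cost
        results.append(medoids)
    best = int(np.argmin(costs))
    medoid_idx = results[best]
    return PhenotypeModel(
        k=k,
        medoids=x[medoid_idx].copy(),
        medoid_indices=medoid_idx,
        cost=float(costs[best]),
        replicate_costs=costs,
        seed=seed,
    )


def assign_phenotypes(model: PhenotypeModel, vectors: np.ndarray) -> np.ndarray:
    """Label each vector 1..k by its nearest medoid (ties -> lowest index)."""
    x = np.asarray(vectors, dtype=float)
    dist = pairwise_chi_squared(x, model.medoids)
    return np.argmin(dist, axis=1) + 1


@dataclass
class SelectKResult:
    selected_k: int | None
    diagnostics: pd.DataFrame
    status: str  # "ok" or "no admissible k"


def _per_case_ratios(
    labels: np.ndarray,
    case_ids: np.ndarray,
    k: int,
    tissue_area: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-case phenotype-ratio features.

    The numerator is the per-case tile count of each phenotype; the
    denominator is the case's tissue area in tile units when given
    (mirroring the ratio-to-total-tissue-area feature definition),
    otherwise the phenotyped-tile count (ratios then sum to 1).
    """
    df = pd.DataFrame({"case": case_ids, "label": labels})
    counts = pd.crosstab(df["case"], df["label"]).reindex(
        columns=range(1, k + 1), fill_value=0
    )
    if tissue_area is None:
        denom = counts.sum(axis=1)
    else:
        denom = pd.Series(tissue_area).reindex(counts.index)
        if denom.isna().any() or (denom <= 0).any():
            raise ValueError("tissue_area must give a positive area per case")
    return counts.div(denom, axis=0)


def select_k(
    vectors: np.ndarray,
    case_ids: np.ndarray,
    k_range: range = range(2, 11),
    dist_threshold: float = 0.2,
    corr_threshold: float = 0.8,
    n_restarts: int = 100,
    seed: int | None = None,
    tissue_area: pd.Series | dict | None = None,
) -> SelectKResult:
    """Choose the number of phenotypes by the distance/correlation criteria.

    For each candidate k the model is fitted and two diagnostics are
    computed: the minimum pairwise chi-squared distance between medoids,
    and the maximum absolute Spearman correlation over all pairs of
    per-case phenotype-ratio features.  k is admissible when the former
    is >= ``dist_threshold`` and the latter <= ``corr_threshold`` (a
    medoid pair closer than 0.2, or a feature correlation above 0.8,
    marks a redundant split).  The largest admissible k is selected.

    ``tissue_area`` optionally gives each case's tissue area in tile
    units as the ratio denominator; without it the phenotyped-tile
    count is used, which closes the ratios to sum 1 (note that at k = 2
    closure makes the two features perfectly anticorrelated).
    """
    case_ids = np.asarray(case_ids)
    if len(case_ids) != len(vectors):
        raise ValueError("case_ids must align with vectors")
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        sub_seed = int(rng.integers(2**31))
        model = kmedoids(vectors, k, n_restarts=n_restarts, seed=sub_seed)
        dmat = model.medoid_distances()
        min_dist = float(dmat[np.triu_indices(k, 1)].min()) if k > 1 else np.inf
        labels = assign_phenotypes(model, vectors)
        ratios = _per_case_ratios(labels, case_ids, k, tissue_area)
        max_corr = 0.0
        for a, b in combinations(ratios.columns, 2):
            rho = spearmanr(ratios[a], ratios[b]).statistic
            if np.isfinite(rho):  # constant columns give NaN: no redundancy signal
                max_corr = max(max_corr, abs(float(rho)))
        rows.append(
            {
                "k": k,
                "cost": model.cost,
                "min_medoid_distance": min_dist,
                "max_abs_feature_correlation": max_corr,
                "admissible": bool(
                    min_dist >= dist_threshold and max_corr <= corr_threshold
                ),
            }
        )
    diagnostics = pd.DataFrame(rows)
    admissible = diagnostics.loc[diagnostics["admissible"], "k"]
    if len(admissible):
        return SelectKResult(int(admissible.max()), diagnostics, "ok")
    return SelectKResult(None, diagnostics, "no admissible k")


def _type_mass(h: np.ndarray) -> np.ndarray:
    """Per-type share of edge mass: own-type edges plus half of mixed edges."""
    from .cellgraph import PAIR_ORDER

    w = np.zeros(4)
    for pos, (i, j) in enumerate(PAIR_ORDER):
        if i == j:
            w[i - 1] += h[pos]
        else:
            w[i - 1] += 0.5 * h[pos]
            w[j - 1] += 0.5 * h[pos]
    return w


def name_phenotypes(
    model: PhenotypeModel, mapping: dict[int, str] | None = None
) -> list[str]:
    """Attach cosmetic tissue names to the phenotypes.

    A user-supplied ``mapping`` (1-based phenotype index -> name) is
    returned verbatim where given.  Otherwise a dominant-pair heuristic
    is applied to each medoid: necrotic edge mass -> ``necrosis``; a
    heavy M-S spectrum -> ``tumor_stroma_interface``; then the dominant
    type decides ``tumor``, ``inflammation``, ``smooth_muscle`` (nearly
    pure S-S connections) or ``stroma`` (mixed spindle spectra).  Names
    never affect any downstream number.
    """
    from .cellgraph import pair_index

    names = []
    for idx, medoid in enumerate(model.medoids, start=1):
        if mapping and idx in mapping:
            names.append(mapping[idx])
            continue
        w = _type_mass(medoid)
        h_ms = medoid[pair_index("M", "S")]
        h_mm = medoid[pair_index("M", "M")]
        h_ss = medoid[pair_index("S", "S")]
        if w[3] >= 0.2:
            names.append("necrosis")
        elif h_ms >= 0.3 or (h_ms >= 0.15 and h_ms >= max(h_mm, h_ss)):
            names.append("tumor_stroma_interface")
        elif w[0] == w.max():
            names.append("tumor")
        elif w[1] == w.max():
            names.append("inflammation")
        elif h_ss >= 0.7:
            names.append("smooth_muscle")
        else:
            names.append("stroma")
    # disambiguate repeats so names stay usable as column labels
    seen: dict[str, int] = {}
    out = []
    for name in names:
        seen[name] = seen.get(name, 0) + 1
        out.append(name if seen[name] == 1 else f"{name}_{seen[name]}")
    model.names = out
    return out
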