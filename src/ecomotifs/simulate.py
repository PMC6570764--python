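"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: count and
presence matrices sampled exactly from the grade-of-membership models,
rectangular species range grids with an optional tropical/temperate
two-band structure, survey-site tables, and ultrametric pure-birth
trees. Each generator returns the stored truth alongside the data so
recovery can be measured directly.

Theta construction ("separation"): each motif's profile is a convex
blend ``(1 - s) * shared_baseline + s * private_block``, where the
private part lives on that motif's own block of features. s = 0 makes
all motifs identical (no recoverable structure); s = 1 gives disjoint
supports (trivially separable). The defaults — moderate membership
concentration (Dirichlet 0.3), separation 0.8, census depth in the
hundreds to a thousand individuals per site — mimic the sparse,
strongly structured community surveys this kind of model is applied to.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .dispersion import GridGeometry, RangeGridSet, SiteTable
from .matrices import CountMatrix, LabelledMatrix, PresenceMatrix
from .phylo import TimeTree

__all__ = [
    "SimTruth",
    "simulate_gom",
    "simulate_ranges",
    "simulate_timetree",
    "make_land_grid",
    "recovery_error",
]


@dataclass
class SimTruth:
    """Ground-truth parameters behind a simulated matrix."""

    omega: np.ndarray
    theta: np.ndarray
    model_kind: str
    depth: int | None
    seed: int | None

    @property
    def K(self) -> int:
        return self.omega.shape[1]


def _blend_theta_multinomial(G: int, K: int, separation: float,
                             rng: np.random.Generator) -> np.ndarray:
    baseline = rng.dirichlet(np.ones(G))
    blocks = np.array_split(np.arange(G), K)
    theta = np.empty((K, G))
    for k, block in enumerate(blocks):
        private = np.zeros(G)
        private[block] = rng.dirichlet(np.ones(block.size))
        theta[k] = (1.0 - separation) * baseline + separation * private
    return theta / theta.sum(axis=1, keepdims=True)


def _blend_theta_bernoulli(G: int, K: int, separation: float,
                           rng: np.random.Generator) -> np.ndarray:
    baseline = rng.uniform(0.15, 0.5, size=G)
    blocks = np.array_split(np.arange(G), K)
    theta = np.empty((K, G))
    for k, block in enumerate(blocks):
        private = np.full(G, 0.02)
        private[block] = 0.9
        theta[k] = (1.0 - separation) * baseline + separation * private
    return theta


def simulate_gom(
    N: int = 100,
    G: int = 50,
    K: int = 3,
    model_kind: str = "multinomial",
    alpha_omega: float = 0.3,
    separation: float = 0.8,
    depth: int = 500,
    seed: int | None = 0,
) -> tuple[LabelledMatrix, SimTruth]:
    """Sample a matrix exactly from the grade-of-membership model.

    Omega rows are Dirichlet(``alpha_omega``); theta rows are the
    separation blend described in the module docstring. For the
    multinomial model every row receives ``depth`` individuals; for the
    Bernoulli model each entry is an independent coin with probability
    ``p = omega @ theta`` and all-absent rows are resampled so the
    output is a valid presence matrix.
    """
    if min(N, G, K) < 1:
        raise ValueError("N, G, K must all be >= 1")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    omega = rng.dirichlet(np.full(K, alpha_omega), size=N)
    row_ids = [f"site_{i:04d}" for i in range(N)]
    col_ids = [f"sp_{g:04d}" for g in range(G)]

    if model_kind == "multinomial":
        if depth < 1:
            raise ValueError("multinomial depth must be >= 1")
        theta = _blend_theta_multinomial(G, K, separation, rng)
        P = omega @ theta
        values = np.vstack([rng.multinomial(depth, P[n]) for n in range(N)])
        matrix: LabelledMatrix = CountMatrix(values, row_ids, col_ids)
        truth_depth: int | None = depth
    elif model_kind == "bernoulli":
        theta = _blend_theta_bernoulli(G, K, separation, rng)
        P = omega @ theta
        values = (rng.random((N, G)) < P).astype(int)
        empty = np.flatnonzero(values.sum(axis=1) == 0)
        while empty.size:
            values[empty] = (rng.random((empty.size, G)) < P[empty]).astype(int)
            empty = np.flatnonzero(values.sum(axis=1) == 0)
        matrix = PresenceMatrix(values, row_ids, col_ids)
        truth_depth = None
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")

    return matrix, SimTruth(omega=omega, theta=theta, model_kind=model_kind,
                            depth=truth_depth, seed=seed)


def recovery_error(fit, truth: SimTruth) -> dict[str, float]:
    """How well a fit recovered the generator's parameters.

    Motifs are aligned to the truth by best theta-row correlation before
    comparing; reports the mean absolute error of omega, the RMSE of
    theta, and the minimum Pearson correlation over matched theta rows.
    """
    from .gom import _theta_correlations, align_motif_rows  # local: avoid cycle

    perm = align_motif_rows(truth.theta, fit.theta)
    omega = fit.omega[:, perm]
    theta = fit.theta[perm]
    corr = _theta_correlations(truth.theta, theta)
    return {
        "omega_mae": float(np.abs(omega - truth.omega).mean()),
        "theta_rmse": float(np.sqrt(((theta - truth.theta) ** 2).mean())),
        "theta_row_corr_min": float(np.diag(corr).min()),
    }


# ---------------------------------------------------------------------------
# geographic fixtures
# ---------------------------------------------------------------------------


def simulate_ranges(
    n_rows: int = 24,
    n_cols: int = 36,
    n_species: int = 60,
    n_sites: int = 20,
    banded: bool = True,
    resolution: float = 1.0,
    lon_min: float = 50.0,
    lat_min: float = 5.0,
    species_per_site: int = 12,
    seed: int | None = 0,
) -> tuple[RangeGridSet, SiteTable, dict[str, list[str]]]:
    """Rectangular species ranges plus survey sites with species lists.

    With ``banded=True`` the species split into two pools confined to the
    northern ("temperate", high-elevation sites) and southern
    ("tropical", low-elevation sites) halves of the grid, so dispersion
    fields carry a known K=2 structure; sites west of the grid midline
    are labelled "west", the rest "east".
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(seed)
    geom = GridGeometry(lon_min, lon_min + n_cols * resolution,
                        lat_min, lat_min + n_rows * resolution, resolution)

    species_ids = [f"sp_{s:03d}" for s in range(n_species)]
    grids = np.zeros((n_species, n_rows, n_cols), dtype=np.uint8)
    half = n_rows // 2
    pools: dict[str, list[str]] = {"temperate": [], "tropical": []}
    for s in range(n_species):
        if banded:
            pool = "temperate" if s < n_species // 2 else "tropical"
            r_lo, r_hi = (0, half) if pool == "temperate" else (half, n_rows)
        else:
            pool = "temperate" if rng.random() < 0.5 else "tropical"
            r_lo, r_hi = 0, n_rows
        pools[pool].append(species_ids[s])
        h = rng.integers(1, max(2, (r_hi - r_lo))) if r_hi - r_lo > 1 else 1
        w = rng.integers(1, max(2, n_cols // 2))
        r0 = rng.integers(r_lo, r_hi - h + 1)
        c0 = rng.integers(0, n_cols - w + 1)
        grids[s, r0:r0 + h, c0:c0 + w] = 1
    ranges = RangeGridSet(geom, species_ids, grids)

    rows = []
    site_species: dict[str, list[str]] = {}
    for i in range(n_sites):
        pool = "temperate" if i % 2 == 0 else "tropical"
        if banded:
            r_lo, r_hi = (0, half) if pool == "temperate" else (half, n_rows)
        else:
            r_lo, r_hi = 0, n_rows
        r = int(rng.integers(r_lo, r_hi))
        c = int(rng.integers(0, n_cols))
        lon, lat = geom.cell_center(r, c)
        elev = float(rng.uniform(2000, 4000) if pool == "temperate" else rng.uniform(200, 1500))
        sid = f"site_{i:03d}"
        rows.append({
            "site_id": sid, "lon": lon, "lat": lat,
            "elevation_m": round(elev, 1),
            "region": "west" if c < n_cols // 2 else "east",
        })
        k = min(species_per_site, len(pools[pool]))
        chosen = rng.choice(pools[pool], size=k, replace=False)
        site_species[sid] = sorted(str(x) for x in chosen)
    return ranges, SiteTable(pd.DataFrame(rows)), site_species


def make_land_grid(
    geometry: GridGeometry,
    ocean_fraction: float = 0.15,
    seed: int | None = 0,
) -> np.ndarray:
    """Land-cover fractions in [0, 1]; a random ``ocean_fraction`` of
    cells get < 0.1 land (they will fail the default land filter)."""
    rng = np.random.default_rng(seed)
    land = rng.uniform(0.2, 1.0, size=geometry.shape)
    ocean = rng.random(geometry.shape) < ocean_fraction
    land[ocean] = rng.uniform(0.0, 0.09, size=int(ocean.sum()))
    return land


# ---------------------------------------------------------------------------
# phylogenetic fixtures
# ---------------------------------------------------------------------------


def simulate_timetree(
    n_tips: int = 16,
    root_age: float = 25.0,
    seed: int | None = 0,
) -> TimeTree:
    """Ultrametric pure-birth (Yule) tree rescaled so the root sits at
    ``root_age`` Myr; tips are labelled sp_000, sp_001, ...
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    # forward simulation: split a uniformly chosen active lineage after an
    # Exp(rate * n_active) wait, until n_tips lineages exist
    root = tree.seed_node
    birth_times: dict[dendropy.Node, float] = {root: 0.0}
    split_times: dict[dendropy.Node, float] = {}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        split_times[node] = t
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        birth_times[left] = birth_times[right] = t
        active.extend([left, right])
    t_end = t + rng.exponential(1.0 / len(active))

    # tip depth below the root equals t_end minus the root's split time
    scale = root_age / (t_end - split_times[root])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            end = split_times.get(node, t_end)
            node.edge.length = (end - birth_times[node]) * scale
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp_{i:03d}")
    return TimeTree(tree)
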