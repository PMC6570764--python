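"""Block Structure ordering, pie-map export, and top-contributor tables.

A Block Structure plot shows each sample's membership vector as a
stacked horizontal bar, with samples grouped into parallel blocks by
region and ordered within each block by site elevation — the layout
that makes elevational motif turnover visible at a glance. The pie-map
export writes one GeoJSON point feature per sample, carrying the
membership proportions, for rendering pies at each sample's coordinates.
Top-contributor tables rank features (species, clades, or map cells)
within a motif either by their profile probability theta_kg or by a
distinctiveness contrast against the other motifs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dispersion import SiteTable
from .gom import MotifFit

__all__ = [
    "StructureLayout",
    "order_block_structure",
    "plot_structure",
    "export_pie_map",
    "write_pie_map",
    "read_pie_map",
    "plot_pie_map",
    "top_contributors",
]


@dataclass
class StructureLayout:
    """Row ordering and block boundaries for a Block Structure plot."""

    row_ids: list[str]
    omega: np.ndarray
    blocks: list[tuple[str, int, int]]  # (region, start, stop) slices into rows
    elevations: np.ndarray

    def __post_init__(self) -> None:
        if self.omega.shape[0] != len(self.row_ids):
            raise ValueError("omega rows must match row ids")


def order_block_structure(fit: MotifFit, sites: SiteTable) -> StructureLayout:
    """Order fit rows into region blocks, ascending elevation within block.

    Blocks follow the lexicographic order of the region labels; ties in
    elevation break by site id. Every fit row must appear in the site
    table.
    """
    if not fit.row_ids:
        raise ValueError("fit carries no row ids")
    meta = sites.table.set_index("site_id")
    missing = [r for r in fit.row_ids if r not in meta.index]
    if missing:
        raise KeyError(f"sites missing metadata: {missing[:10]}")
    sub = meta.loc[fit.row_ids, ["region", "elevation_m"]].reset_index(drop=True)
    sub["site_id"] = fit.row_ids
    sub["_pos"] = np.arange(len(fit.row_ids))
    ordered = sub.sort_values(["region", "elevation_m", "site_id"], kind="mergesort")

    blocks: list[tuple[str, int, int]] = []
    start = 0
    for region, grp in ordered.groupby("region", sort=True):
        blocks.append((str(region), start, start + len(grp)))
        start += len(grp)
    idx = ordered["_pos"].to_numpy()
    return StructureLayout(
        row_ids=ordered["site_id"].tolist(),
        omega=fit.omega[idx],
        blocks=blocks,
        elevations=ordered["elevation_m"].to_numpy(dtype=float),
    )


def plot_structure(layout: StructureLayout, path: str | Path,
                   motif_names: list[str] | None = None) -> None:
    """Stacked-bar Block Structure plot, one panel per region block."""
    K = layout.omega.shape[1]
    names = motif_names or [f"motif {k + 1}" for k in range(K)]
    cmap = plt.get_cmap("tab10")
    fig, axes = plt.subplots(
        1, len(layout.blocks), figsize=(3.2 * len(layout.blocks), 0.25 * len(layout.row_ids) + 1.5),
        squeeze=False, sharex=True,
    )
    for ax, (region, lo, hi) in zip(axes[0], layout.blocks):
        omega = layout.omega[lo:hi]
        ids = layout.row_ids[lo:hi]
        left = np.zeros(hi - lo)
        for k in range(K):
            ax.barh(np.arange(hi - lo), omega[:, k], left=left,
                    color=cmap(k % 10), label=names[k], height=0.9)
            left += omega[:, k]
        ax.set_yticks(np.arange(hi - lo), ids, fontsize=6)
        ax.set_xlim(0, 1)
        ax.invert_yaxis()
        ax.set_title(f"{region} (by elevation)")
    axes[0][0].legend(fontsize=6, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pie map
# ---------------------------------------------------------------------------


def export_pie_map(fit: MotifFit, coords: Mapping[str, tuple[float, float]] | pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection: one point per row with motif proportions.

    ``coords`` maps every fit row id to (lon, lat) — a dict or a
    DataFrame indexed by id with 'lon'/'lat' columns.
    """
    if isinstance(coords, pd.DataFrame):
        coords = {str(i): (float(r["lon"]), float(r["lat"])) for i, r in coords.iterrows()}
    row_ids = fit.row_ids or [f"row{i}" for i in range(fit.n_rows)]
    missing = [r for r in row_ids if r not in coords]
    if missing:
        raise KeyError(f"coordinates missing for rows: {missing[:10]}")
    features = []
    for i, rid in enumerate(row_ids):
        lon, lat = coords[rid]
        props = {"id": rid}
        props.update({f"motif_{k + 1}": float(fit.omega[i, k]) for k in range(fit.K)})
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


def write_pie_map(fit: MotifFit, coords, path: str | Path) -> None:
    Path(path).write_text(json.dumps(export_pie_map(fit, coords), indent=1))


def read_pie_map(path: str | Path) -> pd.DataFrame:
    """Read an exported pie map back into a table of memberships."""
    fc = json.loads(Path(path).read_text())
    rows = []
    for feat in fc["features"]:
        rec = dict(feat["properties"])
        rec["lon"], rec["lat"] = feat["geometry"]["coordinates"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("id")


def plot_pie_map(fit: MotifFit, coords, path: str | Path, pie_radius: float = 0.4) -> None:
    """Convenience map: a small pie of motif membership at each point."""
    fc = export_pie_map(fit, coords)
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(8, 6))
    for feat in fc["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        props = feat["properties"]
        shares = [props[f"motif_{k + 1}"] for k in range(fit.K)]
        start = 0.0
        for k, s in enumerate(shares):
            if s <= 0:
                continue
            wedge = matplotlib.patches.Wedge(
                (lon, lat), pie_radius, 360 * start, 360 * (start + s),
                facecolor=cmap(k % 10), edgecolor="none",
            )
            ax.add_patch(wedge)
            start += s
    lons = [f["geometry"]["coordinates"][0] for f in fc["features"]]
    lats = [f["geometry"]["coordinates"][1] for f in fc["features"]]
    pad = 2 * pie_radius + 0.5
    ax.set_xlim(min(lons) - pad, max(lons) + pad)
    ax.set_ylim(min(lats) - pad, max(lats) + pad)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# top contributors
# ---------------------------------------------------------------------------


def top_contributors(
    fit: MotifFit,
    k: int,
    n_top: int = 10,
    mode: str = "probability",
) -> pd.DataFrame:
    """Features contributing most to motif ``k`` (1-based).

    ``probability`` ranks by theta_kg; ``distinctiveness`` ranks by
    theta_kg minus the mean of the same feature's theta over the other
    motifs (0 when K = 1 would compare against nothing, so the score
    falls back to theta itself). Ties break by feature id.
    """
    if not 1 <= k <= fit.K:
        raise ValueError(f"k must be in 1..{fit.K}")
    if mode not in {"probability", "distinctiveness"}:
        raise ValueError(f"unknown mode {mode!r}")
    G = fit.n_features
    if n_top > G:
        warnings.warn(f"n_top={n_top} exceeds {G} features; truncating")
        n_top = G
    features = fit.col_ids or [f"feature_{j}" for j in range(G)]
    theta_k = fit.theta[k - 1]
    if mode == "probability" or fit.K == 1:
        score = theta_k
    else:
        others = np.delete(fit.theta, k - 1, axis=0)
        score = theta_k - others.mean(axis=0)
    df = pd.DataFrame({"feature": features, "theta": theta_k, "score": score})
    df = df.sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
    out = df.head(n_top).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.insert(1, "motif", k)
    return out
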