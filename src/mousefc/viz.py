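"""Connectome visualization: circular connectograms, matrix heatmaps,
thresholded map overlays.

Rendering is deterministic: fixed color scales ([-1, 1] for correlation
matrices, signed with a magnitude mask for overlays), no timestamps in
the output metadata, and a fixed circular node order (anatomical family,
then hemisphere, with the two hemispheres mirrored around the vertical
axis as is conventional for connectograms).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .types import ConnMatrix, GroupMap

_SEED_COLORS = ("tab:blue", "tab:green", "gold", "tab:red", "tab:purple")


@dataclass
class Connectogram:
    nodes: list            # acronyms in circular order
    edges: list            # (acronym_i, acronym_j, r, seed_tag)
    threshold: float
    node_family: dict


def circular_node_order(region_table: pd.DataFrame) -> list:
    """Left hemisphere by family order down one side, midline, then right
    hemisphere mirrored up the other side."""
    fam_order = list(dict.fromkeys(region_table["family"]))
    key = {f: i for i, f in enumerate(fam_order)}
    t = region_table.assign(_k=[key[f] for f in region_table["family"]])
    left = t[t.hemisphere == "left"].sort_values(["_k", "acronym"])
    right = t[t.hemisphere == "right"].sort_values(["_k", "acronym"])
    mid = t[t.hemisphere == "midline"].sort_values(["_k", "acronym"])
    return (left["acronym"].tolist() + mid["acronym"].tolist()
            + right["acronym"].tolist()[::-1])


def build_connectogram(m: ConnMatrix, region_table: pd.DataFrame,
                       threshold: float = 0.2,
                       seed_regions=None) -> Connectogram:
    """Edge list of region pairs with correlation strictly above threshold.

    If ``seed_regions`` (acronyms) is given, edges are restricted to pairs
    incident to a seed and tagged with that seed's acronym for coloring.
    """
    lut = dict(zip(region_table["id"], region_table["acronym"]))
    acr = [lut[int(i)] for i in m.region_ids]
    if seed_regions is not None:
        unknown = set(seed_regions) - set(acr)
        if unknown:
            raise ValueError(f"unknown seed acronym(s): {sorted(unknown)}")
    edges = []
    R = m.n_regions
    vals = m.values
    for i in range(R):
        for j in range(i + 1, R):
            r = vals[i, j]
            if np.isfinite(r) and r > threshold:
                tag = ""
                if seed_regions is not None:
                    hit = [s for s in seed_regions if s in (acr[i], acr[j])]
                    if not hit:
                        continue
                    tag = hit[0]
                edges.append((acr[i], acr[j], float(r), tag))
    fam = dict(zip(region_table["acronym"], region_table["family"]))
    return Connectogram(nodes=circular_node_order(region_table), edges=edges,
                        threshold=threshold, node_family=fam)


def _new_figure(figsize):
    fig = Figure(figsize=figsize)
    FigureCanvasAgg(fig)
    return fig


def _save(fig: Figure, path) -> None:
    fig.savefig(str(path), dpi=120, metadata={"Software": None})


def render_connectogram(cg: Connectogram, path) -> None:
    """Chord-style circular graph; edge color follows the seed tag."""
    n = len(cg.nodes)
    theta = {a: 2 * np.pi * i / n for i, a in enumerate(cg.nodes)}
    fig = _new_figure((8, 8))
    ax = fig.add_subplot(111)
    ax.set_aspect("equal")
    ax.axis("off")
    seed_tags = sorted({t for *_, t in cg.edges if t})
    color_of = {t: _SEED_COLORS[i % len(_SEED_COLORS)]
                for i, t in enumerate(seed_tags)}
    for a, b, r, tag in cg.edges:
        xa, ya = np.cos(theta[a]), np.sin(theta[a])
        xb, yb = np.cos(theta[b]), np.sin(theta[b])
        # quadratic Bezier through a point pulled toward the center
        mx, my = 0.2 * (xa + xb) / 2, 0.2 * (ya + yb) / 2
        ts = np.linspace(0, 1, 30)[:, None]
        pts = ((1 - ts) ** 2 * np.array([xa, ya]) +
               2 * ts * (1 - ts) * np.array([mx, my]) +
               ts ** 2 * np.array([xb, yb]))
        ax.plot(pts[:, 0], pts[:, 1],
                color=color_of.get(tag, "0.4"), lw=0.5 + 2.0 * abs(r),
                alpha=0.6, zorder=1)
    for a in cg.nodes:
        x, y = np.cos(theta[a]), np.sin(theta[a])
        ax.plot([x], [y], "o", ms=2, color="0.2", zorder=2)
    if n <= 60:  # labels are unreadable beyond that
        for a in cg.nodes:
            ang = theta[a]
            ax.text(1.06 * np.cos(ang), 1.06 * np.sin(ang), a, fontsize=5,
                    ha="center", va="center",
                    rotation=np.degrees(ang) - 90 if np.sin(ang) >= 0
                    else np.degrees(ang) + 90)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_title(f"edges: r > {cg.threshold}")
    _save(fig, path)


def render_matrix_heatmap(m: ConnMatrix, path, labels=None) -> None:
    """Correlation matrix heatmap with a fixed [-1, 1] color scale."""
    vals = m.values
    if not np.isfinite(vals).any():
        raise ValueError("matrix has no finite entries")
    fig = _new_figure((6, 5))
    ax = fig.add_subplot(111)
    im = ax.imshow(vals, vmin=-1.0, vmax=1.0, cmap="RdBu_r",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Pearson r")
    if labels is not None and len(labels) <= 40:
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=5)
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=5)
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    _save(fig, path)


def render_overlay(groupmap: GroupMap, anatomy: np.ndarray, path,
                   r_min: float = 0.15) -> None:
    """Axial mosaic: anatomy in gray, supra-threshold mean r in color.

    Voxels with |mean r| < ``r_min`` are fully transparent, so an
    all-masked map renders as anatomy only.
    """
    if not np.isfinite(anatomy).any():
        raise ValueError("anatomy has no finite values")
    overlay = np.array(groupmap.mean_r, dtype=float)
    overlay[np.abs(overlay) < r_min] = np.nan
    nz = anatomy.shape[2]
    ncol = min(nz, 6)
    nrow = -(-nz // ncol)
    fig = _new_figure((2.0 * ncol, 2.0 * nrow))
    for z in range(nz):
        ax = fig.add_subplot(nrow, ncol, z + 1)
        ax.imshow(anatomy[:, :, z].T, cmap="gray", origin="lower")
        ax.imshow(overlay[:, :, z].T, cmap="RdBu_r", vmin=-1.0, vmax=1.0,
                  origin="lower", alpha=0.9)
        ax.axis("off")
        ax.set_title(f"z={z}", fontsize=6)
    _save(fig, path)
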