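"""Morphometric measurement and population comparison.

Per-tree and pooled metrics (branch pathlength, bifurcation angles, counts,
total dendritic length, branch order, depth/width extents), Sholl profiles,
conditional heatmaps, distribution RMSE, and dendritic-length-by-distance
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import bifurcation_angle_samples
from .trees import MorphTree


class NotRegisteredError(ValueError):
    pass


def _check_registered(tree: MorphTree, tol: float = 1e-6) -> None:
    if np.linalg.norm(tree.soma.position) > tol:
        raise NotRegisteredError(
            "tree is not registered (soma not at the origin); call register()"
        )


@dataclass
class MorphometricSet:
    """Pooled distributions plus one row of scalars per tree."""

    per_tree: pd.DataFrame            # columns: tdl, n_bifurcations, depth, width,
                                      # max_branch_order, n_stems, n_tips
    branch_pathlengths: np.ndarray    # pooled, um
    amplitudes: np.ndarray            # pooled, degrees
    azimuths: np.ndarray              # pooled, degrees
    branch_orders: np.ndarray         # pooled, one per branch

    def pooled(self) -> dict[str, np.ndarray]:
        return {
            "branch_pathlength": self.branch_pathlengths,
            "amplitude": self.amplitudes,
            "azimuth": self.azimuths,
            "branch_order": self.branch_orders,
            "n_bifurcations": self.per_tree["n_bifurcations"].to_numpy(float),
            "tdl": self.per_tree["tdl"].to_numpy(float),
            "depth": self.per_tree["depth"].to_numpy(float),
            "width": self.per_tree["width"].to_numpy(float),
        }


def measure(trees: list[MorphTree]) -> MorphometricSet:
    """All eight morphometrics; width = x-extent, depth = z-extent of the
    registered tree."""
    rows = []
    lengths, orders = [], []
    for tree in trees:
        _check_registered(tree)
        branches = tree.branches()
        pos = tree.positions()
        lengths.extend(b.pathlength for b in branches)
        orders.extend(b.branch_order for b in branches)
        rows.append({
            "tdl": sum(b.pathlength for b in branches),
            "n_bifurcations": tree.n_bifurcations(),
            "depth": float(pos[:, 2].max() - pos[:, 2].min()),
            "width": float(pos[:, 0].max() - pos[:, 0].min()),
            "max_branch_order": max(b.branch_order for b in branches),
            "n_stems": sum(1 for b in branches if b.parent is None),
            "n_tips": len(tree.tips()),
        })
    angles = bifurcation_angle_samples(trees)
    return MorphometricSet(
        per_tree=pd.DataFrame(rows),
        branch_pathlengths=np.asarray(lengths, dtype=float),
        amplitudes=angles["amplitude"],
        azimuths=angles["azimuth"],
        branch_orders=np.asarray(orders, dtype=float),
    )


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

@dataclass
class ShollProfile:
    radii: np.ndarray
    counts: np.ndarray


def _segment_sphere_crossings(a: np.ndarray, b: np.ndarray, r: float) -> int:
    """Number of times the open-closed segment (a, b] crosses the sphere of
    radius r about the origin (tangency counts once)."""
    d = b - a
    A = float(np.dot(d, d))
    if A < 1e-300:
        return 0
    B = 2.0 * float(np.dot(a, d))
    C = float(np.dot(a, a)) - r * r
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return 0
    sq = np.sqrt(disc)
    roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    eps = 1e-12
    if disc == 0.0:
        roots = roots[:1]
    return sum(1 for t in roots if eps < t <= 1.0 + eps)


def sholl(tree: MorphTree, radii) -> ShollProfile:
    """Count intersections of the morphology with concentric spheres centered
    at the soma."""
    _check_registered(tree)
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for c in tree.compartments:
        if c.parent_id == -1:
            continue
        a = tree.node(c.parent_id).position
        b = c.position
        for i, r in enumerate(radii):
            counts[i] += _segment_sphere_crossings(a, b, r)
    return ShollProfile(radii, counts)


def default_sholl_radii(tree: MorphTree, step: float = 10.0) -> np.ndarray:
    tips = np.array([tree.node(t).position for t in tree.tips()])
    rmax = float(np.linalg.norm(tips, axis=1).max())
    return np.arange(step, rmax + step, step)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def conditional_heatmap(conditions, values, cond_bins, value_bins):
    """Column-normalized 2D histogram: each condition-bin column sums to 1.

    Returns (table, empty_columns) where table has shape
    (len(value_bins)-1, len(cond_bins)-1).
    """
    conditions = np.asarray(conditions, dtype=float)
    values = np.asarray(values, dtype=float)
    if conditions.size == 0:
        raise ValueError("no samples")
    H, _, _ = np.histogram2d(values, conditions, bins=[value_bins, cond_bins])
    colsum = H.sum(axis=0)
    empty = colsum == 0
    table = H / np.where(empty, 1.0, colsum)
    return table, empty


def freedman_diaconis_edges(reference: np.ndarray, max_bins: int = 200) -> np.ndarray:
    """Shared bin edges from a pooled reference sample (Freedman-Diaconis)."""
    x = np.asarray(reference, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or x.max() == x.min():
        return np.array([x.min() - 0.5, x.max() + 0.5])
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    h = 2.0 * iqr / np.cbrt(x.size) if iqr > 0 else (x.max() - x.min()) / 10.0
    nb = int(np.clip(np.ceil((x.max() - x.min()) / h), 1, max_bins))
    return np.linspace(x.min(), x.max(), nb + 1)


def distribution_rmse(a, b, bins) -> float:
    """RMSE between two sample sets histogrammed as probability mass on the
    common ``bins`` (use :func:`rmse_from_masses` for pre-binned vectors)."""
    bins = np.asarray(bins, dtype=float)

    def _mass(x):
        h, _ = np.histogram(np.asarray(x, dtype=float), bins=bins)
        tot = h.sum()
        if tot == 0:
            raise ValueError("empty distribution")
        return h / tot

    return rmse_from_masses(_mass(a), _mass(b))


def rmse_from_masses(pa: np.ndarray, pb: np.ndarray) -> float:
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("bin mismatch")
    return float(np.sqrt(np.mean((pa - pb) ** 2)))


# ---------------------------------------------------------------------------
# dendritic length by distance
# ---------------------------------------------------------------------------

def _segment_intervals(tree: MorphTree, axis: str):
    """(interval_lo, interval_hi, segment_length) per compartment segment.

    axis='y' uses the y-coordinate span; axis='pathlength' the cumulative
    pathlength from the soma.
    """
    lo, hi, ln = [], [], []
    if axis == "pathlength":
        dist = {tree.soma_id: 0.0}
        stack = [tree.soma_id]
        while stack:
            nid = stack.pop()
            for kid in tree.children(nid):
                seg = float(np.linalg.norm(
                    tree.node(kid).position - tree.node(nid).position))
                dist[kid] = dist[nid] + seg
                stack.append(kid)
    for c in tree.compartments:
        if c.parent_id == -1:
            continue
        p = tree.node(c.parent_id)
        seg = float(np.linalg.norm(c.position - p.position))
        if axis == "y":
            a, b = p.position[1], c.position[1]
        elif axis == "pathlength":
            a, b = dist[c.parent_id], dist[c.id]
        else:
            raise ValueError(f"unknown axis {axis!r}")
        lo.append(min(a, b))
        hi.append(max(a, b))
        ln.append(seg)
    return np.array(lo), np.array(hi), np.array(ln)


def _apportion(lo, hi, ln, edges) -> np.ndarray:
    out = np.zeros(len(edges) - 1)
    width = hi - lo
    for i in range(len(edges) - 1):
        overlap = np.clip(np.minimum(hi, edges[i + 1]) - np.maximum(lo, edges[i]),
                          0.0, None)
        frac = np.where(width > 1e-12, overlap / np.maximum(width, 1e-12),
                        ((lo > edges[i]) & (lo <= edges[i + 1])).astype(float))
        out[i] = float(np.sum(frac * ln))
    return out


def tdl_by_distance(trees: list[MorphTree], axis: str = "y", bins=None):
    """PDF and CDF of dendritic length versus distance.

    Returns (edges, length_per_bin, pdf, cdf): pdf integrates to 1 over the
    edges; cdf is the running mass.
    """
    for t in trees:
        _check_registered(t)
    parts = [_segment_intervals(t, axis) for t in trees]
    if bins is None:
        top = max(float(p[1].max()) for p in parts)
        bins = np.linspace(0.0, top, 51)
    edges = np.asarray(bins, dtype=float)
    length = np.zeros(len(edges) - 1)
    for lo, hi, ln in parts:
        length += _apportion(lo, hi, ln, edges)
    total = length.sum()
    widths = np.diff(edges)
    pdf = length / (total * widths) if total > 0 else length
    cdf = np.cumsum(length) / total if total > 0 else length
    return edges, length, pdf, cdf


def tdl_per_layer(tree: MorphTree, boundary_length: float,
                  layer_fractions=(1.0 / 3, 1.0 / 3, 1.0 / 3)) -> np.ndarray:
    """Dendritic length within each y-layer between the soma and the boundary."""
    fr = np.asarray(layer_fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr <= 0):
        raise ValueError("layer fractions must be positive and sum to 1")
    edges = np.concatenate([[0.0], np.cumsum(fr)]) * boundary_length
    lo, hi, ln = _segment_intervals(tree, "y")
    return _apportion(lo, hi, ln, edges)
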