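"""Passive electrical validation via series/parallel equivalent resistance.

Each branch is a resistor (unit resistance by default, or proportional to
pathlength).  For a point on the tree, the proximal equivalent resistance is
the series path to the soma and the distal equivalent resistance collapses the
subtree beyond the point with tips tied to a common terminal.  The current
divider R_distal / (R_prox + R_distal) gives the fraction of injected current
flowing toward the soma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import MorphTree, terminal_paths


@dataclass
class TreePoint:
    """A location on a tree: branch index plus fraction along the branch."""

    branch: int
    frac: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac <= 1.0):
            raise ValueError("frac must lie in [0, 1]")


@dataclass
class CurrentFractionSample:
    distance: float            # pathlength from the soma, um
    norm_distance: float       # distance / max terminal pathlength
    fraction: float            # proximal current fraction
    at_tip: bool = False


def _branch_resistances(tree: MorphTree, per_um: bool) -> np.ndarray:
    branches = tree.branches()
    if per_um:
        return np.array([b.pathlength for b in branches])
    return np.ones(len(branches))


def _distal_resistance(tree: MorphTree, res: np.ndarray, idx: int) -> float:
    """Equivalent resistance from the start of branch idx through its subtree
    to the tip terminal (series along branches, parallel at bifurcations)."""
    branches = tree.branches()
    order = []
    stack = [idx]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(branches[i].daughters)
    sub: dict[int, float] = {}
    for i in reversed(order):
        ds = branches[i].daughters
        if not ds:
            sub[i] = res[i]
        else:
            r1, r2 = sub[ds[0]], sub[ds[1]]
            sub[i] = res[i] + (r1 * r2) / (r1 + r2)
    return sub[idx]


def proximal_current_fraction(tree: MorphTree, point: TreePoint,
                              per_um: bool = False,
                              literal_resistance_ratio: bool = False) -> float:
    """Fraction of current injected at ``point`` that flows toward the soma.

    A tip (no distal material) returns 1.  ``literal_resistance_ratio``
    exposes R_prox / (R_prox + R_distal) instead of the current divider.
    """
    branches = tree.branches()
    if not (0 <= point.branch < len(branches)):
        raise ValueError("point is not on the tree")
    res = _branch_resistances(tree, per_um)
    br = branches[point.branch]

    r_prox = point.frac * res[point.branch]
    p = br.parent
    while p is not None:
        r_prox += res[p]
        p = branches[p].parent

    at_tip = not br.daughters and point.frac >= 1.0 - 1e-12
    if at_tip:
        return 1.0
    r_distal = (1.0 - point.frac) * res[point.branch]
    if br.daughters:
        r1 = _distal_resistance(tree, res, br.daughters[0])
        r2 = _distal_resistance(tree, res, br.daughters[1])
        r_distal += (r1 * r2) / (r1 + r2)

    if literal_resistance_ratio:
        return r_prox / (r_prox + r_distal)
    return r_distal / (r_prox + r_distal)


def _distance_to_point(tree: MorphTree, point: TreePoint) -> float:
    branches = tree.branches()
    d = point.frac * branches[point.branch].pathlength
    p = branches[point.branch].parent
    while p is not None:
        d += branches[p].pathlength
        p = branches[p].parent
    return d


def sample_current_fractions(tree: MorphTree, n_points: int,
                             rng: np.random.Generator,
                             per_um: bool = False) -> list[CurrentFractionSample]:
    """Evaluate the proximal current fraction at points drawn uniformly by
    dendritic length; distances are normalized by the maximum terminal
    pathlength."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    branches = tree.branches()
    lengths = np.array([b.pathlength for b in branches])
    weights = lengths / lengths.sum()
    max_path = max(p.total_pathlength for p in terminal_paths(tree))
    out = []
    for _ in range(n_points):
        b = int(rng.choice(len(branches), p=weights))
        f = float(rng.random())
        pt = TreePoint(b, f)
        frac = proximal_current_fraction(tree, pt, per_um=per_um)
        d = _distance_to_point(tree, pt)
        at_tip = not branches[b].daughters and f >= 1.0 - 1e-12
        out.append(CurrentFractionSample(d, d / max_path, frac, at_tip))
    return out


# ---------------------------------------------------------------------------
# quadratic regression
# ---------------------------------------------------------------------------

@dataclass
class QuadraticFit:
    a: float
    b: float
    c: float
    r2: float

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        return self.a * d**2 + self.b * d + self.c

    def cross_r2(self, distances, values) -> float:
        """Fraction of the reference samples' variance explained by this fit."""
        values = np.asarray(values, dtype=float)
        pred = self(np.asarray(distances, dtype=float))
        ss_res = float(np.sum((values - pred) ** 2))
        ss_tot = float(np.sum((values - values.mean()) ** 2))
        if ss_tot == 0:
            return 1.0 if ss_res == 0 else 0.0
        return 1.0 - ss_res / ss_tot


def fit_quadratic(distances, values) -> QuadraticFit:
    """Ordinary least squares f(d) = a d^2 + b d + c."""
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct distances")
    X = np.column_stack([d**2, d, np.ones_like(d)])
    coef, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design")
    fit = QuadraticFit(float(coef[0]), float(coef[1]), float(coef[2]), 0.0)
    fit.r2 = fit.cross_r2(d, v)
    return fit


# ---------------------------------------------------------------------------
# spine-weighted relative current
# ---------------------------------------------------------------------------

def layer_spine_density(distances, boundary_length: float,
                        densities=(1.6, 2.0, 1.4)) -> np.ndarray:
    """Spines per um at each distance given per-third molecular-layer
    densities (inner, middle, outer); defaults are literature-scale values
    for rat dentate granule cells."""
    d = np.asarray(distances, dtype=float)
    edges = np.array([1.0 / 3, 2.0 / 3]) * boundary_length
    idx = np.searchsorted(edges, d, side="right")
    return np.asarray(densities, dtype=float)[np.clip(idx, 0, 2)]


def spine_weighted_current(distances, tdl_per_um, spine_density_per_um,
                           fractions_fit: QuadraticFit,
                           norm_distance=None) -> dict[str, np.ndarray]:
    """Relative somatic current per um of distance.

    spines/um = (dendritic length added per um) * (spine density per um of
    dendrite); relative current = spines/um * fitted proximal fraction.
    """
    d = np.asarray(distances, dtype=float)
    tdl = np.asarray(tdl_per_um, dtype=float)
    dens = np.asarray(spine_density_per_um, dtype=float)
    nd = d / d.max() if norm_distance is None else np.asarray(norm_distance, float)
    spines = tdl * dens
    frac = np.clip(fractions_fit(nd), 0.0, 1.0)
    return {"distance": d, "spines_per_um": spines,
            "relative_current": spines * frac}


def normalized_rmse(curve_a, curve_b) -> float:
    """RMSE between two equally sampled curves, normalized by the reference
    curve's range (curve_a is the reference)."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share a grid")
    rng = a.max() - a.min()
    if rng == 0:
        raise ValueError("reference curve has zero range")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)
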