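"""Neuronal tree data model, SWC I/O, registration, and point-process encoding.

Trees are rooted collections of tapered cylindrical compartments read from or
written to the standard 7-column SWC format.  Branch decomposition, terminal
path extraction, and the conversion of terminal paths into binary bifurcation
point processes on a discretized pathlength axis live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


class SWCParseError(ValueError):
    """Raised for malformed SWC content."""


class TreeStructureError(ValueError):
    """Raised when compartments do not form a valid rooted binary tree."""


@dataclass
class Compartment:
    """A single SWC record: a point with radius linked to its parent."""

    id: int
    parent_id: int
    position: np.ndarray  # (3,) in um
    radius: float
    type_code: int = 3

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius <= 0:
            raise ValueError(f"compartment {self.id}: radius must be > 0")


@dataclass
class Branch:
    """A maximal unbranched compartment run between soma/bifurcation/tip nodes."""

    comp_ids: list[int]           # node ids from branch start (exclusive parent node) to end
    start: np.ndarray
    end: np.ndarray
    pathlength: float
    parent: int | None            # index into the tree's branch list
    daughters: list[int]
    branch_order: int             # bifurcations between soma and this branch
    start_diameter: float
    end_diameter: float


@dataclass
class TerminalPath:
    """Ordered branch indices from a stem to one dendritic tip."""

    branch_indices: list[int]
    total_pathlength: float
    # cumulative pathlength (from the soma) of each bifurcation on the path
    bifurcation_distances: list[float] = field(default_factory=list)


class MorphTree:
    """Rooted binary tree of compartments with a single-point soma."""

    def __init__(self, compartments: list[Compartment], soma_id: int | None = None):
        self.compartments = list(compartments)
        self._by_id = {c.id: c for c in self.compartments}
        if len(self._by_id) != len(self.compartments):
            raise TreeStructureError("duplicate compartment ids")
        roots = [c for c in self.compartments if c.parent_id == -1]
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, found {len(roots)}")
        self.soma_id = soma_id if soma_id is not None else roots[0].id
        if self.soma_id != roots[0].id:
            raise TreeStructureError("soma_id does not match the root compartment")
        self._children: dict[int, list[int]] = {c.id: [] for c in self.compartments}
        for c in self.compartments:
            if c.parent_id == -1:
                continue
            if c.parent_id not in self._by_id:
                raise TreeStructureError(
                    f"compartment {c.id} references unknown parent {c.parent_id}"
                )
            self._children[c.parent_id].append(c.id)
        self._validate()
        self._branches: list[Branch] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        seen = set()
        stack = [self.soma_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise TreeStructureError("cycle detected")
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self.compartments):
            raise TreeStructureError("graph is not connected")
        for c in self.compartments:
            if c.id == self.soma_id:
                continue
            n_child = len(self._children[c.id])
            if n_child > 2:
                raise TreeStructureError(
                    f"compartment {c.id} has {n_child} daughters; only binary "
                    "branching is supported"
                )

    def __len__(self) -> int:
        return len(self.compartments)

    def node(self, nid: int) -> Compartment:
        return self._by_id[nid]

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    @property
    def soma(self) -> Compartment:
        return self._by_id[self.soma_id]

    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.compartments])

    def copy_with_positions(self, positions: np.ndarray) -> "MorphTree":
        comps = [
            Compartment(c.id, c.parent_id, positions[i].copy(), c.radius, c.type_code)
            for i, c in enumerate(self.compartments)
        ]
        return MorphTree(comps, self.soma_id)

    # -- branch decomposition ---------------------------------------------

    def branches(self) -> list[Branch]:
        """Decompose into maximal unbranched branches (stems at order 0)."""
        if self._branches is not None:
            return self._branches
        out: list[Branch] = []
        # (start node id, parent branch index, branch order)
        stack = [(cid, None, 0) for cid in reversed(self._children[self.soma_id])]
        order_of: dict[int, int] = {}
        while stack:
            start, parent_idx, order = stack.pop()
            ids = []
            prev = self.soma_id if parent_idx is None else out[parent_idx].comp_ids[-1]
            length = 0.0
            nid = start
            while True:
                ids.append(nid)
                length += float(
                    np.linalg.norm(self._by_id[nid].position - self._by_id[prev].position)
                )
                kids = self._children[nid]
                if len(kids) != 1:
                    break
                prev = nid
                nid = kids[0]
            idx = len(out)
            start_pos = (
                self.soma.position if parent_idx is None else out[parent_idx].end
            )
            br = Branch(
                comp_ids=ids,
                start=np.asarray(start_pos, dtype=float).copy(),
                end=self._by_id[ids[-1]].position.copy(),
                pathlength=length,
                parent=parent_idx,
                daughters=[],
                branch_order=order,
                start_diameter=2.0 * self._by_id[ids[0]].radius,
                end_diameter=2.0 * self._by_id[ids[-1]].radius,
            )
            out.append(br)
            if parent_idx is not None:
                out[parent_idx].daughters.append(idx)
            order_of[ids[-1]] = order
            for kid in reversed(self._children[ids[-1]]):
                stack.append((kid, idx, order + 1))
        self._branches = out
        return out

    def tips(self) -> list[int]:
        return [c.id for c in self.compartments
                if c.id != self.soma_id and not self._children[c.id]]

    def n_bifurcations(self) -> int:
        return sum(
            1 for c in self.compartments
            if c.id != self.soma_id and len(self._children[c.id]) == 2
        )

    def total_length(self) -> float:
        return float(sum(b.pathlength for b in self.branches()))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> MorphTree:
    """Read a 7-column SWC file into a :class:`MorphTree`.

    Multi-point somata (contiguous type-1 records) are collapsed onto the
    root point; their non-soma children are re-attached to the root.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                cid = int(parts[0])
                tcode = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((cid, tcode, np.array([x, y, z]), r, pid))
    if not records:
        raise SWCParseError(f"{path}: no records")

    ids = {r[0] for r in records}
    for cid, _, _, _, pid in records:
        if pid != -1 and pid not in ids:
            raise TreeStructureError(f"compartment {cid} references undefined parent {pid}")

    # collapse type-1 chains connected to the root into a single soma point
    roots = [r for r in records if r[4] == -1]
    if len(roots) != 1:
        raise TreeStructureError(f"expected exactly one root record, found {len(roots)}")
    root_id = roots[0][0]
    soma_ids = {root_id}
    changed = True
    by_id = {r[0]: r for r in records}
    while changed:
        changed = False
        for cid, tcode, _, _, pid in records:
            if cid not in soma_ids and tcode == 1 and pid in soma_ids:
                soma_ids.add(cid)
                changed = True

    comps = []
    for cid, tcode, pos, r, pid in records:
        if cid in soma_ids and cid != root_id:
            continue
        if pid in soma_ids and pid != root_id:
            pid = root_id
        comps.append(Compartment(cid, pid, pos, r, tcode))
    return MorphTree(comps)


def write_swc(tree: MorphTree, path) -> None:
    """Write standard 7-column SWC; ids renumbered 1..n, parents before children."""
    order: list[int] = []
    stack = [tree.soma_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(tree.children(nid)))
    new_id = {nid: i + 1 for i, nid in enumerate(order)}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in order:
            c = tree.node(nid)
            pid = -1 if c.parent_id == -1 else new_id[c.parent_id]
            x, y, z = c.position
            fh.write(
                f"{new_id[nid]} {c.type_code} {x:.6f} {y:.6f} {z:.6f} "
                f"{c.radius:.6f} {pid}\n"
            )


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-9,
                           max_iter: int = 2000):
    """Smallest-area enclosing ellipse of 2D points (Khachiyan's algorithm).

    Returns (center, axis_lengths, axis_directions) with axis_lengths the full
    axis lengths sorted descending and axis_directions the matching unit
    vectors as rows.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    if d != 2:
        raise ValueError("expected 2D points")
    Q = np.vstack([P.T, np.ones(n)])
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = P.T @ u
    A = np.linalg.inv(P.T @ (u[:, None] * P) - np.outer(center, center)) / d
    evals, evecs = np.linalg.eigh(A)
    # semi-axis lengths are 1/sqrt(eigenvalue); report full axes, major first
    semi = 1.0 / np.sqrt(np.maximum(evals, 1e-300))
    idx = np.argsort(semi)[::-1]
    return center, 2.0 * semi[idx], evecs.T[idx]


def tip_ellipse_axes(tree: MorphTree) -> tuple[float, float]:
    """(major, minor) full axis lengths of the enclosing ellipse of the tip
    projections onto the xz-plane."""
    tips = np.array([tree.node(t).position for t in tree.tips()])
    proj = tips[:, [0, 2]]
    span = proj - proj.mean(axis=0)
    rank = np.linalg.matrix_rank(span, tol=1e-9) if len(proj) > 1 else 0
    if len(proj) < 3 or rank < 2:
        # degenerate: report extent along the principal direction
        if len(proj) == 1:
            return 0.0, 0.0
        _, s, _ = np.linalg.svd(span, full_matrices=False)
        extent = 2.0 * s[0] / math.sqrt(len(proj))
        return float(extent), 0.0
    _, axes, _ = _min_enclosing_ellipse(proj)
    return float(axes[0]), float(axes[1])


def _rotation_aligning(v: np.ndarray, target: np.ndarray) -> Rotation:
    v = v / np.linalg.norm(v)
    target = target / np.linalg.norm(target)
    c = float(np.dot(v, target))
    if c > 1.0 - 1e-12:
        return Rotation.identity()
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to v
        perp = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(v, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(math.pi * perp)
    axis = np.cross(v, target)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(math.acos(max(-1.0, min(1.0, c))) * axis)


def register(tree: MorphTree) -> MorphTree:
    """Register a tree to the standard frame.

    Soma is moved to the origin; the central axis (mean of unit soma-to-tip
    vectors) is aligned with +y; the major axis of the smallest enclosing
    ellipse of tip projections on the xz-plane is aligned with +x.
    """
    pos = tree.positions() - tree.soma.position
    tip_ids = tree.tips()
    if not tip_ids:
        raise TreeStructureError("tree has no terminals")
    id_index = {c.id: i for i, c in enumerate(tree.compartments)}
    tip_pos = pos[[id_index[t] for t in tip_ids]]
    norms = np.linalg.norm(tip_pos, axis=1)
    if np.all(norms < 1e-12):
        raise TreeStructureError("degenerate morphology: all tips coincide with soma")
    units = tip_pos[norms > 1e-12] / norms[norms > 1e-12, None]
    central = units.mean(axis=0)
    if np.linalg.norm(central) < 1e-12:
        raise TreeStructureError("degenerate morphology: central axis undefined")
    rot1 = _rotation_aligning(central, np.array([0.0, 1.0, 0.0]))
    pos = rot1.apply(pos)

    tip_pos = pos[[id_index[t] for t in tip_ids]]
    proj = tip_pos[:, [0, 2]]
    span = proj - proj.mean(axis=0)
    rank = np.linalg.matrix_rank(span, tol=1e-9) if len(proj) > 1 else 0
    if len(proj) >= 3 and rank == 2:
        _, _, dirs = _min_enclosing_ellipse(proj)
        major = dirs[0]
    elif len(proj) >= 2 and rank >= 1:
        _, _, vt = np.linalg.svd(span, full_matrices=False)
        major = vt[0]
    else:
        major = None
    if major is not None:
        if major[0] < 0 or (abs(major[0]) < 1e-12 and major[1] < 0):
            major = -major
        # rotate about +y so that (major_x, major_z) in the xz-plane maps to +x
        theta = math.atan2(major[1], major[0])
        ca, sa = math.cos(theta), math.sin(theta)
        x, z = pos[:, 0].copy(), pos[:, 2].copy()
        pos[:, 0] = ca * x + sa * z
        pos[:, 2] = -sa * x + ca * z
    return tree.copy_with_positions(pos)


# ---------------------------------------------------------------------------
# Terminal paths and point-process encoding
# ---------------------------------------------------------------------------

def terminal_paths(tree: MorphTree) -> list[TerminalPath]:
    """Every path from the soma to a dendritic tip, as branch index sequences."""
    branches = tree.branches()
    paths: list[TerminalPath] = []

    def walk(idx: int, prefix: list[int], dist: float, bifs: list[float]) -> None:
        br = branches[idx]
        prefix = prefix + [idx]
        dist += br.pathlength
        if not br.daughters:
            paths.append(TerminalPath(prefix, dist, list(bifs)))
            return
        bifs = bifs + [dist]
        for d in br.daughters:
            walk(d, prefix, dist, bifs)

    for i, br in enumerate(branches):
        if br.parent is None:
            walk(i, [], 0.0, [])
    return paths


class PointProcessSet:
    """R binary bifurcation sequences on a common discretized pathlength axis.

    ``events`` is an (R, K) uint8 array; ``lengths[r]`` gives the number of
    observed bins of sequence r (the remainder of the row is padding).  The
    final observed bin of every sequence holds the tip event.
    """

    def __init__(self, events: np.ndarray, delta: float,
                 lengths: np.ndarray | None = None,
                 tree_index: np.ndarray | None = None,
                 require_tip: bool = True):
        self.events = np.asarray(events, dtype=np.uint8)
        if self.events.ndim != 2:
            raise ValueError("events must be 2-D (R, K)")
        self.delta = float(delta)
        R, K = self.events.shape
        self.lengths = (
            np.full(R, K, dtype=int) if lengths is None
            else np.asarray(lengths, dtype=int)
        )
        self.tree_index = (
            np.zeros(R, dtype=int) if tree_index is None
            else np.asarray(tree_index, dtype=int)
        )
        self.require_tip = require_tip
        for r in range(R):
            L = self.lengths[r]
            if L < 1 or L > K:
                raise ValueError("invalid sequence length")
            if require_tip and self.events[r, L - 1] != 1:
                raise ValueError(f"sequence {r}: final observed entry must be 1")
            if L < K and self.events[r, L:].any():
                raise ValueError(f"sequence {r}: events beyond observed length")

    @property
    def R(self) -> int:
        return self.events.shape[0]

    @property
    def K(self) -> int:
        return self.events.shape[1]

    @property
    def N_total(self) -> int:
        return int(self.events.sum())

    def active_counts(self) -> np.ndarray:
        """Number of sequences observing each bin."""
        counts = np.zeros(self.K, dtype=int)
        for L in self.lengths:
            counts[:L] += 1
        return counts

    def event_counts(self) -> np.ndarray:
        return self.events.sum(axis=0).astype(int)

    @staticmethod
    def concatenate(sets: list["PointProcessSet"]) -> "PointProcessSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        delta = sets[0].delta
        if any(abs(s.delta - delta) > 1e-12 for s in sets):
            raise ValueError("mismatched delta")
        K = max(s.K for s in sets)
        rows, lens, tidx = [], [], []
        offset = 0
        for s in sets:
            ev = np.zeros((s.R, K), dtype=np.uint8)
            ev[:, : s.K] = s.events
            rows.append(ev)
            lens.append(s.lengths)
            tidx.append(s.tree_index + offset)
            offset += int(s.tree_index.max()) + 1 if s.R else 0
        return PointProcessSet(
            np.vstack(rows), delta, np.concatenate(lens), np.concatenate(tidx),
            require_tip=all(s.require_tip for s in sets),
        )


class DeltaTooLargeError(ValueError):
    pass


def _bin_of(position: float, delta: float) -> int:
    # half-open bins (k*delta, k*delta + delta]; an event exactly at k*delta
    # belongs to bin k-1
    b = int(math.ceil(position / delta - 1e-9)) - 1
    return max(b, 0)


def default_delta(trees: list[MorphTree]) -> float:
    """Half the minimum inter-bifurcation pathlength over all terminal paths,
    floored at 1 um."""
    gaps = []
    for tree in trees:
        for path in terminal_paths(tree):
            marks = path.bifurcation_distances + [path.total_pathlength]
            prev = 0.0
            for m in marks:
                gaps.append(m - prev)
                prev = m
    if not gaps:
        return 1.0
    return max(1.0, 0.5 * min(gaps))


def encode_point_processes(tree: MorphTree, delta: float | None = None,
                           normalize: bool = True, n_bins: int = 100,
                           tree_id: int = 0,
                           tip_events: bool = True) -> PointProcessSet:
    """Encode every terminal path of a tree as a binary point process.

    With ``normalize`` each path is rescaled to unit length and divided into
    ``n_bins`` bins of width 1/n_bins; otherwise bins of ``delta`` um are laid
    out from the soma and sequences have per-path lengths.  The tip always
    contributes the final 1 of its sequence; ``tip_events=False`` keeps the
    tip only as the extent marker (its bin is observed but holds no event),
    for estimating a pure bifurcation rate.
    """
    paths = terminal_paths(tree)
    if normalize:
        delta_eff = 1.0 / n_bins
    else:
        if delta is None:
            delta = default_delta([tree])
        delta_eff = float(delta)

    rows, lengths = [], []
    for p_i, path in enumerate(paths):
        total = path.total_pathlength
        marks = list(path.bifurcation_distances) + [total]
        if normalize:
            marks = [m / total for m in marks]
        bins = [_bin_of(m, delta_eff) for m in marks]
        if len(set(bins)) != len(bins):
            raise DeltaTooLargeError(
                f"delta too large: two events share a bin on terminal path {p_i}"
            )
        L = bins[-1] + 1
        seq = np.zeros(L, dtype=np.uint8)
        seq[bins] = 1
        if not tip_events:
            seq[bins[-1]] = 0
        rows.append(seq)
        lengths.append(L)

    K = max(lengths)
    events = np.zeros((len(rows), K), dtype=np.uint8)
    for r, seq in enumerate(rows):
        events[r, : len(seq)] = seq
    return PointProcessSet(
        events, delta_eff, np.array(lengths),
        np.full(len(rows), tree_id, dtype=int),
        require_tip=tip_events,
    )


def encode_population(trees: list[MorphTree], delta: float | None = None,
                      normalize: bool = True, n_bins: int = 100,
                      tip_events: bool = True) -> PointProcessSet:
    """Pooled encoding of several trees into a single point-process set."""
    if not trees:
        raise ValueError("no trees")
    if not normalize and delta is None:
        delta = default_delta(trees)
    sets = [
        encode_point_processes(t, delta, normalize, n_bins, tree_id=0,
                               tip_events=tip_events)
        for t in trees
    ]
    return PointProcessSet.concatenate(sets)
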