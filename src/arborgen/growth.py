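"""Morphology generation.

New trees are grown stem by stem: a terminal boundary pathlength is sampled
from the empirical terminal-length distribution, stems are placed on a cone
about +y, and each branch carries a thinned heterogeneous point process whose
per-bin probability is indexed by the branch's current distance from the soma.
Bifurcation geometry is drawn from conditional (x, z)-binned histograms of
amplitude and azimuth; every branch terminates exactly at the boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .trees import Compartment, MorphTree, tip_ellipse_axes

DEG = math.pi / 180.0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm < 1e-300:
        raise ValueError("zero-length vector")
    return v / nrm


def _perp_component(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return v - np.dot(v, axis) * axis


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Right-handed (counterclockwise) rotation of v about unit axis."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors."""
    cosv = np.dot(_unit(a), _unit(b))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(cosv)))))


def _toward_axis_reference(point: np.ndarray, parent_dir: np.ndarray) -> np.ndarray:
    """Unit reference direction (perpendicular to the parent) pointing from
    ``point`` toward the central y-axis; an arbitrary perpendicular when the
    point lies on the axis."""
    toward = np.array([-point[0], 0.0, -point[2]])
    ref = _perp_component(toward, parent_dir)
    if np.linalg.norm(ref) < 1e-9:
        ref = _perp_component(np.array([1.0, 0.0, 0.0]), parent_dir)
        if np.linalg.norm(ref) < 1e-9:
            ref = _perp_component(np.array([0.0, 0.0, 1.0]), parent_dir)
    return _unit(ref)


def bifurcation_geometry(parent_vec: np.ndarray, d1: np.ndarray, d2: np.ndarray,
                         point: np.ndarray) -> tuple[float, float, float]:
    """(amplitude, azimuth, orientation_noise), all degrees, for one bifurcation.

    The primary daughter is the one most parallel to the parent (ties break to
    the first daughter).  Azimuth is the clockwise angle (viewed along the
    parent vector from its base) that rotates the secondary daughter about the
    parent so that it points toward the central y-axis.
    """
    p = _unit(parent_vec)
    c1 = float(np.dot(_unit(d1), p))
    c2 = float(np.dot(_unit(d2), p))
    if c2 > c1 + 1e-12:
        primary, secondary = d2, d1
    else:
        primary, secondary = d1, d2
    amplitude = angle_between(primary, secondary)
    noise = angle_between(primary, p)

    s_perp = _perp_component(_unit(secondary), p)
    if np.linalg.norm(s_perp) < 1e-12:
        return amplitude, 0.0, noise
    s_perp = _unit(s_perp)
    ref = _toward_axis_reference(point, p)
    # counterclockwise angle from secondary to reference, about the parent
    ccw = math.atan2(float(np.dot(p, np.cross(s_perp, ref))),
                     float(np.dot(s_perp, ref)))
    azimuth = (-math.degrees(ccw)) % 360.0
    return amplitude, azimuth, noise


def place_secondary(parent_dir: np.ndarray, point: np.ndarray,
                    amplitude: float, azimuth: float) -> np.ndarray:
    """Secondary-daughter unit direction with the given amplitude (degrees from
    the parent direction) and azimuth (inverse of the measurement convention)."""
    p = _unit(parent_dir)
    ref = _toward_axis_reference(point, p)
    # measurement: rotating the secondary clockwise by `azimuth` aligns it with
    # ref, i.e. the secondary sits at ccw angle `azimuth` from ref
    s_perp = _rotate_about(ref, p, azimuth * DEG)
    a = amplitude * DEG
    return _unit(math.cos(a) * p + math.sin(a) * s_perp)


def _perturb_direction(direction: np.ndarray, std_deg: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian angular noise: independent N(0, tan(std)) components in the
    plane perpendicular to the direction, then renormalize."""
    if std_deg <= 0:
        return _unit(direction)
    d = _unit(direction)
    # build an orthonormal basis of the perpendicular plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = _unit(_perp_component(helper, d))
    e2 = np.cross(d, e1)
    sigma = math.tan(std_deg * DEG)
    g1, g2 = rng.normal(0.0, sigma, size=2)
    return _unit(d + g1 * e1 + g2 * e2)


# ---------------------------------------------------------------------------
# conditional angle tables
# ---------------------------------------------------------------------------

class ConditionalAngleTable:
    """2D-binned (x, z) conditional histograms of amplitude and azimuth.

    Empty cells fall back to the x-row marginal, then to the global marginal.
    """

    def __init__(self, x_edges, z_edges, amp_edges=None, azi_edges=None):
        self.x_edges = np.asarray(x_edges, dtype=float)
        self.z_edges = np.asarray(z_edges, dtype=float)
        self.amp_edges = (np.arange(0.0, 180.0 + 1e-9, 10.0)
                          if amp_edges is None else np.asarray(amp_edges, float))
        self.azi_edges = (np.arange(0.0, 360.0 + 1e-9, 10.0)
                          if azi_edges is None else np.asarray(azi_edges, float))
        nx, nz = len(self.x_edges) - 1, len(self.z_edges) - 1
        self.amp_counts = np.zeros((nx, nz, len(self.amp_edges) - 1))
        self.azi_counts = np.zeros((nx, nz, len(self.azi_edges) - 1))

    def _cell(self, x: float, z: float) -> tuple[int, int]:
        ix = int(np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                         0, len(self.x_edges) - 2))
        iz = int(np.clip(np.searchsorted(self.z_edges, z, side="right") - 1,
                         0, len(self.z_edges) - 2))
        return ix, iz

    def add(self, x: float, z: float, amplitude: float, azimuth: float) -> None:
        ix, iz = self._cell(x, z)
        ia = int(np.clip(np.searchsorted(self.amp_edges, amplitude, side="right") - 1,
                         0, self.amp_counts.shape[2] - 1))
        iq = int(np.clip(np.searchsorted(self.azi_edges, azimuth % 360.0,
                                         side="right") - 1,
                         0, self.azi_counts.shape[2] - 1))
        self.amp_counts[ix, iz, ia] += 1
        self.azi_counts[ix, iz, iq] += 1

    def _histogram(self, counts: np.ndarray, ix: int, iz: int) -> np.ndarray:
        cell = counts[ix, iz]
        if cell.sum() > 0:
            return cell / cell.sum()
        row = counts[ix].sum(axis=0)
        if row.sum() > 0:
            return row / row.sum()
        glob = counts.sum(axis=(0, 1))
        if glob.sum() > 0:
            return glob / glob.sum()
        raise ValueError("angle table is empty")

    def _sample(self, counts: np.ndarray, edges: np.ndarray, x: float, z: float,
                rng: np.random.Generator) -> float:
        ix, iz = self._cell(x, z)
        hist = self._histogram(counts, ix, iz)
        b = rng.choice(len(hist), p=hist)
        return float(rng.uniform(edges[b], edges[b + 1]))

    def sample_amplitude(self, x, z, rng) -> float:
        return self._sample(self.amp_counts, self.amp_edges, x, z, rng)

    def sample_azimuth(self, x, z, rng) -> float:
        return self._sample(self.azi_counts, self.azi_edges, x, z, rng)

    def to_dict(self) -> dict:
        return {
            "x_edges": self.x_edges.tolist(), "z_edges": self.z_edges.tolist(),
            "amp_edges": self.amp_edges.tolist(), "azi_edges": self.azi_edges.tolist(),
            "amp_counts": self.amp_counts.tolist(),
            "azi_counts": self.azi_counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalAngleTable":
        t = cls(d["x_edges"], d["z_edges"], d["amp_edges"], d["azi_edges"])
        t.amp_counts = np.asarray(d["amp_counts"], dtype=float)
        t.azi_counts = np.asarray(d["azi_counts"], dtype=float)
        return t


def measure_angle_tables(trees: list[MorphTree],
                         x_edges=None, z_edges=None,
                         amp_edges=None, azi_edges=None) -> ConditionalAngleTable:
    """Accumulate bifurcation amplitude/azimuth histograms per (x, z) cell
    from registered trees."""
    all_bifs = []
    for tree in trees:
        branches = tree.branches()
        for br in branches:
            if len(br.daughters) == 2:
                d1, d2 = (branches[i] for i in br.daughters)
                all_bifs.append((br, d1, d2))
    if not all_bifs:
        raise ValueError("no bifurcations in input trees")

    if x_edges is None or z_edges is None:
        pts = np.array([[b[0].end[0], b[0].end[2]] for b in all_bifs])
        lo = np.floor(pts.min(axis=0) / 20.0) * 20.0
        hi = np.ceil(pts.max(axis=0) / 20.0) * 20.0 + 1e-9
        if x_edges is None:
            x_edges = np.arange(lo[0], hi[0] + 20.0, 20.0)
        if z_edges is None:
            z_edges = np.arange(lo[1], hi[1] + 20.0, 20.0)

    table = ConditionalAngleTable(x_edges, z_edges, amp_edges, azi_edges)
    for br, d1, d2 in all_bifs:
        amp, azi, _ = bifurcation_geometry(
            br.end - br.start, d1.end - d1.start, d2.end - d2.start, br.end
        )
        table.add(br.end[0], br.end[2], amp, azi)
    return table


def bifurcation_angle_samples(trees: list[MorphTree]) -> dict[str, np.ndarray]:
    """Pooled amplitude / azimuth / orientation-noise samples for morphometrics."""
    amps, azis, noises = [], [], []
    for tree in trees:
        branches = tree.branches()
        for br in branches:
            if len(br.daughters) == 2:
                d1, d2 = (branches[i] for i in br.daughters)
                a, q, n = bifurcation_geometry(
                    br.end - br.start, d1.end - d1.start, d2.end - d2.start, br.end
                )
                amps.append(a)
                azis.append(q)
                noises.append(n)
    return {"amplitude": np.array(amps), "azimuth": np.array(azis),
            "orientation_noise": np.array(noises)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenerationConfig:
    """Everything the grower needs; empirical distributions as value arrays."""

    rate: np.ndarray                     # per-bin intensity lambda_k (per unit axis)
    rate_delta: float                    # bin width of the rate axis
    rate_normalized: bool                # rate axis on [0,1] vs absolute um
    terminal_lengths: np.ndarray         # um
    stem_counts: np.ndarray              # integers >= 1
    cone_half_angles: np.ndarray         # degrees, used when n_stems > 1
    tapers: np.ndarray                   # diameter decrease per um (>= 0)
    initial_diameters: np.ndarray        # um
    angle_table: ConditionalAngleTable
    stem_noise_deg: float = 10.0
    elong_noise_deg: float = 5.0
    diameter_floor: float = 0.1
    bif_count_range: tuple[float, float] = (0.0, math.inf)
    major_axis_range: tuple[float, float] = (0.0, math.inf)
    minor_axis_range: tuple[float, float] = (0.0, math.inf)
    soma_radius: float = 5.0
    max_compartments: int = 100_000
    abs_step: float = 5.0                # compartment step (um) for absolute rates

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.terminal_lengths = np.asarray(self.terminal_lengths, dtype=float)
        self.stem_counts = np.asarray(self.stem_counts, dtype=int)
        self.cone_half_angles = np.asarray(self.cone_half_angles, dtype=float)
        self.tapers = np.asarray(self.tapers, dtype=float)
        self.initial_diameters = np.asarray(self.initial_diameters, dtype=float)
        for name in ("terminal_lengths", "stem_counts", "initial_diameters",
                     "tapers", "cone_half_angles"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} distribution is empty")
        if self.rate_delta <= 0:
            raise ValueError("rate_delta must be > 0")
        if self.diameter_floor <= 0:
            raise ValueError("diameter_floor must be > 0")

    def to_dict(self) -> dict:
        return {
            "rate": self.rate.tolist(), "rate_delta": self.rate_delta,
            "rate_normalized": self.rate_normalized,
            "terminal_lengths": self.terminal_lengths.tolist(),
            "stem_counts": self.stem_counts.tolist(),
            "cone_half_angles": self.cone_half_angles.tolist(),
            "tapers": self.tapers.tolist(),
            "initial_diameters": self.initial_diameters.tolist(),
            "angle_table": self.angle_table.to_dict(),
            "stem_noise_deg": self.stem_noise_deg,
            "elong_noise_deg": self.elong_noise_deg,
            "diameter_floor": self.diameter_floor,
            "bif_count_range": list(self.bif_count_range),
            "major_axis_range": list(self.major_axis_range),
            "minor_axis_range": list(self.minor_axis_range),
            "soma_radius": self.soma_radius,
            "max_compartments": self.max_compartments,
            "abs_step": self.abs_step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationConfig":
        d = dict(d)
        d["angle_table"] = ConditionalAngleTable.from_dict(d["angle_table"])
        for key in ("bif_count_range", "major_axis_range", "minor_axis_range"):
            if key in d:
                lo, hi = d[key]
                d[key] = (float(lo), float(hi) if hi is not None else math.inf)
        return cls(**d)

    def save(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, float) and math.isinf(obj):
                return None
            if isinstance(obj, list):
                return [_clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(self.to_dict()), fh)

    @classmethod
    def load(cls, path) -> "GenerationConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("bif_count_range", "major_axis_range", "minor_axis_range"):
            if key in d:
                lo, hi = d[key]
                d[key] = (lo if lo is not None else 0.0,
                          hi if hi is not None else math.inf)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def sample_terminal_length(config: GenerationConfig,
                           rng: np.random.Generator) -> float:
    """Draw the boundary (expected terminal) pathlength from the empirical
    distribution."""
    return float(rng.choice(config.terminal_lengths))


def place_stems(n_stems: int, half_angle: float, noise_std: float,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Stem unit directions: straight up for one stem, else evenly spaced in
    azimuth on a cone about +y, each with Gaussian angular noise."""
    if n_stems < 1:
        raise ValueError("n_stems must be >= 1")
    if n_stems == 1:
        dirs = [np.array([0.0, 1.0, 0.0])]
    else:
        if not (0.0 < half_angle < 90.0):
            raise ValueError("cone half-angle must lie in (0, 90) degrees")
        a = half_angle * DEG
        phase = rng.uniform(0.0, 2.0 * math.pi)
        dirs = []
        for i in range(n_stems):
            phi = phase + 2.0 * math.pi * i / n_stems
            dirs.append(np.array([
                math.sin(a) * math.cos(phi),
                math.cos(a),
                math.sin(a) * math.sin(phi),
            ]))
    return [_perturb_direction(d, noise_std, rng) for d in dirs]


def generation_rate_from_estimate(lam: np.ndarray, estimate_delta: float,
                                  rate_delta: float,
                                  lineage_correction: bool = True) -> np.ndarray:
    """Convert an estimated per-terminal-path intensity into the per-branch
    intensity used by the grower.

    The estimate is fitted to pooled terminal-path sequences, where every
    bifurcation is recounted once per descendant tip; because a bifurcation
    doubles its descendant tips, a per-branch event probability q appears in
    the pooled paths with frequency f = 2q/(1+q).  ``lineage_correction``
    inverts that (q = f/(2-f)) so that regenerated populations reproduce the
    encoded frequencies; disable it for the uncorrected estimate.
    """
    f = np.asarray(lam, dtype=float) * estimate_delta
    if np.any(f >= 2.0):
        raise ValueError("per-bin event probability out of range")
    q = f / (2.0 - f) if lineage_correction else f
    return q / rate_delta


def thinned_point_process(rate, K: int, delta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Simulate a heterogeneous per-bin point process by thinning.

    A homogeneous Bernoulli(lambda_max * delta) process is generated, then
    each event is kept with probability lambda(k)/lambda_max.
    """
    lam = (np.array([float(rate(k)) for k in range(K)])
           if callable(rate) else np.asarray(rate, dtype=float)[:K])
    if np.any(lam < 0):
        raise ValueError("rate must be non-negative")
    lam_max = float(lam.max())
    if lam_max <= 0:
        return np.zeros(K, dtype=np.uint8)
    if lam_max * delta > 1.0:
        raise ValueError("bin too coarse for Bernoulli approximation "
                         f"(lambda_max * delta = {lam_max * delta:.3f} > 1)")
    base = rng.random(K) < lam_max * delta
    keep = rng.random(K) < lam / lam_max
    return (base & keep).astype(np.uint8)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

class GrowthError(RuntimeError):
    pass


def grow(config: GenerationConfig, rng: np.random.Generator) -> MorphTree:
    """Grow one morphology.

    The boundary length L is sampled first; the growth axis is divided into K
    bins (K = len(rate) for a normalized rate, else ceil(L / abs_step)), and
    every branch advances one compartment per bin.  An event in a branch's
    thinned point process triggers a bifurcation at the end of that bin unless
    the boundary would be reached first — the boundary always terminates.
    """
    L = sample_terminal_length(config, rng)
    n_stems = int(rng.choice(config.stem_counts))
    half_angle = float(rng.choice(config.cone_half_angles))
    stem_dirs = place_stems(n_stems, half_angle, config.stem_noise_deg, rng)

    if config.rate_normalized:
        K = len(config.rate)
        step = L / K
        lam_bins = config.rate * config.rate_delta  # per-bin event probability
    else:
        step = config.abs_step
        K = int(math.ceil(L / step))
        idx = np.minimum(
            (np.arange(K) * step / config.rate_delta).astype(int),
            len(config.rate) - 1,
        )
        lam_bins = config.rate[idx] * step
    if np.any(lam_bins > 1.0):
        raise ValueError("rate too high for the growth bin size")

    comps = [Compartment(1, -1, np.zeros(3), config.soma_radius, 1)]
    next_id = 2
    initial_diam = max(float(rng.choice(config.initial_diameters)),
                       config.diameter_floor)

    # stack of branches to grow: (parent comp id, position, direction, bin, diameter)
    stack = []
    for d in reversed(stem_dirs):
        stack.append((1, np.zeros(3), d, 0, initial_diam))

    while stack:
        parent_id, pos, direction, k0, diam = stack.pop()
        taper = max(float(rng.choice(config.tapers)), 0.0)
        events = thinned_point_process(lam_bins[k0:] / step, K - k0, step, rng) \
            if K > k0 else np.zeros(0, dtype=np.uint8)
        pid = parent_id
        k = k0
        while k < K:
            direction = _perturb_direction(direction, config.elong_noise_deg, rng)
            pos = pos + direction * step
            diam = max(diam - taper * step, config.diameter_floor)
            comp = Compartment(next_id, pid, pos.copy(), diam / 2.0, 3)
            comps.append(comp)
            pid = next_id
            next_id += 1
            if len(comps) > config.max_compartments:
                raise GrowthError("growth exceeded the compartment cap")
            if events[k - k0] and k < K - 1:
                # bifurcate here; boundary overrides events in the final bin
                amp = config.angle_table.sample_amplitude(pos[0], pos[2], rng)
                azi = config.angle_table.sample_azimuth(pos[0], pos[2], rng)
                sec_dir = place_secondary(direction, pos, amp, azi)
                stack.append((pid, pos.copy(), direction.copy(), k + 1, diam))
                stack.append((pid, pos.copy(), sec_dir, k + 1, diam))
                break
            k += 1

    return MorphTree(comps)


# ---------------------------------------------------------------------------
# screening, rescaling, populations
# ---------------------------------------------------------------------------

def screen(tree: MorphTree, config: GenerationConfig) -> tuple[bool, list[str]]:
    """Check bifurcation count and tip-ellipse axes against configured ranges."""
    reasons = []
    nb = tree.n_bifurcations()
    lo, hi = config.bif_count_range
    if not (lo <= nb <= hi):
        reasons.append("bifurcation_count")
    major, minor = tip_ellipse_axes(tree)
    lo, hi = config.major_axis_range
    if not (lo <= major <= hi):
        reasons.append("major_axis")
    lo, hi = config.minor_axis_range
    if not (lo <= minor <= hi):
        reasons.append("minor_axis")
    return (not reasons, reasons)


def rescale_xz(tree: MorphTree, target_major: float,
               target_minor: float) -> MorphTree:
    """Affine scale on x and z so the tip-projection ellipse axes hit the
    targets; y is untouched.  Requires a registered tree (major axis on x)."""
    major, minor = tip_ellipse_axes(tree)
    if major <= 0 or minor <= 0:
        raise ValueError("degenerate tip ellipse; cannot rescale")
    pos = tree.positions().copy()
    pos[:, 0] *= target_major / major
    pos[:, 2] *= target_minor / minor
    return tree.copy_with_positions(pos)


@dataclass
class PopulationStats:
    attempts: int = 0
    passed: int = 0
    rescaled: int = 0
    mean_rate: float | None = None

    @property
    def pass_fraction(self) -> float:
        return self.passed / self.attempts if self.attempts else 0.0


def generate_population(config: GenerationConfig, n: int,
                        mode: str = "heterogeneous",
                        rng: np.random.Generator | None = None,
                        rescale_on_fail: bool = True,
                        max_attempts: int | None = None,
                        ) -> tuple[list[MorphTree], PopulationStats]:
    """Grow + screen until n morphologies pass.

    ``mode='homogeneous'`` replaces the per-bin rate with its mean (the
    control comparator).  Axis-range failures are optionally repaired by
    xz-rescaling toward the mid-range targets before re-screening.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("heterogeneous", "homogeneous"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    cfg = config
    stats = PopulationStats()
    if mode == "homogeneous":
        mean_rate = float(np.mean(config.rate))
        d = config.to_dict()
        d["rate"] = [mean_rate] * len(config.rate)
        d["angle_table"] = config.angle_table  # reuse, skip round trip
        cfg = GenerationConfig(**d)
        stats.mean_rate = mean_rate

    def _mid(rng_pair):
        lo, hi = rng_pair
        if math.isinf(hi):
            return None
        return 0.5 * (lo + hi)

    out: list[MorphTree] = []
    while len(out) < n:
        stats.attempts += 1
        tree = grow(cfg, rng)
        ok, reasons = screen(tree, cfg)
        if not ok and rescale_on_fail and "bifurcation_count" not in reasons:
            tmaj, tmin = _mid(cfg.major_axis_range), _mid(cfg.minor_axis_range)
            if tmaj is not None and tmin is not None:
                try:
                    tree = rescale_xz(tree, tmaj, tmin)
                    stats.rescaled += 1
                    ok, reasons = screen(tree, cfg)
                except ValueError:
                    ok = False
        if ok:
            out.append(tree)
            stats.passed += 1
        if stats.attempts >= (max_attempts or 1000) and \
                stats.pass_fraction < 0.01:
            raise GrowthError(
                f"pass rate {stats.pass_fraction:.3%} after {stats.attempts} "
                f"attempts; screening too strict (last failure: {reasons})"
            )
    return out, stats
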