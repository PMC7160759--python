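"""Synthetic data with known ground truth.

Point-process sets simulated from a known rate curve, deterministic toy trees
(chains, Y trees, full binary trees), and full reference populations grown
from a known decaying rate — everything the test suites need without any
external reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .growth import ConditionalAngleTable, GenerationConfig, generate_population
from .ratefilter import StateSpaceParams
from .trees import Compartment, MorphTree, PointProcessSet


@dataclass
class FixtureSpec:
    """Ground-truth settings for synthetic point processes and populations."""

    K: int = 100
    R: int = 100
    delta: float = 0.01
    lam: np.ndarray | None = None          # per-bin intensity (per unit axis)
    params: StateSpaceParams | None = None
    branch_len: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam is None:
            self.lam = default_decaying_rate(self.K, self.delta)
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam * self.delta > 1.0):
            raise ValueError("lambda * delta must be <= 1 in every bin")


def default_decaying_rate(K: int, delta: float, lam0_delta: float = 0.1,
                          tau: float | None = None) -> np.ndarray:
    """Exponentially decaying rate, proximally peaked: lambda_k * delta =
    lam0_delta * exp(-k / tau) with tau = K/4 by default."""
    if tau is None:
        tau = K / 4.0
    k = np.arange(K)
    return lam0_delta * np.exp(-k / tau) / delta


def simulate_point_processes(spec: FixtureSpec,
                             rng: np.random.Generator | None = None
                             ) -> PointProcessSet:
    """R independent Bernoulli(lambda_k * delta) sequences; the final bin of
    every sequence is forced to 1 (tip convention)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = spec.lam * spec.delta
    if np.any(p > 1.0):
        raise ValueError("lambda * delta > 1")
    events = (rng.random((spec.R, spec.K)) < p[None, :]).astype(np.uint8)
    events[:, -1] = 1
    return PointProcessSet(events, spec.delta)


def simulate_latent_point_processes(spec: FixtureSpec,
                                    rng: np.random.Generator | None = None,
                                    force_tip: bool = False
                                    ) -> tuple[PointProcessSet, np.ndarray]:
    """Sequences driven by a shared AR(1) latent state drawn from
    ``spec.params``; returns (point processes, latent path).

    ``force_tip`` additionally applies the tip convention (final bin 1);
    leave it off for clean model-faithful data.
    """
    if spec.params is None:
        raise ValueError("spec.params required")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = spec.params
    x = np.empty(spec.K)
    prev = 0.0
    for k in range(spec.K):
        prev = p.rho * prev + rng.normal(0.0, math.sqrt(p.sigma_eps2))
        x[k] = prev
    lam = np.exp(p.mu + p.beta * x)
    prob = np.clip(lam * spec.delta, 0.0, 1.0)
    events = (rng.random((spec.R, spec.K)) < prob[None, :]).astype(np.uint8)
    if force_tip:
        events[:, -1] = 1
    return PointProcessSet(events, spec.delta, require_tip=force_tip), x


# ---------------------------------------------------------------------------
# toy trees
# ---------------------------------------------------------------------------

def _straight(comps: list[Compartment], next_id: int, parent: int,
              start: np.ndarray, direction: np.ndarray, length: float,
              n_seg: int, radius: float) -> int:
    step = direction / np.linalg.norm(direction) * (length / n_seg)
    pos = start.copy()
    pid = parent
    for _ in range(n_seg):
        pos = pos + step
        comps.append(Compartment(next_id, pid, pos.copy(), radius, 3))
        pid = next_id
        next_id += 1
    return next_id


def make_toy_tree(kind: str, branch_len: float = 10.0, depth: int = 3,
                  n: int = 4, radius: float = 0.5) -> MorphTree:
    """Deterministic fixture trees.

    - ``chain``: unbranched vertical neurite of ``n`` segments x branch_len.
    - ``Y``: vertical stem of branch_len, two daughters of branch_len at
      +/-45 degrees in the xy-plane.
    - ``binary``: full binary tree with ``depth`` bifurcation levels; every
      branch has pathlength branch_len (TDL = (2^(depth+1) - 1) * branch_len).
    """
    comps = [Compartment(1, -1, np.zeros(3), 5.0, 1)]
    nid = 2
    if kind == "chain":
        _straight(comps, nid, 1, np.zeros(3), np.array([0.0, 1.0, 0.0]),
                  branch_len * n, n, radius)
    elif kind == "Y":
        nid = _straight(comps, nid, 1, np.zeros(3), np.array([0.0, 1.0, 0.0]),
                        branch_len, 2, radius)
        top = comps[-1].position.copy()
        fork = comps[-1].id
        s = 1.0 / math.sqrt(2.0)
        nid = _straight(comps, nid, fork, top, np.array([s, s, 0.0]),
                        branch_len, 2, radius)
        _straight(comps, nid, fork, top, np.array([-s, s, 0.0]),
                  branch_len, 2, radius)
    elif kind == "binary":
        if depth > 8:
            raise ValueError("depth must be <= 8")

        def grow_branch(parent, start, direction, level, nid):
            nid = _straight(comps, nid, parent, start, direction,
                            branch_len, 2, radius)
            if level >= depth:
                return nid
            fork_id = comps[-1].id
            top = comps[-1].position.copy()
            # split in alternating planes with a shrinking half-angle
            half = math.radians(40.0 / (level + 1))
            axis = np.array([0.0, 0.0, 1.0]) if level % 2 == 0 \
                else np.array([1.0, 0.0, 0.0])
            d = direction / np.linalg.norm(direction)
            for sign in (1.0, -1.0):
                c, s = math.cos(sign * half), math.sin(sign * half)
                newd = d * c + np.cross(axis, d) * s \
                    + axis * np.dot(axis, d) * (1.0 - c)
                nid = grow_branch(fork_id, top, newd, level + 1, nid)
            return nid

        grow_branch(1, np.zeros(3), np.array([0.0, 1.0, 0.0]), 0, nid)
    else:
        raise ValueError(f"unknown toy tree kind {kind!r}")
    return MorphTree(comps)


# ---------------------------------------------------------------------------
# reference populations
# ---------------------------------------------------------------------------

def uniform_angle_table(amp_lo: float = 20.0, amp_hi: float = 60.0
                        ) -> ConditionalAngleTable:
    """Single-cell angle table: amplitudes uniform on [amp_lo, amp_hi),
    azimuths uniform on [0, 360)."""
    t = ConditionalAngleTable([-1e6, 1e6], [-1e6, 1e6])
    centers = t.amp_edges[:-1] + np.diff(t.amp_edges) / 2.0
    mask = (centers >= amp_lo) & (centers < amp_hi)
    t.amp_counts[0, 0, mask] = 1.0
    t.azi_counts[0, 0, :] = 1.0
    return t


def reference_config(spec: FixtureSpec,
                     rng: np.random.Generator | None = None,
                     permissive: bool = True) -> GenerationConfig:
    """A generation config with the spec's true rate, a broad terminal-length
    distribution, and a simple fixed angle table."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    return GenerationConfig(
        rate=spec.lam,
        rate_delta=spec.delta,
        rate_normalized=True,
        terminal_lengths=rng.normal(300.0, 25.0, size=200).clip(150.0),
        stem_counts=np.array([1, 2, 2, 3]),
        cone_half_angles=rng.uniform(15.0, 40.0, size=50),
        tapers=rng.uniform(0.001, 0.004, size=50),
        initial_diameters=rng.uniform(1.5, 3.0, size=50),
        angle_table=uniform_angle_table(),
        stem_noise_deg=8.0,
        elong_noise_deg=4.0,
        bif_count_range=(0, math.inf) if permissive else (3, 40),
        major_axis_range=(0.0, math.inf),
        minor_axis_range=(0.0, math.inf),
    )


def make_reference_population(spec: FixtureSpec, n: int,
                              rng: np.random.Generator | None = None
                              ) -> list[MorphTree]:
    """Grow a pseudo-"real" population from the spec's true rate so that
    estimate -> regenerate -> measure loops can be closed with known truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    config = reference_config(spec, np.random.default_rng(spec.seed + 1))
    trees, _ = generate_population(config, n, "heterogeneous", rng,
                                   rescale_on_fail=False)
    return trees
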