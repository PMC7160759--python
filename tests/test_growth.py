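import math

import numpy as np
import pytest

import arborgen as ag
from arborgen.growth import (ConditionalAngleTable, GenerationConfig,
                             bifurcation_geometry, generate_population,
                             generation_rate_from_estimate, grow,
                             measure_angle_tables, place_secondary,
                             place_stems, rescale_xz, sample_terminal_length,
                             screen, thinned_point_process)
from arborgen.synth import (FixtureSpec, make_toy_tree, reference_config,
                            uniform_angle_table)
from arborgen.trees import write_swc


def _zero_noise_config(rate_bins=20, lam_delta=0.0, **over):
    spec = FixtureSpec(K=rate_bins, delta=1.0 / rate_bins, seed=0,
                       lam=np.full(rate_bins, lam_delta * rate_bins))
    cfg = reference_config(spec)
    d = cfg.to_dict()
    d["angle_table"] = cfg.angle_table
    defaults = dict(stem_noise_deg=0.0, elong_noise_deg=0.0,
                    terminal_lengths=[200.0], stem_counts=[1],
                    cone_half_angles=[30.0])
    defaults.update(over)
    d.update(defaults)
    return GenerationConfig(**d)


# ---------------------------------------------------------------------------
# stems / thinning / terminal length
# ---------------------------------------------------------------------------

class TestPlaceStems:
    def test_single_stem_points_up(self, rng):
        dirs = place_stems(1, 30.0, 0.0, rng)
        np.testing.assert_allclose(dirs[0], [0, 1, 0], atol=1e-12)

    def test_four_stems_on_cone(self, rng):
        dirs = place_stems(4, 30.0, 0.0, rng)
        assert len(dirs) == 4
        for d in dirs:
            assert math.isclose(
                math.degrees(math.acos(d[1])), 30.0, abs_tol=1e-9)
        az = sorted(math.atan2(d[2], d[0]) % (2 * math.pi) for d in dirs)
        gaps = np.diff(az + [az[0] + 2 * math.pi])
        np.testing.assert_allclose(gaps, math.pi / 2, atol=1e-9)

    def test_unit_norm(self, rng):
        for d in place_stems(5, 45.0, 10.0, rng):
            assert math.isclose(np.linalg.norm(d), 1.0, abs_tol=1e-12)

    def test_invalid_half_angle(self, rng):
        with pytest.raises(ValueError):
            place_stems(3, 95.0, 0.0, rng)
        with pytest.raises(ValueError):
            place_stems(2, 0.0, 0.0, rng)


class TestThinning:
    def test_max_rate_is_noop_binomial(self):
        rng = np.random.default_rng(4)
        K, lam, delta = 100_000, 0.08, 1.0
        seq = thinned_point_process(np.full(K, lam), K, delta, rng)
        p = lam * delta
        se = math.sqrt(p * (1 - p) / K)
        assert abs(seq.mean() - p) <= 3 * se

    def test_zero_rate_all_zero(self, rng):
        seq = thinned_point_process(np.zeros(50), 50, 1.0, rng)
        assert seq.sum() == 0

    def test_step_rate_frequencies(self):
        rng = np.random.default_rng(11)
        K = 40
        lam = np.where(np.arange(K) < 20, 0.09, 0.02)
        reps = 10_000
        counts = np.zeros(K)
        for _ in range(reps):
            counts += thinned_point_process(lam, K, 1.0, rng)
        freq = counts / reps
        se = np.sqrt(lam * (1 - lam) / reps)
        assert np.all(np.abs(freq - lam) <= 3 * se)

    def test_too_coarse_bin_raises(self, rng):
        with pytest.raises(ValueError, match="coarse"):
            thinned_point_process(np.full(10, 0.3), 10, 5.0, rng)

    def test_callable_rate(self, rng):
        seq = thinned_point_process(lambda k: 0.05 if k < 5 else 0.0,
                                    10, 1.0, rng)
        assert seq[5:].sum() == 0


class TestTerminalLength:
    def test_single_value(self, rng):
        cfg = _zero_noise_config(terminal_lengths=[123.0])
        assert sample_terminal_length(cfg, rng) == 123.0

    def test_seeded_reproducible(self):
        cfg = _zero_noise_config(terminal_lengths=list(range(100, 400)))
        a = [sample_terminal_length(cfg, np.random.default_rng(5))
             for _ in range(1)]
        b = [sample_terminal_length(cfg, np.random.default_rng(5))
             for _ in range(1)]
        assert a == b

    def test_dkw_band(self):
        rng = np.random.default_rng(21)
        source = np.sort(rng.normal(300, 30, size=500))
        cfg = _zero_noise_config(terminal_lengths=source.tolist())
        draws = np.array([sample_terminal_length(cfg, rng)
                          for _ in range(10_000)])
        # DKW: sup |F_n - F| <= sqrt(log(2/alpha) / (2n)) w.p. 1-alpha
        eps = math.sqrt(math.log(2 / 0.01) / (2 * len(draws)))
        grid = np.linspace(source.min(), source.max(), 200)
        f_src = np.searchsorted(source, grid, side="right") / len(source)
        f_emp = np.searchsorted(np.sort(draws), grid, side="right") / len(draws)
        assert np.max(np.abs(f_src - f_emp)) <= eps


# ---------------------------------------------------------------------------
# bifurcation geometry
# ---------------------------------------------------------------------------

class TestBifurcationGeometry:
    def test_hand_right_angle(self):
        # parent along +y at a point on +x; primary continues +y, secondary +x
        amp, azi, noise = bifurcation_geometry(
            np.array([0.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0]),
            np.array([1.0, 0.0, 0.0]), np.array([50.0, 100.0, 0.0]))
        assert math.isclose(amp, 90.0, abs_tol=1e-9)
        assert math.isclose(noise, 0.0, abs_tol=1e-9)
        # secondary points along +x, away from the y-axis; rotating it
        # clockwise (viewed along +y from below) by 180 deg points it inward
        assert math.isclose(azi, 180.0, abs_tol=1e-9)

    def test_collinear_primary_zero_noise(self):
        _, _, noise = bifurcation_geometry(
            np.array([0.0, 2.0, 0.0]), np.array([0.0, 5.0, 0.0]),
            np.array([1.0, 1.0, 0.0]), np.array([10.0, 10.0, 10.0]))
        assert noise == 0.0

    def test_symmetric_tie_breaks_to_first(self):
        parent = np.array([0.0, 1.0, 0.0])
        d1 = np.array([1.0, 1.0, 0.0])
        d2 = np.array([-1.0, 1.0, 0.0])
        amp1, _, noise1 = bifurcation_geometry(parent, d1, d2,
                                               np.array([5.0, 5.0, 0.0]))
        assert math.isclose(noise1, 45.0, abs_tol=1e-9)  # primary is d1

    def test_place_secondary_round_trip(self, rng):
        for _ in range(50):
            parent = rng.normal(size=3)
            parent /= np.linalg.norm(parent)
            point = rng.normal(scale=40.0, size=3)
            amp = float(rng.uniform(10.0, 170.0))
            azi = float(rng.uniform(0.0, 360.0))
            sec = place_secondary(parent, point, amp, azi)
            amp2, azi2, _ = bifurcation_geometry(parent, parent, sec, point)
            assert math.isclose(amp, amp2, abs_tol=1e-6)
            assert min(abs(azi - azi2), 360 - abs(azi - azi2)) < 1e-6


class TestAngleTables:
    def test_single_bifurcation_lands_in_cell(self):
        y = make_toy_tree("Y", 10.0)
        table = measure_angle_tables([y], x_edges=[-20, 0, 20],
                                     z_edges=[-20, 0, 20])
        # bifurcation at (0, 10, 0): x=0 -> second x cell, z=0 -> second z cell
        assert table.amp_counts.sum() == 1
        assert table.amp_counts[1, 1].sum() == 1
        # daughters at +-45 deg from vertical: amplitude 90
        ia = np.argmax(table.amp_counts[1, 1])
        assert table.amp_edges[ia] <= 90.0 <= table.amp_edges[ia + 1] + 1e-9

    def test_no_bifurcations_raises(self, chain_tree):
        with pytest.raises(ValueError):
            measure_angle_tables([chain_tree])

    def test_cell_histograms_normalized(self, small_population):
        table = measure_angle_tables(small_population)
        nx, nz, _ = table.amp_counts.shape
        for ix in range(nx):
            for iz in range(nz):
                h = table.amp_counts[ix, iz]
                if h.sum() > 0:
                    hist = table._histogram(table.amp_counts, ix, iz)
                    assert math.isclose(hist.sum(), 1.0, abs_tol=1e-12)

    def test_empty_cell_falls_back(self):
        t = uniform_angle_table(30.0, 40.0)
        rng = np.random.default_rng(0)
        # any (x, z) works: single global cell
        a = t.sample_amplitude(1e5, -1e5, rng)
        assert 30.0 <= a < 40.0

    def test_round_trip_dict(self):
        t = uniform_angle_table()
        t2 = ConditionalAngleTable.from_dict(t.to_dict())
        np.testing.assert_array_equal(t.amp_counts, t2.amp_counts)
        np.testing.assert_array_equal(t.azi_edges, t2.azi_edges)


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

class TestGrow:
    def test_zero_rate_single_unbranched_stem(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0)
        tree = grow(cfg, rng)
        assert tree.n_bifurcations() == 0
        paths = ag.terminal_paths(tree)
        assert len(paths) == 1
        assert math.isclose(paths[0].total_pathlength, 200.0, rel_tol=1e-9)

    def test_zero_noise_straight_vertical(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0)
        tree = grow(cfg, rng)
        pos = tree.positions()
        assert np.allclose(pos[:, [0, 2]], 0.0, atol=1e-9)
        assert math.isclose(pos[:, 1].max(), 200.0, rel_tol=1e-9)

    def test_structural_contract(self):
        spec = FixtureSpec(K=40, delta=0.025, seed=77)
        cfg = reference_config(spec)
        rng = np.random.default_rng(42)
        for _ in range(10):
            tree = grow(cfg, rng)
            # binary + acyclic enforced by MorphTree construction
            for nid in (c.id for c in tree.compartments):
                assert len(tree.children(nid)) <= 2 or nid == tree.soma_id
            lengths = [p.total_pathlength for p in ag.terminal_paths(tree)]
            delta_um = max(lengths) / spec.K
            assert max(lengths) - min(lengths) <= 2 * delta_um + 1e-6

    def test_degenerate_angle_table_controls_amplitude(self):
        # all amplitude mass in the 40-50 bin: every generated bifurcation
        # must show amplitude within that bin (half-bin slack)
        spec = FixtureSpec(K=30, delta=1 / 30, seed=5,
                           lam=np.full(30, 0.12 * 30))
        cfg = reference_config(spec)
        d = cfg.to_dict()
        d["angle_table"] = uniform_angle_table(40.0, 50.0)
        d.update(elong_noise_deg=0.0, stem_noise_deg=0.0, stem_counts=[1])
        cfg = GenerationConfig(**d)
        rng = np.random.default_rng(3)
        from arborgen.growth import bifurcation_angle_samples
        amps = []
        for _ in range(20):
            amps.extend(bifurcation_angle_samples([grow(cfg, rng)])["amplitude"])
        assert len(amps) > 10
        assert np.all(np.asarray(amps) >= 35.0)
        assert np.all(np.asarray(amps) <= 55.0)

    def test_diameter_floor_and_taper(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0, tapers=[0.05],
                                 initial_diameters=[2.0])
        tree = grow(cfg, rng)
        radii = np.array([c.radius for c in tree.compartments
                          if c.type_code == 3])
        assert radii.min() >= cfg.diameter_floor / 2.0 - 1e-12
        assert radii[0] > radii[-1]

    def test_compartment_cap(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0, max_compartments=5)
        with pytest.raises(Exception, match="cap"):
            grow(cfg, rng)


# ---------------------------------------------------------------------------
# screening / rescaling / population
# ---------------------------------------------------------------------------

class TestScreenRescale:
    def test_bifurcation_count_fail_reason(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0, bif_count_range=(5, 50))
        tree = grow(cfg, rng)
        ok, reasons = screen(tree, cfg)
        assert not ok and "bifurcation_count" in reasons

    def test_passing_tree(self, rng):
        cfg = _zero_noise_config(lam_delta=0.0)
        tree = grow(cfg, rng)
        ok, reasons = screen(tree, cfg)
        assert ok and reasons == []

    def test_batch_recount_oracle(self, small_population):
        spec = FixtureSpec(K=40, delta=0.025, seed=2024)
        cfg = reference_config(spec)
        d = cfg.to_dict()
        d["angle_table"] = cfg.angle_table
        d["bif_count_range"] = (2, 10)
        cfg = GenerationConfig(**d)
        from arborgen.trees import tip_ellipse_axes
        for tree in small_population:
            ok, _ = screen(tree, cfg)
            # independent recount: bifurcations via children dict and axes
            nb = sum(1 for c in tree.compartments
                     if c.id != tree.soma_id and len(tree.children(c.id)) == 2)
            major, minor = tip_ellipse_axes(tree)
            expected = (2 <= nb <= 10
                        and cfg.major_axis_range[0] <= major
                        and cfg.minor_axis_range[0] <= minor)
            assert ok == expected

    def test_rescale_identity(self, small_population):
        from arborgen.trees import register, tip_ellipse_axes
        tree = register(small_population[0])
        major, minor = tip_ellipse_axes(tree)
        if minor <= 0:
            pytest.skip("degenerate fixture ellipse")
        same = rescale_xz(tree, major, minor)
        assert np.allclose(same.positions(), tree.positions(), atol=1e-9)

    def test_rescale_doubles_coordinates(self, small_population):
        from arborgen.trees import register, tip_ellipse_axes
        tree = register(small_population[4])
        major, minor = tip_ellipse_axes(tree)
        if minor <= 0:
            pytest.skip("degenerate fixture ellipse")
        doubled = rescale_xz(tree, 2 * major, 2 * minor)
        np.testing.assert_allclose(doubled.positions()[:, 0],
                                   2 * tree.positions()[:, 0], atol=1e-9)
        np.testing.assert_allclose(doubled.positions()[:, 2],
                                   2 * tree.positions()[:, 2], atol=1e-9)
        np.testing.assert_allclose(doubled.positions()[:, 1],
                                   tree.positions()[:, 1], atol=1e-12)

    def test_rescale_hits_targets(self, small_population):
        from arborgen.trees import register, tip_ellipse_axes
        tree = register(small_population[5])
        major, minor = tip_ellipse_axes(tree)
        if minor <= 0:
            pytest.skip("degenerate fixture ellipse")
        scaled = rescale_xz(tree, 150.0, 80.0)
        major2, minor2 = tip_ellipse_axes(scaled)
        assert math.isclose(major2, 150.0, rel_tol=1e-6)
        assert math.isclose(minor2, 80.0, rel_tol=1e-6)


class TestGeneratePopulation:
    def test_single_tree_permissive(self):
        spec = FixtureSpec(K=30, delta=1 / 30, seed=9)
        cfg = reference_config(spec)
        trees, stats = generate_population(
            cfg, 1, rng=np.random.default_rng(1), rescale_on_fail=False)
        assert len(trees) == 1
        assert stats.pass_fraction == 1.0

    def test_seed_reproducible_bitwise(self, tmp_path):
        spec = FixtureSpec(K=30, delta=1 / 30, seed=9)
        cfg = reference_config(spec)
        outs = []
        for run in range(2):
            trees, _ = generate_population(
                cfg, 3, rng=np.random.default_rng(99), rescale_on_fail=False)
            blobs = []
            for i, t in enumerate(trees):
                p = tmp_path / f"{run}_{i}.swc"
                write_swc(t, p)
                blobs.append(p.read_bytes())
            outs.append(blobs)
        assert outs[0] == outs[1]

    def test_heterogeneous_beats_homogeneous_proximally(self):
        spec = FixtureSpec(K=30, delta=1 / 30, seed=13)
        cfg = reference_config(spec)
        het, _ = generate_population(cfg, 100, "heterogeneous",
                                     np.random.default_rng(7),
                                     rescale_on_fail=False)
        hom, stats = generate_population(cfg, 100, "homogeneous",
                                         np.random.default_rng(8),
                                         rescale_on_fail=False)
        assert stats.mean_rate is not None

        def prox(trees):
            out = []
            for t in trees:
                pp = ag.encode_point_processes(t, normalize=True, n_bins=30,
                                               tip_events=False)
                out.append(pp.events[:, :15].sum())
            return np.array(out, dtype=float)

        from scipy.stats import mannwhitneyu
        _, p = mannwhitneyu(prox(het), prox(hom), alternative="greater")
        assert p < 0.01

    def test_unknown_mode_raises(self):
        spec = FixtureSpec(K=20, delta=0.05, seed=1)
        cfg = reference_config(spec)
        with pytest.raises(ValueError):
            generate_population(cfg, 1, "other")

    def test_impossible_screen_aborts(self):
        spec = FixtureSpec(K=20, delta=0.05, seed=1)
        cfg = reference_config(spec)
        d = cfg.to_dict()
        d["angle_table"] = cfg.angle_table
        d["bif_count_range"] = (1000, 2000)
        cfg = GenerationConfig(**d)
        with pytest.raises(Exception, match="pass rate"):
            generate_population(cfg, 1, rng=np.random.default_rng(0),
                                max_attempts=50)


class TestRateConversion:
    def test_lineage_correction_round_trip(self):
        q = np.array([0.02, 0.05, 0.1])
        f = 2 * q / (1 + q)
        got = generation_rate_from_estimate(f / 0.01, 0.01, 0.01,
                                            lineage_correction=True)
        np.testing.assert_allclose(got * 0.01, q, rtol=1e-12)

    def test_uncorrected_passthrough(self):
        lam = np.array([1.0, 2.0])
        got = generation_rate_from_estimate(lam, 0.02, 0.05,
                                            lineage_correction=False)
        np.testing.assert_allclose(got * 0.05, lam * 0.02)


class TestConfigIO:
    def test_json_round_trip(self, tmp_path):
        spec = FixtureSpec(K=20, delta=0.05, seed=2)
        cfg = reference_config(spec)
        path = tmp_path / "cfg.json"
        cfg.save(path)
        loaded = GenerationConfig.load(path)
        np.testing.assert_allclose(loaded.rate, cfg.rate)
        np.testing.assert_allclose(loaded.terminal_lengths,
                                   cfg.terminal_lengths)
        assert loaded.rate_normalized == cfg.rate_normalized
        assert math.isinf(loaded.bif_count_range[1])

    def test_empty_distribution_rejected(self):
        spec = FixtureSpec(K=20, delta=0.05, seed=2)
        cfg = reference_config(spec)
        d = cfg.to_dict()
        d["angle_table"] = cfg.angle_table
        d["tapers"] = []
        with pytest.raises(ValueError, match="tapers"):
            GenerationConfig(**d)
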