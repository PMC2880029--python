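"""Cluster invasion, bright features, low pixels, twins, fractional maps."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from beadqc.array_model import build_layout, build_neighbour_graph, nominal_positions
from beadqc.spatial import (
    count_twin_pairs,
    detect_bright_features,
    detect_low_pixels,
    expand_cluster,
    expected_twin_pairs,
    find_nondecoded_clusters,
    flag_bright_neighbours,
    flag_low_pixel_beads,
    fractional_intensity_map,
    permutation_null_twins,
)
from beadqc.synthetic import ArtifactSpec, SimulationConfig, simulate_section


def oracle_clusters(graph, decoded, min_size):
    """Independent oracle: networkx components of the non-decoded subgraph
    restricted to those containing a seed (a bead with 6 non-decoded
    neighbours)."""
    nondec = ~np.asarray(decoded, dtype=bool)
    G = nx.Graph()
    G.add_nodes_from(np.flatnonzero(nondec).tolist())
    for u, v in graph.edges():
        if nondec[u] and nondec[v]:
            G.add_edge(int(u), int(v))
    seeds = {int(b) for b in np.flatnonzero(nondec)
             if graph.degree[b] == 6 and np.all(nondec[graph.neighbours(b)])}
    comps = []
    for comp in nx.connected_components(G):
        if len(comp) >= min_size and comp & seeds:
            comps.append(frozenset(comp))
    return set(comps)


class TestClusters:
    def test_scattered_failures_have_no_cluster(self, small_graph):
        decoded = np.ones(small_graph.n, dtype=bool)
        decoded[[3, 17, 40]] = False  # isolated non-decoded beads
        assert find_nondecoded_clusters(small_graph, decoded, min_size=1) == []

    def test_matches_networkx_oracle_on_random_patterns(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=20, cols=20)
        graph = build_neighbour_graph(grid)
        rng = np.random.default_rng(28)
        for trial in range(50):
            decoded = rng.random(graph.n) > 0.35
            min_size = int(rng.integers(2, 12))
            got = {frozenset(c.members.tolist())
                   for c in find_nondecoded_clusters(graph, decoded, min_size)}
            assert got == oracle_clusters(graph, decoded, min_size)

    def test_injected_disc_recovered_exactly(self):
        cfg = SimulationConfig(seed=29, rows=30, cols=30, non_decode_rate=0.0,
                               artifacts=(ArtifactSpec("nondecoded_cluster",
                                                       {"size": 80}),))
        sec = simulate_section(cfg, render=False)
        decoded = sec.beads["bead_type_id"].to_numpy() >= 0
        clusters = find_nondecoded_clusters(sec.graph, decoded, min_size=50)
        assert len(clusters) == 1
        assert set(clusters[0].members.tolist()) == set(sec.truth[0].beads.tolist())

    def test_two_separated_discs_stay_disjoint(self):
        cfg = SimulationConfig(
            seed=30, rows=40, cols=40, non_decode_rate=0.0,
            artifacts=(
                ArtifactSpec("nondecoded_cluster", {"size": 60, "seed_bead": 410}),
                ArtifactSpec("nondecoded_cluster", {"size": 60, "seed_bead": 1230}),
            ))
        sec = simulate_section(cfg, render=False)
        decoded = sec.beads["bead_type_id"].to_numpy() >= 0
        clusters = find_nondecoded_clusters(sec.graph, decoded, min_size=50)
        assert len(clusters) == 2
        members = [set(c.members.tolist()) for c in clusters]
        assert not (members[0] & members[1])

    def test_halo_expansion_rings(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=25, cols=25)
        graph = build_neighbour_graph(grid)
        decoded = np.ones(graph.n, dtype=bool)
        centre = int(grid.index_of(12, 12))
        # hex disc: centre plus first ring, all non-decoded
        disc = [centre] + [int(v) for v in graph.neighbours(centre)]
        decoded[disc] = False
        clusters = find_nondecoded_clusters(graph, decoded, min_size=7)
        assert len(clusters) == 1
        # rings=0 -> no halo
        got0 = expand_cluster(clusters, graph, decoded, rings=0)[0].halo
        assert got0.size == 0
        # rings=1 -> brute-force boundary: decoded beads adjacent to the disc
        got1 = set(expand_cluster(clusters, graph, decoded, rings=1)[0].halo.tolist())
        boundary = set()
        for b in disc:
            for nb in graph.neighbours(b):
                if decoded[nb]:
                    boundary.add(int(nb))
        assert got1 == boundary
        got2 = set(expand_cluster(clusters, graph, decoded, rings=2)[0].halo.tolist())
        assert got1 <= got2 and len(got2) > len(got1)


class TestBrightFeatures:
    def test_blank_image_has_no_features(self):
        img = np.full((64, 64), 500.0)
        assert detect_bright_features(img, intensity_threshold=1000) == []

    def test_saturated_bead_detected_with_accurate_centroid(self):
        cfg = SimulationConfig(seed=31, rows=20, cols=20,
                               artifacts=(ArtifactSpec(
                                   "bright_bead",
                                   {"bead": 210, "brightness": 60000.0}),))
        sec = simulate_section(cfg)
        bx = sec.beads["x"].iloc[210]
        by = sec.beads["y"].iloc[210]
        feats = detect_bright_features(
            sec.image, intensity_threshold=30000.0, min_mass=40,
            bead_centres=sec.beads[["x", "y"]].to_numpy())
        assert len(feats) == 1
        assert feats[0].mass >= 40
        assert np.hypot(feats[0].centroid[0] - bx, feats[0].centroid[1] - by) < 1.0
        assert feats[0].bead_index == 210

    def test_elongated_streak_rejected_by_circularity(self):
        img = np.full((64, 64), 100.0)
        img[30:33, 10:40] = 60000.0  # 3x30 bar: 4*pi*A/P^2 well below 0.8
        feats = detect_bright_features(img, intensity_threshold=30000.0,
                                       min_mass=40, min_circularity=0.8)
        assert feats == []

    def test_neighbours_of_bright_bead_flagged_and_elevated(self):
        from beadqc.extraction import extract_all
        from beadqc.summarize import residual_log_intensity

        bead = 210
        cfg = SimulationConfig(seed=32, rows=20, cols=20, n_bead_types=20,
                               within_type_sd=0.1,
                               artifacts=(ArtifactSpec(
                                   "bright_bead",
                                   {"bead": bead, "brightness": 60000.0}),))
        sec = simulate_section(cfg)
        feats = detect_bright_features(
            sec.image, intensity_threshold=30000.0,
            bead_centres=sec.beads[["x", "y"]].to_numpy())
        ms = flag_bright_neighbours(feats, sec.graph)
        nbrs = set(sec.graph.neighbours(bead).tolist())
        assert set(np.flatnonzero(ms.flags("bright_neighbour"))) == nbrs
        assert np.flatnonzero(ms.flags("bright_bead")).tolist() == [bead]
        out, _ = extract_all(sec.image, sec.beads)
        resid = residual_log_intensity(out)
        # encroachment: most neighbours read far above their type median (some
        # can instead be suppressed by the sharpening moat around the spot,
        # and non-decoded neighbours have no residual)
        nbr_resid = resid[list(nbrs)]
        assert np.sum(nbr_resid[np.isfinite(nbr_resid)] >= 1.0) >= 3
        assert np.nanmax(nbr_resid) >= 2.0

    def test_no_features_no_flags(self, small_graph):
        ms = flag_bright_neighbours([], small_graph)
        assert not ms.any_flagged().any()


class TestLowPixels:
    def test_gaussian_background_has_none(self):
        rng = np.random.default_rng(33)
        img = np.rint(rng.normal(500, 10, (80, 80))).clip(0)
        assert len(detect_low_pixels(img)) == 0

    def test_single_injected_pixel_found(self):
        rng = np.random.default_rng(34)
        img = np.rint(rng.normal(500, 10, (80, 80))).clip(0)
        img[37, 53] = 5
        got = detect_low_pixels(img)
        assert got.tolist() == [[37, 53]]

    def test_threshold_monotone_in_low_fraction(self):
        rng = np.random.default_rng(35)
        img = np.rint(rng.normal(500, 80, (60, 60))).clip(0)
        sizes = [len(detect_low_pixels(img, f)) for f in (0.8, 0.5, 0.2)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_affected_beads_match_window_membership_oracle(self):
        cfg = SimulationConfig(seed=36, rows=20, cols=20)
        sec = simulate_section(cfg)
        img = sec.image.astype(float)
        py, px = 60, 70
        img[py, px] = 3.0
        pixels = detect_low_pixels(img)
        assert [py, px] in pixels.tolist()
        ms = flag_low_pixel_beads(pixels, sec.beads, img)
        flagged = set(np.flatnonzero(ms.flags("low_pixel")))
        # oracle: beads whose 17x17 window covers the pixel and where the
        # pixel ranks among the window's five smallest
        expect = set()
        for i, (x, y) in enumerate(zip(sec.beads["x"], sec.beads["y"])):
            ax, ay = int(np.floor(x)), int(np.floor(y))
            if abs(ax - px) <= 8 and abs(ay - py) <= 8:
                win = img[ay - 8:ay + 9, ax - 8:ax + 9].ravel()
                if img[py, px] <= np.partition(win, 4)[4]:
                    expect.add(i)
        assert flagged == expect
        assert 1 <= len(flagged) <= 12

    def test_low_pixel_outside_all_windows_flags_nothing(self):
        cfg = SimulationConfig(seed=37, rows=10, cols=10)
        sec = simulate_section(cfg)
        img = sec.image.astype(float)
        img[2, 2] = 1.0  # far outside any background window
        ms = flag_low_pixel_beads(np.array([[2, 2]]), sec.beads, img)
        assert not ms.any_flagged().any()

    def test_median5_background_more_robust_than_mean5(self):
        from beadqc.extraction import ExtractionOptions, compute_background

        cfg = SimulationConfig(seed=38, rows=20, cols=20)
        sec = simulate_section(cfg)
        img = sec.image.astype(float)
        py, px = 60, 70
        img[py, px] = 3.0
        ms = flag_low_pixel_beads(np.array([[py, px]]), sec.beads, img)
        for i in np.flatnonzero(ms.flags("low_pixel")):
            centre = (sec.beads["x"].iloc[i], sec.beads["y"].iloc[i])
            mean5 = compute_background(img, centre)
            med5 = compute_background(img, centre,
                                      ExtractionOptions(background_rule="median5"))
            assert mean5 < med5


class TestTwins:
    def test_distinct_types_have_no_twins(self, small_graph):
        ids = np.arange(small_graph.n)
        assert count_twin_pairs(small_graph, ids) == 0

    def test_single_type_counts_every_edge(self, small_graph):
        ids = np.zeros(small_graph.n, dtype=int)
        assert count_twin_pairs(small_graph, ids) == small_graph.edges().shape[0]

    def test_hex_flower_centre_and_petal(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=3, cols=3)
        graph = build_neighbour_graph(grid)
        centre = int(grid.index_of(1, 1))
        petal = int(graph.neighbours(centre)[0])
        ids = np.arange(graph.n) + 100
        ids[petal] = ids[centre]
        assert count_twin_pairs(graph, ids) == 1

    def test_matches_brute_force_edge_loop(self, small_graph):
        rng = np.random.default_rng(39)
        for _ in range(10):
            ids = rng.integers(-1, 6, small_graph.n)
            brute = 0
            for u, v in small_graph.edges():
                if ids[u] >= 0 and ids[u] == ids[v]:
                    brute += 1
            assert count_twin_pairs(small_graph, ids) == brute

    def test_idealized_expectation(self):
        assert expected_twin_pairs(1_000_000, 6, 50_000) == 60.0
        assert expected_twin_pairs(1000, 4, 1) == 2000.0
        with pytest.raises(ValueError):
            expected_twin_pairs(100, 6, 0)

    def test_expectation_matches_monte_carlo(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=30, cols=30)
        graph = build_neighbour_graph(grid)
        edges = graph.edges()
        rng = np.random.default_rng(40)
        counts = [int(np.sum(
            (ids := rng.integers(0, 45, graph.n))[edges[:, 0]] == ids[edges[:, 1]]))
            for _ in range(200)]
        mean_deg = graph.degree.mean()
        expect = expected_twin_pairs(graph.n, mean_deg, 45)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) <= 3 * se


class TestPermutationNull:
    def test_permutation_preserves_id_multiset(self, small_graph):
        rng = np.random.default_rng(41)
        ids = rng.integers(0, 5, small_graph.n)
        ids[:4] = -1
        null, p, obs = permutation_null_twins(small_graph, ids, n_perm=20, seed=0)
        assert null.shape == (20,)
        assert 0 < p <= 1
        # re-run: determinism under seed
        null2, p2, obs2 = permutation_null_twins(small_graph, ids, n_perm=20, seed=0)
        assert np.array_equal(null, null2) and p == p2 and obs == obs2

    def test_null_mean_matches_fixed_multiset_expectation(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=25, cols=25)
        graph = build_neighbour_graph(grid)
        rng = np.random.default_rng(42)
        ids = rng.integers(0, 30, graph.n)
        null, _, _ = permutation_null_twins(graph, ids, n_perm=400, seed=1)
        n = graph.n
        counts = np.bincount(ids)
        p_same = float(np.sum(counts * (counts - 1)) / (n * (n - 1)))
        expect = graph.edges().shape[0] * p_same
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean() - expect) <= 3 * se

    def test_detects_constructed_twin_excess(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=25, cols=25)
        graph = build_neighbour_graph(grid)
        rng = np.random.default_rng(43)
        ids = rng.integers(0, 60, graph.n)
        # copy each of 60 random beads' ids onto one neighbour: ~3x excess
        for b in rng.choice(graph.n, 60, replace=False):
            nbrs = graph.neighbours(int(b))
            ids[int(nbrs[0])] = ids[b]
        null, p, obs = permutation_null_twins(graph, ids, n_perm=200, seed=2)
        assert obs > null.mean() * 2
        assert p <= 0.01

    def test_random_ids_are_calibrated(self, wg6_layout):
        grid = nominal_positions(wg6_layout, (0.0, 0.0), rows=20, cols=20)
        graph = build_neighbour_graph(grid)
        inside_central = 0
        n_runs = 50
        for seed in range(n_runs):
            ids = np.random.default_rng(seed).integers(0, 25, graph.n)
            null, _, obs = permutation_null_twins(graph, ids, n_perm=100,
                                                  seed=seed)
            lo, hi = np.quantile(null, [0.025, 0.975])
            inside_central += int(lo <= obs <= hi)
        assert inside_central >= int(0.9 * n_runs)


class TestFractionalMap:
    def test_forced_fraction_fills_single_bin(self):
        beads = pd.DataFrame({
            "x": np.arange(20) + 0.5, "y": np.arange(20) + 0.5,
            "intensity": np.full(20, 100.0), "bead_type_id": np.zeros(20, int),
        })
        means, counts = fractional_intensity_map(beads, bins=10)
        assert counts.sum() == 20
        assert counts[5, 5] == 20
        assert np.isfinite(means).sum() == 1

    def test_injected_fractional_dependence_recovered(self):
        rng = np.random.default_rng(44)
        n = 20000
        fx = rng.random(n)
        beads = pd.DataFrame({
            "x": rng.integers(10, 100, n) + fx,
            "y": rng.integers(10, 100, n) + rng.random(n),
            "intensity": 1000.0 * (1 + 0.3 * fx),
            "bead_type_id": rng.integers(0, 50, n),
        })
        means, counts = fractional_intensity_map(beads, bins=10)
        col_means = np.nanmean(means, axis=0)  # mean per frac_x bin
        assert (np.diff(col_means) > 0).all()

    def test_clean_map_flat_and_residual_mode_centred(self):
        rng = np.random.default_rng(45)
        n = 20000
        ids = rng.integers(0, 40, n)
        level = rng.uniform(8, 12, 40)
        beads = pd.DataFrame({
            "x": rng.integers(10, 100, n) + rng.random(n),
            "y": rng.integers(10, 100, n) + rng.random(n),
            "intensity": 2.0 ** (level[ids] + rng.normal(0, 0.2, n)),
            "bead_type_id": ids,
        })
        means, counts = fractional_intensity_map(beads, bins=10,
                                                 mode="residual_log_intensity")
        assert counts.min() > 0
        # per-bin sampling error ~ sd/sqrt(n_bin); no spatial trend
        bound = 3 * 0.2 / np.sqrt(counts.min())
        assert np.nanstd(means) <= 3 * bound
        assert abs(np.nanmean(means)) < 0.05
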