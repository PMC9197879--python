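import numpy as np
import pytest

from morphotime.io import (
    SWC_AXON,
    SWC_DENDRITE,
    SWC_SOMA,
    AnnotationRecord,
    BasketCounts,
    LayerGeometry,
)
from morphotime.morphometrics import (
    branch_levels,
    classify_collaterals,
    extract_features,
    filopodia,
    load_schema,
    relative_ml_position,
    sholl_counts,
    soma_volume_ellipsoid,
    spans,
    straightness,
    structural_counts,
    total_length,
    weighted_basket_score,
)
from morphotime.simulate import fixture_schema, simulate_swc

from conftest import build_recon, random_compartment_tree


def chain(start_id, parent, struct, points):
    """Node tuples for a chain of points hanging from ``parent``."""
    out = []
    pid = parent
    for i, p in enumerate(points):
        out.append((start_id + i, pid, struct, *p))
        pid = start_id + i
    return out


class TestTotalLength:
    def test_straight_axon_five_segments(self):
        pts = [(i * 2.0, 50.0, 0.0) for i in range(1, 6)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        assert total_length(recon, "axon") == pytest.approx(10.0)

    def test_y_tree_additivity(self):
        nodes = [(1, -1, SWC_SOMA, 0, 0, 0),
                 (2, 1, SWC_AXON, 3, 0, 0),        # stem 3
                 (3, 2, SWC_AXON, 13, 0, 0),       # arm 10
                 (4, 2, SWC_AXON, 3, 7, 0)]        # arm 7
        recon = build_recon(nodes)
        assert total_length(recon, "axon") == pytest.approx(20.0)

    def test_random_tree_matches_edge_sum_oracle(self):
        recon = random_compartment_tree(seed=11, n_nodes=200)
        # independent edge-wise oracle
        idx = {int(i): k for k, i in enumerate(recon.ids)}
        expected = 0.0
        for k, pid in enumerate(recon.parents):
            if pid != -1 and recon.structure[k] == SWC_AXON:
                expected += np.linalg.norm(recon.xyz[k] - recon.xyz[idx[int(pid)]])
        assert total_length(recon, "axon") == pytest.approx(expected)

    def test_unknown_compartment_rejected(self, three_node_recon):
        with pytest.raises(ValueError, match="compartment"):
            total_length(three_node_recon, "glia")

    def test_compartment_lengths_partition_tree_length(self):
        recon = random_compartment_tree(seed=3, n_nodes=80)
        total_edges = recon.edge_lengths().sum()
        by_comp = sum(total_length(recon, c)
                      for c in ("axon", "dendrite", "soma", "unspecified"))
        assert by_comp == pytest.approx(total_edges)


class TestSholl:
    def test_straight_process(self):
        pts = [(0.0, 50 + d, 0.0) for d in (20.0, 40.0, 60.0)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        np.testing.assert_array_equal(
            sholl_counts(recon, "axon", [10, 50, 100]), [1, 1, 0])

    def test_reentry_counts_twice(self):
        pts = [(0.0, 50 + d, 0.0) for d in (60.0, 40.0)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        assert sholl_counts(recon, "axon", [50.0])[0] == 2

    def test_empty_compartment_gives_zeros(self, three_node_recon):
        # no 'unspecified' nodes at all
        assert sholl_counts(three_node_recon, "unspecified", [10.0]).sum() == 0

    def test_beyond_maximal_extent_is_zero(self):
        recon = random_compartment_tree(seed=5, n_nodes=60)
        assert sholl_counts(recon, "axon", [10_000.0])[0] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_arc_sampling_oracle(self, seed):
        recon = random_compartment_tree(seed=seed, n_nodes=150, step=1.5)
        center = recon.soma_centroid()
        radii = [5.0, 9.0, 13.0]
        child, parent = recon.edges()
        mask = recon.structure[child] == SWC_AXON
        counts = np.zeros(len(radii), dtype=int)
        t = np.linspace(0.0, 1.0, 60)
        for c, p in zip(child[mask], parent[mask]):
            seg = recon.xyz[p] + t[:, None] * (recon.xyz[c] - recon.xyz[p])
            d = np.linalg.norm(seg - center, axis=1)
            for ri, r in enumerate(radii):
                counts[ri] += int(np.sum(np.diff(np.sign(d - r)) != 0))
        np.testing.assert_array_equal(
            sholl_counts(recon, "axon", radii), counts)


class TestBranchLevels:
    def test_unbranched(self):
        pts = [(0, 50 + d, 0) for d in (5.0, 10.0, 15.0)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        assert branch_levels(recon, "axon") == (0.0, 0)

    def test_single_bifurcation(self):
        nodes = [(1, -1, SWC_SOMA, 0, 0, 0),
                 (2, 1, SWC_AXON, 5, 0, 0),
                 (3, 2, SWC_AXON, 10, 2, 0),
                 (4, 2, SWC_AXON, 10, -2, 0)]
        mean, mx = branch_levels(build_recon(nodes), "axon")
        assert mx == 1
        assert mean == pytest.approx(2.0 / 3.0)

    def test_binary_tree_matches_path_enumeration(self):
        # full binary tree of depth 4; oracle counts branch points above
        # each segment by walking the construction
        nodes = [(1, -1, SWC_SOMA, 0, 0, 0)]
        next_id = 2
        frontier = [(1, np.array([0.0, 0.0, 0.0]))]
        for depth in range(4):
            new_frontier = []
            for parent, pos in frontier:
                for sgn in (1, -1):
                    p = pos + np.array([5.0, sgn * 5.0 / (depth + 1), 0.0])
                    nodes.append((next_id, parent, SWC_AXON, *p))
                    new_frontier.append((next_id, p))
                    next_id += 1
            frontier = new_frontier
        # oracle: every node is its own segment (all internal nodes have two
        # children); the two depth-0 nodes are compartment roots at level 0
        # and each depth adds exactly one branch point to every path
        expected = []
        for depth in range(4):
            expected += [depth] * (2 ** (depth + 1))
        mean, mx = branch_levels(build_recon(nodes), "axon")
        assert mx == max(expected)
        assert mean == pytest.approx(float(np.mean(expected)))


class TestStraightness:
    def test_straight_segment(self):
        pts = [(d, 50.0, 0.0) for d in (3.0, 6.0, 9.0)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        assert straightness(recon, "axon") == pytest.approx(1.0)

    def test_semicircular_arc_closed_form(self):
        r = 20.0
        theta = np.linspace(0, np.pi, 400)
        pts = [(r - r * np.cos(t), 50.0 + r * np.sin(t), 0.0)
               for t in theta[1:]]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        assert straightness(recon, "axon") == pytest.approx(2 / np.pi, rel=1e-3)

    def test_random_tree_matches_chord_over_path_oracle(self):
        # star of straight polyline segments: length-weighted mean of the
        # per-segment ratios equals total chord over total path
        rng = np.random.default_rng(8)
        nodes = [(1, -1, SWC_SOMA, 0, 0, 0)]
        nid = 2
        total_chord = total_path = 0.0
        for _ in range(6):
            start = np.zeros(3)
            pid = 1
            chord_start = None
            path = 0.0
            for j in range(5):
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                new = start + step * rng.uniform(1.0, 4.0)
                nodes.append((nid, pid, SWC_AXON, *new))
                path += np.linalg.norm(new - start)
                if chord_start is None:
                    chord_start = np.zeros(3)
                pid = nid
                nid += 1
                start = new
            total_chord += np.linalg.norm(start - chord_start)
            total_path += path
        recon = build_recon(nodes)
        assert straightness(recon, "axon") == pytest.approx(
            total_chord / total_path)

    def test_weighted_vs_unweighted_flag(self):
        nodes = [(1, -1, SWC_SOMA, 0, 0, 0),
                 (2, 1, SWC_AXON, 10, 0, 0),
                 (3, 2, SWC_AXON, 20, 0, 0),
                 (4, 2, SWC_AXON, 21, 1, 0),
                 (5, 4, SWC_AXON, 20, 2, 0)]
        recon = build_recon(nodes)
        assert straightness(recon, "axon", weighted=True) != pytest.approx(
            straightness(recon, "axon", weighted=False))


class TestFilopodia:
    def test_threshold_keeps_short_terminals(self, geom):
        # three terminal branches of lengths 1.0, 1.4, 2.0
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0),
                 (2, 1, SWC_DENDRITE, 0, 60, 0),
                 (3, 2, SWC_DENDRITE, 1.0, 60, 0),
                 (4, 2, SWC_DENDRITE, 0, 61.4, 0),
                 (5, 2, SWC_DENDRITE, -2.0, 60, 0)]
        recon = build_recon(nodes)
        count, density = filopodia(recon)
        assert count == 2
        assert density == pytest.approx(2 / total_length(recon, "dendrite"))

    def test_no_short_terminals(self):
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0),
                 (2, 1, SWC_DENDRITE, 0, 70, 0)]
        assert filopodia(build_recon(nodes)) == (0, 0.0)

    def test_matches_terminal_enumeration_oracle(self):
        recon = random_compartment_tree(seed=13, n_nodes=120, step=1.2,
                                        compartment=SWC_DENDRITE)
        count, _ = filopodia(recon, threshold=1.5)
        # oracle: walk every leaf up to the nearest branch point
        children = {i: [] for i in range(recon.n_nodes)}
        ppos = recon.parent_positions()
        for k, p in enumerate(ppos):
            if p >= 0:
                children[p].append(k)
        expected = 0
        for leaf in range(recon.n_nodes):
            if recon.structure[leaf] != SWC_DENDRITE or children[leaf]:
                continue
            length = 0.0
            node = leaf
            while ppos[node] >= 0:
                par = ppos[node]
                length += np.linalg.norm(recon.xyz[node] - recon.xyz[par])
                if len(children[par]) != 1 or recon.structure[par] != SWC_DENDRITE:
                    break
                node = par
            expected += length < 1.5
        assert count == expected


class TestSpans:
    def test_tangential_line(self, geom):
        pts = [(d, 50.0, 0.0) for d in np.linspace(1, 80, 8)]
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0)]
                            + chain(2, 1, SWC_AXON, pts))
        ml, tang, z = spans(recon, geom, "axon")
        assert tang == pytest.approx(79.0)
        assert ml == pytest.approx(0.0)
        assert z == pytest.approx(0.0)

    def test_single_node_zero(self, geom, three_node_recon):
        assert spans(three_node_recon, geom, "dendrite") == (0.0, 0.0, 0.0)

    def test_rotated_axes_project_consistently(self):
        # rotate the frame about z; spans follow the projection arithmetic
        ang = np.deg2rad(30)
        geom_rot = LayerGeometry(
            pcl_top=0.0, ml_top=120.0,
            ml_normal_axis=[-np.sin(ang), np.cos(ang), 0.0],
            ml_tangential_axis=[np.cos(ang), np.sin(ang), 0.0])
        recon = random_compartment_tree(seed=2, n_nodes=60)
        pts = recon.xyz[recon.structure == SWC_AXON]
        for axis, got in zip(
                [geom_rot.ml_normal_axis, geom_rot.ml_tangential_axis,
                 geom_rot.z_axis],
                spans(recon, geom_rot, "axon")):
            proj = pts @ axis
            assert got == pytest.approx(proj.max() - proj.min())


class TestCollaterals:
    def _shaft_with_branch(self, angle_deg, up=True):
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0)]
        nodes += chain(2, 1, SWC_AXON,
                       [(x, 50.0, 0.0) for x in (30.0, 60.0, 90.0, 120.0)])
        a = np.deg2rad(angle_deg)
        sgn = 1.0 if up else -1.0
        start = np.array([60.0, 50.0, 0.0])
        d = np.array([np.cos(a), sgn * np.sin(a), 0.0])
        nodes += chain(7, 3, SWC_AXON, [tuple(start + d * t)
                                        for t in (10.0, 20.0, 30.0)])
        return build_recon(nodes)

    def test_perpendicular_up_branch(self, geom):
        stats = classify_collaterals(self._shaft_with_branch(90.0), geom)
        assert stats.up.count == 1
        assert stats.down.count == 0
        assert stats.up.total_length == pytest.approx(30.0)
        assert stats.up.percent == pytest.approx(100.0)

    def test_branch_below_threshold_excluded(self, geom):
        stats = classify_collaterals(self._shaft_with_branch(20.0), geom)
        assert stats.up.count == 0 and stats.down.count == 0

    def test_downward_branch_classified_down(self, geom):
        stats = classify_collaterals(self._shaft_with_branch(60.0, up=False),
                                     geom)
        assert stats.down.count == 1 and stats.up.count == 0

    def test_axonless_cell_rejected(self, geom):
        recon = build_recon([(1, -1, SWC_SOMA, 0, 50, 0),
                             (2, 1, SWC_DENDRITE, 0, 60, 0)])
        with pytest.raises(ValueError, match="no axon"):
            classify_collaterals(recon, geom)

    def test_matches_exhaustive_angle_oracle(self, geom):
        # several straight branches at known angles off a straight shaft:
        # inclusion is a pure angle comparison
        angles = [15.0, 35.0, 55.0, 25.0, 80.0]
        ups = [True, False, True, True, False]
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0)]
        shaft_x = np.linspace(20, 300, 15)
        nodes += chain(2, 1, SWC_AXON, [(x, 50.0, 0.0) for x in shaft_x])
        nid = 2 + len(shaft_x)
        for i, (ang, up) in enumerate(zip(angles, ups)):
            attach = 2 + 2 * i  # every other shaft node
            start = np.array([shaft_x[2 * i], 50.0, 0.0])
            a = np.deg2rad(ang)
            d = np.array([np.cos(a), (1 if up else -1) * np.sin(a), 0.0])
            nodes += chain(nid, attach, SWC_AXON,
                           [tuple(start + d * t) for t in (8.0, 16.0)])
            nid += 2
        stats = classify_collaterals(build_recon(nodes), geom)
        included = [(a, u) for a, u in zip(angles, ups) if a > 30.0]
        assert stats.up.count == sum(1 for _, u in included if u)
        assert stats.down.count == sum(1 for _, u in included if not u)


class TestScalarFeatures:
    def test_weighted_basket_score_values(self):
        assert weighted_basket_score(BasketCounts(2, 0, 1)) == pytest.approx(2.5)
        assert weighted_basket_score((0, 0, 0)) == 0.0
        assert weighted_basket_score((1, 1, 1)) == pytest.approx(2.25)

    def test_weighted_basket_score_additive(self):
        a, b = BasketCounts(2, 1, 0), BasketCounts(1, 0, 3)
        merged = BasketCounts(3, 1, 3)
        assert weighted_basket_score(merged) == pytest.approx(
            weighted_basket_score(a) + weighted_basket_score(b))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_basket_score((-1, 0, 0))

    def test_ellipsoid_volume_both_conventions(self):
        assert soma_volume_ellipsoid(1, 1, 1) == pytest.approx(4 * np.pi / 3)
        assert soma_volume_ellipsoid(1, 1, 1, "geometric") == pytest.approx(
            np.pi / 6)
        assert soma_volume_ellipsoid(2, 1, 1) == pytest.approx(
            2 * soma_volume_ellipsoid(1, 1, 1))
        with pytest.raises(ValueError):
            soma_volume_ellipsoid(0, 1, 1)

    def test_relative_ml_position(self, geom):
        assert relative_ml_position(60.0, geom) == pytest.approx(0.5)
        assert relative_ml_position(0.0, geom) == 0.0
        assert relative_ml_position(30.0, geom) == pytest.approx(0.25)


class TestStructuralCounts:
    def test_primary_dendrites_and_acd(self, geom):
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0),
                 (2, 1, SWC_DENDRITE, 0, 60, 0),
                 (3, 1, SWC_DENDRITE, 5, 55, 0),
                 (4, 1, SWC_DENDRITE, -5, 55, 0),
                 (5, 2, SWC_AXON, 10, 60, 0),
                 (6, 5, SWC_AXON, 10, -5, 0)]
        sc = structural_counts(build_recon(nodes), geom)
        assert sc.primary_dendrites == 3
        assert sc.axon_carrying_dendrite is True
        assert sc.pcl_reaching_branches == 1  # one tip below the PCL top

    def test_all_tips_above_pcl(self, geom, three_node_recon):
        sc = structural_counts(three_node_recon, geom)
        assert sc.pcl_reaching_branches == 0
        assert sc.axon_carrying_dendrite is False


class TestExtractFeatures:
    def test_fixture_ground_truth_recovered(self):
        recon, geom, truth = simulate_swc(seed=42)
        fv = extract_features(recon, geom, fixture_schema())
        for name, expected in truth.items():
            got = fv.values[name]
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-9), name

    def test_dendriteless_cell_flags_dendritic_features_missing(self, geom):
        schema = load_schema("mature_27")
        ann = AnnotationRecord(soma_volume=500.0)
        nodes = [(1, -1, SWC_SOMA, 0, 50, 0)]
        nodes += chain(2, 1, SWC_AXON, [(x, 50.0, 0.0) for x in (20.0, 40.0)])
        fv = extract_features(build_recon(nodes, annotations=ann), geom, schema)
        assert fv.provenance["dendrite_length"] == "missing"
        assert np.isnan(fv.values["filopodia_count"])
        assert fv.provenance["axon_length"] == "computed"

    def test_missing_annotation_raises(self, geom, three_node_recon):
        schema = load_schema("mature_27")
        with pytest.raises(ValueError, match="soma_volume"):
            extract_features(three_node_recon, geom, schema)

    def test_translation_changes_only_location_features(self):
        recon, geom, _ = simulate_swc(seed=7)
        fv0 = extract_features(recon, geom, fixture_schema())
        # tangential/z translation: everything identical
        fv1 = extract_features(recon.translated([25.0, 0.0, -10.0]), geom,
                               fixture_schema())
        np.testing.assert_allclose(fv0.values, fv1.values, rtol=1e-9)
        # normal translation: location features shift, sizes do not
        fv2 = extract_features(recon.translated([0.0, 5.0, 0.0]), geom,
                               fixture_schema())
        assert fv2.values["soma_height"] == pytest.approx(
            fv0.values["soma_height"] + 5.0)
        assert fv2.values["axon_length"] == pytest.approx(
            fv0.values["axon_length"])
        assert fv2.values["axon_span"] == pytest.approx(
            fv0.values["axon_span"])

    def test_schema_presets_load(self):
        assert len(load_schema("mature_27").features) == 27
        assert len(load_schema("developmental_28").features) == 28
        sch = load_schema("clustering_19")
        assert len(sch.clustering_subset) == 19
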