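"""Morphology I/O, morphometry and d_lambda discretization."""

import math

import numpy as np
import pytest

import dendromaps as dm
from dendromaps.exceptions import StructuralError, SwcParseError
from dendromaps.morphology import (
    MorphNode,
    MorphTree,
    compartmentalize,
    read_swc,
    space_constant_100,
    write_swc,
)


def chain_tree(spacing=50.0, n=3, bend_at=None):
    """Soma plus a chain of dendritic nodes; optional right-angle bend."""
    nodes = [MorphNode(1, 1, 0, 0, 0, 5.0, -1)]
    x = y = 0.0
    for k in range(n):
        if bend_at is not None and k >= bend_at:
            y += spacing
        else:
            x += spacing
        nodes.append(MorphNode(k + 2, 4, x, y, 0, 0.5, k + 1))
    return MorphTree(nodes)


class TestSwcIO:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# comment\n1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
        tree = read_swc(p)
        assert len(tree.nodes) == 3
        secs = [s for s in tree.sections() if s.type_code != 1]
        assert len(secs) == 1 and secs[0].is_terminal

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 ten 0 0 1 1\n")
        with pytest.raises(SwcParseError, match="line 2"):
            read_swc(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 5\n")
        with pytest.raises(SwcParseError, match="7 columns"):
            read_swc(p)

    def test_orphan_parent_rejected(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 9\n")
        with pytest.raises(StructuralError, match="parent 9"):
            read_swc(p)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(StructuralError, match="radius"):
            MorphTree([MorphNode(1, 1, 0, 0, 0, 0.0, -1)])

    def test_empty_tree_refused(self):
        with pytest.raises(StructuralError):
            MorphTree([])

    def test_round_trip_identity(self, tmp_path, small_tree):
        p = tmp_path / "rt.swc"
        mapping = write_swc(small_tree, p)
        back = read_swc(p)
        assert len(back.nodes) == len(small_tree.nodes)
        for a, b in zip(small_tree.nodes, back.nodes):
            assert mapping[a.node_id] == b.node_id
            assert a.type_code == b.type_code
            assert np.allclose([a.x, a.y, a.z, a.radius], [b.x, b.y, b.z, b.radius],
                               rtol=1e-5)
            pa = -1 if a.parent_id == -1 else mapping[a.parent_id]
            assert pa == b.parent_id

    def test_noncontiguous_ids_renumbered(self, tmp_path):
        nodes = [MorphNode(7, 1, 0, 0, 0, 5, -1), MorphNode(30, 3, 10, 0, 0, 1, 7)]
        mapping = write_swc(MorphTree(nodes), tmp_path / "x.swc")
        assert mapping == {7: 1, 30: 2}
        back = read_swc(tmp_path / "x.swc")
        assert [n.node_id for n in back.nodes] == [1, 2]


class TestMorphometry:
    def test_total_length_chain(self):
        assert chain_tree(50.0, 3).total_dendritic_length() == pytest.approx(0.15)

    def test_soma_only_zero_length(self):
        tree = MorphTree([MorphNode(1, 1, 0, 0, 0, 5, -1)])
        assert tree.total_dendritic_length() == 0.0

    def test_section_lengths_sum_to_total(self, small_tree):
        """Independent oracle: brute-force sum of the per-section length table."""
        secs = small_tree.sections()
        total = sum(s.length for s in secs if s.type_code in (3, 4))
        assert total / 1000.0 == pytest.approx(small_tree.total_dendritic_length(),
                                               rel=1e-9)

    def test_radial_vs_path_distance(self):
        tree = chain_tree(100.0, 2, bend_at=1)  # two 100 um edges at right angle
        tip = tree.nodes[-1].node_id
        assert tree.path_distance(tip) == pytest.approx(200.0)
        assert tree.radial_distance(tip) == pytest.approx(100.0 * math.sqrt(2))
        assert tree.radial_distance(1) == 0.0 and tree.path_distance(1) == 0.0

    def test_straight_cable_path_equals_radial(self):
        tree = chain_tree(50.0, 4)
        for n in tree.nodes[1:]:
            assert tree.path_distance(n.node_id) == pytest.approx(
                tree.radial_distance(n.node_id))

    def test_path_dominates_radial_everywhere(self, small_tree):
        """Arc length bounds the chord for every dendritic point (soma nodes
        are the distance origin by convention and are excluded)."""
        for n in small_tree.nodes:
            if n.type_code == 1:
                continue
            assert small_tree.path_distance(n.node_id) >= (
                small_tree.radial_distance(n.node_id) - 1e-6)


class TestSpaceConstant:
    def test_closed_form(self):
        # 1e5 * sqrt(1 / (4 pi * 100 * 70 * 1)) = 337.2 um
        assert space_constant_100(1.0, 70.0, 1.0) == pytest.approx(337.2, abs=0.05)

    def test_sqrt_scaling(self):
        base = space_constant_100(1.0, 70.0, 1.0)
        assert space_constant_100(4.0, 70.0, 1.0) == pytest.approx(2 * base)
        assert space_constant_100(1.0, 280.0, 1.0) == pytest.approx(base / 2)

    @pytest.mark.parametrize("bad", [(0, 70, 1), (1, -3, 1), (1, 70, 0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            space_constant_100(*bad)


class TestCompartmentalize:
    def segment_count(self, length, diameter=1.0, d_lambda=0.1):
        nodes = [MorphNode(1, 1, 0, 0, 0, 5, -1)]
        n_nodes = max(int(length // 10), 1)
        for k in range(n_nodes):
            nodes.append(
                MorphNode(k + 2, 4, (k + 1) * length / n_nodes, 0, 0,
                          diameter / 2, k + 1))
        grid = compartmentalize(MorphTree(nodes), d_lambda=d_lambda)
        return len(grid) - 1  # exclude the soma segment

    def test_d_lambda_counts(self):
        # lambda_100(d=1, ra=70) = 337 um: L=100 -> smallest odd n with 100/n < 33.7
        assert self.segment_count(100.0) == 3
        assert self.segment_count(10.0) == 1

    def test_halving_d_lambda_never_decreases_counts(self, small_tree):
        coarse = compartmentalize(small_tree, d_lambda=0.1)
        fine = compartmentalize(small_tree, d_lambda=0.05)
        c1 = {sid: len(coarse.section_segments(sid)) for sid in coarse._by_section}
        c2 = {sid: len(fine.section_segments(sid)) for sid in fine._by_section}
        assert all(c2[sid] >= c1[sid] for sid in c1)

    def test_odd_counts_and_positive_areas(self, small_tree):
        grid = compartmentalize(small_tree)
        for sid, idx in grid._by_section.items():
            if grid.segments[idx[0]].type_code != 1:
                assert len(idx) % 2 == 1
        assert all(s.area > 0 for s in grid.segments)

    def test_segment_areas_sum_to_section_frustum(self, small_tree):
        """Per section, segment areas must rebuild the whole frustum area."""
        grid = compartmentalize(small_tree)
        tree = small_tree
        for sec in tree.sections():
            if sec.type_code == 1:
                continue
            chain = [sec.anchor_id] + sec.node_ids
            area = 0.0
            for a, b in zip(chain[:-1], chain[1:]):
                na, nb = tree.node(a), tree.node(b)
                L = float(np.linalg.norm(na.position - nb.position))
                slant = math.sqrt(L**2 + (na.radius - nb.radius) ** 2)
                area += math.pi * (na.radius + nb.radius) * slant
            got = sum(grid.segments[i].area for i in grid.section_segments(sec.section_id))
            assert got == pytest.approx(area, rel=1e-6)

    def test_locate_prefers_trunk(self, passive_small):
        seg = passive_small.grid.segments[passive_small.grid.locate(150.0)]
        assert seg.is_trunk
        assert abs(seg.radial_distance - 150.0) < 30.0
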