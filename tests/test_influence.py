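"""Influence fields of a localized HCN cluster."""

import numpy as np
import pandas as pd
import pytest

import dendromaps as dm
from dendromaps.exceptions import ConfigurationError
from dendromaps.influence import (
    ChannelCluster,
    InfluenceField,
    arbor_influence_map,
    default_cluster,
    influence_field,
    insert_cluster,
)

from conftest import FAST_CHIRP


def trunk_sites(model, n=8):
    trunk = model.grid.trunk_indices()
    stride = max(len(trunk) // n, 1)
    return trunk[::stride]


class TestInsertCluster:
    def test_zero_conductance_identity(self, passive_small):
        out = insert_cluster(passive_small, ChannelCluster(200.0, 0.0))
        assert np.array_equal(out.system.g_h, passive_small.system.g_h)
        assert out is not passive_small

    def test_original_untouched_and_density_correct(self, passive_small):
        cluster = ChannelCluster(200.0, 10.0)  # 10 nS
        out = insert_cluster(passive_small, cluster)
        assert np.all(passive_small.system.g_h == 0)
        seg = out.grid.locate(200.0, kind="path")
        area = out.grid.segments[seg].area
        assert out.mech.gh[seg] == pytest.approx(10.0 / area * 1e5)

    def test_insertions_additive(self, passive_small):
        c = ChannelCluster(200.0, 5.0)
        once = insert_cluster(passive_small, c)
        twice = insert_cluster(once, c)
        seg = passive_small.grid.locate(200.0, kind="path")
        assert twice.mech.gh[seg] == pytest.approx(2 * once.mech.gh[seg])

    def test_area_normalization(self, passive_small):
        """Same total conductance on segments of different area yields
        inversely proportional density increments."""
        grid = passive_small.grid
        trunk = grid.trunk_indices()[1:]
        a, b = trunk[1], trunk[-2]
        out_a = insert_cluster(passive_small,
                               ChannelCluster(grid.segments[a].path_distance, 7.0))
        out_b = insert_cluster(passive_small,
                               ChannelCluster(grid.segments[b].path_distance, 7.0))
        da = out_a.mech.gh[a] - passive_small.mech.gh[a]
        db = out_b.mech.gh[b] - passive_small.mech.gh[b]
        assert da * grid.segments[a].area == pytest.approx(db * grid.segments[b].area,
                                                           rel=1e-9)

    def test_location_beyond_trunk_rejected(self, passive_small):
        with pytest.raises(ConfigurationError):
            insert_cluster(passive_small, ChannelCluster(5000.0, 5.0))


class TestInfluenceField:
    def test_rin_field_peaks_at_cluster(self, passive_small):
        cluster = default_cluster(passive_small)
        fld = influence_field(passive_small, cluster, "rin",
                              sites=trunk_sites(passive_small))
        t = fld.table
        assert not fld.degenerate
        assert t.lam.between(0.0, 1.0).all()
        # brute-force scan: the maximum sits at the site nearest the cluster
        peak_x = t.loc[t.influence.idxmax(), "x_um"]
        site_x = [passive_small.grid.segments[s].path_distance
                  for s in trunk_sites(passive_small)]
        nearest = min(site_x, key=lambda x: abs(x - cluster.location_um))
        assert peak_x == pytest.approx(nearest)
        # influence reaches the soma
        assert t.loc[t.x_um.idxmin(), "influence"] > 0

    def test_zero_cluster_degenerate(self, passive_small):
        fld = influence_field(passive_small, ChannelCluster(200.0, 0.0), "rin",
                              sites=trunk_sites(passive_small))
        assert fld.degenerate
        assert (fld.table.lam == 0).all()

    def test_gradient_background_reference_matches_measurement(self, gradient_small):
        """M_org on the gradient background must equal the standalone R_in
        measurement (no interaction with the perturbation machinery)."""
        sites = trunk_sites(gradient_small, 4)
        fld = influence_field(gradient_small, default_cluster(gradient_small),
                              "rin", sites=sites)
        from dendromaps.measurements import REDUCED_AMPLITUDES, measure_rin
        for _, row in fld.table.iterrows():
            direct = measure_rin(gradient_small, int(row.site),
                                 amplitudes=REDUCED_AMPLITUDES)
            assert row.m_org == pytest.approx(direct, rel=1e-12)


class TestAuc:
    def make_field(self, x, lam, influence):
        t = pd.DataFrame(dict(site=range(len(x)), x_um=x, m_org=1.0, m_new=1.0,
                              influence=influence, lam=lam))
        return InfluenceField(t, "rin", "passive", ChannelCluster(1.0, 1.0))

    def test_rectangle(self):
        x = np.linspace(0, 450, 10)
        a_norm, _ = self.make_field(x, np.ones(10), np.ones(10)).auc()
        assert a_norm == pytest.approx(450.0)

    def test_triangle(self):
        x = np.linspace(0, 450, 91)
        lam = 1.0 - np.abs(x - 225.0) / 225.0
        a_norm, _ = self.make_field(x, lam, lam).auc()
        assert a_norm == pytest.approx(225.0, rel=1e-3)

    def test_matches_fine_grid_oracle(self):
        x = np.linspace(0, 450, 25)
        lam = np.exp(-((x - 300.0) / 120.0) ** 2)
        a_norm, _ = self.make_field(x, lam, lam).auc()
        xf = np.linspace(0, 450, 5001)
        fine = np.trapezoid(np.interp(xf, x, lam), xf)
        assert a_norm == pytest.approx(fine, rel=0.01)


class TestArborMap:
    def test_trunk_restriction_consistent(self, passive_small):
        cluster = default_cluster(passive_small)
        sites = trunk_sites(passive_small, 4)
        fld = influence_field(passive_small, cluster, "rin", sites=sites)
        amap = arbor_influence_map(passive_small, cluster, "rin", sites=sites)
        merged = fld.table.merge(amap, on="site", suffixes=("_f", "_a"))
        assert np.allclose(merged.influence_f, merged.influence_a, rtol=1e-9)

    def test_obliques_carry_influence(self, passive_small):
        """Off-trunk segments feel a trunk cluster in a compact tree."""
        cluster = default_cluster(passive_small)
        grid = passive_small.grid
        oblique_sites = [s.index for s in grid.segments
                         if s.type_code == 4 and not s.is_trunk][:4]
        amap = arbor_influence_map(passive_small, cluster, "rin",
                                   sites=oblique_sites)
        assert (amap.influence > 0).all()
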