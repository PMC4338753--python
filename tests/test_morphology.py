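import math

import numpy as np
import pytest

from purkinje import morphology as M


class TestAxon:
    def test_section_inventory(self):
        ax = M.build_axon()
        by_tag = {}
        for s in ax:
            by_tag.setdefault(s.tag, []).append(s)
        ais = by_tag[M.RegionTag.AIS]
        assert len(ais) == 1
        assert ais[0].length == 17.0 and ais[0].diameter == 0.97
        assert len(by_tag[M.RegionTag.PARA_AIS]) == 1
        assert len(by_tag[M.RegionTag.MYELIN]) == 4
        assert len(by_tag[M.RegionTag.NODE]) == 3
        assert len(by_tag[M.RegionTag.COLLATERAL]) == 2
        for s in by_tag[M.RegionTag.MYELIN]:
            assert s.length == 100.0 and s.diameter == 0.73
        for s in by_tag[M.RegionTag.NODE]:
            assert s.length == 4.0 and s.diameter == 0.73
        for s in by_tag[M.RegionTag.COLLATERAL]:
            assert s.length == 100.0 and s.diameter == 0.6

    def test_ais_lateral_area(self):
        ax = M.build_axon()
        ais = [s for s in ax if s.tag is M.RegionTag.AIS][0]
        assert ais.lateral_area == pytest.approx(math.pi * 0.97 * 17, rel=1e-12)
        assert ais.lateral_area == pytest.approx(51.81, abs=0.05)

    def test_collateral_attaches_at_second_node(self):
        ax = M.build_axon(start_id=1, parent_id=0)
        nodes = [s for s in ax if s.tag is M.RegionTag.NODE]
        coll = [s for s in ax if s.tag is M.RegionTag.COLLATERAL]
        first = [c for c in coll if c.parent_id == nodes[1].id]
        assert len(first) == 1
        assert coll[1].parent_id == first[0].id

    def test_deterministic(self):
        a = M.build_axon()
        b = M.build_axon()
        assert [(s.id, s.parent_id, s.tag, s.diameter, s.length) for s in a] \
            == [(s.id, s.parent_id, s.tag, s.diameter, s.length) for s in b]

    def test_path_length_ais_to_third_node(self):
        m = M.build_cell(n_dend=3, seed=0)
        ais = m.with_tag(M.RegionTag.AIS)[0]
        node3 = m.with_tag(M.RegionTag.NODE)[2]
        # 8.5 + 4 + 100 + 4 + 100 + 4 + 100 + 2 midpoint-to-midpoint
        assert m.path_length(ais.id, node3.id) == pytest.approx(322.5)


class TestSurrogateDendrites:
    def test_full_scale_counts_and_ranges(self):
        dend = M.generate_surrogate_dendrites(70000.0, 1599, seed=1)
        assert len(dend) == 1599
        d = np.array([s.diameter for s in dend])
        L = np.array([s.length for s in dend])
        assert d.min() >= M.DEND_DIAM_MIN and d.max() <= M.DEND_DIAM_MAX
        assert L.min() >= M.DEND_LEN_MIN

    def test_total_area_reduced_tree(self):
        m = M.build_cell(n_dend=48, seed=1)
        assert m.total_area() == pytest.approx(70000.0, rel=0.02)

    def test_total_area_full_tree(self):
        m = M.build_cell(n_dend=1599, seed=1)
        assert m.total_area() == pytest.approx(70000.0, rel=0.02)

    def test_determinism(self):
        m1 = M.build_cell(n_dend=48, seed=3)
        m2 = M.build_cell(n_dend=48, seed=3)
        assert m1.to_json() == m2.to_json()
        m3 = M.build_cell(n_dend=48, seed=4)
        assert m1.to_json() != m3.to_json()

    def test_three_orders_and_taper(self):
        m = M.build_cell(n_dend=200, seed=2)
        for tag in M.DENDRITE_TAGS:
            assert len(m.with_tag(tag)) > 0
        by_id = {s.id: s for s in m.sections}
        for s in m.sections:
            if s.tag in M.DENDRITE_TAGS:
                par = by_id[s.parent_id]
                if par.tag in M.DENDRITE_TAGS:
                    assert s.diameter <= par.diameter + 1e-9
                else:  # trunk attaches to soma
                    assert s.tag is M.RegionTag.TRUNK

    def test_tag_thresholds(self):
        m = M.build_cell(n_dend=300, seed=5)
        for s in m.with_tag(M.RegionTag.PRINCIPAL):
            assert s.diameter >= M.TERMINAL_DIAM_MAX
        for s in m.with_tag(M.RegionTag.TERMINAL):
            assert s.diameter < M.TERMINAL_DIAM_MAX

    def test_infeasible_target_raises(self):
        with pytest.raises(M.InfeasibleTargetError):
            # far below what 20 sections at minimum calibre can shed
            M.generate_surrogate_dendrites(M.soma_axon_area() + 10.0, 20, 1)
        with pytest.raises(M.InfeasibleTargetError):
            M.generate_surrogate_dendrites(70000.0, 48, 1, strict_ranges=True)

    def test_strict_ranges_full_scale(self):
        dend = M.generate_surrogate_dendrites(70000.0, 1599, 2,
                                              strict_ranges=True)
        L = np.array([s.length for s in dend])
        assert L.max() <= M.DEND_LEN_MAX + 1e-9
        area = sum(s.lateral_area for s in dend) + M.soma_axon_area()
        assert area == pytest.approx(70000.0, rel=0.02)


class TestArea:
    def test_unit_cylinder(self):
        s = M.SectionGeometry(0, M.ROOT, M.RegionTag.TERMINAL, 1.0, 1.0)
        assert M.Morphology([s]).total_area() == pytest.approx(math.pi)

    def test_axon_area_hand_sum(self):
        ax = M.build_axon()
        expect = math.pi * (0.97 * 17 + 0.97 * 4 + 4 * 0.73 * 100
                            + 3 * 0.73 * 4 + 2 * 0.6 * 100)
        assert sum(s.lateral_area for s in ax) == pytest.approx(expect)

    def test_additivity(self):
        m = M.build_cell(n_dend=24, seed=1)
        leaf = [s for s in m.sections
                if not m.children_of(s.id) and s.tag in M.DENDRITE_TAGS][0]
        rest = [s for s in m.sections if s.id != leaf.id]
        m2 = M.Morphology(rest)
        assert m.total_area() - m2.total_area() \
            == pytest.approx(leaf.lateral_area)


class TestValidation:
    def test_cycle_detected(self):
        a = M.SectionGeometry(0, 1, M.RegionTag.SOMA, 1, 1)
        b = M.SectionGeometry(1, 0, M.RegionTag.AIS, 1, 1)
        c = M.SectionGeometry(2, M.ROOT, M.RegionTag.NODE, 1, 1)
        with pytest.raises(M.MorphologyError):
            M.Morphology([a, b, c])

    def test_self_parent_rejected(self):
        a = M.SectionGeometry(0, M.ROOT, M.RegionTag.SOMA, 1, 1)
        b = M.SectionGeometry(1, 1, M.RegionTag.AIS, 1, 1)
        with pytest.raises(M.MorphologyError):
            M.Morphology([a, b])

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(M.MorphologyError):
            M.SectionGeometry(0, M.ROOT, M.RegionTag.SOMA, 0.0, 1.0)


class TestSWC:
    def test_round_trip(self, tmp_path):
        m = M.build_cell(n_dend=48, seed=1)
        path = tmp_path / "cell.swc"
        M.write_swc(m, path)
        m2 = M.read_swc(path)
        assert len(m2) == len(m)
        for a, b in zip(m.sections, m2.sections):
            assert a.id == b.id and a.parent_id == b.parent_id
            assert a.tag == b.tag
            assert abs(a.diameter - b.diameter) < 1e-6
            assert abs(a.length - b.length) < 1e-6

    def test_cyclic_parentage_error(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 2\n2 1 10 0 0 5 1\n")
        with pytest.raises(M.SWCError):
            M.read_swc(path)

    def test_self_parent_error(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 1\n")
        with pytest.raises(M.SWCError):
            M.read_swc(path)

    def test_malformed_record_error(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5\n")
        with pytest.raises(M.SWCError):
            M.read_swc(path)

    def test_toy_three_point_merge(self, tmp_path):
        # unbranched chain of equal radii collapses to one cylinder with
        # diameter = 2 * radius
        path = tmp_path / "toy.swc"
        path.write_text("1 3 0 0 0 0.5 -1\n"
                        "2 3 5 0 0 0.5 1\n"
                        "3 3 10 0 0 0.5 2\n")
        m = M.read_swc(path, merge_unbranched=True)
        dend = [s for s in m.sections if s.parent_id != M.ROOT]
        assert len(dend) == 1
        assert dend[0].diameter == pytest.approx(1.0)
        assert dend[0].length == pytest.approx(10.0)


class TestDiscretization:
    def test_lambda_rule(self, passive_defaults):
        m = M.build_cell(n_dend=48, seed=1, passive=passive_defaults)
        for s in m.sections:
            if s.tag is M.RegionTag.MYELIN:
                assert s.n_compartments == 1
            else:
                lam = M.lambda_f(s.diameter, passive_defaults.ra,
                                 passive_defaults.cm_of(s.tag))
                assert s.length / s.n_compartments <= 0.1 * lam + 1e-9
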