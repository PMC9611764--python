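import json
import math

import numpy as np
import pytest

from ffr0d.ffr_analysis import compare_with_without
from ffr0d.synthetic_data import (
    IdealizedFixtureSpec,
    SchemaError,
    SyntheticTreeConfig,
    make_idealized,
    make_patient_like,
    read_tree,
    tree_from_json,
    tree_to_json,
    write_tree,
)
from ffr0d.vessel_model import mmhg_to_pa


class TestIdealizedFixtures:
    def test_reference_dimensions(self, model1, model2, model3):
        for tree in (model1, model2, model3):
            assert tree.main_vessel.start == 0.0
            assert tree.main_vessel.end == 75e-3
            assert np.all(tree.main_vessel.diameter_samples == 3e-3)
            (sten,) = tree.stenoses
            assert sten.length_L == 10e-3
            assert sten.area_ratio == 0.2
            assert tree.inlet_pressure_P_in == mmhg_to_pa(90.0)
        assert model1.side_branches == []
        for tree, offset in ((model2, -25e-3), (model3, 25e-3)):
            (br,) = tree.side_branches
            assert br.diameter == 2.5e-3
            assert br.angle == 75.0
            assert br.attach_position == pytest.approx(37.5e-3 + offset, abs=1e-15)

    def test_minimum_lumen_diameter(self, model1):
        (sten,) = model1.stenoses
        prof = model1.stenosed_profile()
        d_min = prof.diameter_at(sten.center_position)
        assert d_min == pytest.approx(3e-3 * math.sqrt(0.2), rel=1e-12)
        assert d_min == pytest.approx(1.342e-3, rel=1e-3)

    def test_branch_variants_differ_only_in_position(self, model2, model3):
        b2, b3 = model2.side_branches[0], model3.side_branches[0]
        assert b2.diameter == b3.diameter
        assert b2.outlet == b3.outlet
        assert b2.attach_position != b3.attach_position
        assert model2.main_outlet == model3.main_outlet
        assert model2.stenoses == model3.stenoses

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            IdealizedFixtureSpec(variant="model4")


class TestPatientLike:
    def test_same_seed_byte_identical(self):
        cfg = SyntheticTreeConfig(seed=11, layout="patient2_like")
        assert tree_to_json(make_patient_like(cfg)) == tree_to_json(make_patient_like(cfg))

    def test_different_seeds_differ(self):
        a = tree_to_json(make_patient_like(SyntheticTreeConfig(seed=1)))
        b = tree_to_json(make_patient_like(SyntheticTreeConfig(seed=2)))
        assert a != b

    def test_frame_spacing_is_oct_pullback_spacing(self):
        tree = make_patient_like(SyntheticTreeConfig(seed=5))
        spacing = np.diff(tree.main_vessel.arc_length_samples)
        assert np.allclose(spacing, 0.2e-3, rtol=0.0, atol=1e-15)

    def test_zero_noise_gives_smooth_taper(self):
        cfg = SyntheticTreeConfig(seed=3, area_noise_sd=0.0)
        tree = make_patient_like(cfg)
        d = tree.main_vessel.diameter_samples
        assert np.allclose(np.diff(d, 2), 0.0, atol=1e-12)  # linear taper
        assert d[0] == pytest.approx(cfg.main_diameter_proximal, rel=1e-12)
        assert d[-1] == pytest.approx(cfg.main_diameter_distal, rel=1e-12)

    def test_layouts_place_stenosis_relative_to_branches(self):
        p1 = make_patient_like(SyntheticTreeConfig(seed=9, layout="patient1_like"))
        sten = p1.stenoses[0]
        upstream = [b for b in p1.side_branches if b.attach_position < sten.start]
        assert len(upstream) == len(p1.side_branches) - 1  # one small distal branch
        p2 = make_patient_like(SyntheticTreeConfig(seed=9, layout="patient2_like"))
        sten2 = p2.stenoses[0]
        assert all(b.attach_position > sten2.end for b in p2.side_branches)

    def test_no_sub_half_millimetre_branches(self):
        for seed in range(5):
            tree = make_patient_like(SyntheticTreeConfig(seed=seed))
            assert all(b.diameter >= 0.5e-3 for b in tree.side_branches)

    def test_downstream_layout_has_larger_branch_effect(self):
        """At matched lesion severity, a stenosis proximal to the branches
        loses more FFR to side-branch flow than one distal to them."""
        kw = dict(seed=7, severity_range=(0.3, 0.3))
        c1 = compare_with_without(
            make_patient_like(SyntheticTreeConfig(layout="patient1_like", **kw))
        )
        c2 = compare_with_without(
            make_patient_like(SyntheticTreeConfig(layout="patient2_like", **kw))
        )
        assert c2.delta_ffr > c1.delta_ffr

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTreeConfig(seed=0, branch_diameter_range=(0.3e-3, 1e-3))
        with pytest.raises(ValueError):
            SyntheticTreeConfig(seed=0, layout="patient3_like")


class TestJsonRoundTrip:
    @pytest.mark.parametrize("variant", ["model1_no_branch", "model3_downstream"])
    def test_idealized_round_trip_exact(self, tmp_path, variant):
        tree = make_idealized(IdealizedFixtureSpec(variant=variant))
        path = tmp_path / "tree.json"
        write_tree(tree, path)
        assert read_tree(path) == tree

    def test_patient_round_trip_exact(self, tmp_path):
        tree = make_patient_like(SyntheticTreeConfig(seed=13, layout="patient2_like"))
        path = tmp_path / "tree.json"
        write_tree(tree, path)
        back = read_tree(path)
        assert back == tree
        # serialization is idempotent byte-for-byte
        assert tree_to_json(back) == path.read_text()

    def test_missing_main_outlet_rejected(self, model1):
        doc = json.loads(tree_to_json(model1))
        del doc["main_outlet"]
        with pytest.raises(SchemaError, match="main_outlet"):
            tree_from_json(json.dumps(doc))

    def test_unknown_schema_version_rejected(self, model1):
        doc = json.loads(tree_to_json(model1))
        doc["schema"] = "vessel-tree/99"
        with pytest.raises(SchemaError, match="unsupported schema version"):
            tree_from_json(json.dumps(doc))

    def test_invalid_geometry_rejected(self, model1):
        doc = json.loads(tree_to_json(model1))
        doc["stenoses"][0]["area_ratio"] = 1.5
        with pytest.raises(SchemaError):
            tree_from_json(json.dumps(doc))
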