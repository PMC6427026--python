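"""Helical symmetry: pitch arithmetic, stacking, estimation, contacts."""

import math

import numpy as np
import pytest

import fibrilmetrics as fm
from fibrilmetrics.exceptions import InputError, ParameterError


class TestPitch:
    def test_deposited_symmetry_gives_300nm_pitch(self):
        pitch, crossover, hand = fm.pitch_and_crossover(
            fm.HelicalSymmetry(4.8, -0.58))
        assert pitch == pytest.approx(2979.31, abs=0.01)
        assert crossover == pytest.approx(pitch / 2)
        assert hand == "left"

    def test_full_turn_per_subunit(self):
        pitch, _, hand = fm.pitch_and_crossover(fm.HelicalSymmetry(4.8, 360.0))
        assert pitch == pytest.approx(4.8)
        assert hand == "right"

    def test_one_degree_twist(self):
        pitch, _, _ = fm.pitch_and_crossover(fm.HelicalSymmetry(4.8, -1.0))
        assert pitch == pytest.approx(1728.0)

    def test_pure_translation_has_infinite_pitch(self):
        pitch, _, hand = fm.pitch_and_crossover(fm.HelicalSymmetry(4.8, 0.0))
        assert math.isinf(pitch) and hand == "none"

    def test_identity_pitch_times_twist_equals_rise(self):
        for rise, twist in [(2.0, 0.3), (4.8, -0.58), (10.0, 5.0)]:
            pitch, _, _ = fm.pitch_and_crossover(fm.HelicalSymmetry(rise, twist))
            assert pitch * abs(twist) / 360.0 == pytest.approx(rise, rel=1e-12)

    def test_invalid_symmetry_rejected(self):
        with pytest.raises(ParameterError):
            fm.HelicalSymmetry(-1.0, 0.58)
        with pytest.raises(ParameterError):
            fm.HelicalSymmetry(4.8, 400.0)


class TestBuildStack:
    def test_screw_operation_maps_layer_onto_next(self, arch_layer, stack5):
        # applying the screw to layer k reproduces layer k+1 exactly
        from fibrilmetrics.helical import _screw_matrix
        sym = fm.HelicalSymmetry(4.8, -0.58)
        rot, t = _screw_matrix(sym, 1)
        for a, b in zip(stack5.chains[:-1], stack5.chains[1:]):
            xa = stack5.select_chain(a).coords() @ rot.T + t
            xb = stack5.select_chain(b).coords()
            assert np.abs(xa - xb).max() < 1e-9

    def test_rigid_transform_preserves_distances(self, arch_layer, stack5):
        d0 = np.linalg.norm(np.diff(arch_layer.coords(), axis=0), axis=1)
        top = stack5.select_chain(stack5.chains[-1])
        d4 = np.linalg.norm(np.diff(top.coords(), axis=0), axis=1)
        np.testing.assert_allclose(d4, d0, rtol=1e-9)

    def test_zero_twist_is_pure_translation(self, arch_layer):
        stack = fm.build_stack(arch_layer, fm.HelicalSymmetry(4.8, 0.0), 3)
        a = stack.select_chain("A").coords()
        b = stack.select_chain("B").coords()
        np.testing.assert_allclose(b - a, np.tile([0.0, 0.0, 4.8], (len(a), 1)),
                                   atol=1e-12)

    def test_five_layer_stack_shape(self, stack5, arch_layer):
        assert len(stack5.chains) == 5
        assert stack5.n_atoms == 5 * arch_layer.n_atoms

    def test_atom_count_cap(self, arch_layer):
        with pytest.raises(ParameterError):
            fm.build_stack(arch_layer, fm.HelicalSymmetry(4.8, -0.58),
                           10**8 // arch_layer.n_atoms)


class TestEstimateSymmetry:
    @pytest.mark.parametrize("rise", [2.0, 4.8, 10.0])
    @pytest.mark.parametrize("twist", [0.3, -0.3, 0.58, -0.58, 5.0, -5.0])
    def test_round_trip_identity(self, arch_layer, rise, twist):
        stack = fm.build_stack(arch_layer, fm.HelicalSymmetry(rise, twist), 4)
        est = fm.estimate_symmetry_from_model(stack)
        assert est.symmetry.rise == pytest.approx(rise, abs=1e-6)
        assert est.symmetry.twist == pytest.approx(twist, abs=1e-6)
        assert est.rmsd < 1e-9

    def test_single_chain_rejected(self, arch_layer):
        with pytest.raises(InputError):
            fm.estimate_symmetry_from_model(arch_layer)

    def test_unmatched_atom_sets_rejected(self, arch_layer, stack5):
        clipped = fm.AtomicModel(stack5.atoms.iloc[:-1],
                                 stack5.layer_of_chain)
        with pytest.raises(InputError):
            fm.estimate_symmetry_from_model(clipped)

    def test_align_to_axis_recovers_z_convention(self, arch_layer):
        stack = fm.build_stack(arch_layer, fm.HelicalSymmetry(4.8, -0.58), 4)
        rot = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        tilted = stack.transformed(rot, np.array([5.0, -3.0, 2.0]))
        aligned = fm.align_to_axis(tilted)
        est = fm.estimate_symmetry_from_model(aligned)
        np.testing.assert_allclose(est.axis, [0, 0, 1], atol=1e-8)
        assert est.symmetry.rise == pytest.approx(4.8, abs=1e-8)


class TestAxialSpanAndWidth:
    def test_flat_layer_has_zero_span(self, arch_layer):
        assert fm.axial_height_span(arch_layer, "A") == 0.0

    def test_span_is_ca_z_extent(self):
        z = np.linspace(-2.5, 2.5, 10)
        model = fm.AtomicModel.from_arrays(
            np.column_stack([np.arange(10) * 3.8, np.zeros(10), z]))
        assert fm.axial_height_span(model, "A") == pytest.approx(5.0)

    def test_missing_ca_rejected(self):
        model = fm.AtomicModel.from_arrays(np.zeros((3, 3)) + np.arange(3)[:, None],
                                           name="CB")
        with pytest.raises(InputError):
            fm.axial_height_span(model, "A")

    def test_ring_width_in_both_modes(self):
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        ring = fm.AtomicModel.from_arrays(np.column_stack(
            [50 * np.cos(theta), 50 * np.sin(theta), np.zeros(90)]))
        assert fm.measure_width(ring) == pytest.approx(100.0, abs=0.1)
        assert fm.measure_width(ring, mode="surface") == pytest.approx(
            100.0 + 2 * 1.70, abs=0.1)

    def test_single_atom_width_zero_in_center_mode(self):
        atom = fm.AtomicModel.from_arrays(np.array([[1.0, 2.0, 3.0]]))
        assert fm.measure_width(atom) == 0.0


class TestContacts:
    def test_aligned_layers_touch_at_generous_cutoff_only(self, arch_layer):
        stack = fm.build_stack(arch_layer, fm.HelicalSymmetry(4.8, 0.0), 2)
        wide = fm.interlayer_contacts(stack, cutoff=5.0)
        off1 = wide.at_offset(1)
        # every residue pairs with its vertical neighbour one layer up
        assert set(off1[off1.res_a == off1.res_b].res_a) == set(range(1, 13))
        tight = fm.interlayer_contacts(stack, cutoff=3.0)
        assert len(tight.at_offset(1)) == 0

    def test_offsets_canonicalised_nonnegative(self, stack5):
        cm = fm.interlayer_contacts(stack5, cutoff=5.0)
        assert (cm.entries["offset"] >= 0).all()

    def test_salt_bridge_detection(self):
        import pandas as pd
        rows = [("A", 25, "ARG", "NH1", "N", 0.0, 0.0, 0.0),
                ("B", 84, "GLU", "OE1", "O", 0.0, 0.0, 3.5),
                ("B", 86, "ASP", "OD1", "O", 0.0, 0.0, -4.4)]
        model = fm.AtomicModel(pd.DataFrame(rows, columns=[
            "chain", "res_seq", "res_name", "name", "element", "x", "y", "z"]),
            layer_of_chain={"A": 0, "B": 1})
        cm = fm.interlayer_contacts(model, cutoff=4.5)
        assert bool(cm.between(25, 84, 1)["salt_bridge"].iloc[0])
        assert not bool(cm.between(25, 86, 1)["salt_bridge"].iloc[0])

    def test_polar_stack_lacks_perpendicular_c2(self, stack5):
        from fibrilmetrics.helical import has_perpendicular_c2
        assert not has_perpendicular_c2(stack5)
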