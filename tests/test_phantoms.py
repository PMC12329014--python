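"""Phantom generators: geometry, concentration ranges, labels, determinism."""

import numpy as np
import pytest

from specmat.materials import MaterialComposition
from specmat.phantoms import (
    CYLINDER_DIAMETERS_CM,
    PILOT_DIAMETERS_CM,
    FeatureClass,
    Label,
    class_label_for_voxel,
    feature_class_map,
    generate_cylindrical_phantom,
    generate_pilot_water_phantom,
    generate_virtual_patient,
)


class TestCylindricalPhantom:
    def test_sixteen_inserts_four_split(self):
        vol = generate_cylindrical_phantom(20.0, seed=1, n=96, nz=1)
        inserts = vol.meta["inserts"]
        wholes = [i for i in inserts if i.half is None]
        halves = [i for i in inserts if i.half is not None]
        assert len(wholes) == 12
        assert len(halves) == 8  # 4 split inserts x 2 halves
        split_centers = {i.center_cm for i in halves}
        assert len(split_centers) == 4
        # split halves carry different material classes
        by_center = {}
        for h in halves:
            by_center.setdefault(h.center_cm, []).append(h.material_class)
        assert all(a != b for a, b in by_center.values())

    def test_everything_inside_disc(self):
        vol = generate_cylindrical_phantom(20.0, seed=2, n=96, nz=1)
        yy, xx = vol.grid_cm()
        outside = np.hypot(yy, xx) > 10.0
        assert (vol.labels[0][outside] == Label.AIR).all()
        for arr in vol.concentrations.values():
            assert (arr[0][outside] == 0).all()

    def test_deterministic_per_seed(self):
        a = generate_cylindrical_phantom(28.0, seed=7, n=64, nz=1)
        b = generate_cylindrical_phantom(28.0, seed=7, n=64, nz=1)
        assert (a.labels == b.labels).all()
        for mat in a.concentrations:
            assert (a.concentrations[mat] == b.concentrations[mat]).all()
        c = generate_cylindrical_phantom(28.0, seed=8, n=64, nz=1)
        assert (a.labels != c.labels).any()

    def test_concentration_ranges_over_seeds(self):
        limits = {"iodine": 7.5, "gadolinium": 5.0, "calcium": 300.0}
        for seed in range(40):
            vol = generate_cylindrical_phantom(20.0, seed=seed, n=64, nz=1)
            for mat, hi in limits.items():
                arr = vol.concentrations[mat]
                assert arr.min() >= 0.0
                assert arr.max() <= hi + 1e-6

    def test_insert_radii_in_range(self):
        for seed in range(10):
            vol = generate_cylindrical_phantom(36.0, seed=seed, n=64, nz=1)
            radii = [i.radius_cm for i in vol.meta["inserts"]]
            assert all(0.75 <= r <= 1.5 for r in radii)

    def test_noncanonical_diameter_flagged(self):
        assert generate_cylindrical_phantom(30.0, seed=0, n=64, nz=1).meta[
            "canonical"
        ] is False
        assert generate_cylindrical_phantom(20.0, seed=0, n=64, nz=1).meta[
            "canonical"
        ] is True

    def test_voxelization_converges(self):
        """Halving the voxel size changes insert area fractions by < 2%."""
        coarse = generate_cylindrical_phantom(20.0, seed=3, n=192, nz=1)
        fine = generate_cylindrical_phantom(20.0, seed=3, n=384, nz=1)
        for vol_pair in (("iodine"), ("gadolinium")):
            a = (coarse.concentrations[vol_pair][0] > 0).mean()
            b = (fine.concentrations[vol_pair][0] > 0).mean()
            if b > 0:
                assert abs(a - b) / b < 0.02


class TestPilotPhantom:
    def test_two_label_classes_no_contrast(self):
        vol = generate_pilot_water_phantom(30.0, n=64, nz=1)
        assert set(np.unique(vol.labels)) == {Label.AIR, Label.WATER}
        for arr in vol.concentrations.values():
            assert (arr == 0).all()

    def test_canonical_pilot_sizes(self):
        assert PILOT_DIAMETERS_CM == (20.0, 25.0, 30.0, 35.0, 40.0)
        assert CYLINDER_DIAMETERS_CM == (20.0, 28.0, 36.0, 42.0)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            generate_pilot_water_phantom(-5.0)


@pytest.fixture(scope="module")
def vp():
    return generate_virtual_patient("medium", seed=4, n=128, nz=5)


class TestVirtualPatient:

    def test_aorta_iodine_in_range(self, vp):
        assert 4.0 <= vp.meta["aorta_iodine"] <= 7.0
        aorta_vals = vp.concentrations["iodine"][vp.organs["aorta"]]
        assert (aorta_vals[aorta_vals > 0] >= 2.0).all()  # vessels 2-5, aorta 4-7
        assert vp.concentrations["iodine"].max() <= 7.0

    def test_gadolinium_only_in_collecting_systems(self, vp):
        gd = vp.concentrations["gadolinium"]
        assert gd.max() <= 3.5 and gd[gd > 0].min() >= 0.5
        assert ((gd > 0) <= vp.organs["collecting_system"]).all()

    def test_two_plaques(self, vp):
        assert vp.meta["n_plaques"] == 2
        ca = vp.concentrations["calcium"]
        assert (ca[ca > 0] >= 200.0).all() and ca.max() <= 400.0
        assert ((ca > 0) <= vp.organs["plaques"]).all()

    def test_body_size_in_group_range(self):
        for group, (lo, hi) in (
            ("small", (23.0, 25.7)),
            ("extra_large", (38.0, 43.3)),
        ):
            vol = generate_virtual_patient(group, seed=1, n=64, nz=1)
            assert lo <= vol.meta["diameter_cm"] <= hi

    def test_bone_present(self, vp):
        assert (vp.labels == Label.BONE).any()

    def test_invalid_size_group(self):
        with pytest.raises(ValueError):
            generate_virtual_patient("gigantic", seed=0)


class TestFeatureClasses:
    @pytest.mark.parametrize(
        "composition,expected",
        [
            (MaterialComposition("water"), FeatureClass.BACKGROUND),
            (MaterialComposition("cortical_bone"), FeatureClass.BACKGROUND),
            (MaterialComposition("water", {"calcium": 150.0}), FeatureClass.CALCIUM),
            (MaterialComposition("water", {"iodine": 3.0}), FeatureClass.CONTRAST),
            (
                MaterialComposition("water", {"iodine": 2.0, "gadolinium": 1.0}),
                FeatureClass.CONTRAST,
            ),
            (MaterialComposition("soft_tissue"), FeatureClass.TISSUE),
            (
                MaterialComposition("soft_tissue", {"iodine": 2.0}),
                FeatureClass.TISSUE,  # tissue dominates iodine/tissue mixtures
            ),
        ],
    )
    def test_voxel_rules(self, composition, expected):
        assert class_label_for_voxel(composition) == expected

    def test_spine_is_background_in_patient_map(self):
        vp = generate_virtual_patient("small", seed=2, n=96, nz=3)
        cls = feature_class_map(vp)
        assert (cls[vp.labels == Label.BONE] == FeatureClass.BACKGROUND).all()

    def test_map_consistent_with_labels(self):
        vol = generate_cylindrical_phantom(20.0, seed=9, n=96, nz=1)
        cls = feature_class_map(vol)
        # class-i voxels carry no contrast
        background = cls == FeatureClass.BACKGROUND
        for mat in ("iodine", "gadolinium", "calcium"):
            assert (vol.concentrations[mat][background] == 0).all()
        assert (cls[vol.labels == Label.SOFT_TISSUE] == FeatureClass.TISSUE).all()
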