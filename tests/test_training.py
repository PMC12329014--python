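"""Fold construction, two-phase training, and freezing contracts."""

import numpy as np
import pytest

from specmat.phantoms import FeatureClass
from specmat.training import (
    FoldSplit,
    TrainingConfig,
    build_patch_dataset,
    make_folds,
    train_concentration_network,
)


def canonical_phantom_ids():
    """12 phantoms x 3 dose tiers = 36 acquisitions."""
    return [f"cyl_{p}" for p in range(12) for _ in range(3)]


class TestFolds:
    def test_canonical_structure(self):
        folds = make_folds(canonical_phantom_ids(), k=12, seed=0)
        assert len(folds) == 12
        for f in folds:
            assert len(f.test) == 3
            assert len(f.validation) == 4
            assert len(f.train) == 29
            all_idx = set(f.test) | set(f.validation) | set(f.train)
            assert len(all_idx) == 36  # disjoint partitions

    def test_test_split_grouped_by_phantom(self):
        ids = canonical_phantom_ids()
        for f in make_folds(ids, k=12, seed=1):
            assert len({ids[i] for i in f.test}) == 1

    def test_every_phantom_tested_once(self):
        ids = canonical_phantom_ids()
        tested = set()
        for f in make_folds(ids, k=12, seed=2):
            tested.update(ids[i] for i in f.test)
        assert tested == set(ids)

    def test_seeded_reproducibility(self):
        a = make_folds(canonical_phantom_ids(), k=12, seed=3)
        b = make_folds(canonical_phantom_ids(), k=12, seed=3)
        assert a == b

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["p1"] * 3 + ["p2"] * 3, k=5, seed=0)


class TestPatchDataset:
    def test_material_patches_all_kept(self, cyl_pairs_tiny):
        full = build_patch_dataset(cyl_pairs_tiny, seed=0, background_keep=0.0)
        # with keep=0 every remaining patch holds at least one labeled voxel
        assert len(full) > 0
        assert all(c.any() for c in full.classes)

    def test_background_subsampling_seeded(self, cyl_pairs_tiny):
        a = build_patch_dataset(cyl_pairs_tiny, seed=1, background_keep=0.5)
        b = build_patch_dataset(cyl_pairs_tiny, seed=1, background_keep=0.5)
        assert len(a) == len(b)
        assert (a.x == b.x).all()

    def test_targets_consistent(self, cyl_pairs_tiny):
        data = build_patch_dataset(cyl_pairs_tiny, seed=0)
        assert data.mask.shape == data.classes.shape
        assert (data.mask == (data.classes != FeatureClass.BACKGROUND)).all()
        assert (data.tissue == (data.classes == FeatureClass.TISSUE)).all()
        assert (data.conc >= 0).all()


class TestTwoPhaseTraining:
    def test_feature_training_progress_and_checkpoint(self, trained_nets):
        hist = trained_nets["feature_history"]
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        # restored checkpoint = argmin of validation loss
        net, val = trained_nets["feature"], trained_nets["val"]
        from specmat.training import _eval_feature_loss

        restored = _eval_feature_loss(net, val, 8)
        assert restored == pytest.approx(hist["val_loss"].min(), rel=1e-5)

    def test_concentration_training_improves(self, trained_nets):
        hist = trained_nets["concentration_history"]
        assert hist["val_loss"].min() < hist["val_loss"].iloc[0] + 1e-9

    def test_feature_weights_frozen_bit_identical(self, trained_nets):
        """Phase-2 training must not touch a single feature-net byte."""
        fnet = trained_nets["feature"]
        before = fnet.weights_hash()
        cfg = TrainingConfig(
            learning_rate=1e-3, batch_size=8, max_epochs=1, patience=2, seed=9
        )
        train_concentration_network(
            fnet, trained_nets["train"], trained_nets["val"], cfg
        )
        assert fnet.weights_hash() == before

    def test_identical_seeds_identical_history(self, cyl_pairs_tiny):
        from specmat.training import train_feature_network

        data = build_patch_dataset(cyl_pairs_tiny[:2], seed=3, background_keep=0.3)
        cfg = TrainingConfig(
            learning_rate=1e-3, batch_size=8, max_epochs=2, patience=5, seed=11
        )
        _, h1 = train_feature_network(data, data, cfg)
        _, h2 = train_feature_network(data, data, cfg)
        assert (h1["train_loss"] == h2["train_loss"]).all()
        assert (h1["val_loss"] == h2["val_loss"]).all()


class TestPrediction:
    def test_predict_material_maps_contracts(self, cyl_pairs_tiny, trained_nets):
        from specmat.decompose import predict_material_maps

        acq, truth = cyl_pairs_tiny[0]
        maps = predict_material_maps(
            acq, trained_nets["feature"], trained_nets["concentration"]
        )
        nz, m, _ = acq.hu["low"].shape
        for mat in ("iodine", "gadolinium", "calcium"):
            assert maps.concentrations[mat].shape == (nz, m, m)
            assert (maps.concentrations[mat] >= 0).all()
        # class map consistent with stored probabilities
        assert (maps.class_map == maps.class_probabilities.argmax(axis=1)).all()
        # background voxels carry zero concentration
        bg = maps.class_map == FeatureClass.BACKGROUND
        for mat in maps.concentrations:
            assert (maps.concentrations[mat][bg] == 0).all()
        assert maps.meta["method"] == "dual_unet"

    def test_prediction_deterministic(self, cyl_pairs_tiny, trained_nets):
        from specmat.decompose import predict_material_maps

        acq, _ = cyl_pairs_tiny[1]
        a = predict_material_maps(
            acq, trained_nets["feature"], trained_nets["concentration"]
        )
        b = predict_material_maps(
            acq, trained_nets["feature"], trained_nets["concentration"]
        )
        assert (a.class_map == b.class_map).all()
        for mat in a.concentrations:
            assert (a.concentrations[mat] == b.concentrations[mat]).all()

    def test_rotation_consistency_on_symmetric_phantom(
        self, noiseless_water_acq, trained_nets
    ):
        """90-degree rotation of a symmetric input permutes the class map.

        The architecture is not exactly rotation-equivariant (transposed
        convolutions break it), so this is a smoke bound, not an identity.
        """
        from specmat.decompose import predict_material_maps
        from specmat.simulate import SpectralAcquisition

        acq = noiseless_water_acq
        rot = SpectralAcquisition(
            hu={k: np.rot90(v, axes=(1, 2)).copy() for k, v in acq.hu.items()},
            recon_fov_cm=acq.recon_fov_cm,
            slice_mm=acq.slice_mm,
            meta=dict(acq.meta),
        )
        maps = predict_material_maps(
            acq, trained_nets["feature"], trained_nets["concentration"]
        )
        maps_rot = predict_material_maps(
            rot, trained_nets["feature"], trained_nets["concentration"]
        )
        expected = np.rot90(maps.class_map, axes=(1, 2))
        agreement = (maps_rot.class_map == expected).mean()
        assert agreement > 0.9
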