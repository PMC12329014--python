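"""Shared fixtures: tiny-scale simulations reused across the suite.

Everything is generated programmatically at a reduced problem size (96-pixel
grids, 96 views, single slices) so the whole suite runs on one CPU in
minutes; the physics and contracts under test are scale-free.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from specmat.phantoms import MaterialVolume, generate_pilot_water_phantom
from specmat.simulate import Protocol, resample_ground_truth, simulate_acquisition
from specmat.workflows import Scale

TINY_N = 96
TINY_VIEWS = 96


def tiny_protocol(mAs=200.0, noise=False, seed=0, **kw):
    return Protocol(
        mAs=mAs,
        n_views=TINY_VIEWS,
        recon_matrix=TINY_N,
        noise=noise,
        seed=seed,
        **kw,
    )


TINY_SCALE = Scale("tiny", TINY_N, TINY_N, TINY_VIEWS, 1, 1, 1, 4, 8, 1e-3, 1)


def two_material_volume(
    iodine=3.2, gadolinium=2.5, n=TINY_N, diameter=20.0
) -> MaterialVolume:
    """Water cylinder with one iodine and one gadolinium insert."""
    vol = generate_pilot_water_phantom(diameter, n=n, nz=1)
    yy, xx = vol.grid_cm()
    vol.concentrations["iodine"][0][(yy**2 + (xx + 5) ** 2) <= 1.5**2] = iodine
    vol.concentrations["gadolinium"][0][(yy**2 + (xx - 5) ** 2) <= 1.5**2] = gadolinium
    vol.meta = {
        "kind": "two_material",
        "diameter_cm": diameter,
        "phantom_id": "two_mat",
    }
    return vol


def eroded_mask(mask3d: np.ndarray, iterations: int = 2) -> np.ndarray:
    return np.stack(
        [ndimage.binary_erosion(m, iterations=iterations) for m in mask3d]
    )


@pytest.fixture(scope="session")
def registry():
    from specmat.materials import default_registry

    return default_registry()


@pytest.fixture(scope="session")
def spectrum():
    from specmat.materials import make_spectrum

    return make_spectrum()


@pytest.fixture(scope="session")
def bins():
    from specmat.materials import EnergyBins

    return EnergyBins()


@pytest.fixture(scope="session")
def noiseless_two_mat():
    """Noiseless two-bin acquisition of the two-material cylinder + truth."""
    vol = two_material_volume()
    acq = simulate_acquisition(vol, tiny_protocol(noise=False))
    return acq, resample_ground_truth(vol, acq)


@pytest.fixture(scope="session")
def noiseless_water_acq():
    vol = generate_pilot_water_phantom(20.0, n=TINY_N, nz=1)
    return simulate_acquisition(vol, tiny_protocol(noise=False))


@pytest.fixture(scope="session")
def sensitivity_model():
    from specmat.workflows import calibrate_baseline

    return calibrate_baseline(TINY_SCALE)


@pytest.fixture(scope="session")
def pilot_and_model():
    """Canonical 5x5 pilot grid at tiny scale + fitted noise model."""
    from specmat.isonoise import fit_noise_model, run_pilot

    pilot = run_pilot(
        seed=3, n=TINY_N, nz=1, n_views=TINY_VIEWS, recon_matrix=TINY_N
    )
    return pilot, fit_noise_model(pilot)


@pytest.fixture(scope="session")
def cyl_pairs_tiny(pilot_and_model):
    """One cylinder per canonical size, one dose tier, with ground truth."""
    from specmat.isonoise import CYLINDER_CURRENTS_MAS
    from specmat.phantoms import generate_cylindrical_phantom

    _, model = pilot_and_model
    pairs = []
    rng = np.random.default_rng(17)
    for d, currents in CYLINDER_CURRENTS_MAS.items():
        vol = generate_cylindrical_phantom(d, seed=int(d), n=TINY_N, nz=1)
        acq = simulate_acquisition(
            vol,
            tiny_protocol(
                mAs=currents[1], noise=True, seed=int(rng.integers(2**31 - 1))
            ),
        )
        acq.meta.update({"isonoise_hu": model.predict(d, currents[1]),
                         "dose_tier": 1})
        pairs.append((acq, resample_ground_truth(vol, acq)))
    return pairs


@pytest.fixture(scope="session")
def trained_nets(cyl_pairs_tiny):
    """Feature + concentration nets briefly trained on the tiny cylinders."""
    from specmat.training import (
        TrainingConfig,
        build_patch_dataset,
        train_concentration_network,
        train_feature_network,
    )

    config = TrainingConfig(
        learning_rate=2e-3, batch_size=8, max_epochs=10, patience=10, seed=5
    )
    data = build_patch_dataset(cyl_pairs_tiny, seed=5, background_keep=0.5)
    rng = np.random.default_rng(5)
    idx = rng.permutation(len(data))
    n_val = max(2, len(data) // 6)
    from specmat.training import PatchDataset

    def sub(i):
        return PatchDataset(
            data.x[i], data.classes[i], data.conc[i], data.tissue[i], data.mask[i]
        )

    train, val = sub(idx[n_val:]), sub(idx[:n_val])
    fnet, fhist = train_feature_network(train, val, config)
    cnet, chist = train_concentration_network(fnet, train, val, config)
    return {
        "feature": fnet,
        "concentration": cnet,
        "feature_history": fhist,
        "concentration_history": chist,
        "train": train,
        "val": val,
        "config": config,
    }
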