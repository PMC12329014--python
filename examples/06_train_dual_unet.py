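"""Train the two-stage decomposition network on a small cylinder dataset.

Phase 1 trains the 4-class feature U-Net (per-voxel cross-entropy); phase 2
freezes it and trains the concentration U-Net on its 16 penultimate feature
channels.  Takes a few minutes at this reduced scale.
"""

import numpy as np

from specmat import (
    Protocol,
    TrainingConfig,
    build_patch_dataset,
    predict_material_maps,
    simulate_acquisition,
    train_concentration_network,
    train_feature_network,
)
from specmat.evaluation import classification_metrics, regression_metrics, roi_statistics
from specmat.phantoms import feature_class_map, generate_cylindrical_phantom
from specmat.simulate import resample_ground_truth
from specmat.training import PatchDataset

# six training cylinders + one held-out, one noisy acquisition each
pairs = []
for i, d in enumerate((20.0, 20.0, 28.0, 28.0, 36.0, 42.0, 36.0)):
    vol = generate_cylindrical_phantom(d, seed=60 + i, n=128, nz=1)
    acq = simulate_acquisition(
        vol, Protocol(mAs=150.0, n_views=160, recon_matrix=128, seed=i)
    )
    pairs.append((acq, resample_ground_truth(vol, acq)))
train_pairs, test_pair = pairs[:-1], pairs[-1]

data = build_patch_dataset(train_pairs, seed=0, background_keep=0.3)
split = int(0.85 * len(data))
sub = lambda sl: PatchDataset(*(getattr(data, f)[sl] for f in
                                ("x", "classes", "conc", "tissue", "mask")))
config = TrainingConfig(learning_rate=1e-3, batch_size=16, max_epochs=6,
                        patience=6, seed=0)

fnet, fhist = train_feature_network(sub(slice(0, split)), sub(slice(split, None)),
                                    config)
print("feature network validation cross-entropy per epoch:")
print(fhist[["epoch", "train_loss", "val_loss"]].round(3).to_string(index=False))

cnet, chist = train_concentration_network(
    fnet, sub(slice(0, split)), sub(slice(split, None)), config
)
print(f"\nconcentration network: val loss {chist['val_loss'].iloc[0]:.3f} -> "
      f"{chist['val_loss'].min():.3f}")

acq, truth = test_pair
maps = predict_material_maps(acq, fnet, cnet)
cm = classification_metrics(feature_class_map(truth), maps.class_map)
print("\nheld-out phantom, voxel classification:")
print(cm.round(3).to_string(index=False))
rows = roi_statistics(maps.concentrations, truth)
print("\nheld-out phantom, ROI quantification:")
print(regression_metrics(rows).round(2).to_string(index=False))
# At this toy scale the network sees minutes of training; the full protocol
# (512 grids, 100 epochs, 12-fold cross-validation) uses the same code path.
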