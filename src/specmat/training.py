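"""Two-phase training, cross-validation folds, and the hybrid experiment.

Phase 1 trains the feature (classification) U-Net with per-voxel
cross-entropy; phase 2 freezes it and trains the concentration U-Net on its
16 penultimate feature channels.  The canonical cylindrical dataset is 12
phantoms x 3 isonoise dose tiers = 36 acquisitions, split 12-fold with one
whole phantom (its 3 dose tiers) held out per fold — acquisitions of one
phantom never straddle the test boundary.

The hybrid experiment retrains the networks on cylinders plus a growing
number of anthropomorphic virtual patients and tracks multilabel
classification metrics on a fixed held-out virtual-patient set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import classification_metrics
from .nn.layers import Adam, ReduceLROnPlateau
from .nn.unet import ConcentrationNetwork, FeatureNetwork
from .patches import PatchGrid, build_input_stack, extract_patches
from .phantoms import FeatureClass, MaterialVolume, feature_class_map
from .simulate import SpectralAcquisition

__all__ = [
    "TrainingConfig",
    "FoldSplit",
    "PatchDataset",
    "make_folds",
    "build_patch_dataset",
    "train_feature_network",
    "train_concentration_network",
    "hybrid_training_experiment",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (canonical defaults; scale down explicitly)."""

    patch_size: int = 64
    learning_rate: float = 1.0e-4
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    background_keep: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs", "patch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    test: tuple[int, ...]  # acquisition indices
    validation: tuple[int, ...]
    train: tuple[int, ...]


def make_folds(
    phantom_ids: list[str], k: int = 12, seed: int = 0, n_validation: int = 4
) -> list[FoldSplit]:
    """Seeded k-fold splits grouped by phantom.

    ``phantom_ids`` lists the owning phantom of each acquisition.  Each fold
    holds out every acquisition of one phantom as the test set, then draws
    ``n_validation`` validation acquisitions from the remainder.
    """
    ids = np.asarray(phantom_ids)
    phantoms = sorted(set(phantom_ids))
    if k > len(phantoms):
        raise ValueError(
            f"{k} folds requested but only {len(phantoms)} phantoms available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(phantoms))
    folds = []
    for f in range(k):
        test_phantom = phantoms[order[f]]
        test = np.flatnonzero(ids == test_phantom)
        rest = np.flatnonzero(ids != test_phantom)
        if len(rest) <= n_validation:
            raise ValueError("not enough acquisitions for the validation split")
        val = rng.choice(rest, size=n_validation, replace=False)
        train = np.setdiff1d(rest, val)
        folds.append(
            FoldSplit(
                fold=f,
                test=tuple(int(i) for i in test),
                validation=tuple(int(i) for i in sorted(val)),
                train=tuple(int(i) for i in train),
            )
        )
    return folds


@dataclass
class PatchDataset:
    """Training patches: inputs, class targets, and regression targets."""

    x: np.ndarray  # (N, 4, p, p)
    classes: np.ndarray  # (N, p, p) int
    conc: np.ndarray  # (N, 3, p, p) mg/mL
    tissue: np.ndarray  # (N, p, p) {0,1}
    mask: np.ndarray  # (N, p, p) bool, non-background voxels

    def __len__(self):
        return len(self.x)


def build_patch_dataset(
    pairs: list[tuple[SpectralAcquisition, MaterialVolume]],
    seed: int = 0,
    background_keep: float = 0.1,
) -> PatchDataset:
    """Cut acquisitions + aligned ground truth into training patches.

    Patches containing any non-background voxel are all kept; all-background
    patches are subsampled to ``background_keep`` to limit class imbalance.
    """
    rng = np.random.default_rng(seed)
    xs, cs, qs, ts, ms = [], [], [], [], []
    for acq, truth in pairs:
        stack = build_input_stack(acq)
        cls_vol = feature_class_map(truth)
        nz, _, n, _ = stack.channels.shape
        grid = PatchGrid((n, n))
        for k in range(nz):
            xp = extract_patches(stack.channels[k], grid)
            cp = extract_patches(cls_vol[k][None], grid)[:, 0]
            qp = np.stack(
                [
                    extract_patches(truth.concentrations[m][k][None], grid)[:, 0]
                    for m in ("iodine", "gadolinium", "calcium")
                ],
                axis=1,
            )
            keep = cp.any(axis=(1, 2)) | (
                rng.random(len(cp)) < background_keep
            )
            xs.append(xp[keep])
            cs.append(cp[keep])
            qs.append(qp[keep])
            ts.append((cp[keep] == FeatureClass.TISSUE).astype(np.float32))
            ms.append(cp[keep] != FeatureClass.BACKGROUND)
    return PatchDataset(
        x=np.concatenate(xs).astype(np.float32),
        classes=np.concatenate(cs).astype(np.int64),
        conc=np.concatenate(qs).astype(np.float32),
        tissue=np.concatenate(ts),
        mask=np.concatenate(ms),
    )


class DivergenceError(RuntimeError):
    pass


def _epoch_batches(n: int, batch: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch] for i in range(0, n, batch)]


def train_feature_network(
    train: PatchDataset,
    val: PatchDataset,
    config: TrainingConfig,
    net: FeatureNetwork | None = None,
) -> tuple[FeatureNetwork, pd.DataFrame]:
    """Phase-1 training with early stopping on validation cross-entropy.

    Returns the network restored to its best-validation checkpoint plus the
    per-epoch history.
    """
    net = net or FeatureNetwork(seed=config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(
        opt, factor=config.plateau_factor, patience=config.plateau_patience
    )
    rng = np.random.default_rng(config.seed + 1)
    best_loss, best_state, bad = np.inf, net.state_dict(), 0
    history = []
    for epoch in range(config.max_epochs):
        losses = []
        for idx in _epoch_batches(len(train), config.batch_size, rng):
            loss = net.train_step(train.x[idx], train.classes[idx], opt)
            if not np.isfinite(loss):
                raise DivergenceError(f"NaN training loss at epoch {epoch}")
            losses.append(loss)
        val_loss = _eval_feature_loss(net, val, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        sched.step(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss, best_state, bad = val_loss, net.state_dict(), 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    net.load_state_dict(best_state)
    return net, pd.DataFrame(history)


def _eval_feature_loss(net: FeatureNetwork, data: PatchDataset, batch: int) -> float:
    losses, weights = [], []
    for i in range(0, len(data), batch):
        sl = slice(i, i + batch)
        losses.append(net.loss(data.x[sl], data.classes[sl]))
        weights.append(len(data.x[sl]))
    return float(np.average(losses, weights=weights))


def train_concentration_network(
    feature_net: FeatureNetwork,
    train: PatchDataset,
    val: PatchDataset,
    config: TrainingConfig,
    net: ConcentrationNetwork | None = None,
) -> tuple[ConcentrationNetwork, pd.DataFrame]:
    """Phase-2 training; the feature network stays frozen (hash-verified)."""
    net = net or ConcentrationNetwork(seed=config.seed + 100)
    frozen_hash = feature_net.weights_hash()
    opt = Adam(net.params(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(
        opt, factor=config.plateau_factor, patience=config.plateau_patience
    )
    rng = np.random.default_rng(config.seed + 2)

    def feats_of(x):
        return feature_net.forward(x, train=False)[1]

    best_loss, best_state, bad = np.inf, net.state_dict(), 0
    history = []
    for epoch in range(config.max_epochs):
        losses = []
        for idx in _epoch_batches(len(train), config.batch_size, rng):
            loss = net.train_step(
                feats_of(train.x[idx]),
                train.conc[idx],
                train.tissue[idx],
                train.mask[idx],
                opt,
            )
            if not np.isfinite(loss):
                raise DivergenceError(f"NaN training loss at epoch {epoch}")
            losses.append(loss)
        val_losses = [
            net.loss(
                feats_of(val.x[i : i + config.batch_size]),
                val.conc[i : i + config.batch_size],
                val.tissue[i : i + config.batch_size],
                val.mask[i : i + config.batch_size],
            )
            for i in range(0, len(val), config.batch_size)
        ]
        val_loss = float(np.mean(val_losses))
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        sched.step(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss, best_state, bad = val_loss, net.state_dict(), 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    net.load_state_dict(best_state)
    if feature_net.weights_hash() != frozen_hash:
        raise RuntimeError("feature network weights changed during phase 2")
    return net, pd.DataFrame(history)


def hybrid_training_experiment(
    cylinder_pairs: list[tuple[SpectralAcquisition, MaterialVolume]],
    vp_train_pairs: list[tuple[SpectralAcquisition, MaterialVolume]],
    vp_test_pairs: list[tuple[SpectralAcquisition, MaterialVolume]],
    n_values: tuple[int, ...] = tuple(range(9)),
    seeds: tuple[int, ...] = (0,),
    config: TrainingConfig | None = None,
    train_concentration: bool = True,
) -> pd.DataFrame:
    """Classification performance vs the number of virtual patients trained on.

    For each (n, seed): retrain the networks on all cylinder acquisitions
    plus the acquisitions of the first n virtual-patient phantoms, then score
    multilabel metrics on the fixed held-out virtual-patient set.  Returns a
    tidy table with one row per (n, seed, class).
    """
    config = config or TrainingConfig()
    if max(n_values) > len({p[1].meta["phantom_id"] for p in vp_train_pairs}):
        raise ValueError("not enough virtual-patient phantoms for n_values")
    vp_by_phantom: dict[str, list] = {}
    for pair in vp_train_pairs:
        vp_by_phantom.setdefault(pair[1].meta["phantom_id"], []).append(pair)
    vp_order = sorted(vp_by_phantom)

    rows = []
    for seed in seeds:
        for n_vp in n_values:
            pairs = list(cylinder_pairs)
            for pid in vp_order[:n_vp]:
                pairs.extend(vp_by_phantom[pid])
            cfg = TrainingConfig(
                **{
                    **config.__dict__,
                    "seed": int(config.seed + 1000 * seed + n_vp),
                }
            )
            data = build_patch_dataset(
                pairs, seed=cfg.seed, background_keep=cfg.background_keep
            )
            rng = np.random.default_rng(cfg.seed + 3)
            idx = rng.permutation(len(data))
            n_val = max(1, len(data) // 8)
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            subset = lambda d, i: PatchDataset(
                d.x[i], d.classes[i], d.conc[i], d.tissue[i], d.mask[i]
            )
            fnet, _ = train_feature_network(
                subset(data, tr_idx), subset(data, val_idx), cfg
            )
            if train_concentration:
                train_concentration_network(
                    fnet, subset(data, tr_idx), subset(data, val_idx), cfg
                )
            # score on held-out virtual patients
            true_all, pred_all = [], []
            for acq, truth in vp_test_pairs:
                stack = build_input_stack(acq)
                nz, _, nn_, _ = stack.channels.shape
                grid = PatchGrid((nn_, nn_))
                from .patches import stitch_patches

                for k in range(nz):
                    xp = extract_patches(stack.channels[k], grid)
                    probs, _ = fnet.forward(xp, train=False)
                    full = stitch_patches(probs, grid, prob_channels=slice(0, 4))
                    pred_all.append(full.argmax(axis=0))
                true_all.append(feature_class_map(truth))
            metrics = classification_metrics(
                np.concatenate([t.ravel() for t in true_all]),
                np.concatenate([p.ravel() for p in pred_all]),
            )
            for _, r in metrics.iterrows():
                rows.append({"n_virtual": n_vp, "seed": seed, **r.to_dict()})
    return pd.DataFrame(rows)
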