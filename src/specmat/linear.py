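"""Classical sensitivity-matrix material decomposition.

The linear model: per voxel, the vector of per-bin measurements X (here HU,
affine-equivalent to linear attenuation since water is the shared reference)
is a linear map of the basis-material concentrations Y through the
sensitivity matrix Gamma (M bins x N materials),

    X = Gamma Y.

Gamma is calibrated by least squares from ROIs of known concentration and
inverted per voxel by pseudo-inverse.  With two bins only two basis
materials are identifiable; asking for more raises a rank error — the
structural limitation the learned decomposition is meant to sidestep.
This module doubles as the exactness oracle on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensitivityModel",
    "CalibrationError",
    "RankDeficiencyError",
    "calibrate_sensitivity",
    "decompose_linear",
]


class CalibrationError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    """More basis materials requested than energy bins can support."""


@dataclass(frozen=True)
class SensitivityModel:
    """Gamma matrix with calibration provenance."""

    gamma: np.ndarray  # (M bins, N materials), HU per (mg/mL)
    materials: tuple[str, ...]
    bins: tuple[str, ...] = ("low", "high")
    residual_rms: float = 0.0
    condition_number: float = float("nan")
    calibration: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_materials(self) -> int:
        return self.gamma.shape[1]


def calibrate_sensitivity(
    measurements: np.ndarray,
    concentrations: np.ndarray,
    materials: tuple[str, ...],
    bins: tuple[str, ...] = ("low", "high"),
    calibration_meta: dict | None = None,
) -> SensitivityModel:
    """Least-squares estimate of Gamma from paired ROI means.

    Parameters
    ----------
    measurements
        (n_samples, M) per-bin ROI means (HU).
    concentrations
        (n_samples, N) known concentrations (mg/mL).
    """
    X = np.asarray(measurements, dtype=float)
    Y = np.asarray(concentrations, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise CalibrationError("measurements and concentrations disagree in length")
    if Y.shape[0] < Y.shape[1]:
        raise CalibrationError(
            f"need at least {Y.shape[1]} calibration samples, got {Y.shape[0]}"
        )
    if np.linalg.matrix_rank(Y) < Y.shape[1]:
        # name the offending (most collinear) pair for the error message
        c = np.corrcoef(Y, rowvar=False)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        raise CalibrationError(
            f"calibration concentrations are rank deficient; materials "
            f"{materials[i]!r} and {materials[j]!r} are collinear"
        )
    # X = Y Gamma^T  (row-wise)  ->  solve for Gamma^T
    gamma_t, res, _, _ = np.linalg.lstsq(Y, X, rcond=None)
    gamma = gamma_t.T
    resid = X - Y @ gamma_t
    return SensitivityModel(
        gamma=gamma,
        materials=tuple(materials),
        bins=tuple(bins),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        condition_number=float(np.linalg.cond(gamma)),
        calibration=dict(calibration_meta or {}, n_samples=int(Y.shape[0])),
    )


def decompose_linear(
    X: np.ndarray,
    model: SensitivityModel,
    nonnegative: bool = False,
) -> tuple[np.ndarray, dict]:
    """Per-voxel pseudo-inverse solve of X = Gamma Y.

    ``X`` has the bin axis last: (..., M).  Returns (Y, info) with Y of shape
    (..., N) and metadata flagging any nonnegativity clamp.
    """
    if model.n_materials > model.n_bins:
        raise RankDeficiencyError(
            f"{model.n_materials} basis materials requested from "
            f"{model.n_bins} energy bins; the linear system is underdetermined"
        )
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.n_bins:
        raise ValueError(f"last axis of X must have length {model.n_bins}")
    pinv = np.linalg.pinv(model.gamma)
    Y = X @ pinv.T
    info = {"nonnegative_clamped": False, "materials": model.materials}
    if nonnegative:
        clamped = Y < 0
        if clamped.any():
            info["nonnegative_clamped"] = True
            info["clamped_fraction"] = float(clamped.mean())
        Y = np.clip(Y, 0.0, None)
    return Y, info
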