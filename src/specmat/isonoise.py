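"""Isonoise dose calibration from the water-phantom pilot study.

Image noise (HU standard deviation in a centered water ROI) is measured on a
grid of water-phantom diameters x tube currents, a linear plane
``noise ~ a + b*diameter + c*mAs`` is fitted per energy bin, and the fit is
inverted to pick the mAs that yields a target noise level ("isonoise") for
any phantom size.  The low-energy bin drives the inversion; the high-bin fit
is carried alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phantoms import generate_pilot_water_phantom
from .simulate import Protocol, SpectralAcquisition, simulate_acquisition

__all__ = [
    "NoiseModel",
    "PILOT_CURRENTS_MAS",
    "ISONOISE_TARGETS_HU",
    "measure_roi_noise",
    "run_pilot",
    "fit_noise_model",
    "mas_for_isonoise",
]

#: canonical pilot tube-current grid (mAs)
PILOT_CURRENTS_MAS = (25.0, 50.0, 100.0, 150.0, 200.0)

#: canonical isonoise targets (HU) per cylinder size group: 3 dose tiers each
ISONOISE_TARGETS_HU = {
    20.0: (8.5, 5.0, 3.0),
    28.0: (16.5, 13.0, 8.5),
    36.0: (21.5, 19.0, 16.5),
    42.0: (25.5, 23.5, 21.5),
}

#: isonoise targets (HU) per virtual-patient size group: full and reduced dose
VP_ISONOISE_TARGETS_HU = {
    "small": (3.0, 5.0),
    "medium": (8.5, 13.0),
    "large": (16.5, 19.0),
    "extra_large": (21.5, 23.5),
}

#: canonical tube currents (mAs) per cylinder diameter, one triplet of dose
#: tiers per size; at reduced simulator scales the noise targets are derived
#: from these currents through the fitted noise plane (the absolute HU tiers
#: above presume the full-resolution flux regime)
CYLINDER_CURRENTS_MAS = {
    20.0: (44.0, 110.0, 150.0),
    28.0: (46.0, 113.0, 198.0),
    36.0: (106.0, 153.0, 200.0),
    42.0: (145.0, 184.0, 221.0),
}

#: virtual patients: (reduced, full) dose currents, midpoints of the
#: per-group ranges
VP_CURRENTS_MAS = {
    "small": (194.0, 231.5),
    "medium": (152.5, 237.5),
    "large": (135.5, 183.0),
    "extra_large": (158.5, 196.5),
}


class RoiPlacementError(ValueError):
    """ROI leaves the uniform water region."""


class InfeasibleTargetError(ValueError):
    """Requested noise target unreachable inside the allowed mAs range."""


@dataclass(frozen=True)
class NoiseModel:
    """Per-bin linear noise plane: noise = a + b*diameter + c*mAs (HU)."""

    coeffs: dict[str, tuple[float, float, float]]  # bin -> (a, b, c)
    diagnostics: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def predict(self, diameter_cm: float, mAs: float, bin_name: str = "low") -> float:
        a, b, c = self.coeffs[bin_name]
        return a + b * diameter_cm + c * mAs


def measure_roi_noise(
    acquisition: SpectralAcquisition,
    roi_radius_cm: float = 3.0,
    water_radius_cm: float | None = None,
) -> dict[str, float]:
    """HU std in a centered circular ROI, per bin, averaged over slices."""
    m = acquisition.matrix
    px = acquisition.pixel_cm
    if water_radius_cm is None:
        d = acquisition.meta.get("diameter_cm")
        water_radius_cm = d / 2.0 if d else acquisition.recon_fov_cm / 2.0
    if roi_radius_cm >= water_radius_cm - 2 * px:
        raise RoiPlacementError(
            f"ROI radius {roi_radius_cm} cm reaches the water boundary "
            f"(water radius {water_radius_cm} cm)"
        )
    c = (np.arange(m) - (m - 1) / 2.0) * px
    yy, xx = np.meshgrid(c, c, indexing="ij")
    roi = np.hypot(yy, xx) <= roi_radius_cm
    return {
        name: float(np.mean([vol[k][roi].std() for k in range(vol.shape[0])]))
        for name, vol in acquisition.hu.items()
    }


def run_pilot(
    diameters_cm=(20.0, 25.0, 30.0, 35.0, 40.0),
    currents_mas=PILOT_CURRENTS_MAS,
    seed: int = 0,
    n: int = 512,
    nz: int = 1,
    n_views: int = 720,
    recon_matrix: int = 512,
    roi_radius_cm: float = 3.0,
) -> pd.DataFrame:
    """Simulate the pilot grid and return tidy noise measurements."""
    rows = []
    rng = np.random.default_rng(seed)
    for d in diameters_cm:
        vol = generate_pilot_water_phantom(d, n=n, nz=nz)
        for mas in currents_mas:
            prot = Protocol(
                mAs=mas,
                n_views=n_views,
                recon_matrix=recon_matrix,
                seed=int(rng.integers(2**31 - 1)),
            )
            acq = simulate_acquisition(vol, prot)
            noise = measure_roi_noise(acq, roi_radius_cm=roi_radius_cm)
            for name, hu_sd in noise.items():
                rows.append(
                    {"diameter_cm": d, "mAs": mas, "bin": name, "noise_hu": hu_sd}
                )
    return pd.DataFrame(rows)


def fit_noise_model(pilot: pd.DataFrame) -> NoiseModel:
    """OLS plane fit per bin over the pilot measurements."""
    coeffs, diag = {}, {}
    for name, sub in pilot.groupby("bin"):
        if sub[["diameter_cm", "mAs"]].drop_duplicates().shape[0] < 6:
            raise ValueError("need at least 6 distinct (diameter, mAs) points")
        X = sm.add_constant(sub[["diameter_cm", "mAs"]].to_numpy())
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("rank-deficient pilot design")
        fit = sm.OLS(sub["noise_hu"].to_numpy(), X).fit()
        coeffs[name] = tuple(float(v) for v in fit.params)
        diag[name] = {
            "r_squared": float(fit.rsquared),
            "residual_sd": float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        }
    return NoiseModel(
        coeffs=coeffs,
        diagnostics=diag,
        provenance={
            "n_points": int(len(pilot) // pilot["bin"].nunique()),
            "diameters": sorted(pilot["diameter_cm"].unique().tolist()),
            "currents": sorted(pilot["mAs"].unique().tolist()),
        },
    )


def mas_for_isonoise(
    model: NoiseModel,
    diameter_cm: float,
    target_noise_hu: float,
    bin_name: str = "low",
    mas_range: tuple[float, float] = (10.0, 1000.0),
) -> float:
    """Invert the linear noise plane for the tube current hitting a target.

    The result is clipped to ``mas_range`` with a warning; an unreachable
    target (non-negative mAs slope, or clipping by more than 2x) raises.
    """
    a, b, c = model.coeffs[bin_name]
    if c >= 0:
        raise InfeasibleTargetError(
            "noise model has non-negative mAs slope; cannot invert for dose"
        )
    mas = (target_noise_hu - a - b * diameter_cm) / c
    lo, hi = mas_range
    if mas < lo / 2 or mas > hi * 2:
        raise InfeasibleTargetError(
            f"target {target_noise_hu} HU at {diameter_cm} cm needs {mas:.0f} mAs, "
            f"far outside allowed range {mas_range}"
        )
    if not lo <= mas <= hi:
        warnings.warn(
            f"isonoise mAs {mas:.0f} clipped to protocol range {mas_range}",
            stacklevel=2,
        )
        mas = float(np.clip(mas, lo, hi))
    return float(mas)
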