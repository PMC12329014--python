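"""Energy-dependent X-ray physics of basis materials and mixtures.

The quantification problem rests on the energy dependence of linear
attenuation: a voxel holding a dilute mixture of contrast agents in a solvent
(water or soft tissue) attenuates as

    mu_tot(E) = rho_solvent * (mu/rho)_solvent(E) + sum_i c_i * (mu/rho)_i(E)

with solute concentrations ``c_i`` in g/cm^3 (mg/mL / 1000).  The K-edge
discontinuities of iodine (33.17 keV) and gadolinium (50.24 keV) straddle the
two counting bins split at 65 keV, which is what makes the two agents
separable from two energy windows.

Mass-attenuation anchors are shipped as plain-text tables sampled from
standard published compilations and resampled log-log onto a 1 keV grid
(10-120 keV) at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationTable",
    "MaterialRegistry",
    "MaterialComposition",
    "Spectrum",
    "EnergyBins",
    "default_registry",
    "mixture_mu",
    "effective_bin_mu",
    "mu_to_hu",
    "make_spectrum",
]

ENERGY_GRID_KEV = np.arange(10.0, 121.0, 1.0)

#: nominal densities (g/cm3) of the solid/solvent materials in the registry
_DENSITIES = {
    "water": 1.000,
    "soft_tissue": 1.060,
    "iodine": 4.930,
    "gadolinium": 7.900,
    "calcium": 1.550,
    "cortical_bone": 1.920,
    "aluminum": 2.699,
}

K_EDGES_KEV = {"iodine": 33.1694, "gadolinium": 50.2391}


class MaterialError(KeyError):
    """Unknown material requested from the registry."""


class EnergyRangeError(ValueError):
    """Energy outside the tabulated 10-120 keV grid."""


@dataclass(frozen=True)
class AttenuationTable:
    """Mass attenuation of one material on the common 1 keV grid."""

    material: str
    energies: np.ndarray  # keV
    mu_over_rho: np.ndarray  # cm^2/g
    density: float  # g/cm^3

    def __call__(self, energy_kev) -> np.ndarray:
        """Interpolated mu/rho (cm^2/g) at ``energy_kev``."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise EnergyRangeError(
                f"energy outside tabulated grid "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        return np.interp(e, self.energies, self.mu_over_rho)

    def mu(self, energy_kev) -> np.ndarray:
        """Linear attenuation (1/cm) of the pure material at nominal density."""
        return self.density * self(energy_kev)


def _load_anchor_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = (
        resources.files("specmat.data.attenuation")
        .joinpath(f"{name}.tsv")
        .read_text()
    )
    rows = [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def _resample_loglog(
    e_anchor: np.ndarray, mu_anchor: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    # log-log interpolation; K edges are encoded as double points a fraction
    # of an eV apart, so plain interpolation keeps the discontinuity sharp
    return np.exp(
        np.interp(np.log(grid), np.log(e_anchor), np.log(mu_anchor))
    )


class MaterialRegistry:
    """Lookup of :class:`AttenuationTable` by material name."""

    def __init__(self, tables: dict[str, AttenuationTable]):
        self._tables = dict(tables)

    def __getitem__(self, name: str) -> AttenuationTable:
        try:
            return self._tables[name]
        except KeyError:
            raise MaterialError(
                f"unknown material {name!r}; registered: {sorted(self._tables)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._tables

    def names(self) -> list[str]:
        return sorted(self._tables)


_REGISTRY: MaterialRegistry | None = None


def default_registry() -> MaterialRegistry:
    """Registry of the shipped materials, resampled to the 1 keV grid."""
    global _REGISTRY
    if _REGISTRY is None:
        tables = {}
        for name, rho in _DENSITIES.items():
            e, m = _load_anchor_table(name)
            tables[name] = AttenuationTable(
                material=name,
                energies=ENERGY_GRID_KEV,
                mu_over_rho=_resample_loglog(e, m, ENERGY_GRID_KEV),
                density=rho,
            )
        _REGISTRY = MaterialRegistry(tables)
    return _REGISTRY


@dataclass(frozen=True)
class MaterialComposition:
    """A voxel composition: a solvent plus dilute solute concentrations.

    ``solutes`` maps material name to concentration in mg/mL.  The dilute
    approximation ignores solvent displacement, matching how mg/mL phantom
    inserts are specified.
    """

    solvent: str = "water"
    solutes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, c in self.solutes.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}: {c}")


def mixture_mu(
    composition: MaterialComposition,
    energy_kev,
    registry: MaterialRegistry | None = None,
):
    """Linear attenuation (1/cm) of a dilute mixture at ``energy_kev``.

    Linear in each solute concentration by construction.
    """
    reg = registry or default_registry()
    mu = reg[composition.solvent].mu(energy_kev)
    for name, mg_per_ml in composition.solutes.items():
        mu = mu + (mg_per_ml / 1000.0) * reg[name](energy_kev)
    return mu


@dataclass(frozen=True)
class Spectrum:
    """Relative source fluence per energy, normalized to sum to one."""

    energies: np.ndarray  # keV
    fluence_weights: np.ndarray
    kv: float = 120.0

    def __post_init__(self):
        w = np.asarray(self.fluence_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("fluence weights must be nonnegative")
        if np.any(w[np.asarray(self.energies) > self.kv] > 0):
            raise ValueError("fluence above tube voltage must be zero")
        object.__setattr__(self, "fluence_weights", w / w.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.fluence_weights))


class ConfigError(ValueError):
    pass


def make_spectrum(
    kv: float = 120.0,
    filtration_mm_al: float = 7.0,
    registry: MaterialRegistry | None = None,
) -> Spectrum:
    """Analytic filtered-bremsstrahlung spectrum on the 1 keV grid.

    Kramers-type shape (kv - E)/E hardened by an aluminum filter; no
    characteristic lines.  Deterministic for fixed parameters.
    """
    if not (80.0 <= kv <= 150.0):
        raise ConfigError(f"tube voltage {kv} kV outside supported 80-150 kV")
    if filtration_mm_al < 0:
        raise ConfigError("negative aluminum filtration")
    reg = registry or default_registry()
    e = ENERGY_GRID_KEV
    raw = np.clip(kv - e, 0.0, None) / e
    al = reg["aluminum"]
    transmission = np.exp(-al.mu(e) * (filtration_mm_al / 10.0))
    return Spectrum(energies=e, fluence_weights=raw * transmission, kv=kv)


@dataclass(frozen=True)
class EnergyBins:
    """Two counting bins from thresholds: low = [t0, t1), high = [t1, kv]."""

    thresholds: tuple[float, float] = (20.0, 65.0)
    kv: float = 120.0

    def __post_init__(self):
        t0, t1 = self.thresholds
        if not (t0 < t1 < self.kv):
            raise ConfigError(
                f"thresholds {self.thresholds} must be strictly increasing "
                f"and below {self.kv} kV"
            )

    @property
    def names(self) -> tuple[str, str]:
        return ("low", "high")

    def mask(self, name: str, energies: np.ndarray) -> np.ndarray:
        t0, t1 = self.thresholds
        e = np.asarray(energies)
        if name == "low":
            return (e >= t0) & (e < t1)
        if name == "high":
            return (e >= t1) & (e <= self.kv)
        raise ConfigError(f"unknown bin {name!r}")


def effective_bin_mu(
    composition: MaterialComposition,
    spectrum: Spectrum,
    bins: EnergyBins,
    bin_name: str,
    registry: MaterialRegistry | None = None,
) -> float:
    """Fluence-weighted mean linear attenuation over one bin's energies.

    The value for pure water defines that bin's HU reference.
    """
    mask = bins.mask(bin_name, spectrum.energies)
    w = spectrum.fluence_weights[mask]
    if w.sum() <= 0:
        raise ConfigError(f"bin {bin_name!r} holds no fluence")
    mu = mixture_mu(composition, spectrum.energies[mask], registry)
    return float(np.sum(w * mu) / w.sum())


def mu_to_hu(mu, mu_water_eff: float):
    """Hounsfield conversion: HU = 1000 (mu - mu_w) / mu_w."""
    if mu_water_eff <= 0:
        raise ValueError("water reference attenuation must be positive")
    return 1000.0 * (np.asarray(mu) - mu_water_eff) / mu_water_eff
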