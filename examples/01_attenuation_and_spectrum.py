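"""Energy-dependent attenuation of the basis materials and the source beam.

Prints the mass attenuation of iodine and gadolinium around their K edges
and the effective per-bin attenuation of water — the physics that makes the
two contrast agents separable from two counting bins split at 65 keV.
"""

from specmat import (
    EnergyBins,
    MaterialComposition,
    default_registry,
    effective_bin_mu,
    make_spectrum,
    mixture_mu,
)

registry = default_registry()
spectrum = make_spectrum()  # 120 kV bremsstrahlung, 7 mm Al filtration
bins = EnergyBins()  # thresholds 20 / 65 keV

print(f"spectrum mean energy: {spectrum.mean_energy:.1f} keV")
print("\nmass attenuation (cm^2/g) across the K edges:")
for material, edge in (("iodine", 33), ("gadolinium", 50)):
    lo, hi = registry[material](float(edge)), registry[material](edge + 1.0)
    print(f"  {material:>10}: {lo:7.2f} at {edge} keV -> {hi:7.2f} at {edge + 1} keV")

water = MaterialComposition("water")
spiked = MaterialComposition("water", {"iodine": 5.0})
print("\nlinear attenuation at 60 keV (1/cm):")
print(f"  water              : {mixture_mu(water, 60.0):.4f}")
print(f"  water + 5 mg/mL I  : {mixture_mu(spiked, 60.0):.4f}")

print("\neffective attenuation per counting bin (1/cm):")
for name in bins.names:
    mu_w = effective_bin_mu(water, spectrum, bins, name)
    mu_i = effective_bin_mu(spiked, spectrum, bins, name)
    print(f"  {name:>4} bin: water {mu_w:.4f}, +iodine {mu_i:.4f} "
          f"(+{1000 * (mu_i - mu_w) / mu_w:.0f} HU)")
# The iodine enhancement is much larger in the low bin: that asymmetry,
# and its reversal for gadolinium above its 50 keV K edge, carries the
# material information the decomposition exploits.
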