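"""Simulate a two-bin photon-counting acquisition and inspect the HU images.

Projects a contrast cylinder through the polychromatic simulator, adds
Poisson counting noise, reconstructs both energy bins with FBP and reports
per-insert HU — showing the spectral contrast between iodine and gadolinium.
"""

import numpy as np
from scipy import ndimage

from specmat import Protocol, simulate_acquisition
from specmat.phantoms import generate_pilot_water_phantom
from specmat.simulate import resample_ground_truth

# a 20 cm water cylinder with one iodine and one gadolinium insert
vol = generate_pilot_water_phantom(20.0, n=256, nz=1)
yy, xx = vol.grid_cm()
vol.concentrations["iodine"][0][(yy**2 + (xx + 5) ** 2) <= 1.5**2] = 5.0
vol.concentrations["gadolinium"][0][(yy**2 + (xx - 5) ** 2) <= 1.5**2] = 4.0
vol.meta = {"kind": "demo", "diameter_cm": 20.0, "phantom_id": "demo"}

protocol = Protocol(mAs=150.0, n_views=240, recon_matrix=256, seed=4)
acq = simulate_acquisition(vol, protocol)
truth = resample_ground_truth(vol, acq)

print(f"reconstructed {acq.matrix}x{acq.matrix} over {acq.recon_fov_cm:.0f} cm, "
      f"mAs {acq.meta['mAs']:.0f}")
for mat, conc in (("iodine", 5.0), ("gadolinium", 4.0)):
    mask = np.stack([ndimage.binary_erosion(m) for m in
                     truth.concentrations[mat] > 0])
    low = acq.hu["low"][mask].mean()
    high = acq.hu["high"][mask].mean()
    print(f"  {mat:>10} {conc:.0f} mg/mL: low bin {low:6.1f} HU, "
          f"high bin {high:6.1f} HU, high/low ratio {high / low:.2f}")
# Iodine loses most of its enhancement in the high bin; gadolinium, with its
# K edge at 50 keV, keeps a much larger share — that ratio difference is the
# signal the decomposition uses.

# a centered water ROI on the reconstruction grid
c = (np.arange(acq.matrix) - (acq.matrix - 1) / 2.0) * acq.pixel_cm
ry, rx = np.meshgrid(c, c, indexing="ij")
water = np.hypot(ry, rx) < 3.0
print(f"  water center: {acq.hu['low'][0][water].mean():5.1f} HU "
      f"(should sit near 0), noise {acq.hu['low'][0][water].std():.1f} HU sd")
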