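"""Generate the three phantom families and inspect their ground truth.

Builds one cylindrical insert phantom, one pilot water cylinder and one
anthropomorphic virtual patient, and prints what each contains.
"""

import numpy as np

from specmat import (
    generate_cylindrical_phantom,
    generate_pilot_water_phantom,
    generate_virtual_patient,
)
from specmat.phantoms import FeatureClass, feature_class_map

cyl = generate_cylindrical_phantom(diameter_cm=20.0, seed=7, n=256, nz=3)
inserts = cyl.meta["inserts"]
print(f"cylinder: {cyl.meta['phantom_id']}, {len(inserts)} insert regions "
      f"({sum(i.half is not None for i in inserts)} half-discs from split inserts)")
for i in inserts[:4]:
    conc = ", ".join(f"{m} {c:.2f} mg/mL" for m, c in i.concentrations.items())
    print(f"  r={i.radius_cm:.2f} cm  {i.material_class:<22} {conc or 'no contrast'}")

pilot = generate_pilot_water_phantom(30.0, n=256, nz=1)
print(f"\npilot water phantom: {pilot.meta['phantom_id']}, "
      f"labels {sorted(np.unique(pilot.labels).tolist())} (air, water only)")

vp = generate_virtual_patient("medium", seed=3, n=256, nz=5)
print(f"\nvirtual patient: {vp.meta['phantom_id']}, "
      f"lateral diameter {vp.meta['diameter_cm']:.1f} cm")
print(f"  aorta iodine       : {vp.meta['aorta_iodine']:.2f} mg/mL")
print(f"  collecting-system Gd: {vp.meta['gadolinium']:.2f} mg/mL")
print(f"  calcified plaques  : {vp.meta['n_plaques']}")

classes = feature_class_map(vp)
total = classes.size
print("\nvoxel fractions per classifier class (virtual patient):")
for cls in FeatureClass:
    print(f"  {cls.name.lower():<10} {np.mean(classes == cls) * 100:5.1f} %")
# Note the spine/ribs count as background: only vascular calcium is a
# positive class for the classifier.
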