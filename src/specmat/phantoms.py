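"""Seeded generators for the ground-truth digital phantoms.

Three families:

* cylindrical insert phantoms — a water cylinder (20/28/36/42 cm) carrying two
  rings of eight contrast inserts each, used to train and test quantification;
* pilot water phantoms — uniform cylinders for the noise/dose calibration;
* procedural anthropomorphic abdomens — a stand-in for licensed
  anthropomorphic phantom libraries: elliptical body, liver with contrast
  vessels, kidneys with gadolinium-filled collecting systems, aorta with two
  calcified plaques, spine and ribs.

Every generator is deterministic given its seed and returns a
:class:`MaterialVolume`: a label map (air / water / soft tissue / bone)
plus per-material concentration maps in mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .materials import MaterialComposition

__all__ = [
    "Label",
    "FeatureClass",
    "InsertSpec",
    "MaterialVolume",
    "GenerationError",
    "generate_cylindrical_phantom",
    "generate_pilot_water_phantom",
    "generate_virtual_patient",
    "class_label_for_voxel",
    "feature_class_map",
    "CYLINDER_DIAMETERS_CM",
    "PILOT_DIAMETERS_CM",
    "SIZE_GROUPS",
    "INSERT_CLASSES",
]

CYLINDER_DIAMETERS_CM = (20.0, 28.0, 36.0, 42.0)
PILOT_DIAMETERS_CM = (20.0, 25.0, 30.0, 35.0, 40.0)

#: lateral-diameter ranges (cm) per size group of the anthropomorphic cohort
SIZE_GROUPS = {
    "small": (23.0, 25.7),
    "medium": (27.5, 32.6),
    "large": (33.3, 36.9),
    "extra_large": (38.0, 43.3),
}

CONCENTRATIONS = ("iodine", "gadolinium", "calcium")


class Label(IntEnum):
    AIR = 0
    WATER = 1
    SOFT_TISSUE = 2
    BONE = 3


class FeatureClass(IntEnum):
    """The 4 classes the feature network predicts per voxel."""

    BACKGROUND = 0  # water, air, and skeletal bone
    CALCIUM = 1  # calcium without tissue (vascular plaque in patients)
    CONTRAST = 2  # iodine and/or gadolinium without tissue
    TISSUE = 3  # any voxel containing soft tissue


class GenerationError(RuntimeError):
    """Raised when inserts cannot be placed without overlap."""


#: the seven insert material classes and their concentration ranges (mg/mL)
INSERT_CLASSES = {
    "soft_tissue": {},
    "iodine": {"iodine": (0.0, 7.5)},
    "gadolinium": {"gadolinium": (0.0, 5.0)},
    "calcium": {"calcium": (0.0, 300.0)},
    # mixture class: each agent in half its pure range
    "iodine_gadolinium": {"iodine": (0.0, 3.75), "gadolinium": (0.0, 2.5)},
    "iodine_soft_tissue": {"iodine": (0.0, 2.5)},
    "gadolinium_soft_tissue": {"gadolinium": (0.0, 4.0)},
}

_TISSUE_CLASSES = {"soft_tissue", "iodine_soft_tissue", "gadolinium_soft_tissue"}


@dataclass
class InsertSpec:
    """One cylindrical insert (or one half of a split insert)."""

    center_cm: tuple[float, float]
    radius_cm: float
    material_class: str
    concentrations: dict[str, float] = field(default_factory=dict)
    half: int | None = None  # 0/1 for split halves, None for whole inserts
    split_angle: float | None = None


@dataclass
class MaterialVolume:
    """Voxelized ground truth: labels + per-material concentration maps."""

    labels: np.ndarray  # (nz, n, n) int8, Label values
    concentrations: dict[str, np.ndarray]  # mg/mL, same shape, float32
    fov_cm: float
    slice_mm: float = 2.0
    meta: dict = field(default_factory=dict)
    uniform_z: bool = False
    organs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name in CONCENTRATIONS:
            self.concentrations.setdefault(
                name, np.zeros(self.labels.shape, dtype=np.float32)
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n(self) -> int:
        return self.labels.shape[-1]

    @property
    def pixel_cm(self) -> float:
        return self.fov_cm / self.n

    def grid_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (y, x) in cm, origin at volume center."""
        half = self.fov_cm / 2.0
        c = (np.arange(self.n) + 0.5) * self.pixel_cm - half
        return np.meshgrid(c, c, indexing="ij")

    def solvent_masks(self, k: int) -> dict[str, np.ndarray]:
        """Per-slice solvent masks keyed by registry material name."""
        lab = self.labels[k]
        return {
            "water": lab == Label.WATER,
            "soft_tissue": lab == Label.SOFT_TISSUE,
            "cortical_bone": lab == Label.BONE,
        }


def _disc(yy, xx, center, radius):
    cy, cx = center[1], center[0]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _sample_concentrations(rng, material_class: str) -> dict[str, float]:
    return {
        mat: float(rng.uniform(lo, hi))
        for mat, (lo, hi) in INSERT_CLASSES[material_class].items()
    }


def _place_ring_inserts(rng, ring_radius: float, count: int) -> list:
    """Centers and radii on one ring, avoiding overlap (bounded retries)."""
    base = rng.uniform(0, 2 * np.pi)
    angles = base + 2 * np.pi * np.arange(count) / count
    angles = angles + rng.uniform(-0.08, 0.08, size=count)
    centers = np.stack(
        [ring_radius * np.cos(angles), ring_radius * np.sin(angles)], axis=1
    )
    gap = 0.1  # cm clearance between inserts
    for _ in range(200):
        radii = rng.uniform(0.75, 1.5, size=count)
        ok = True
        for i in range(count):
            j = (i + 1) % count
            d = np.hypot(*(centers[i] - centers[j]))
            if radii[i] + radii[j] + gap > d:
                ok = False
                break
        if ok:
            return [(tuple(c), float(r)) for c, r in zip(centers, radii)]
    raise GenerationError(
        f"could not place {count} non-overlapping inserts on ring r={ring_radius}"
    )


def generate_cylindrical_phantom(
    diameter_cm: float,
    seed: int,
    n: int = 512,
    nz: int = 15,
    fov_cm: float | None = None,
    slice_mm: float = 2.0,
) -> MaterialVolume:
    """Water cylinder with 16 contrast inserts on rings of radius 3.5 and 7 cm.

    Four of the sixteen inserts are split along a random diameter into two
    half-discs of different material classes.  Canonical diameters are
    20/28/36/42 cm; other values are accepted but flagged in metadata.
    """
    rng = np.random.default_rng(seed)
    if fov_cm is None:
        fov_cm = diameter_cm + 4.0

    vol = MaterialVolume(
        labels=np.zeros((1, n, n), dtype=np.int8),
        concentrations={},
        fov_cm=fov_cm,
        slice_mm=slice_mm,
        uniform_z=True,
    )
    yy, xx = vol.grid_cm()
    body = _disc(yy, xx, (0.0, 0.0), diameter_cm / 2.0)
    lab = vol.labels[0]
    lab[body] = Label.WATER

    placements = _place_ring_inserts(rng, 3.5, 8) + _place_ring_inserts(rng, 7.0, 8)
    split_ids = rng.choice(16, size=4, replace=False)

    inserts: list[InsertSpec] = []
    classes = list(INSERT_CLASSES)
    for idx, (center, radius) in enumerate(placements):
        disc = _disc(yy, xx, center, radius)
        if idx in split_ids:
            cls_a, cls_b = rng.choice(classes, size=2, replace=False)
            theta = rng.uniform(0, np.pi)
            nvec = np.array([np.cos(theta), np.sin(theta)])
            side = (xx - center[0]) * nvec[0] + (yy - center[1]) * nvec[1] >= 0
            halves = [(cls_a, disc & side), (cls_b, disc & ~side)]
        else:
            cls = rng.choice(classes)
            halves = [(cls, disc)]
        for h, (cls, mask) in enumerate(halves):
            conc = _sample_concentrations(rng, cls)
            lab[mask] = (
                Label.SOFT_TISSUE if cls in _TISSUE_CLASSES else Label.WATER
            )
            for mat, c in conc.items():
                vol.concentrations[mat][0][mask] = c
            inserts.append(
                InsertSpec(
                    center_cm=center,
                    radius_cm=radius,
                    material_class=cls,
                    concentrations=conc,
                    half=h if len(halves) > 1 else None,
                    split_angle=theta if len(halves) > 1 else None,
                )
            )

    _broadcast_z(vol, nz)
    vol.meta = {
        "kind": "cylinder",
        "diameter_cm": diameter_cm,
        "canonical": diameter_cm in CYLINDER_DIAMETERS_CM,
        "seed": int(seed),
        "inserts": inserts,
        "phantom_id": f"cyl_d{int(diameter_cm)}_s{seed}",
    }
    return vol


def generate_pilot_water_phantom(
    diameter_cm: float,
    n: int = 512,
    nz: int = 15,
    fov_cm: float | None = None,
    slice_mm: float = 2.0,
) -> MaterialVolume:
    """Uniform water cylinder for the noise pilot study (no inserts)."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    if fov_cm is None:
        fov_cm = diameter_cm + 4.0
    vol = MaterialVolume(
        labels=np.zeros((1, n, n), dtype=np.int8),
        concentrations={},
        fov_cm=fov_cm,
        slice_mm=slice_mm,
        uniform_z=True,
    )
    yy, xx = vol.grid_cm()
    vol.labels[0][_disc(yy, xx, (0.0, 0.0), diameter_cm / 2.0)] = Label.WATER
    _broadcast_z(vol, nz)
    vol.meta = {
        "kind": "pilot",
        "diameter_cm": diameter_cm,
        "canonical": diameter_cm in PILOT_DIAMETERS_CM,
        "phantom_id": f"pilot_d{int(diameter_cm)}",
    }
    return vol


def _broadcast_z(vol: MaterialVolume, nz: int) -> None:
    vol.labels = np.repeat(vol.labels, nz, axis=0)
    for mat in vol.concentrations:
        vol.concentrations[mat] = np.repeat(vol.concentrations[mat], nz, axis=0)


def _ellipse(yy, xx, center, ax, ay):
    return ((xx - center[0]) / ax) ** 2 + ((yy - center[1]) / ay) ** 2 <= 1.0


def generate_virtual_patient(
    size_group: str,
    seed: int,
    n: int = 512,
    nz: int = 15,
    fov_cm: float | None = None,
    slice_mm: float = 2.0,
) -> MaterialVolume:
    """Procedural abdominal phantom for the dual-contrast scenario.

    Emulates a delayed-iodine / early-gadolinium protocol: gadolinium
    (0.5-3.5 mg/mL) sits in the renal collecting systems, iodine in the aorta
    (4-7 mg/mL) and intra-organ vessels (2-5 mg/mL); exactly two calcified
    plaques lie on the aortic wall at liver level; spine and ribs are cortical
    bone (background class for the classifier).  Anatomy is 2.5-D: organ
    contours are scaled smoothly along z.
    """
    if size_group not in SIZE_GROUPS:
        raise ValueError(
            f"unknown size group {size_group!r}; expected one of {list(SIZE_GROUPS)}"
        )
    rng = np.random.default_rng(seed)
    lo, hi = SIZE_GROUPS[size_group]
    lateral_cm = float(rng.uniform(lo, hi))
    if fov_cm is None:
        fov_cm = lateral_cm + 5.0

    a = lateral_cm / 2.0  # lateral semi-axis
    b = 0.72 * a  # AP semi-axis; +y is posterior
    spine_c = (0.0, 0.62 * b)
    spine_r = min(1.6, 0.22 * b)
    aorta_c = (-0.12 * a, spine_c[1] - spine_r - 1.4)
    aorta_r = 1.0
    aorta_iodine = float(rng.uniform(4.0, 7.0))
    gd_conc = float(rng.uniform(0.5, 3.5))

    # liver on the patient's right (image left, x<0 is arbitrary; use x>0)
    liver_c = (0.35 * a, -0.05 * b)
    liver_ax, liver_ay = 0.42 * a, 0.52 * b
    n_vessels = int(rng.integers(3, 6))
    vessels = []
    for _ in range(n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.7)
        vx = liver_c[0] + rad * liver_ax * np.cos(ang) * 0.8
        vy = liver_c[1] + rad * liver_ay * np.sin(ang) * 0.8
        vessels.append(((vx, vy), rng.uniform(0.2, 0.4), float(rng.uniform(2.0, 5.0))))

    kidney_cs = [(-0.55 * a, 0.30 * b), (0.55 * a, 0.30 * b)]
    kid_ax, kid_ay = 0.14 * a, 0.19 * b

    # two plaques on the aortic wall at liver level (middle slices)
    band = np.arange(nz // 3, max(2 * nz // 3, nz // 3 + 1))
    if len(band) < 2:
        band = np.arange(nz)
    plaque_slices = sorted(rng.choice(band, 2, replace=len(band) < 2))
    plaque_specs = []
    for ps in plaque_slices:
        ang = rng.uniform(0, 2 * np.pi)
        pr = float(rng.uniform(0.15, 0.30))  # 3-6 mm diameter
        pc = (
            aorta_c[0] + (aorta_r - 0.5 * pr) * np.cos(ang),
            aorta_c[1] + (aorta_r - 0.5 * pr) * np.sin(ang),
        )
        plaque_specs.append((int(ps), pc, pr, float(rng.uniform(200.0, 400.0))))

    labels = np.zeros((nz, n, n), dtype=np.int8)
    conc = {
        m: np.zeros((nz, n, n), dtype=np.float32) for m in CONCENTRATIONS
    }
    organs = {
        name: np.zeros((nz, n, n), dtype=bool)
        for name in ("liver", "kidneys", "collecting_system", "aorta", "plaques")
    }

    vol = MaterialVolume(
        labels=labels, concentrations=conc, fov_cm=fov_cm, slice_mm=slice_mm
    )
    yy, xx = vol.grid_cm()
    zc = (nz - 1) / 2.0

    for k in range(nz):
        s = 1.0 - 0.05 * abs(k - zc) / max(zc, 1.0)  # gentle craniocaudal taper
        lab = labels[k]
        body = _ellipse(yy, xx, (0.0, 0.0), a * s, b * s)
        lab[body] = Label.SOFT_TISSUE

        liver = _ellipse(yy, xx, liver_c, liver_ax * s, liver_ay * s) & body
        organs["liver"][k] = liver
        for vc, vr, vi in vessels:
            vm = _disc(yy, xx, vc, vr) & liver
            lab[vm] = Label.WATER
            conc["iodine"][k][vm] = vi

        for kc in kidney_cs:
            kid = _ellipse(yy, xx, kc, kid_ax * s, kid_ay * s) & body
            organs["kidneys"][k] |= kid
            cs = _ellipse(yy, xx, kc, 0.45 * kid_ax * s, 0.45 * kid_ay * s) & body
            organs["collecting_system"][k] |= cs
            lab[cs] = Label.WATER
            conc["gadolinium"][k][cs] = gd_conc

        aorta = _disc(yy, xx, aorta_c, aorta_r)
        organs["aorta"][k] = aorta
        lab[aorta] = Label.WATER
        conc["iodine"][k][aorta] = aorta_iodine

        spine = _disc(yy, xx, spine_c, spine_r)
        lab[spine & body] = Label.BONE
        # ribs: bone discs inset along the posterior-lateral body contour
        for ang in np.linspace(0.15 * np.pi, 0.85 * np.pi, 6):
            rc = (0.88 * a * s * np.cos(ang), 0.88 * b * s * np.sin(ang))
            rib = _disc(yy, xx, rc, 0.45) & body
            lab[rib] = Label.BONE
            conc["iodine"][k][rib] = 0.0
            conc["gadolinium"][k][rib] = 0.0

    for ps, pc, pr, pca in plaque_specs:
        pm = _disc(yy, xx, pc, pr)
        labels[ps][pm] = Label.WATER
        conc["calcium"][ps][pm] = pca
        conc["iodine"][ps][pm] = 0.0
        organs["plaques"][ps] |= pm

    vol.organs = organs
    vol.meta = {
        "kind": "virtual_patient",
        "size_group": size_group,
        "diameter_cm": lateral_cm,
        "seed": int(seed),
        "aorta_iodine": aorta_iodine,
        "gadolinium": gd_conc,
        "n_plaques": 2,
        "phantom_id": f"vp_{size_group}_s{seed}",
    }
    return vol


def class_label_for_voxel(composition: MaterialComposition) -> FeatureClass:
    """Map one voxel composition to its feature class.

    Tissue dominates (any voxel containing soft tissue is class TISSUE);
    skeletal bone counts as background — only vascular calcium, modeled as
    calcium in water, is the positive calcium class.
    """
    if composition.solvent == "soft_tissue":
        return FeatureClass.TISSUE
    if composition.solvent == "cortical_bone":
        return FeatureClass.BACKGROUND
    c = composition.solutes
    if c.get("calcium", 0.0) > 0:
        return FeatureClass.CALCIUM
    if c.get("iodine", 0.0) > 0 or c.get("gadolinium", 0.0) > 0:
        return FeatureClass.CONTRAST
    return FeatureClass.BACKGROUND


def feature_class_map(volume: MaterialVolume) -> np.ndarray:
    """Vectorized 4-class ground-truth map for a whole volume."""
    lab = volume.labels
    iodine = volume.concentrations["iodine"]
    gado = volume.concentrations["gadolinium"]
    calcium = volume.concentrations["calcium"]

    cls = np.zeros(lab.shape, dtype=np.int8)
    water = lab == Label.WATER
    cls[water & (calcium > 0)] = FeatureClass.CALCIUM
    cls[water & (calcium == 0) & ((iodine > 0) | (gado > 0))] = FeatureClass.CONTRAST
    cls[lab == Label.SOFT_TISSUE] = FeatureClass.TISSUE
    return cls
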