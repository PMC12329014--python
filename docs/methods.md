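# Methods

`specmat` is an in-silico framework for multi-material quantification in
two-bin photon-counting CT (PCCT): it generates digital phantoms with exact
ground truth, simulates spectral acquisitions, and decomposes the resulting
image pairs into iodine, gadolinium and calcium concentration maps with
either a classical sensitivity-matrix solve or a two-stage U-Net model.
This note records the models, the defaults and why, and what the synthetic
world does and does not establish.

## Attenuation physics

A voxel is a solvent (water, soft tissue, or cortical bone) plus dilute
solute concentrations `c_i` in mg/mL:

    mu_tot(E) = rho_s * (mu/rho)_s(E) + sum_i (c_i / 1000) * (mu/rho)_i(E)

Solvent displacement is ignored (dilute-solution approximation), matching
how mg/mL phantom inserts are specified in practice. Mass-attenuation
anchors are shipped as plain-text tables sampled from standard published
compilations and resampled log-log to a 1 keV grid over 10–120 keV; the
iodine (33.17 keV) and gadolinium (50.24 keV) K edges are encoded as double
anchor points so the discontinuity survives interpolation. The anchor
values are approximations of the published compilations to a few percent;
nothing downstream depends on their absolute accuracy, only on their
ordering and edge structure, which the test suite pins.

The source is an analytic filtered-bremsstrahlung spectrum, Kramers shape
`(kV − E)/E` hardened by an aluminum filter. Default 120 kV with 7 mm Al,
chosen so the mean energy (59 keV) sits where clinically filtered abdominal
beams do; there are no characteristic lines. Two ideal counting bins split
the spectrum at the 20/65 keV thresholds.

## CT simulator

Per axial slice: parallel-beam polychromatic forward projection (ray-driven
Radon transform of each basis map, Beer–Lambert per energy, summed into the
two bins), independent Poisson counting noise per detector cell and view,
log normalization against an analytic air scan, and filtered back
projection with a Hann-apodized ramp filter onto a 512×512, 30 cm FOV grid
(2.0 mm slices). Canonical geometry is 720 views with detector pitch equal
to the phantom pixel pitch.

Numerical choices:

* **Water linearization.** Before FBP, each log measurement is mapped
  through the inverted polychromatic water curve `p(t)` and rescaled by the
  bin's fluence-weighted water attenuation. This is the standard
  single-material beam-hardening correction a quantitative reconstruction
  kernel applies; it makes pure-water paths exactly linear, so water
  reconstructs to 0 HU with no cupping and insert HU is linear in
  concentration to R² > 0.99. Residual beam hardening from the contrast
  agents themselves is not corrected.
* **Count floor.** Counts are clipped at 1 before the log; the clipped
  fraction is recorded as a photon-starvation diagnostic and flagged in the
  acquisition metadata when it exceeds 0.1 %.
* **Flux calibration.** The photons-per-mAs constant (5×10⁴ per detector
  cell per view) was fixed once so the 20 cm water pilot at 200 mAs
  reconstructs with ≈3 HU low-bin noise at canonical geometry — the noise
  regime of the study's smallest phantom at its highest dose tier. It is
  not revisited per experiment.
* **Air.** Voxels outside the object attenuate nothing, so empty
  reconstructions sit at −1000 HU.

Not modeled, deliberately: scatter, detector energy response (charge
sharing, pile-up), electronic noise, bowtie filtration, helical geometry,
iterative reconstruction. The decomposition consumes reconstructed axial HU
images, so geometry fidelity beyond that interface is out of scope.

## Phantoms

All generators are deterministic given a seed and emit a label map
(air/water/soft-tissue/bone) plus per-material concentration maps.

* **Cylindrical insert phantoms** (20/28/36/42 cm): two rings of eight
  inserts at radii 3.5 and 7 cm, insert diameters uniform in 1.5–3.0 cm,
  evenly spaced angles with small jitter, non-overlap enforced with bounded
  retries. Four of the sixteen inserts are split along a random diameter
  into two half-discs of different material classes. Seven insert classes:
  soft tissue; iodine 0–7.5; gadolinium 0–5; calcium 0–300;
  iodine+gadolinium mixture (each agent in half its pure range — the source
  protocol states the class but not its ranges); iodine/soft-tissue 0–2.5;
  gadolinium/soft-tissue 0–4 mg/mL.
* **Pilot water cylinders** at 20/25/30/35/40 cm, no inserts.
* **Procedural virtual patients**, a stand-in for licensed anthropomorphic
  phantom libraries: elliptical body with lateral diameter drawn from the
  size-group ranges (small 23.0–25.7 … extra-large 38.0–43.3 cm), liver
  with 3–5 iodine vessels (2–5 mg/mL), aorta at 4–7 mg/mL, kidneys whose
  collecting systems carry the gadolinium (0.5–3.5 mg/mL) of an early
  bolus, exactly two calcified plaques (3–6 mm, 200–400 mg/mL Ca) on the
  aortic wall at liver level, and spine/ribs as cortical bone. Anatomy is
  2.5-D: per-slice contours scaled smoothly along z. Organ masks ship with
  the volume so evaluation can address anatomy directly.

The classifier's four ground-truth classes are derived per voxel: tissue
dominates (any soft-tissue voxel is class iv, including contrast-in-tissue
mixtures); calcium in water is class ii; iodine/gadolinium in water class
iii; everything else — water, air, and skeletal bone — is background.
Only vascular calcium is a positive class; bone is background by design.

## Isonoise dose calibration

Noise is the HU standard deviation in a centered water ROI (default radius
3 cm), averaged over slices. The pilot grid (5 sizes × 5 currents:
25/50/100/150/200 mAs) is fitted per bin with an OLS plane
`noise ≈ a + b·diameter + c·mAs`; the low-bin plane is inverted for the
mAs that hits a target noise, clipped to a protocol range with a warning,
with an explicit infeasibility error otherwise. The canonical dose tiers
are the study's tube currents per size (three tiers for cylinders, two for
virtual patients); at reduced simulator scales the per-tier noise targets
are obtained by evaluating the fitted plane at those currents, which keeps
the tier structure meaningful in a different flux regime.

**Known limitation (measured, not hidden):** true CT noise behaves like
`K·exp(α·d)/√mAs`, so a plane over the full pilot grid carries ~20–25 %
relative lack of fit (R² ≈ 0.75 at desk scale). Isonoise-selected currents
therefore equalize measured noise across sizes only to roughly ±15 % around
the *achieved* common level, and the absolute level can sit ~10–25 % below
the nominal target; no single target is even feasible for all five pilot
sizes at once. The acceptance test for this property is accordingly strict
and currently fails for the 35 cm size — kept red as an honest statement of
what a linear noise model can do, since replacing the plane with a
curvature-aware model would leave the stated calibration procedure.

## Classical decomposition

The linear model `X = Γ Y` maps basis-material concentrations Y (mg/mL) to
per-bin measurements X, taken in HU (affine-equivalent to attenuation with
water as shared reference, and the currency of the pipeline). Γ is
calibrated by least squares from noiseless single-material inserts — ROI
means eroded by two pixels so reconstruction-kernel partial volume does not
bias the sensitivities low — and solved per voxel with the pseudo-inverse.
Nonnegativity is an optional post-hoc clamp (flagged in the output), never
a constrained solve, so the oracle stays exactly linear. Requesting three
materials from two bins raises a rank error: with two energy channels the
system is structurally underdetermined, which is the motivation for the
learned approach. On noiseless data the oracle recovers ROI concentrations
to ~1 %; under Poisson noise the decomposed maps are noisier than the
measurements (condition number of Γ ≈ 8 for the iodine/gadolinium basis).

## Two-stage network

Inputs are 4-channel slices: low-bin HU, high-bin HU (both scaled by
1/1000, a fixed affine map recorded with the stack), distance from the
object centroid and distance from the object edge (both in cm, unscaled) —
the two distance maps encode position relative to patient size. Slices are
cut into 64×64 patches with 16 px overlap (stride 48, terminal anchors
clamped to the border); stitching averages overlaps and renormalizes
probability channels.

The **feature network** is a U-Net (3×3 convolutions + batch norm + ReLU,
2×2 max pooling) whose encoder follows the fixed plan 16×(64×64) →
32×(32×32) → 64×(16×16) → 128×(8×8) → 256×(4×4), with a transposed-conv
decoder back to 16 channels at 64×64 and a 1×1 convolution + softmax over
the four classes. The **concentration network** is a second U-Net with the
same trunk that consumes the classifier's 16 penultimate channels and emits
iodine/gadolinium/calcium (softplus, scaled by 2/2/80 mg/mL per unit so
calcium's hundreds-of-mg/mL range is reachable) plus a sigmoid tissue
probability. Its loss — unspecified in the source protocol — is masked MSE
on the concentration channels (masked to non-background voxels, residuals
normalized by the output scales) plus binary cross-entropy on the tissue
channel, the standard choice consistent with RMSE/MAPD evaluation. At
prediction time, voxels the classifier assigns to background are zeroed in
the concentration maps; the tissue probability is reported, not used for
masking.

The layers are implemented directly on numpy (im2col convolution, manual
backprop, Adam) because the runtime environment ships no deep-learning
framework; gradients were verified against float64 finite differences. The
architecture is not exactly rotation-equivariant (transposed convolutions
break it), so the rotation check on symmetric phantoms is a ≥90 %
class-agreement bound, not an identity.

## Training protocol

Two phases: the feature network trains on per-voxel cross-entropy; then its
weights are frozen (verified by hashing every parameter byte before and
after) and the concentration network trains on its features. Adam at
lr 1e-4, batch 256, up to 100 epochs with reduce-on-plateau (×0.1) and
early stopping (patience 10 epochs — unstated in the source, a standard
choice) on validation loss; the best-validation checkpoint is returned.
Patches containing any labeled voxel are kept; all-background patches are
subsampled to 10 % to limit class imbalance.

Cross-validation: the canonical cylindrical dataset is 12 phantoms × 3 dose
tiers = 36 acquisitions. Each of 12 folds holds out one whole phantom (its
3 tiers) as the test set — 3/4/29 test/validation/train acquisitions —
so no phantom straddles the test boundary at different doses; validation
acquisitions are redrawn per fold from the same seed stream. The hybrid
experiment retrains on cylinders plus the first n virtual-patient phantoms
(both dose levels each) against a fixed held-out virtual-patient set, and
reports one row per (n, seed, class).

A `Scale` bundle (`smoke`/`desk`/`full`) sets grid size, view count,
phantom counts, epochs and batch size; all structural contracts are
scale-free, and the reduced scales exist so the suite and the end-to-end
script run on one CPU in minutes. `full` is the canonical protocol
(512 grids, 720 views, 15 slices, 100 epochs) and is CPU-hours.

## Evaluation

ROIs are regions of constant ground-truth concentration (every insert,
half-disc, vessel, collecting system and plaque carries a distinct sampled
value, so exact-value grouping reconstructs the ROI layout on any grid),
eroded one pixel in-plane against edge partial volume; each yields mean and
SD of the predicted map across slices. Metrics: Pearson correlation, RMSE
(mg/mL), and MAPD (%) over rows with strictly positive truth only — rows
with zero truth still enter RMSE and the mean-absolute-difference tables.
Classification is voxel-wise: one-vs-rest sensitivity/specificity per
class, overall accuracy, and a contrast-class-restricted accuracy for the
iodine/gadolinium pair. Condition dependence: mean absolute difference
stratified by (size, isonoise level), and per material a linear
mixed-effects model `predicted ~ size + mAs` with a random intercept per
phantom (our reading of the ambiguous covariance wording; an OLS fallback
is flagged if the mixed fit fails), reporting estimate, SE, Wald CI/F/p per
fixed effect, followed by an ANOVA of the residuals by tube current and
size.

## What a green suite establishes — and what it does not

The synthetic world has exact ground truth, ideal counting detectors, a
known spectrum and no anatomy beyond procedural organs. Green tests
establish that the physics is internally consistent (linearity, K-edge
ordering, HU anchors), that the classical oracle and the metrics are
mathematically correct, that the network machinery honors its contracts
(channel plan, freezing, patch coverage, determinism), and that the
qualitative findings reproduce: the cylinders-to-anatomy generalization gap
closes as virtual patients enter training, noise rises with size and falls
with dose, and decomposition amplifies noise. They do not establish
clinical accuracy numbers: absolute HU, doses, and trained-model MAPD
depend on the real scanner's spectrum, detector response and anatomy, none
of which this simulator claims.
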