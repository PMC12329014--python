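"""The pilot noise study and isonoise dose selection.

Measures image noise over the water-phantom pilot grid (5 sizes x 5 tube
currents), fits the linear noise model per energy bin, and inverts it to
pick tube currents that match a noise target across phantom sizes.
"""

from specmat import fit_noise_model, mas_for_isonoise, run_pilot

# reduced grids keep this a ~1 minute demonstration
pilot = run_pilot(seed=2, n=128, nz=1, n_views=160, recon_matrix=128)
print("pilot measurements (low bin, HU sd):")
low = pilot[pilot["bin"] == "low"].pivot(
    index="diameter_cm", columns="mAs", values="noise_hu"
)
print(low.round(2).to_string())

model = fit_noise_model(pilot)
a, b, c = model.coeffs["low"]
print(f"\nlow-bin plane: noise = {a:.2f} + {b:.3f}*diameter {c:+.4f}*mAs  "
      f"(R^2 {model.diagnostics['low']['r_squared']:.2f})")
# bigger phantoms are noisier (b > 0); more dose is quieter (c < 0)

target = model.predict(35.0, 100.0)
print(f"\nisonoise target {target:.1f} HU -> selected tube currents:")
for d in (30.0, 35.0, 40.0):
    print(f"  {d:.0f} cm phantom: {mas_for_isonoise(model, d, target):6.1f} mAs")
# The same image-noise level then costs far more dose in a large patient —
# the trade-off the study's dose tiers are built on.
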