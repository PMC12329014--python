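"""The whole study in one call: phantoms -> doses -> training -> statistics.

Runs the end-to-end pipeline at smoke scale (a couple of minutes) and prints
the tables it produces: quantification metrics, classification metrics, the
mean-absolute-difference breakdown by acquisition condition, and the linear
mixed-effects condition analysis.
"""

from specmat import run_pipeline

results = run_pipeline(seed=0, scale="smoke", outdir="scratch/pipeline_demo")

print("ROI quantification (held-out cylinder acquisitions):")
print(results["regression_metrics"].round(2).to_string(index=False))

print("\nsensitivity-matrix baseline on the same acquisitions:")
print(results["baseline_regression_metrics"].round(2).to_string(index=False))

print("\nmean absolute difference by size and isonoise level (mg/mL):")
print(results["mad_by_condition"].round(3).to_string(index=False))

if "mixed_model" in results:
    print("\nmixed-effects condition analysis (estimate per fixed effect):")
    cols = ["material", "effect", "estimate", "se", "f_stat", "p_value"]
    print(results["mixed_model"][cols].round(3).to_string(index=False))

print("\nvirtual-patient classification:")
print(results["vp_classification_metrics"].round(3).to_string(index=False))
# At smoke scale the network trains for two epochs, so the numbers gauge the
# plumbing, not attainable accuracy; scale="desk" or "full" raises fidelity.
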