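"""Consecutive-timepoint comparisons on a labeling kinetics experiment.

Six timepoints (0, 1, 2, 4, 6, 24 h) produce five comparison families
(1vs0 … 24vs6). A feature is time-responsive if it is significant in at
least one consecutive interval after FDR adjustment.
"""

from isodiff import generate_preset, time_responsive, timecourse_comparisons

dataset, _ = generate_preset("timecourse_p3", seed=42)

results = timecourse_comparisons(
    dataset, condition="control", test="t_test", seed=42
)
print("comparison families:", sorted(set(results["comparison"]),
                                     key=list(results["comparison"]).index), "\n")

flags = time_responsive(results)
fc = flags[flags["quantity"] == "fractional_contribution"]
print(fc.to_string(index=False))
# Every tracer-incorporating metabolite responds in enrichment (its φ
# climbs from 0 toward steady state); the unlabeled control does not.
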