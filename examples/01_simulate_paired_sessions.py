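"""Simulate one subject's paired oral / isoglycaemic-IV sessions.

Builds a severely obese NGT subject, runs the triple-load oral test
(25/75/100 g) and derives the matching intravenous dextrose schedule,
then prints how well the intravenous arm replicates the oral
glycaemia — the defining property of the isoglycaemic design.
"""

import numpy as np

import glucoroute as gr

subject = gr.SubjectProfile("demo", "NGT", age=46, weight=150, bmi=52,
                            basal_glucose=5.35, basal_insulin=0.0,
                            basal_cpeptide=1.0)
phys = gr.default_physiology("NGT")
cfg = gr.CohortConfig(rng_seed=1)

oral, oral_truth = gr.simulate_oral_session(subject, phys, cfg)
igivi, igivi_truth = gr.simulate_igivi_session(subject, phys, cfg, oral_truth)

on = oral_truth.times >= 0
print(f"oral peak glucose     : {oral_truth.glucose[on].max():.2f} mmol/l")
print(f"oral peak insulin     : {oral_truth.insulin[on].max():.0f} pmol/l")
print(f"IGIVI peak insulin    : {igivi_truth.insulin[on].max():.0f} pmol/l")

target = np.interp(igivi_truth.times[on], oral_truth.times, oral_truth.glucose)
rms = np.sqrt(np.mean((igivi_truth.glucose[on] - target) ** 2))
print(f"glycaemia tracking RMS: {rms:.3f} mmol/l")
print(f"total dextrose infused: "
      f"{np.trapezoid(igivi_truth.gir[on], igivi_truth.times[on]) * subject.weight * 180.156 / 1e6:.0f} g")
print()
print("The two sessions share one glycaemic profile (RMS well below the")
print("assay noise), while oral insulin is amplified by the incretin")
print("effect — exactly the contrast the paired design isolates.")
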