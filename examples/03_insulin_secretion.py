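"""Deconvolve the insulin secretion rate from plasma C-peptide.

C-peptide escapes the liver, so its plasma curve plus population
two-compartment kinetics gives prehepatic secretion. The example
quantifies the incretin effect: the same glycaemia elicits far more
secretion when glucose is swallowed.
"""

import numpy as np

import glucoroute as gr

subject = gr.SubjectProfile("demo", "NGT", 46, 150, 52, 5.35, 0.0, 1.0)
phys = gr.default_physiology("NGT")
cfg = gr.CohortConfig(rng_seed=1)
oral, oral_truth = gr.simulate_oral_session(subject, phys, cfg)
igivi, _ = gr.simulate_igivi_session(subject, phys, cfg, oral_truth)

kin = gr.population_kinetics(subject)
print(f"C-peptide kinetics: t1/2 = {kin.t_half_short}/{kin.t_half_long} min, "
      f"V1 = {kin.v1:.1f} l, basal ISR = {kin.basal_isr(1000.0):.0f} pmol/min")

for label, session in (("oral ", oral), ("IGIVI", igivi)):
    res = gr.deconvolve_isr(session.cpeptide, kin)
    means = [gr.total_isr(res, s) for s in gr.SEGMENTS]
    print(f"{label}: mean ISR per load = "
          + " / ".join(f"{m:.0f}" for m in means)
          + f" pmol/min (residual {res.residual_rms:.0f} pmol/l)")
print()
print("Oral secretion exceeds the isoglycaemic intravenous secretion in")
print("every segment: that excess is the incretin effect.")
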