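"""Fit the three-load oral minimal model of beta-cell sensitivity.

Eight parameters (three static betas, three dynamic K_d's, threshold
h, delay tau) are estimated in one weighted fit of the full 0-360 min
C-peptide record; the example checks recovery against the generator's
known values and prints the derived phi indices.
"""

import numpy as np

import glucoroute as gr

subject = gr.SubjectProfile("demo", "NGT", 46, 150, 52, 5.35, 0.0, 1.0)
phys = gr.default_physiology("NGT", beta_true=(105, 85, 120),
                             kd_true=(480, 380, 550))
cfg = gr.CohortConfig(rng_seed=1)
session, _ = gr.simulate_oral_session(subject, phys, cfg)

fit = gr.fit_three_segment(session)
gain = phys.incretin_gain  # oral sessions express incretin-amplified values

print(f"{'segment':>8s}  {'beta est':>9s} {'beta true':>9s}"
      f"  {'Kd est':>8s} {'Kd true':>8s}  {'phi_global':>10s}")
for i in range(3):
    print(f"{i + 1:8d}  {fit.beta[i]:9.1f} {gain * phys.beta_true[i]:9.1f}"
          f"  {fit.kd[i]:8.0f} {gain * phys.kd_true[i]:8.0f}"
          f"  {fit.phi_global[f'segment{i + 1}']:10.1f}")
print(f"threshold h = {fit.h:.2f} mmol/l, delay tau = {fit.tau:.1f} min, "
      f"weighted residual = {100 * fit.residual_rms:.1f}% of basal C-peptide")
print()
print("Despite 5% assay noise the static sensitivities (phi_s = beta) come")
print("back close to the incretin-scaled truth; phi_global combines static")
print("and dynamic secretion per unit of suprathreshold glycaemia.")
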