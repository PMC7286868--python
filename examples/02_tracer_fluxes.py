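"""Reconstruct glucose fluxes from the dual-tracer enrichments.

Applies the non-steady-state Steele equation to a simulated oral
session and compares the reconstructed total appearance, oral
appearance and endogenous production against the generator's truth.
"""

import numpy as np

import glucoroute as gr

subject = gr.SubjectProfile("demo", "NGT", 46, 150, 52, 5.35, 0.0, 1.0)
phys = gr.default_physiology("NGT")
cfg = gr.CohortConfig(rng_seed=1).noise_free()
session, truth = gr.simulate_oral_session(subject, phys, cfg)

flux = gr.analyze_session(session, gr.PoolModel())

ra_true = np.interp(flux.times, truth.times, truth.ra_total)
egp_true = np.interp(flux.times, truth.times, truth.egp)
print(f"mean total Ra (est)  : {flux.ra_total.mean():.1f} umol/kg/min")
print(f"mean total Ra (true) : {ra_true.mean():.1f} umol/kg/min")
print(f"Ra RMSE / mean       : {np.sqrt(np.mean((flux.ra_total - ra_true)**2)) / ra_true.mean():.1%}")
print(f"EGP RMSE / basal EGP : {np.sqrt(np.mean((flux.egp - egp_true)**2)) / phys.egp_b:.1%}")
seg1 = flux.times <= 120
print(f"segment-1 oral Ra    : {np.trapezoid(flux.ra_oral[seg1], flux.times[seg1]):.0f} umol/kg"
      f"  (25 g load = {25e6 / 180.156 / subject.weight:.0f} umol/kg ingested)")
print()
print("On noise-free data the Steele chain recovers the latent fluxes to")
print("a few percent; the oral-Ra integral stays below the ingested dose,")
print("as tracer mass balance demands.")
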