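"""Compute the paired insulin-sensitivity / secretion index panel.

Runs the whole per-session analysis (fluxes, deconvolution, indices)
on one subject's paired sessions and prints the headline contrasts:
glucose clearance per unit insulin (MCR/I), total secretion, insulin
clearance and the disposition index.
"""

import glucoroute as gr
from glucoroute.pipeline import analyze_one

subject = gr.SubjectProfile("demo", "NGT", 46, 150, 52, 5.35, 0.0, 1.0)
phys = gr.default_physiology("NGT")
cfg = gr.CohortConfig(rng_seed=1)
oral, oral_truth = gr.simulate_oral_session(subject, phys, cfg)
igivi, _ = gr.simulate_igivi_session(subject, phys, cfg, oral_truth)

a_oral = analyze_one(oral, fit_betacell=False)
a_igivi = analyze_one(igivi, fit_betacell=False)

rows = [
    ("MCR/I  [ml/min/kg per nmol/l]", "mcr_i", "mean"),
    ("total ISR        [pmol/min]", "isr", "mean"),
    ("insulin clearance   [l/min]", "insulin_clearance", "session"),
    ("disposition index", "di", "mean"),
]
print(f"{'index':32s}  {'oral':>8s}  {'IGIVI':>8s}")
for label, attr, key in rows:
    o = getattr(a_oral.panel, attr)[key]
    i = getattr(a_igivi.panel, attr)[key]
    print(f"{label:32s}  {o:8.2f}  {i:8.2f}")
print(f"{'insulinogenic index':32s}  {a_oral.panel.insulinogenic_index:8.1f}"
      f"  {a_igivi.panel.insulinogenic_index:8.1f}")
print(f"{'Adipo-IR [mmol/l x pmol/l]':32s}  {a_oral.panel.adipo_ir:8.1f}"
      f"  {a_igivi.panel.adipo_ir:8.1f}")
print()
print("The oral route shows lower sensitivity (MCR/I), higher secretion,")
print("lower insulin clearance and a lower disposition index — the")
print("compensatory-insulin-resistance pattern of oral glucose delivery.")
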