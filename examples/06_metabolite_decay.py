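"""Insulin-driven metabolite disappearance, compared between routes.

Fits decaying exponentials to lactate and amino-acid curves from the
paired sessions, normalises the coefficients by insulin exposure, and
compares routes with a Z test — the route difference widens once the
unequal insulin levels are accounted for.
"""

import glucoroute as gr
from glucoroute.metabolites import fit_decay, normalize_beta, ztest_betas

subject = gr.SubjectProfile("demo", "NGT", 46, 150, 52, 5.35, 0.0, 1.0)
phys = gr.default_physiology("NGT")
cfg = gr.CohortConfig(rng_seed=1)
oral, oral_truth = gr.simulate_oral_session(subject, phys, cfg)
igivi, _ = gr.simulate_igivi_session(subject, phys, cfg, oral_truth)

for met in ("lactate", "isoleucine"):
    fits = {}
    for label, session in (("oral", oral), ("igivi", igivi)):
        f = fit_decay(session.metabolites[met])
        fits[label] = f
        bn = normalize_beta(f, session.insulin)
        print(f"{met:11s} {label:5s}: beta = {f.beta:.5f} 1/min "
              f"(SE {f.beta_se:.5f}), per-insulin = {bn:.2e}")
    z, p = ztest_betas(fits["oral"], fits["igivi"])
    print(f"{met:11s} oral vs igivi: Z = {z:+.2f}, p = {p:.3f}")
print()
print("Raw decay is faster intravenously despite lower insulin; per unit")
print("of insulin the oral route clears metabolites far less effectively —")
print("insulin's anti-proteolytic/anti-lipolytic action is blunted after")
print("oral glucose.")
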