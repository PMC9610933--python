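"""The three-drug loss-of-response surface.

Evaluates P(MOAA/S < 2) at a few concentration combinations and shows the
interaction effect: the probability of the combination exceeds what the
purely additive surface (all interaction coefficients zero) predicts.
"""

from dataclasses import replace

from sedsim import default_config, lor_probability

sp = default_config().surface
additive = replace(sp, beta_ma=0.0, beta_mp=0.0, beta_ap=0.0, beta_map=0.0)

cases = [
    ("no drug", 0.0, 0.0, 0.0),
    ("midazolam alone at its C50", sp.C50_mid, 0.0, 0.0),
    ("half-C50 of each drug", sp.C50_mid / 2, sp.C50_alf / 2, sp.C50_prop / 2),
    ("typical sedation mix", 0.05, 100.0, 1.5),
]
print(f"{'combination':32s} {'P(LOR)':>8s} {'additive':>9s}")
for label, cm, ca, cp in cases:
    p = lor_probability(cm, ca, cp, sp)
    p0 = lor_probability(cm, ca, cp, additive)
    print(f"{label:32s} {p:8.3f} {p0:9.3f}")
print(
    "\nConcentrations: midazolam/propofol in ug/mL, opioid in alfentanil-\n"
    "equivalent ng/mL.  Where P exceeds the additive column the configured\n"
    "interaction terms predict supra-additive (synergistic) sedation."
)
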