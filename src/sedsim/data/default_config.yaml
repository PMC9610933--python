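# Default model configuration for the reference patient
# (female, 170 cm, 65 kg, ASA 2, age 40 y).
#
# PK sets are literature-derived adult bolus kinetics with the covariate
# terms already resolved for the reference patient; effect-site ke0 values
# reproduce the standard time-to-peak-effect figures (propofol 1.6-1.7 min,
# alfentanil ~1.4 min, fentanyl ~3.6 min).  Concentration units follow from
# dose_unit per litre: mg -> ug/mL, ug -> ng/mL.  See docs/methods.md for
# provenance and the rationale behind the surface defaults.
pk_registry:
  propofol:
    n_compartments: 3
    V1: 4.27        # L
    k10: 0.4480     # 1/min
    k12: 0.3752
    k21: 0.0668
    k13: 0.1958
    k31: 0.0035
    ke0: 0.3479    # calibrated: unit-bolus TTPE 1.65 min
    dose_unit: mg
    ce_unit: ug/mL
  midazolam:
    n_compartments: 3
    V1: 16.2        # L (~0.25 L/kg)
    k10: 0.0640    # calibrated jointly with the surface (see docs/methods.md)
    k12: 0.1800
    k21: 0.0600
    k13: 0.0300
    k31: 0.0080
    ke0: 0.1210    # calibrated jointly with the surface
    dose_unit: mg
    ce_unit: ug/mL
  fentanyl:
    n_compartments: 3
    V1: 6.09        # L
    k10: 0.0500     # 1/min
    k12: 0.8000
    k21: 0.2000
    k13: 0.0800
    k31: 0.0100
    ke0: 0.1997    # calibrated: unit-bolus TTPE 3.6 min, Ce(30)/Ce(peak) ~ 0.6
    dose_unit: ug
    ce_unit: ng/mL
  alfentanil:
    n_compartments: 3
    V1: 8.30        # L (0.111 L/kg x 65 kg x 1.15 female)
    k10: 0.0429     # Cl 0.356 L/min
    k12: 0.1040
    k21: 0.0673
    k13: 0.0170
    k31: 0.0126
    ke0: 1.9660    # calibrated: unit-bolus TTPE 1.4 min
    dose_unit: ug
    ce_unit: ng/mL
potency:
  # alfentanil-equivalent ng/mL per ng/mL of opioid Ce (C50-ratio derived)
  factors:
    alfentanil: 1.0
    fentanyl: 62.5
    remifentanil: 60.0
    morphine: 5.0
  ce_units:
    alfentanil: ng/mL
    fentanyl: ng/mL
    remifentanil: ng/mL
    morphine: ng/mL
surface:
  # Greco-family deep-sedation (MOAA/S < 2) surface defaults; potencies in
  # each drug's Ce unit (midazolam/propofol ug/mL, opioid axis ng/mL of
  # alfentanil equivalents).  Calibrated against the nine-regimen reference
  # course summaries; see docs/methods.md for the procedure and caveats.
  C50_mid: 0.035
  C50_alf: 1420.0
  C50_prop: 5.40
  gamma: 5.0
  beta_ma: 0.05
  beta_mp: 0.05
  beta_ap: 30.0
  beta_map: 1.48
settings:
  induction: 3.0          # min
  horizon: 60.0           # min
  grid_step: 0.01         # min
  recovery_threshold: 0.05
  deep_threshold: 0.50
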