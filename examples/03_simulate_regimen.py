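"""Simulate one sedation course from total study doses.

Builds a rule-based bolus schedule (midazolam and fentanyl at induction,
propofol divided), runs the PK -> opioid-equivalence -> surface pipeline,
and reports the model-predicted recovery time T_rm and the fraction of the
procedure spent in deep sedation (P(LOR) > 50%).
"""

from sedsim import (
    DrugTotals,
    build_schedule,
    deep_sedation_ratio,
    default_config,
    predicted_recovery_time,
    simulate_course,
)

cfg = default_config()
totals = DrugTotals(midazolam_total=2.0, opioid_total=75.0, opioid_name="fentanyl",
                    propofol_total=120.0)
regimen = build_schedule(totals, T_p=20.0, regimen_id="demo")

print("schedule:")
for b in regimen.boluses:
    unit = "mg" if b.drug_name in ("midazolam", "propofol") else "ug"
    print(f"  {b.time:5.1f} min  {b.drug_name:10s} {b.amount:g} {unit}")

course = simulate_course(regimen, cfg.pk_registry, cfg.potency, cfg.surface, cfg.settings)
t_rm = predicted_recovery_time(course, cfg.settings.recovery_threshold)
ratio = deep_sedation_ratio(course, cfg.settings.deep_threshold)
print(f"\npredicted recovery time T_rm : {t_rm:.1f} min from simulation start")
print(f"intraprocedural deep sedation: {100 * ratio:.0f}% of the procedure window")
print(
    "\nT_rm is the first time after the sedation peak at which the predicted\n"
    "probability of MOAA/S < 2 falls below 5%; the deep-sedation ratio is the\n"
    "measure of the procedure window with that probability above 50%."
)
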