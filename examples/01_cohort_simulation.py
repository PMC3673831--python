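"""Simulate a lung-cancer-screening cohort and summarize it Table-1 style.

The generator draws demographics, smoking history, CT biomarkers and a COPD
label from a known logistic model, then spirometry consistent with the label.
"""

from copdct import CohortConfig, generate_cohort, summarize_cohort

records = generate_cohort(CohortConfig(n=1140, seed=1))
s = summarize_cohort(records)

print(f"subjects:                {s['n']}")
print(f"age (y):                 {s['age_mean']:.1f} +/- {s['age_sd']:.1f}")
print(f"BMI (kg/m2):             {s['bmi_mean']:.1f} +/- {s['bmi_sd']:.1f}")
print(f"current smokers:         {s['current_smoker_pct']:.1f} %")
print(f"packyears median (IQR):  {s['packyears_median']:.0f} "
      f"({s['packyears_iqr'][0]:.0f} - {s['packyears_iqr'][1]:.0f})")
print(f"COPD prevalence:         {s['copd_prevalence_pct']:.1f} %  ({s['copd_n']} subjects)")
print(f"  mild / moderate / severe: {s['mild_pct_of_copd']:.1f} / "
      f"{s['moderate_pct_of_copd']:.1f} / {s['severe_pct_of_copd']:.1f} % of COPD")
print(f"emphysema index IN-950:  median {s['in950_median']:.2f} % "
      f"(IQR {s['in950_iqr'][0]:.2f} - {s['in950_iqr'][1]:.2f})")
print(f"air trapping E/I:        median {s['ei_median']:.2f} "
      f"(IQR {s['ei_iqr'][0]:.2f} - {s['ei_iqr'][1]:.2f})")
print(f"Pi10 (mm):               {s['pi10_mean']:.2f} +/- {s['pi10_sd']:.2f}")
print()
print("A screening population of male heavy smokers: ~38% have spirometric")
print("COPD; the three CT biomarkers carry most of the diagnostic signal.")
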