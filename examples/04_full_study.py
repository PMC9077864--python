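"""Run the full synthetic scanning study and print its comparison tables.

Renders calibration and accuracy scans for every compensating material in
both scan modes, runs the whole ROI -> netOD -> fit -> uncertainty chain,
and prints the accuracy and uniformity summaries. Takes a few seconds.
"""

from clodscan import StudyConfig, run_calibration_study

report = run_calibration_study(StudyConfig(seed=42))
summary = report["summary"]

print("average dose difference (%, over 25/70 cGy and both modes):")
for material, value in summary["average_dose_diff_pct"].items():
    print(f"  {material:>3}: {value:5.2f}")

print("\nscan-uniformity CV (reflective mode):")
for material, cv in summary["uniformity_cv"]["reflective"].items():
    print(f"  {material:>3}: {cv:.4f}")

ratios = summary["mode_sensitivity_ratio"]
print("\nreflective/transmission sensitivity ratio per material:")
for material, ratio in ratios.items():
    print(f"  {material:>3}: {ratio:.3f}")

print(f"\nmaterial ranking by accuracy (best first): {summary['ranking_by_accuracy']}")
print(
    "\nThe bare air gap scatters the Newton's-ring phase between scans and\n"
    "ranks worst on both metrics; optical grease index-matches the gap and\n"
    "ranks best, the ordering the methodology is designed to demonstrate."
)
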