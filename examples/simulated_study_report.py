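"""Simulate a full multi-observer study and run the agreement analysis.

Generates a 100-case study (three imperfect human observers plus an
automatic detector; 84 cases complete for all humans), then computes the
pooled Dice, weighted kappa and Bland-Altman tables for every observer
pair, with case-bootstrap confidence intervals.
"""

from mitoagree import AnalysisConfig, BootstrapSpec, run_analysis
from mitoagree.simulate import SimulationParams, simulate_study

params = SimulationParams(n_cases=100, seed=11)
dataset, truth = simulate_study(params)
print(f"simulated {dataset.n_cases} cases, {truth.total_objects} true mitoses")

report = run_analysis(
    AnalysisConfig(
        annotations=dataset,
        observers=["obs1", "obs2", "obs3"],
        automatic="auto",
        bootstrap=BootstrapSpec(n_boot=500, seed=11),
    )
)
print(f"{report.n_cases} cases annotated by all observers\n")

cols = ["observer_a", "observer_b", "count_a", "count_b", "n_shared",
        "dice", "dice_ci_low", "dice_ci_high"]
print("pooled Dice per observer pair (with 95% case-bootstrap CI):")
print(report.dice_table[cols].round(4).to_string(index=False))

print("\nscore agreement (quadratic-weighted kappa) and count bias:")
k = report.kappa_table[["observer_a", "observer_b", "kappa",
                        "two_point_discrepancies"]]
ba = report.bland_altman_table[["mean_difference", "la_low", "la_high"]]
print(k.join(ba).round(4).to_string(index=False))
# Human pairs land around D ≈ 0.6-0.7 and kappa ≈ 0.8-0.9 — observers
# agree on totals far better than on individual objects.  The automatic
# detector shows lower D, more two-point score discrepancies, and a mild
# overcount (negative mean difference: its extra false positives outweigh
# its missed objects).
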