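"""Full per-condition pipeline: four pD scenarios to four solution states.

Generates the canonical scenario suite (random coil, folded dimer, 9:1
dimer mixture, open bundle), runs Guinier + Kratky + P(r) + model fits +
molecular-weight ratios against the coil standard, and prints the state
assignment with its evidence.
"""

from bundlesans import ConditionConfig, generate_bundle_scenarios, run_pipeline

scenarios = generate_bundle_scenarios(seed=0, n_conformations=8000)
model = {"pD 1.7": "debye", "pD ~13": "joint_clubs"}
dmax = {"pD 1.7": 90.0, "pD 6.4": 50.0, "pD 9.6": 50.0, "pD ~13": 120.0}

conditions = [
    ConditionConfig(curve=curve, label=label,
                    concentration=curve.concentration,
                    model=model.get(label, "none"), dmax=dmax[label],
                    is_standard=(label == "pD 1.7"),
                    n_conformations=1500)
    for label, (curve, _) in scenarios.items()
]

report = run_pipeline(conditions, seed=7)
for cond in report.conditions:
    print(f"{cond.label}: {cond.state}")
    for item in cond.evidence:
        print(f"   - {item}")

# The assignment needs at least two independent evidence items per state:
# the I(0)/C molecular-weight band and the Kratky shape class, plus the
# model-fit comparison for the open-bundle call.
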