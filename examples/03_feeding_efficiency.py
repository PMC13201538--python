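"""Feeding rates from predation trials and the energetic-efficiency ratio.

Simulates 24-h trials (20 prey offered per arena), fits the ln F scaling
model per prey taxon, predicts each fish's intake at its metabolic-chamber
temperature, and forms y = omega * F_J / I_J — the fraction of metabolic
demand covered by assimilated intake. y < 1 flags an energetically
constrained fish.
"""

from thermotrout import efficiency, feeding, respirometry, scaling, synth

config = synth.GeneratorConfig(seed=11)
cohort = synth.generate_cohort(config)
trials = synth.generate_feeding_trials(cohort, config)
traces, specs = synth.generate_all_respirometry(cohort, config)

best, _ = feeding.fit_feeding_model(trials, cohort, prey_taxon="Simulium vittatum")
print("feeding model terms:", " + ".join(best.spec) or "intercept only")

prey = feeding.PreyEnergetics("Simulium vittatum", mean_mass_mg=1.5, energy_J_per_mg=22.0)
meta = cohort.set_index("fish_id")
records = []
for run in traces:
    for met in respirometry.process_run(run, specs).rates:
        if not met.qc_pass:
            continue
        F = scaling.predict(
            best, float(meta.loc[met.fish_id, "mass_mg"]), met.mean_temp_C,
            str(meta.loc[met.fish_id, "regime"]),
        )
        records.append(efficiency.energetic_efficiency(met, F, prey))

constrained = sum(r.constrained for r in records)
print(f"\n{len(records)} fish; example record:")
r = records[0]
print(
    f"  intake {r.intake_J_per_h:.1f} J/h x omega {r.omega:.3f} "
    f"vs expenditure {r.expenditure_J_per_h:.1f} J/h -> y = {r.y:.3f}"
)
print(
    f"{constrained}/{len(records)} fish have y < 1: their assimilated intake of "
    "this prey alone would not cover routine metabolic costs."
)
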