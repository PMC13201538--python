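"""From sealed-chamber oxygen traces to whole-organism metabolic rates.

Simulates one in-stream respirometry run (ten fish plus a fish-free
control chamber logging dissolved O2 every minute), then trims the 30-min
acclimation period, fits the O2 depletion slope over the next 2 h,
subtracts the control's background slope, scales by the net water volume
and applies the r^2 >= 0.8 quality rule.
"""

import numpy as np

from thermotrout import respirometry, synth

config = synth.GeneratorConfig(seed=42)
cohort = synth.generate_cohort(config)
run0 = cohort[cohort["run_id"] == 0]

rng = np.random.default_rng(1)
traces, specs = synth.generate_respirometry_run(run0, config, rng)
result = respirometry.process_run(traces, specs)

truth = cohort.set_index("fish_id")["true_rate_mgO2_per_h"]
print(f"{'fish':>12} {'mg O2/h':>8} {'J/h':>8} {'r2':>6}  QC   true rate")
for rec in result.rates:
    print(
        f"{rec.fish_id:>12} {rec.rate_mgO2_per_h:8.3f} {rec.rate_J_per_h:8.2f} "
        f"{rec.r2:6.3f}  {'ok' if rec.qc_pass else 'FAIL':4} {truth[rec.fish_id]:8.3f}"
    )
print(
    f"\n{len(result.rates)} chambers processed, {result.n_excluded} excluded by QC. "
    "Recovered rates track the generating rates; J/h = mg O2/h x 20.1/1.429."
)
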