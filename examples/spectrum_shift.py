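"""The case-spectrum-shift mechanism on synthetic cohorts.

Replicates the two-round study on freshly generated cohorts and compares the
round-1 and round-2 sensitivity of each screening modality.  With the
calibrated defaults, detection difficulty is a latent per-case trait, so the
first round removes the easy cases and the second round faces a harder mix;
with difficulty_weight = 0 the effect disappears.
"""

from dataclasses import replace

from retscreen import paper_default_config, spectrum_shift_experiment

config = paper_default_config()
out = spectrum_shift_experiment(config, n_reps=10, seed=7)
print("calibrated defaults (difficulty-dependent detection):")
for arm, s in out.items():
    print(
        f"  {arm}: sensitivity {100 * s.sens_r1:.1f}% -> {100 * s.sens_r2:.1f}%"
        f"  (drop {100 * s.sens_drop:.1f} pp, {s.sens_drop / s.sens_drop_se:.1f} MC SE)"
        f"  prevalence {100 * s.prev_r1:.1f}% -> {100 * s.prev_r2:.1f}%"
    )

flat = {arm: replace(gp, difficulty_weight=0.0) for arm, gp in config.graders.items()}
out0 = spectrum_shift_experiment(replace(config, graders=flat), n_reps=10, seed=7)
print("difficulty decoupled from detection (difficulty_weight = 0):")
for arm, s in out0.items():
    print(f"  {arm}: drop {100 * s.sens_drop:.2f} pp ({s.sens_drop_se * 100:.2f} pp SE)")

# A positive drop several Monte-Carlo standard errors wide appears only when
# detection probability depends on the latent case difficulty.
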