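"""Analyze one trial of footfall timings: phases, duty factor, gait class.

Builds a short synthetic running-trot trial (duty factor 0.45, one stride
per second), segments it into strides and prints the recovered stride
parameters, the footfall-pattern classification, and the aerial-phase
report.
"""

from hippogait import (
    SimConfig,
    analyze_trial,
    classify,
    detect_aerial,
    generate_trial,
    support_timeline,
)

trial = generate_trial(
    SimConfig(gait="trot", df_mean=0.45, sf=1.0, n_strides=4,
              phase_jitter_sd=0.01, df_jitter_sd=0.01, seed=42)
)
strides, summary = analyze_trial(trial)

print(f"strides analyzed: {summary.n_strides}")
print("trial-mean limb phases (fraction of stride after the LH footfall):")
for limb, phase in summary.phases.items():
    print(f"  {limb.value}: {phase:.3f}")
print(f"mean duty factor: {summary.df_mean:.3f}   "
      f"stride frequency: {summary.stride_frequency:.3f} Hz")

gait = classify(summary)
print(f"footfall pattern: {gait.class8} ({gait.class4}), "
      f"{gait.locomotion}, {gait.symmetry}")

aerial = detect_aerial(support_timeline(summary), summary)
print(f"aerial phase: {aerial.has_aerial} "
      f"(fraction of stride airborne: {aerial.aerial_fraction:.3f})")

# A trot at DF < 0.5 is a 'running' trot: the diagonal pairs no longer
# overlap in stance, so two short whole-body aerial windows open per
# stride; their total length approaches 2 x (0.5 - DF) for an ideal trot.
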