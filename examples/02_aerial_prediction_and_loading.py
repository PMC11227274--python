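"""Aerial-phase prediction from mean phases, and peak limb forces.

Uses the observed hippo trot mean limb phases (LF 0.46, RH 0.51, RF 0.94)
to compute the ipsilateral footfall gaps, predicts whether an aerial phase
occurs at several duty factors, and estimates the peak vertical ground
reaction force of one forelimb from the half-cosine loading model.
"""

from hippogait import (
    LimbId,
    StrideParams,
    detect_aerial,
    peak_vertical_grf,
    support_timeline,
)


def hippo_params(df):
    phases = {LimbId.LH: 0.0, LimbId.LF: 0.46,
              LimbId.RH: 0.51, LimbId.RF: 0.94}
    dfs = {limb: df for limb in LimbId}
    return StrideParams(duration=1.0, phases=phases, duty_factors=dfs,
                        stance={l: df for l in LimbId},
                        swing={l: 1 - df for l in LimbId})


print("mean hippo trot phases: LF 0.46, RH 0.51, RF 0.94")
report = detect_aerial(support_timeline(hippo_params(0.5)), hippo_params(0.5))
print(f"ipsilateral gaps: left pair {1 - 0.46:.2f}, right pair "
      f"{0.94 - 0.51:.2f} -> max {report.max_ipsilateral_gap:.2f}")
print()
print("DF    predicted aerial   exact aerial fraction")
for df in [0.36, 0.45, 0.50, 0.60, 0.76]:
    p = hippo_params(df)
    r = detect_aerial(support_timeline(p), p)
    print(f"{df:.2f}      {str(r.predicted_simplified):5s}            "
          f"{r.aerial_fraction:.3f}")

print()
print("half-cosine peak vertical GRF of one forelimb (30% of body weight")
print("per forelimb averaged over the stride):")
for df in [0.37, 0.50, 0.75]:
    print(f"  DF {df:.2f}: {peak_vertical_grf(df, 0.30):.2f} body weights")

# The simplified criterion predicts an aerial phase whenever DF drops
# below the largest gap between consecutive ipsilateral footfalls (~0.54
# here); the exact support timeline shows how much of the stride is truly
# airborne.  Lower duty factors concentrate the same body-weight impulse
# into shorter stances, raising the peak force.
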