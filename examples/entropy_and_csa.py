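"""How CSA and sample entropy respond to disease severity.

Generates recordings across a severity sweep with the coupled severity
profile and prints how the distribution index (CSA) and the regularity
index (SSE) move, alongside the detected ODI3.
"""

from noxtk import (
    SimulationConfig,
    compute_csa,
    compute_sse,
    detect_desaturations,
    generate_recording,
    track_baseline,
)

print(f"{'true rate/h':>12} {'ODI3/h':>8} {'CSA':>7} {'SSE':>6}")
for rate in (0.0, 5.0, 15.0, 40.0):
    cfg = SimulationConfig.severity_profile(rate, seed=int(rate) + 1, duration_h=6.0)
    rec, truth = generate_recording(cfg)
    baseline = track_baseline(rec)
    odi3 = len(detect_desaturations(rec, baseline, 3.0)) / rec.valid_sleep_hours
    print(f"{truth.true_rate_per_h:12.1f} {odi3:8.1f} "
          f"{compute_csa(rec):7.0f} {compute_sse(rec):6.2f}")

print("\nBoth indices rise with severity: CSA because more probability mass")
print("sits at lower saturations, SSE because the trace grows less regular.")
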