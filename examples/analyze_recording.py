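"""Analyze one overnight SpO2 recording end to end.

Simulates a symptomatic child's overnight oximetry (so the script is
self-contained), writes/reads it through the CSV dialect, applies the
quality gate, and prints every screening index the toolkit computes.
"""

import tempfile
from pathlib import Path

from noxtk import (
    SimulationConfig,
    generate_recording,
    quality_check,
    read_recording,
    summarize,
    write_recording,
)

# a typical pre-treatment severity profile: ~18 desaturations/h
cfg = SimulationConfig(seed=42, duration_h=6.8)
rec, truth = generate_recording(cfg, subject_id="demo", visit="pre")

with tempfile.TemporaryDirectory() as d:
    path = write_recording(rec, Path(d) / "demo.csv")
    rec = read_recording(path, subject_id="demo", visit="pre")

qr = quality_check(rec)
print(f"analyzed sleep: {qr.duration_h:.2f} h, artifacts {qr.artifact_pct:.2f}% "
      f"-> {'PASS' if qr.passes else 'FAIL'}")

s = summarize(rec)
print(f"mean SpO2 {s.mean_spo2:.2f}%  SD {s.sd_spo2:.2f}%")
print(f"ODI3 {s.odi3:.1f}/h  ODI4 {s.odi4:.1f}/h  (true event rate "
      f"{truth.true_rate_per_h:.1f}/h)")
print(f"McGill score {s.mos}  ({s.n_clusters} desaturation clusters)")
print(f"CSA {s.csa:.0f}  (100 = perfectly saturated night)")
print(f"SSE {s.sse:.2f}  (higher = more irregular trace)")
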