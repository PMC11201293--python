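"""Generate a small synthetic two-group cohort and inspect its ground truth.

The generator plants the study conditions the pipeline is built to
detect: patients switch between brain states more often than controls
(0.08 vs 0.06 transitions per step), occupy state 1 more and states 3/6
less, and carry regional amplitude/coherence deficits in the affected
parcels.
"""

import numpy as np

import restdyn as rd

cfg = rd.SimulationConfig(
    n_patients=15, n_controls=15, n_parcels=20, n_volumes=230, seed=42
)
cohort = rd.generate_cohort(cfg)

for group in ("patient", "control"):
    subs = cohort.subjects(group)
    sr = np.mean([cohort.truth["sr"][s] for s in subs])
    fo = np.mean([cohort.truth["fo"][s] for s in subs], axis=0)
    print(f"{group:8s} n={len(subs):3d}  true mean SR={sr:.4f}  "
          f"FO={np.round(fo, 3)}")

print(f"\naffected parcels (amplitude factor): {cfg.affected_parcels}")
print("Patients' truth SR sits near the planted 0.08 and controls near 0.06;")
print("the FO vector shows the raised state-1 / lowered state-3,6 occupancy.")
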