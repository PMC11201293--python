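"""Group-level HMM brain states: fractional occupancy and switching rate.

One 6-state Gaussian HMM is fitted on all subjects' z-scored series
concatenated; each subject is then Viterbi-decoded under the shared
model, giving per-subject occupancies (FO1..FO6) and a switching rate.
"""

import restdyn as rd

cfg = rd.SimulationConfig(
    n_patients=40, n_controls=40, n_parcels=20, n_volumes=230, seed=5
)
cohort = rd.generate_cohort(cfg)

features, result, paths = rd.extract_hmm_features(
    cohort.node_series, n_states=6, seed=0, n_restarts=3
)
print(f"EM converged in {len(result.ll_history)} iterations "
      f"(final log-likelihood {result.log_likelihood:.0f})")

for group in ("patient", "control"):
    subs = cohort.subjects(group)
    est = features.loc[subs, "SR"].mean()
    true = sum(cohort.truth["sr"][s] for s in subs) / len(subs)
    print(f"{group:8s} decoded mean SR = {est:.4f}   (truth {true:.4f})")

print("\nThe decoded group means recover the planted 0.08 (patients) vs"
      "\n0.06 (controls) switching-rate contrast; FO1..FO6 and SR form the"
      "\n7 HMM features of each subject's dynamic block.")
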