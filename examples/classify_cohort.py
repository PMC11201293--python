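"""End-to-end desk-scale run: features -> selection -> four-kernel SVMs.

Runs the reduced preset (20 patients vs 20 controls, 20 parcels) through
the complete pipeline and prints the strategy x kernel metric table plus
a permutation p-value, mirroring the layout of a classification-results
table.  Takes a minute or two on one CPU.
"""

from restdyn.pipeline import RunConfig, report, run_all

cfg = RunConfig.desk(seed=0)
metrics = run_all(cfg, out_dir="scratch/desk_example")

print(report(metrics).round(4).to_string(index=False))
for key, perm in metrics["permutations"].items():
    print(f"\npermutation test [{key}]: observed AUC={perm['observed_auc']:.3f}, "
          f"p={perm['p_value']:.4f} ({perm['n_permutations']} permutations)")
print("\nAUC/accuracy/sensitivity/specificity are means over 5 stratified"
      "\nfolds; selection is re-run inside each training fold. The planted"
      "\ngroup effects put RBF/sigmoid kernels in the AUC >= 0.8 regime,"
      "\nwhile label permutation drops AUC to chance (p < 0.05).")
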