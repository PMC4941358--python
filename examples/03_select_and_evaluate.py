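"""Full selection and evaluation pipeline on data with a known answer.

A pair signal is planted at gap g=2 in the positive class.  The pipeline
scans g = 0..4, ranks features per gap by ANOVA F, runs incremental
feature selection (IFS) with one frozen 3-fold partition, and should
recover g* = 2.  The chosen feature prefix is then evaluated by the
deterministic jackknife (leave-one-out) test.
"""

from acpred import CVConfig, SynthSpec, generate, jackknife, select_best_g

spec = SynthSpec(n_pos=60, n_neg=60, enrichment_factor=1.0,
                 planted_gap=2, planted_density=0.35, seed=0)
dataset = generate(spec)
print(f"dataset: {dataset.m_pos}+{dataset.m_neg} peptides, "
      f"pair signal planted at g={spec.planted_gap}")

selection = select_best_g(dataset, (0, 1, 2, 3, 4),
                          cv=CVConfig(k=3, seed=7), policy="skip")
for g, result in selection.per_g.items():
    print(f"  g={g}: IFS peak Acc={100 * result.peak_acc:6.2f}% "
          f"at Theta={result.theta}")
best = selection.best_result
print(f"selected g*={selection.best_g} with Theta={best.theta} features")

metrics, counts = jackknife(dataset, "ggap", selection.best_g,
                            subset=best.optimal_subset, policy="skip")
row = metrics.as_row()
print(f"jackknife on the selected subset: Sn={row['Sn_pct']}% "
      f"Sp={row['Sp_pct']}% Acc={row['Acc_pct']}% MCC={row['MCC']}")
print("(accuracy well above the 50% majority rate shows the planted gap "
      "was both detected and exploited)")
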