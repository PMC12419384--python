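"""Sensitivity analysis of one contaminated locus.

Simulates a 10-SNP locus with a true causal effect of 0.3 plus one planted
outlier whose outcome effect is shifted by 8 outcome-SEs, then compares the
whole estimator battery: IVW is pulled by the outlier, the weighted median
and mode resist it, MR-PRESSO identifies and removes it, and leave-one-out
shows which SNP drives the full-set estimate.
"""

from lipidmr import (
    SyntheticTruth, egger, harmonize, ivw, leave_one_out, mr_presso,
    retained, simulate_two_sample, weighted_median, weighted_mode,
)

truth = SyntheticTruth(theta=0.3, n_snp=10, outlier_ids=frozenset({4}),
                       outlier_shift=8.0, seed=7)
ds = simulate_two_sample(truth)
insts = retained(harmonize(ds.exposure, ds.outcome))
print(f"true effect {truth.theta}, planted outlier: {ds.truth_echo['outlier_snps']}\n")

rows = [ivw(insts), ivw(insts, random_effects=True), egger(insts)[0],
        weighted_median(insts, seed=1), weighted_mode(insts, seed=1)]
report, corrected = mr_presso(insts, n_sim=1000, seed=1)
rows.append(corrected)
for r in rows:
    print(f"{r.method:26s} beta {r.beta:+.3f}  95% CI ({r.ci_low:+.3f}, "
          f"{r.ci_high:+.3f})  p {r.pvalue:.2e}")

print(f"\nMR-PRESSO global p {report.global_p:.4f}, "
      f"outliers flagged: {sorted(report.outliers_flagged)}")

loo, same_side = leave_one_out(insts)
worst = loo.loc[(loo.beta - ivw(insts).beta).abs().idxmax()]
print(f"leave-one-out: largest shift when dropping {worst.snp_dropped} "
      f"(beta {worst.beta:+.3f}); all CIs same side of zero: {same_side}")
print("\nThe outlier-corrected and robust estimators should sit near 0.3")
print("while the plain IVW is displaced toward the outlier's ratio.")
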