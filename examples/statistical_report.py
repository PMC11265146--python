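"""Summarize a benchmark run the way a methods-comparison paper would.

Takes fold-level evaluation records and produces: bootstrap 95% CIs of mean
balanced accuracy per condition, Dunn's pairwise tests (Holm-adjusted) on
the condition differences, and an OLS model of balanced accuracy on the
design factors with estimated-marginal-means contrasts for the
normalization method.
"""

import warnings

import pandas as pd

import fsnorm as fn

warnings.simplefilter("ignore")

cohort = fn.simulate_paired_cohort(fn.SimulationConfig(n_samples=120, p_genes=600, seed=3))
frames = []
for direction in ("A_trains", "B_trains"):
    recs = fn.nested_cv_experiment(
        cohort, direction, "svm_linear", "full", fn.CVConfig(outer_k=5, inner_k=3, seed=2)
    )
    frames.append(fn.records_to_frame(recs))
records = pd.concat(frames, ignore_index=True)

print("bootstrap 95% CIs of mean balanced accuracy (1,000 resamples of fold values):")
for cond, sub in records.groupby("condition"):
    ci = fn.bootstrap_ci(sub.balanced_accuracy.to_numpy(), B=1000, seed=0)
    print(f"  {cond:<10} {ci.statistic:.3f}  [{ci.ci[0]:.3f}, {ci.ci[1]:.3f}]")

piv = records[records.direction == "A_trains"].pivot_table(
    index="outer_fold", columns="condition", values="balanced_accuracy"
)
names = list(piv.columns)
print("\nDunn pairwise tests (Holm-adjusted), A trains:")
for r in fn.dunn_test([piv[c].tolist() for c in names], names=names):
    flag = "*" if r.adjusted_p < 0.05 else " "
    print(f" {flag} {r.method}: z={r.statistic:+.2f}, adj p={r.adjusted_p:.3g}")

fit = fn.ols_fit(
    records,
    response="balanced_accuracy",
    terms=["direction", "condition"],
    reference_levels={"condition": "reference", "direction": "A_trains"},
)
print("\nOLS coefficients (beta = accuracy difference vs reference level):")
print(fit.table.round(3).to_string(index=False))

print("\nestimated-marginal-means contrasts for the normalization method:")
for c in fn.marginal_means_contrasts(fit, "condition"):
    flag = "*" if c.adjusted_p < 0.05 else " "
    print(f" {flag} {c.method}: diff={c.statistic:+.3f}, adj p={c.adjusted_p:.3g}")
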