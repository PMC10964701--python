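"""Run the full two-sample MR estimator suite on simulated data.

The scenario has a true causal log-odds ratio of 0.2 with mild balanced
pleiotropy; all estimators should agree near exp(0.2) ~ 1.22, the Egger
intercept should hover near zero, and the Steiger test should confirm
the exposure-to-outcome direction.
"""

from triangmr import (MRScenario, egger_estimate, harmonize_pair,
                      ivw_estimate, kept, presso, raps_estimate,
                      simulate_mr_dataset, steiger_test,
                      weighted_median_estimate)

scen = MRScenario(m_instruments=50, beta_causal=0.2, pleiotropy_sd=0.01,
                  seed=7)
sim = simulate_mr_dataset(scen)
pairs = kept(harmonize_pair(sim.exposure, sim.outcome))

results = [
    ivw_estimate(pairs),
    egger_estimate(pairs),
    weighted_median_estimate(pairs, seed=1),
    weighted_median_estimate(pairs, penalized=True, seed=2),
    presso(pairs, seed=3),
    raps_estimate(pairs, overdispersion=True),
]
print(f"{'method':8s} {'OR':>6s} {'95% CI':>16s} {'p':>9s}")
for r in results:
    print(f"{r.method:8s} {r.or_value:6.3f} "
          f"[{r.ci_low:6.3f}, {r.ci_high:6.3f}] {r.pvalue:9.2e}")

egger = results[1]
print(f"\nEgger intercept p = {egger.extras['egger_intercept_p']:.3f} "
      "(no directional pleiotropy detected)")
gp = results[4].extras["global_p"]
note = ("balanced pleiotropy detected; the headline PRESSO estimate is the "
        "outlier-free IVW" if gp < 0.05 else "no outlier heterogeneity")
print(f"PRESSO global p = {gp:.3f} ({note})")
st = steiger_test(pairs, scen.n_exposure, scen.n_outcome)
print(f"Steiger direction correct: {st.direction_correct} "
      f"(r2 exposure {st.r2_exposure:.4f} vs outcome {st.r2_outcome:.5f})")
print("\nAgreement across pleiotropy-robust estimators supports a causal "
      "interpretation; the true OR is exp(0.2) = 1.221.")
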