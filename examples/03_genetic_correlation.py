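"""Estimate genetic correlation by bivariate LD-score regression.

Simulates two polygenic traits with a true rg of 0.4 and recovers it by
regressing z1*z2 on LD scores, with heritabilities from the z^2
regressions and a block-jackknife standard error.
"""

from triangmr import LdscScenario, estimate_rg, simulate_ldsc_dataset

scen = LdscScenario(h2_trait1=0.3, h2_trait2=0.25, rg_true=0.4,
                    m_snps=20_000, n1=50_000, n2=50_000, seed=11)
scores, z = simulate_ldsc_dataset(scen)
res = estimate_rg(z.rename(columns={"Z1": "Z"})[["SNP", "Z"]],
                  z.rename(columns={"Z2": "Z"})[["SNP", "Z"]],
                  scores, scen.n1, scen.n2)

print(f"h2 trait 1: {res.h2_1:.3f} (SE {res.h2_1_se:.3f}); "
      f"h2 trait 2: {res.h2_2:.3f} (SE {res.h2_2_se:.3f})")
print(f"rg = {res.rg:.3f} (SE {res.rg_se:.3f}, p = {res.rg_p:.2e}), "
      f"status = {res.status}")
print("\nThe jackknife CI should cover the generating rg of 0.4; the free "
      "intercepts absorb confounding inflation and sample overlap.")
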