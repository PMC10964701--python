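"""End-to-end evidence triangulation on two synthetic trait pairs.

One pair carries a causal effect, a genetic correlation, and a shared
causal variant (expected verdict: strong genetic evidence, explanation
i); the other is null on all three tracks (explanation ix).
"""

import tempfile

from triangmr import demo_config, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline(demo_config(seed=7), output_dir=tmp)
    cols = ["pair", "ldsc_state", "mr_state", "coloc_state", "mr_or",
            "mean_pph4", "pattern", "explanation"]
    print(report.verdicts[cols].to_string(index=False))
    print()
    for _, row in report.verdicts.iterrows():
        print(f"{row['pair']}: {row['explanation_text']}")
print("\nThe verdict crosses the three tracks' significance calls: "
      "explanation i needs all three to agree in direction, while a "
      "significant MR alone (pattern 5) is read as a possible false "
      "positive.")
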