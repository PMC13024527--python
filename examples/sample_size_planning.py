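"""Plan a diagnostic-device study with both sample-size estimators.

Compares an AI reader expected to reach 95% accuracy against a minimum
acceptable 85%, then sizes the positive/negative groups for expected
sensitivity/specificity of 95% at a 0.05 confidence half-width.
"""

from dudem.study_design import single_arm_n, diagnostic_n, adjust_for_dropout

n1 = single_arm_n(pt=0.95, p0=0.85, alpha=0.05, power=0.8)
n1_adj = adjust_for_dropout(n1, 0.2)
print(f"single-arm target-value design: n = {n1} per group")
print(f"  with 20% anticipated dropout: {n1_adj} per group "
      f"({2 * n1_adj} total at 1:1 allocation)")

n2 = diagnostic_n(p=0.95, delta=0.05, alpha=0.05)
n2_adj = adjust_for_dropout(n2, 0.2)
print(f"diagnostic-accuracy design:     n = {n2} per group")
print(f"  with 20% anticipated dropout: {n2_adj} per group "
      f"({2 * n2_adj} total: positives + negatives)")

print("\nThe larger of the two (98 vs 91 per group) sets the minimum cohort.")
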