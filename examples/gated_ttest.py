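"""The variance-ratio-gated two-sample t-test on a single probe.

Two probes are tested: one with comparable case/control spread, one with
strongly inflated case variance. The F pretest routes the first to the
pooled-variance t-test and the second to Welch's test.
"""
import numpy as np

from genevote import select_and_test

rng = np.random.default_rng(0)

equal_spread_case = rng.normal(7.8, 1.0, 6)
equal_spread_ctrl = rng.normal(7.0, 1.0, 6)
inflated_case = rng.normal(7.8, 4.0, 6)
inflated_ctrl = rng.normal(7.0, 0.5, 6)

for label, case, ctrl in [("comparable spread", equal_spread_case, equal_spread_ctrl),
                          ("inflated case variance", inflated_case, inflated_ctrl)]:
    r = select_and_test(case, ctrl, f_alpha=0.05, probe_id=label)
    print(f"{label}:")
    print(f"  F = {r.f_statistic:6.2f}  F-test p = {r.f_p:.4f}  "
          f"-> {r.branch} branch")
    print(f"  t = {r.t_statistic:6.2f}  df = {r.t_df:5.2f}  p = {r.p_value:.4f}")

print("\nThe F-test p decides the branch: below 0.05 the variances are "
      "treated as unequal\nand the Welch test (fractional df) replaces the "
      "pooled test (integer df).")
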