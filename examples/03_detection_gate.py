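"""The KS detection gate: does a lane contain EVs beyond background?

Per-FOV EV counts from a lane are compared against the empty-lane negative
control with a one-sided two-sample KS test (exact permutation p-value at
these sample sizes); analysis proceeds only when p < 0.01.
"""

from evquant import gate_condition, ks_one_tailed

sample_counts = [34, 41, 29, 38, 45, 31]   # EVs per FOV, test lane
control_counts = [1, 0, 2, 0, 1, 0]        # EVs per FOV, empty lane

res = gate_condition(ks_one_tailed(sample_counts, control_counts), threshold=0.01)
print(f"D+ = {res.ks_statistic:.3f}, p = {res.p_value:.5f} ({res.method})")
print(f"gate passed: {res.passed}")

# a lane with too few fields of view can never pass, whatever the counts:
weak = gate_condition(ks_one_tailed([50, 60, 70], [0, 0, 1]), threshold=0.01)
print(
    f"\n3 FOVs, complete separation: p = {weak.p_value:.3f} -> passed: {weak.passed}"
    "\n(with 3 vs 3 observations the smallest achievable exact p is 1/20)"
)
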