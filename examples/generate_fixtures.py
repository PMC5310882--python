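"""Synthetic feature tables whose PE values are pinned by construction.

Each policy is a known point on the equality scale, which makes the
generated tables exact test inputs: proportional protection scores
corrected PE_p = 1, a feasible fixed amount scores corrected PE_f = 1,
all-protection-in-one-feature scores 0, and random protection lands
strictly in between.
"""

from pequal import PolicySpec, make_table, pe_fixed, pe_proportional

for policy in ("proportional", "fixed", "perfectly_unequal", "random"):
    spec = PolicySpec(
        policy=policy, n=10, mean_area=1000.0, cv=0.3, amount=100.0, seed=7
    )
    t = make_table(spec)
    print(
        f"{policy:>18}: corrected PE_p = {pe_proportional(t).corrected:6.3f}, "
        f"corrected PE_f = {pe_fixed(t).corrected:6.3f}"
    )
print()
print("The first three values are exact by construction (1, 1 and 0);")
print("the random policy draws p_i = a_i * Uniform(0,1), so its PE varies")
print("with the seed but always stays strictly between 0 and 1.")
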