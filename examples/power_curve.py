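"""Analytic power of a binary-outcome MR analysis across design choices.

Power depends on the outcome sample size and case fraction, the variance of
the exposure explained by the instruments (r^2) and the hypothesized odds
ratio. Printed per row: the power of a two-sided IVW test at alpha = 0.05.
"""

from bimr import PowerInput, mr_power_binary

n, k = 385_276, 80_265 / 385_276
print(f"outcome GWAS: n = {n:,}, case fraction = {k:.3f}\n")
print(f"{'OR':>5s} " + " ".join(f"r2={r2:g}" for r2 in (0.005, 0.01, 0.02, 0.05)))
for odds_ratio in (1.05, 1.1, 1.2, 1.31, 1.5):
    row = [
        mr_power_binary(PowerInput(n=n, k_ratio=k, odds_ratio=odds_ratio, r2=r2))
        for r2 in (0.005, 0.01, 0.02, 0.05)
    ]
    print(f"{odds_ratio:5.2f} " + " ".join(f"{p:8.1%}" for p in row))

print("\nRows are hypothesized odds ratios per unit log-odds of exposure;")
print("columns are instrument strength. Small effects need either strong")
print("instruments or very large outcome GWAS to be detectable.")
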