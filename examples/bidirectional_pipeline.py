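"""Run the full bidirectional pipeline on the synthetic scenario pack.

Each direction selects its own instruments (p <= 5e-8, LD-clumped),
harmonizes them against the other trait's GWAS, and reports the principal
IVW random-effects estimate plus sensitivity analyses and diagnostics.
"""

import numpy as np

from bimr import MRConfig, generate_two_sample, run_direction, scenario

for name, label in (("mdd_to_gerd", "MDD -> GERD"), ("gerd_to_mdd", "GERD -> MDD")):
    truth = scenario(name, seed=11)
    exposure, outcome, ld, _ = generate_two_sample(truth)
    cfg = MRConfig(seed=11, case_fraction_outcome=truth.case_fraction_outcome)
    rep = run_direction(exposure, outcome, cfg, ld, *label.split(" -> "))

    est = rep.estimates["ivw_random"]
    print(f"=== {label} (true OR {np.exp(truth.theta):.2f}) ===")
    print(f"instruments: {rep.instrument_counts}")
    print(f"IVW random:  OR {est['odds_ratio']:.3f} "
          f"[{est['or_ci_low']:.3f}, {est['or_ci_high']:.3f}]  p = {est['pvalue']:.2e}")
    print(f"Cochran's Q: {rep.heterogeneity['q']:.2f} (p = {rep.heterogeneity['pvalue']:.3f})")
    print(f"Egger intercept: {rep.egger_intercept['intercept']:+.4f} "
          f"(p = {rep.egger_intercept['pvalue']:.3f})")
    print(f"PRESSO outliers: {rep.presso['outlier_variant_ids'] or 'none'}")
    print(f"mean F: {rep.strength['mean_f']:.1f}   power: {rep.power['power']:.0%}\n")

print("A CI excluding OR = 1 in both directions is the bidirectional-causality")
print("signature; a null Egger intercept and no PRESSO outliers indicate the")
print("estimate is not driven by directional pleiotropy.")
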