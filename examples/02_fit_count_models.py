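"""Fit the count IRT model battery on a synthetic pilot study.

Synthesizes a 208-person x 9-item dataset at the reference study conditions
(family easiness 10.80 / 9.08 / 7.12 correct associations, person SD 0.229),
then fits the person-only null model, the RPCM (one easiness per item) and
the RPCM-r (easiness explained by visual load), and compares them.
"""

import numpy as np

from figmem import fit_person_only, fit_rpcm, fit_rpcm_r, lrt, synthesize_study

data = synthesize_study(seed=12)
print(f"data: {data.n_persons} persons x {data.n_items} items, "
      f"scores 0..{data.max_score}")

f0 = fit_person_only(data)
f1 = fit_rpcm(data)
f2 = fit_rpcm_r(data)

print("\nRPCM item easiness (expected score at average ability), counts scale:")
for name, b, se in zip(f1.param_names, f1.beta, f1.beta_se()):
    lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
    print(f"  {name}: {np.exp(b):5.2f}  [{lo:.2f}; {hi:.2f}]")

print("\nRPCM-r easiness per visual-load level:")
for name, b in zip(f2.param_names, f2.beta):
    print(f"  {name}: {np.exp(b):5.2f}")
print(f"person SD (log scale): {f1.person_sd:.3f}, "
      f"95% CI {tuple(round(x, 3) for x in f1.person_sd_ci())}")

chi2, df, p = lrt(f0, f1)
print(f"\nitems matter: person-only vs RPCM chi2({df}) = {chi2:.2f}, p = {p:.2g}")
chi2, df, p = lrt(f2, f1)
print(f"load explains most difficulty: RPCM-r vs RPCM chi2({df}) = {chi2:.2f}, "
      f"p = {p:.3f}")
print("-> easiness decreasing in visual load; a small within-family residual")
print("   remains, which is what the second LRT quantifies.")
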