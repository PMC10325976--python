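"""Stratify a small variant table into deleteriousness tiers.

Builds a toy table of RNF213 missense variants with CADD and VIPUR scores,
fits a two-component Gaussian mixture to each score by EM, derives the
high-score cutpoints and prints the tier of each variant.
"""

import numpy as np

from moyastrat import AnnotatedVariant, classify_variants, fit_score_model

rng = np.random.default_rng(0)

# two clusters per score: most variants are tolerated, a minority damaging
cadd = np.concatenate([rng.normal(14, 3, 30), rng.normal(29, 3, 12)])
vipur = np.clip(np.concatenate([rng.normal(0.2, 0.08, 30),
                                rng.normal(0.7, 0.12, 12)]), 0, 1)

variants = [
    AnnotatedVariant(variant_id=f"v{i:02d}", gene="RNF213",
                     cadd=float(c), vipur=float(p) if i % 9 else None)
    for i, (c, p) in enumerate(zip(cadd, vipur))
]

cadd_fit = fit_score_model([v.cadd for v in variants if v.cadd is not None])
vipur_fit = fit_score_model([v.vipur for v in variants if v.vipur is not None])

print(f"CADD  cutpoint: {cadd_fit.cutpoint:.2f} "
      f"(component means {cadd_fit.means[0]:.1f} / {cadd_fit.means[1]:.1f})")
print(f"VIPUR cutpoint: {vipur_fit.cutpoint:.3f} "
      f"(component means {vipur_fit.means[0]:.2f} / {vipur_fit.means[1]:.2f})")

calls = classify_variants(variants, cadd_fit, vipur_fit)
counts = {}
for c in calls:
    counts[c.tier] = counts.get(c.tier, 0) + 1
print("tier counts:", counts)
print("A variant is 'deleterious' when both scores fall in their high-score")
print("cluster, 'possibly deleterious' on one high score, else 'benign';")
print("a missing VIPUR score means the call rests on CADD alone.")
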