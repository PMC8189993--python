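"""Individualised-divergence ordination against the typical reference.

Transforms every simulated individual into per-measure log-Bayes-factor
divergences from the typical design, decomposes the standardised correlation
structure, and summarises species in polar form (distance and compass angle
from the typical anchor).  Finally contrasts the published omnivore and
fragmentary-feeder groups.
"""

import pandas as pd

import chelamorph as cm
from chelamorph.ordination import polar_table

reference = cm.load_reference_summaries()
cohort = cm.simulate_cohort(cm.CohortSpec(summaries=reference, seed=1))
typ_ind, trow = cm.build_typical_reference(cohort)
full = pd.concat([cohort, typ_ind], ignore_index=True)
summaries = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                      ignore_index=True)

matrix = cm.build_divergence_matrix(full, summaries)
model = cm.decompose(matrix)
m6 = cm.decompose(cm.build_divergence_matrix(full, summaries,
                                             with_indicators=False))
print("six-measure eigenvalues:", [round(float(v), 3)
                                   for v in m6.eigenvalues])
print(f"top-2 share of trace: {m6.eigenvalues[:2].sum() / 6:.1%} "
      "(two latent components: overall chelal scale, then an aspect-ratio "
      "contrast of lengths against heights)")

polar = polar_table(model).set_index("species_code")
print("\npolar positions (distance from typical, compass angle):")
for code in ["Typical", "Ca4", "KL", "D5"]:
    row = polar.loc[code]
    angle = "undefined" if not row.angle_defined else f"{row.angle:6.1f} deg"
    print(f"  {code:8s} distance {row.distance:7.3f}  angle {angle}")

meta = cm.load_species_metadata()
omn = meta[meta.published_group == "omnivore"].species_code
frag = meta[meta.published_group == "fragmentary"].species_code
res = cm.group_contrast(model, omn, frag, n_permutations=999, seed=1)
print("\nomnivores vs fragmentary feeders:")
print(f"  species distance Welch p   = {res['distance_welch']['p']:.3f}")
print(f"  individual angle MWW p     = {res['angle_mww'].p_randomization}")
print("  (the groups differ in direction, not distance, from the typical "
      "design — the published signature)")
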