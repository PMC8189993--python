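"""The field-prediction workflow on an 'unknown' sample.

Simulates a field sample of 20 specimens from one reference species'
published moments, pretends not to know it, and runs the five-step
prediction: summarise, divergence-transform, place on the published
nomogram, match nearest reference species, attach the trophic narrative.
"""

import chelamorph as cm

reference = cm.load_reference_summaries()
truth = "AL2"   # Aleuroglyphus ovatus, a small burrowing omnivore

sub = reference[reference.species_code.isin([truth, "Typical"])]
sample = cm.simulate_cohort(cm.CohortSpec(summaries=sub, seed=42))
report = cm.field_predict(sample[["IL", "L1U", "L2M", "CHI", "CLI"]])

print(f"route: {report['route']}  (n = {report['n']})")
print(f"nomogram position: Score1 = {report['nomogram']['score1']:.2f}, "
      f"Score2 = {report['nomogram']['score2']:.2f}")
print("nearest species on the nomogram plane:")
for match in report["nomogram_matches"][:3]:
    print(f"  {match['species_code']:8s} distance {match['distance']:.2f}")
best = report["best_match"]
print(f"\nbest match {best['species_code']} "
      f"({best['group']}, {best['habit']}):")
print(f"  {best['narrative']}")
print(f"\n(true species: {truth})")
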