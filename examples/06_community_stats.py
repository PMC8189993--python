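"""Community statistics: Welch from summaries, size-ratio null models,
circular two-sample tests.

Reproduces two published Welch results from the summary table alone, then
tests Hutchinson-style size spacing for the three bulb/foliage mites that
co-occur on plant material.
"""

import numpy as np

import chelamorph as cm

ref = cm.load_reference_summaries().set_index("species_code")

r = cm.welch_from_summary(ref.loc["R1", "IL_mean"], ref.loc["R1", "IL_sd"], 20,
                          ref.loc["R2", "IL_mean"], ref.loc["R2", "IL_sd"], 20)
print(f"R1 vs R2 idiosomal index: Welch t = {r.t:.2f}, p = {r.p:.3f} "
      "(published 0.045 - the two cultures differ only in scale)")

meta = cm.load_species_metadata()
pests = set(meta[meta.pest].species_code)
vr = ref.drop("Typical").VR_mean
a, b = vr[vr.index.isin(pests)], vr[~vr.index.isin(pests)]
r2 = cm.welch_from_summary(a.mean(), a.std(ddof=1), len(a),
                           b.mean(), b.std(ddof=1), len(b))
print(f"pest vs non-pest velocity ratio: p = {r2.p:.4f} "
      "(published 0.1024 - VR alone does not predict pest status)")

sizes = sorted(ref.loc[["T6", "R2", "R1"], "IL_mean"])
t = cm.size_ratio_null_test(sizes, iterations=1000, seed=1)
print(f"\nplant-material community sizes {np.round(sizes, 2).tolist()}:")
print(f"  adjacent ratios {sizes[1]/sizes[0]:.3f}, {sizes[2]/sizes[1]:.3f}")
for name, p in t.p_values.items():
    print(f"  {name:20s} lower-tail p = {p:.3f}")
print("  (small metrics = regular spacing; the published analysis reports a "
      "p < 0.1 rejection for this community without naming the metric — "
      "none of the four metrics reaches it from the summary sizes alone)")

rng = np.random.default_rng(1)
north = np.degrees(rng.vonmises(0.0, 4.0, 15)) % 360
south = np.degrees(rng.vonmises(np.pi, 4.0, 15)) % 360
w = cm.watson_two_sample(north, south, mode="both", n_permutations=999,
                        seed=1)
print(f"\nantipodal angle clusters: Watson U2 = {w.statistic:.3f}, "
      f"randomization p = {w.p_randomization:.3f}")
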