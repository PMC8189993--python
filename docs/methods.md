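# Methods

## The mechanical model

Astigmatid chelicerae are modelled as frictionless rigid levers.  The
moveable digit rotates in a condyle; adductor muscles in the tubular
cheliceral shaft pull a tendon attached to the digit's base.  Five primary
measures per individual (µm): the idiosomal index `IL` (an intercoxal
body-length surrogate robust to slide-mounting distortion — "size"), the
chelal input lever `L1U`, the moveable-digit length `L2M` (the gape — the
largest graspable morsel, assuming a maximal opening of about 60°, with no
angular correction applied), the cheliceral height `CHI` (a proxy for
adductor cross-section) and the cheliceral length `CLI` (reach).

The velocity ratio `VR = L1U/L2M` is the lever's ideal mechanical
advantage.  Tendon force is estimated twice, because the true muscle
topology is unknown:

* pennate fibres filling the shaft: `F1P = (CHI/2)·(CLI − 1.1·L2M)`.  The
  1.1 condyle-inflation factor accounts for the part of the moveable digit
  that sits inside the base and shortens the usable muscle space; the
  halving of `CHI` leaves room for the abductor below the adductor.  Both
  constants are exposed in `data/constants.yaml` (`condyle_inflation`,
  `adductor_shaft_fraction`) but default to the reference values and are
  sensitivity knobs only.
* radial fibres on the base cross-section: `F1C = π(CHI/2)²`.

Rectified by the lever, `F2P = F1P·VR`, `F2C = F1C·VR`, and the consensus
crunch force is `F2AV = (F2P+F2C)/2` (µm²; a force surrogate comparable
across studies).  Cross-suborder comparisons use the toughness surrogate
`VR·CHI²` (the full squared height, matching the comparative records'
convention) — both are reported to avoid confusion.  When `CLI ≤ 1.1·L2M`
the pennate muscle space is non-positive and the model raises an explicit
error rather than returning a negative force.

All relative sizing is simple division at the individual level
(`CLI/IL`, `L2M/IL`, `L2M/CLI`, `CHI/CLI`, `F2AV/IL`, `CLI/L2M`, `L1U/CHI`).

## Reference data

The packaged reference table holds the per-species mean ± SD (n = 20 adult
females per species) of the six analysis measures plus `VR` for 47 species,
and a synthetic "Typical" pseudo-species: typical individual *i*'s measure
*k* is the mean over the 47 species of individual *i*'s measure *k*.  Its
means are therefore the column means of the species means (IL 216.42 µm,
L1U 12.66, L2M 26.45, CHI 51.59, CLI 98.17) with much smaller spreads
(e.g. IL sd 2.995 µm — the spread of a 47-species average).

Two transcription conventions matter:

* values are stored exactly as printed (2 dp); species `F2AV` summaries are
  **not** re-derived from the primaries.  Recomputing a species' force from
  its primary means differs from the stored mean-of-individual-forces by a
  Jensen gap of up to 3.4 % (D3); the validation report therefore checks the
  Typical `F2AV` against recomputation from the Typical primary means
  (0.016 % apart) instead of a column-mean identity, which holds only for
  the linear measures and `VR`.
* the Typical row's SDs use the higher-precision values given alongside the
  construction (2.995, 0.238, 0.239, 0.621, 0.689, 33.228) rather than the
  2-dp table rendering.

Shipped metadata: taxonomy, the nine pest species, the published
omnivore/fragmentary (21/26) and surface/interstitial (20/27) binary splits
(the specialists' binary assignment is not rule-derivable and is never
recomputed), the published four-way functional groups, the transcribed
verbal coding and narratives (verification/display data), and the
cross-suborder comparative records (41 rows, carried verbatim — some source
rows have product ≠ leverage × height², deliberately unreconciled).

## Synthetic cohorts

The raw individuals behind the reference summaries are unpublished, so
cohorts are regenerated: per species, `n` individuals (default 20, the
study's sample size) with independent Normal draws per primary measure at
the stored mean/SD; forces computed per individual from its own primaries.
Draws violating positivity or the pennate condition are redrawn (preserving
approximate Normality near the boundary; >100 consecutive failures abort
naming the species).  Per-species substreams are derived from the global
seed by hashing the species code, so adding or removing a species never
perturbs the others.

Within-species independence is the default: the published mean
per-individual `CLI/IL` of 0.466 (vs 0.462 for the ratio of means) is
reproduced under independence, which is the one individual-level statistic
available to calibrate against.  A 5×5 correlation matrix can be supplied
for sensitivity analysis.  What the generator does **not** emulate: real
within-species allometric correlation (so generated `F2AV` SDs do not match
the printed ones, which embed unknown covariance — they are not asserted
anywhere), measurement error beyond the printed SDs, and any ontogenetic,
sex or plasticity structure.  Passing tests therefore demonstrate the
pipeline's behaviour under the stated distributional assumptions, not on
real specimens.

## Divergence ordination

Each observation is transformed to its individualised divergence
(a quadratic-discriminant log Bayes factor) from the typical reference:

    lbf = ln σ_j + (x − µ_j)²/(2σ_j²) − ln σ_48 − (x − µ_48)²/(2σ_48²)

which is identically zero for the typical individuals.  (As printed, the
quadratic terms put the species model in the numerator of a
reference-vs-species ratio — inverted relative to a textbook species-vs-
reference factor; it is implemented as published and flagged, not
corrected.)  The six lbf columns, plus 0/1 indicators for all 48 species
including the reference pseudo-species (config-switchable), are
standardised; the MCSSCP matrix of the standardised columns is the
correlation matrix scaled by (rows−1), and the correlation matrix is
eigendecomposed.

Numerical conventions:

* **Orientation.**  Components are sign-oriented deterministically:
  non-negative summed loading over the six measure columns — except
  component 2, whose published measure loadings sum negative; it is
  oriented so the `IL` loading is non-positive.  This matches the published
  nomogram signs (all-positive component 1; component 2 led by `−0.796·
  lbf_IL`) and makes output reproducible across linear-algebra back-ends.
* **Origin.**  Scores are anchored at the typical centroid (all typical
  rows are identical, so they map exactly to the origin).  Species polar
  summaries — distance and compass angle, 0° = North = +component 2,
  clockwise — are thus measured from the typical design.
* **Group contrasts.**  Distances are compared at the species level (one
  point per species) with Welch's t; angles at the individual level with
  Watson's U² and the Mardia–Watson–Wheeler uniform-scores test
  (large-sample and randomization).  Species-level angles of the published
  groups do not separate — all species fall in a one-sided fan from the
  typical anchor, and the 21-vs-26 point angle comparison is dominated by
  the fan's width — whereas the individual-level comparison recovers the
  published signature (design groups differing in direction but not
  distance).  The published angle p-values all sit at the randomization
  floor, consistent with this choice.

The published eigen normalisers (5.48, 1.81) and component weights are
constants of the original fit, stored as versioned data and used only by
the nomogram; they are never re-derived, and re-running `decompose` on new
data yields a new, clearly distinct model.

## Heuristic classification

Eight ±1 descriptors against the typical cuts: absolute cuts are the
Typical means; ratio cuts are ratios of Typical means (`CLI/IL` 0.45361,
`F2AV/IL` 4.28117, `L2M/IL` 0.12222, `L2M/CLI` 0.26943) compared against
each species' ratio of means.  Ties code low (−1) — the Typical row itself
carries the all-low labels.  The descriptor→measure mapping and tie rule
were reverse-engineered from the published verbal table and are verified
cell-by-cell (47 × 8 + 8 cells, exact) by a shipped test, not assumed.

Morsel class from (food size, hardness) signs: both high → pan-saprophage;
big/soft → macro; small/hard → micro; both low → fragmentary feeder.
Groups: large ∧ pan → type-1 omnivore; small ∧ fragmentary → type-2
fragmentary feeder; small ∧ long-reach ∧ pan → small omnivore; otherwise
specialist (sub-labelled from the remaining signs, e.g. small/short/pan →
"wide-mouthed durophage").  Habit is surface iff the size sign is high,
which reproduces the published 20/27 split exactly.  Narratives are
template-assembled (habit sentence, foraging clause, morsel clause with
class token, epithet set keyed on habit × class) and matched against the
published sentences at token level — the published wording varies
idiosyncratically between rows and five rows are explicitly "unique types",
so verbatim equality is not asserted.

Cross-suborder banding uses the published threshold constants (toughness
1039.0 / 2642.7 / 3807.0; velocity ratio 0.276 / 0.5 / 0.65; pest-range
flag at toughness ≥ 1100.6), ties banding down.  The pest constant cannot
be reconciled with species-mean arithmetic for any packaged pest species
and is carried as a constant only.

## Nomogram and field prediction

A field sample (n ≥ 2) is scored by computing each individual's six lbf
values with the sample's own mean/SD as the species model against the
packaged typical, applying the published weights, and averaging; a sample
statistically identical to the typical maps to the origin.  Samples with
n < 10 warn that the SD estimates are weak (the published procedure does
not say how small-sample σ should enter; it is used as printed).

Nearest-species matching has three routes: (i) Euclidean distance on the
nomogram plane to each reference species' coordinates — reference species
are placed by their *expected* divergence under their own printed moments,
so sample and reference coordinates are on the same footing; (ii) the raw
six-measure distance `d_j` to the printed species means — deliberately
mixing µm and µm² as published, so the crunch force dominates (a
standardised variant exists and is marked non-canonical); (iii) the ±1
sign-code lookup (codes derived from the packaged table; ties to the
match reported together), which tolerates missing measures.  `field_predict`
uses the nomogram route for samples and `d_j` for single specimens, and
attaches the best match's functional group and narrative.  In seeded
recovery studies (cohorts of 20 regenerated from each species' printed
moments) the true species lands in the top-3 nomogram matches in ≥ 90 % of
runs; mean-specimen `d_j` alone manages ~85 % because several species sit
within one standard error of each other on the force axis.

## Statistics

* Welch's t from summary statistics (Satterthwaite df, two-sided),
  identical to the raw-data test whenever the summaries match.
* Watson's two-sample U² on pooled orderings with the limiting-distribution
  tail series, and the Mardia–Watson–Wheeler uniform-scores test with the
  χ²(2) large-sample approximation; both offer label-permutation
  randomization p-values, p = (1 + #{stat ≥ observed})/(B + 1).  Angles are
  degrees at the interface, radians internally; ties take average circular
  ranks.
* Size-ratio null battery: observed variance and minimum of adjacent size
  ratios (larger/next-larger, always ≥ 1) and differences on the sorted
  sizes; the null fixes the observed extremes and redraws interior sizes
  i.i.d. Uniform(min, max); p-values are lower-tail (small metrics indicate
  regular spacing) with the same add-one convention, 1000 iterations by
  default, seeded.

## Problem sizes and known limitations

Default analyses use the study's own scale — 47 species × 20 individuals —
with Monte-Carlo suites over 10–20 seeds and 199–999 permutations; the full
test suite and the acceptance script each run in well under a minute.

The original individual-level results (exact scores, eigenvalues,
permutation p-values, individual-correlation R² values) are not
reproducible without the unpublished raw specimens; they are replaced by
the property suites described above.  The top-2 eigenvalue share of the
six-measure decomposition is 0.805 ± 0.011 across seeds under the
independence default — "two latent components" holds throughout, the 0.80
line only on the seed average.  The published size-spacing rejection
(p < 0.1) for the three-species plant-material community names no metric
and does not reproduce from the summary sizes; all four metrics are
reported without privilege.  Geometric morphometrics (Procrustes/thin-plate
splines), heat-map rendering and enzyme-assay data are out of scope.
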