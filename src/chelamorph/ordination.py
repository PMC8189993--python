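"""Individualised-divergence ordination against the typical reference mite.

Each measurement is replaced by its individualised divergence: the quadratic
discriminant log Bayes factor contrasting the individual's own species Normal
model with the typical-reference Normal model,

    lbf = ln(sd_species) + (x - mean_species)^2 / (2 sd_species^2)
        - ln(sd_ref)     - (x - mean_ref)^2     / (2 sd_ref^2)

evaluated per measure.  It is zero on average for the typical individuals
themselves.  (As printed, the quadratic terms carry the species model in the
numerator of a reference-vs-species ratio — the sign convention is inverted
relative to a textbook "species vs reference" log Bayes factor; it is kept
as published and flagged here rather than corrected.)

The lbf columns (plus optional 0/1 species indicators, the reference
pseudo-species included) are standardised and their correlation matrix
eigendecomposed; the mean-corrected sums of squares and cross-products
(MCSSCP) matrix of the standardised columns is this correlation matrix scaled
by (rows - 1).  Species are then summarised in polar form — distance from the
origin (the typical design) and compass angle (0° = North = +component 2,
clockwise, East = 90°) — and group hypotheses are tested on distances
(Welch) and angles (circular two-sample tests), one point per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from chelamorph.reference import MEASURES, TYPICAL_CODE
from chelamorph import stats as cstats


def lbf(x, species_mean, species_sd, ref_mean, ref_sd):
    """Individualised divergence of observation ``x`` for one measure.

    Vectorised over ``x``.  Raises on non-positive standard deviations.
    """
    if not species_sd > 0 or not ref_sd > 0:
        raise ValueError(
            f"standard deviations must be strictly positive "
            f"(species sd {species_sd}, reference sd {ref_sd})")
    x = np.asarray(x, dtype=float)
    out = (np.log(species_sd) + (x - species_mean) ** 2 / (2 * species_sd ** 2)
           - np.log(ref_sd) - (x - ref_mean) ** 2 / (2 * ref_sd ** 2))
    return out.item() if out.ndim == 0 else out


@dataclass
class DivergenceMatrix:
    """Standardised lbf (+ indicator) design matrix with its provenance."""
    data: pd.DataFrame                 # standardised columns
    raw_lbf: pd.DataFrame              # lbf columns before standardisation
    row_species: pd.Series             # species code per row
    measure_cols: list[str]
    indicator_cols: list[str]
    col_means: pd.Series               # pre-standardisation
    col_sds: pd.Series


def build_divergence_matrix(cohort: pd.DataFrame, summaries: pd.DataFrame,
                            with_indicators: bool = True,
                            include_reference_indicator: bool = True,
                            ) -> DivergenceMatrix:
    """Transform a per-individual table (must include the typical
    pseudo-species rows) into the standardised divergence design matrix.

    ``summaries`` must hold mean/sd per analysis measure for every species
    present, including the Typical row used as the reference.
    """
    lookup = summaries.set_index("species_code")
    if TYPICAL_CODE not in lookup.index:
        raise ValueError("summaries must include the Typical reference row")
    ref = lookup.loc[TYPICAL_CODE]
    cols = {}
    for m in MEASURES:
        vals = np.empty(len(cohort))
        for code, idx in cohort.groupby("species_code").groups.items():
            if code not in lookup.index:
                raise ValueError(f"no summary for species {code!r}")
            row = lookup.loc[code]
            vals[cohort.index.get_indexer(idx)] = lbf(
                cohort.loc[idx, m].to_numpy(),
                row[f"{m}_mean"], row[f"{m}_sd"],
                ref[f"{m}_mean"], ref[f"{m}_sd"])
        cols[f"lbf_{m}"] = vals
    raw = pd.DataFrame(cols, index=cohort.index)
    design = raw.copy()
    indicator_cols = []
    if with_indicators:
        for code in pd.unique(cohort.species_code):
            if code == TYPICAL_CODE and not include_reference_indicator:
                continue
            col = f"is_{code}"
            design[col] = (cohort.species_code == code).astype(float)
            indicator_cols.append(col)
    means = design.mean()
    sds = design.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"constant column {bad!r} cannot be standardised")
    standardised = (design - means) / sds
    return DivergenceMatrix(
        data=standardised, raw_lbf=raw,
        row_species=cohort.species_code.reset_index(drop=True),
        measure_cols=[f"lbf_{m}" for m in MEASURES],
        indicator_cols=indicator_cols, col_means=means, col_sds=sds)


@dataclass
class OrdinationModel:
    eigenvalues: np.ndarray            # descending
    loadings: pd.DataFrame             # columns PC1.. indexed by design column
    scores: pd.DataFrame               # species_code + PC columns, per row
    measure_cols: list[str]
    orientation_flips: list[bool] = field(default_factory=list)


def decompose(matrix: DivergenceMatrix) -> OrdinationModel:
    """Eigendecompose the correlation matrix of all (standardised) columns.

    Components are sorted by descending eigenvalue and sign-oriented
    deterministically: each component is flipped so the summed loading over
    the six measure columns is non-negative — except component 2, which is
    resolved so its IL loading is non-positive (its measure loadings sum to a
    negative value in the published fit, so the summed-loading rule cannot
    orient it; the published component 2 contrasts lengths against heights
    with a negative IL weight).
    """
    X = matrix.data.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to decompose")
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    midx = [matrix.data.columns.get_loc(c) for c in matrix.measure_cols]
    il_idx = matrix.data.columns.get_loc("lbf_IL")
    flips = []
    for k in range(evecs.shape[1]):
        if k == 1:
            flip = evecs[il_idx, k] > 0
        else:
            flip = evecs[midx, k].sum() < 0
        if flip:
            evecs[:, k] = -evecs[:, k]
        flips.append(bool(flip))
    pcs = [f"PC{k + 1}" for k in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=matrix.data.columns, columns=pcs)
    raw_scores = X @ evecs
    # anchor the score origin at the typical reference: the polar summaries
    # measure distance/angle from the typical design, and every typical row
    # is identical (all lbf exactly zero), so this maps them exactly to 0
    is_ref = (matrix.row_species == TYPICAL_CODE).to_numpy()
    if is_ref.any():
        raw_scores = raw_scores - raw_scores[is_ref].mean(axis=0)
    scores = pd.DataFrame(raw_scores, columns=pcs)
    scores.insert(0, "species_code", matrix.row_species.to_numpy())
    return OrdinationModel(eigenvalues=evals, loadings=loadings,
                           scores=scores, measure_cols=matrix.measure_cols,
                           orientation_flips=flips)


def _compass(s1: float, s2: float) -> float:
    """Compass angle in degrees of the point (component1, component2):
    0° at North (+PC2), clockwise, East (+PC1) at 90°."""
    return float(np.degrees(np.arctan2(s1, s2)) % 360.0)


def polar_summary(model: OrdinationModel, species_code: str) -> pd.Series:
    """Species-mean position on components 1-2 in polar form."""
    sub = model.scores[model.scores.species_code == species_code]
    if len(sub) == 0:
        raise KeyError(f"unknown species {species_code!r}")
    s1 = float(sub.PC1.mean())
    s2 = float(sub.PC2.mean())
    dist = float(np.hypot(s1, s2))
    at_origin = dist <= 1e-12   # numerically at the reference anchor
    return pd.Series(dict(species_code=species_code, distance=dist,
                          angle=np.nan if at_origin else _compass(s1, s2),
                          angle_defined=not at_origin))


def polar_table(model: OrdinationModel) -> pd.DataFrame:
    """Polar summary for every species in the model."""
    return pd.DataFrame([polar_summary(model, c)
                         for c in pd.unique(model.scores.species_code)])


def group_contrast(model: OrdinationModel, group_a, group_b,
                   n_permutations: int = 999, seed: int = 0) -> dict:
    """Distance and angle hypothesis tests between two species groups.

    Distances are compared at the species level (one polar point per
    species; individual-level n would make any difference vanish): Welch's
    t on the species distances.  Angles are compared at the individual
    level — the angular signature of a design group is carried by the whole
    cloud of its individuals, and the group contrasts of interest drive the
    randomization p to its floor there, while species-level angles (21 and
    26 points) are far noisier.  Watson's two-sample U² and the
    Mardia–Watson–Wheeler test, each with large-sample and randomization
    p-values, are reported.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two species")
    polar = polar_table(model).set_index("species_code")
    missing = [c for c in group_a + group_b if c not in polar.index]
    if missing:
        raise KeyError(f"species without scores: {missing}")
    da = polar.loc[group_a, "distance"].to_numpy()
    db = polar.loc[group_b, "distance"].to_numpy()
    sc = model.scores
    ind_angles = np.degrees(np.arctan2(sc.PC1, sc.PC2)) % 360.0
    at_origin = (sc.PC1 == 0) & (sc.PC2 == 0)
    aa = ind_angles[sc.species_code.isin(group_a) & ~at_origin].to_numpy()
    ab = ind_angles[sc.species_code.isin(group_b) & ~at_origin].to_numpy()
    welch = sps.ttest_ind(da, db, equal_var=False)
    return dict(
        distance_welch=dict(t=float(welch.statistic), p=float(welch.pvalue)),
        angle_watson=cstats.watson_two_sample(
            aa, ab, mode="both", n_permutations=n_permutations, seed=seed),
        angle_mww=cstats.mardia_watson_wheeler(
            aa, ab, mode="both", n_permutations=n_permutations, seed=seed),
    )
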