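"""Field-prediction nomogram and nearest-species matching.

The nomogram places a field sample in the two-component divergence space of
the reference analysis using the published fixed coefficients:

    Score1 = (0.525 lbf_IL + 0.889 lbf_L1U + 0.927 lbf_L2M
              + 0.954 lbf_CHI + 0.906 lbf_CLI + 0.925 lbf_F2AV) / sqrt(5.48)
    Score2 = (-0.796 lbf_IL + 0.333 lbf_L1U + 0.010 lbf_L2M
              + 0.104 lbf_CHI - 0.200 lbf_CLI + 0.216 lbf_F2AV) / sqrt(1.81)

with each lbf computed from the sample's own mean/sd (as the species model)
against the packaged typical reference.  A sample statistically identical to
the typical design maps to the origin.  The weights and the normalisers 5.48
and 1.81 are constants of the original fit, stored as versioned data and
never re-derived; changing the reference table does not change them.

Single specimens are matched instead by the raw six-measure Euclidean
distance d_j to each reference species' means (the distance deliberately
mixes µm and µm² exactly as published, so the crunch force dominates — a
standardised variant is available but non-canonical), or by the
high-throughput ±1 sign-code lookup which tolerates missing measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chelamorph.forces import chelal_forces
from chelamorph.ordination import lbf
from chelamorph.reference import (
    MEASURES, constants, load_reference_summaries, species_rows, typical_row,
)


@dataclass(frozen=True)
class NomogramPoint:
    score1: float
    score2: float
    per_individual: pd.DataFrame      # individual-level Score1/Score2
    lbf_means: dict                   # per-measure mean lbf contribution


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    method: str                       # euclidean_dj | sign_code_manhattan
    ranking: pd.DataFrame             # species_code, distance (non-decreasing)

    @property
    def best(self) -> pd.DataFrame:
        """All co-minimal matches (ties reported together)."""
        d0 = self.ranking.distance.iloc[0]
        return self.ranking[self.ranking.distance == d0]


def _complete_f2av(values: dict) -> dict:
    vals = dict(values)
    if "F2AV" not in vals or vals.get("F2AV") is None:
        vals["F2AV"] = chelal_forces(
            IL=vals.get("IL"), L1U=vals["L1U"], L2M=vals["L2M"],
            CHI=vals["CHI"], CLI=vals["CLI"]).F2AV
    return vals


def _typical_params():
    return constants()["typical"]


def nomogram_scores(sample: pd.DataFrame,
                    typical: dict | None = None) -> NomogramPoint:
    """Score a field sample (one individual per row, columns IL, L1U, L2M,
    CHI, CLI and optionally F2AV) on the published nomogram.

    The sample's own mean and sample sd per measure play the species role in
    the divergence; the typical parameters default to the packaged reference.
    Requires n >= 2 (a single specimen has no sd — use
    :func:`nearest_species_euclidean`).  Samples with n < 10 warn that the
    sd estimates are weak.
    """
    if len(sample) < 2:
        raise ValueError("nomogram scoring needs n >= 2 individuals "
                         "(single specimens: use nearest_species_euclidean)")
    if len(sample) < 10:
        warnings.warn("sample n < 10: per-measure sd estimates are weak; "
                      "nomogram position is approximate", stacklevel=2)
    sample = sample.copy()
    if "F2AV" not in sample.columns:
        sample["F2AV"] = [
            chelal_forces(L1U=r.L1U, L2M=r.L2M, CHI=r.CHI, CLI=r.CLI).F2AV
            for r in sample.itertuples()]
    typ = typical or _typical_params()
    nomo = constants()["nomogram"]
    w1, w2 = nomo["score1_weights"], nomo["score2_weights"]
    n1 = math.sqrt(nomo["normaliser1"])
    n2 = math.sqrt(nomo["normaliser2"])
    lbf_cols = {}
    for m in MEASURES:
        mu, sd = sample[m].mean(), sample[m].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"sample sd for {m} must be > 0")
        lbf_cols[m] = lbf(sample[m].to_numpy(), mu, sd,
                          typ[m]["mean"], typ[m]["sd"])
    per = pd.DataFrame(lbf_cols, index=sample.index)
    s1 = sum(w1[m] * per[m] for m in MEASURES) / n1
    s2 = sum(w2[m] * per[m] for m in MEASURES) / n2
    per_ind = pd.DataFrame({"Score1": s1, "Score2": s2})
    return NomogramPoint(score1=float(s1.mean()), score2=float(s2.mean()),
                         per_individual=per_ind,
                         lbf_means={m: float(per[m].mean()) for m in MEASURES})


def scores_from_lbf(lbf_values: dict) -> tuple[float, float]:
    """Assemble (Score1, Score2) from per-measure divergences with the
    published weights and normalisers."""
    nomo = constants()["nomogram"]
    w1, w2 = nomo["score1_weights"], nomo["score2_weights"]
    s1 = sum(w1[m] * lbf_values[m] for m in MEASURES)
    s2 = sum(w2[m] * lbf_values[m] for m in MEASURES)
    return (s1 / math.sqrt(nomo["normaliser1"]),
            s2 / math.sqrt(nomo["normaliser2"]))


def expected_lbf(mean: float, sd: float, measure: str,
                 typical: dict | None = None) -> float:
    """Expected divergence of draws from Normal(mean, sd²) scored under
    their own model against the typical reference — the species-level lbf
    coordinate used to place reference species on the nomogram on the same
    footing as a field sample's averaged per-individual lbf."""
    typ = (typical or _typical_params())[measure]
    return (math.log(sd) + 0.5 - math.log(typ["sd"])
            - (sd ** 2 + (mean - typ["mean"]) ** 2) / (2 * typ["sd"] ** 2))


def reference_nomogram_points(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Nomogram coordinates (Score1, Score2) of every reference species,
    from the printed per-species means/SDs via the expected divergence."""
    from chelamorph.reference import species_rows as _species_rows

    if reference is None:
        reference = load_reference_summaries()
    nomo = constants()["nomogram"]
    w1, w2 = nomo["score1_weights"], nomo["score2_weights"]
    n1 = math.sqrt(nomo["normaliser1"])
    n2 = math.sqrt(nomo["normaliser2"])
    rows = []
    for _, r in _species_rows(reference).iterrows():
        l = {m: expected_lbf(r[f"{m}_mean"], r[f"{m}_sd"], m) for m in MEASURES}
        rows.append(dict(
            species_code=r.species_code,
            Score1=sum(w1[m] * l[m] for m in MEASURES) / n1,
            Score2=sum(w2[m] * l[m] for m in MEASURES) / n2))
    return pd.DataFrame(rows)


def nearest_species_nomogram(point: NomogramPoint,
                             reference: pd.DataFrame | None = None,
                             query_id: str = "query") -> MatchResult:
    """Rank reference species by Euclidean distance to the sample's point on
    the two-component nomogram plane — the matching step of the field
    workflow for samples of two or more specimens."""
    pts = reference_nomogram_points(reference)
    d = np.hypot(pts.Score1 - point.score1, pts.Score2 - point.score2)
    rank = (pd.DataFrame({"species_code": pts.species_code, "distance": d})
            .sort_values(["distance", "species_code"], kind="stable")
            .reset_index(drop=True))
    return MatchResult(query_id=query_id, method="nomogram_euclidean",
                       ranking=rank)


def nearest_species_euclidean(values: dict, reference: pd.DataFrame | None = None,
                              query_id: str = "query",
                              standardised: bool = False) -> MatchResult:
    """Rank reference species by d_j = sqrt(sum_k (x_k - mean_jk)^2) over the
    six measures.  F2AV is recomputed from the primaries when absent.

    ``standardised=True`` divides each axis by the reference column SD of the
    species means first — a clearly non-canonical variant (the published d_j
    is raw and crunch-force dominated).
    """
    if reference is None:
        reference = load_reference_summaries()
    vals = _complete_f2av(values)
    missing = [m for m in MEASURES if m not in vals]
    if missing:
        raise ValueError(f"missing measures {missing}")
    sp = species_rows(reference)
    x = np.array([vals[m] for m in MEASURES], dtype=float)
    M = sp[[f"{m}_mean" for m in MEASURES]].to_numpy()
    if standardised:
        scale = M.std(axis=0, ddof=1)
        d = np.sqrt((((M - x) / scale) ** 2).sum(axis=1))
    else:
        d = np.sqrt(((M - x) ** 2).sum(axis=1))
    rank = (pd.DataFrame({"species_code": sp.species_code, "distance": d})
            .sort_values(["distance", "species_code"], kind="stable")
            .reset_index(drop=True))
    return MatchResult(query_id=query_id, method="euclidean_dj", ranking=rank)


def sign_code(values: dict, typical: dict | None = None) -> dict:
    """±1 code of the available measures against the typical means
    (ties code -1, like the heuristic coder)."""
    typ = typical or _typical_params()
    return {m: (1 if values[m] > typ[m]["mean"] else -1)
            for m in MEASURES if m in values and values[m] is not None}


def sign_code_lookup(values: dict, reference: pd.DataFrame | None = None,
                     query_id: str = "query") -> MatchResult:
    """High-throughput screening match: compare the query's ±1 code to each
    reference species' code; distance = number of mismatching available
    slots (a Manhattan-style count).  Tolerates missing measures (at least
    one required); co-minimal species are all reported."""
    if reference is None:
        reference = load_reference_summaries()
    q = sign_code(values)
    if not q:
        raise ValueError("at least one measure is required")
    typ = _typical_params()
    sp = species_rows(reference)
    dists = []
    for _, r in sp.iterrows():
        ref_vals = {m: r[f"{m}_mean"] for m in MEASURES}
        rc = sign_code(ref_vals, typ)
        dists.append(sum(q[m] != rc[m] for m in q))
    rank = (pd.DataFrame({"species_code": sp.species_code,
                          "distance": dists})
            .sort_values(["distance", "species_code"], kind="stable")
            .reset_index(drop=True))
    return MatchResult(query_id=query_id, method="sign_code_manhattan",
                       ranking=rank)


def field_predict(sample: pd.DataFrame,
                  reference: pd.DataFrame | None = None,
                  query_id: str = "field_sample") -> dict:
    """The five-step field workflow on a sample of measured specimens.

    Summarise the sample; place it on the nomogram (n >= 2) or fall back to
    the single-specimen d_j route; rank nearest reference species for the
    sample mean specimen (Euclidean and sign-code); attach the trophic
    classification narrative of the best Euclidean match.  Returns one
    structured report with per-step provenance.
    """
    from chelamorph.heuristics import (
        assign_functional_group, encode_trophic_descriptors, verbal_summary)

    if reference is None:
        reference = load_reference_summaries()
    if len(sample) == 0:
        raise ValueError("empty sample")
    sample = sample.copy()
    if "F2AV" not in sample.columns:
        sample["F2AV"] = [
            chelal_forces(L1U=r.L1U, L2M=r.L2M, CHI=r.CHI, CLI=r.CLI).F2AV
            for r in sample.itertuples()]
    mean_specimen = {m: float(sample[m].mean()) for m in MEASURES}
    report = dict(query_id=query_id, n=len(sample),
                  sample_means=mean_specimen)
    single = len(sample) == 1
    report["route"] = ("single_specimen_dj" if single else "nomogram")
    if not single:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            point = nomogram_scores(sample)
        report["nomogram"] = dict(score1=point.score1, score2=point.score2,
                                  lbf_means=point.lbf_means)
        nm = nearest_species_nomogram(point, reference, query_id)
        report["nomogram_matches"] = nm.ranking.head(5).to_dict("records")
    eu = nearest_species_euclidean(mean_specimen, reference, query_id)
    sc = sign_code_lookup(mean_specimen, reference, query_id)
    report["euclidean_matches"] = eu.ranking.head(5).to_dict("records")
    report["sign_code_matches"] = sc.best.to_dict("records")
    best = (report["nomogram_matches"][0]["species_code"] if not single
            else eu.ranking.species_code.iloc[0])
    typ = typical_row(reference)
    row = species_rows(reference).set_index("species_code").loc[best]
    row = pd.Series(dict(row), name=best)
    row["species_code"] = best
    code = encode_trophic_descriptors(row, typ)
    grp = assign_functional_group(code)
    report["best_match"] = dict(species_code=best,
                                group=grp.group,
                                morsel_class=grp.morsel_class,
                                habit=grp.habit,
                                narrative=verbal_summary(code, grp)["text"])
    # a sample sitting at the typical design itself reads as the generalist
    if not single and abs(report["nomogram"]["score1"]) < 0.05 \
            and abs(report["nomogram"]["score2"]) < 0.05:
        report["note"] = ("sample is statistically indistinguishable from "
                          "the typical generalist design")
    return report
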