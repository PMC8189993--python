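"""Synthetic per-species cohorts and the "typical" reference construction.

The published analysis rests on 20 measured females per species, summarised
to mean ± SD; the raw individuals are unpublished.  This module regenerates
cohorts with the statistical structure the analysis assumes — independent
Normal variation per primary measure at the per-species means/SDs — so every
downstream stage (divergence ordination, nomogram recovery, group contrasts)
is testable without external data.  Crunch force per synthetic individual is
computed from its own primaries via the lever model, keeping generator and
force model consistent.

The "typical" reference set is rebuilt exactly as published: synthetic
individual *i*'s measure *k* is the mean over the 47 species of individual
*i*'s measure *k* (applied to all six measures including F2AV), giving a 48th
pseudo-species with its own mean and sample SD.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chelamorph.forces import augment_measurements
from chelamorph.reference import (
    MEASURES, PRIMARY_MEASURES, TYPICAL_CODE, species_rows,
)

_REDRAW_LIMIT = 100


@dataclass
class CohortSpec:
    """Generation plan for per-species cohorts.

    ``within_species_correlation`` is a 5×5 correlation matrix over the
    primary measures (order IL, L1U, L2M, CHI, CLI); identity (independence)
    by default — the published mean per-individual CLI/IL of 0.466 is
    compatible with independence.
    """
    summaries: pd.DataFrame
    n_per_species: int = 20
    seed: int = 0
    within_species_correlation: np.ndarray | None = None

    def __post_init__(self):
        if self.n_per_species < 2:
            raise ValueError("n_per_species must be >= 2")
        if self.within_species_correlation is not None:
            c = np.asarray(self.within_species_correlation, dtype=float)
            if c.shape != (5, 5) or not np.allclose(c, c.T):
                raise ValueError("correlation must be a symmetric 5x5 matrix")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation diagonal must be 1")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation must be positive semi-definite")
            self.within_species_correlation = c


def _species_rng(seed: int, code: str) -> np.random.Generator:
    # stable per-species substream: adding/removing a species never perturbs
    # the draws of the others
    digest = hashlib.blake2s(code.encode(), digest_size=4).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "big")])


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw ``n_per_species`` individuals per species row of the summary
    table.  Draws violating positivity or the pennate-space condition
    ``CLI > 1.1*L2M`` are redrawn (truncation-by-redraw preserves approximate
    Normality near the boundary); more than 100 consecutive redraws for one
    individual aborts naming the species.

    Returns a per-individual frame with species_code, individual_id, the five
    primaries and all derived force/ratio columns.  Identical specs produce
    bit-identical output.
    """
    sp = species_rows(spec.summaries)
    corr = spec.within_species_correlation
    chol = None if corr is None else np.linalg.cholesky(
        corr + 1e-12 * np.eye(5))
    frames = []
    for _, row in sp.iterrows():
        rng = _species_rng(spec.seed, row.species_code)
        means = np.array([row[f"{m}_mean"] for m in PRIMARY_MEASURES])
        sds = np.array([row[f"{m}_sd"] for m in PRIMARY_MEASURES])
        draws = np.empty((spec.n_per_species, 5))
        for i in range(spec.n_per_species):
            for attempt in range(_REDRAW_LIMIT + 1):
                z = rng.standard_normal(5)
                if chol is not None:
                    z = chol @ z
                x = means + sds * z
                il, l1u, l2m, chi, cli = x
                if (x > 0).all() and cli > 1.1 * l2m:
                    draws[i] = x
                    break
            else:
                raise RuntimeError(
                    f"generation failure for species {row.species_code!r}: "
                    f"{_REDRAW_LIMIT} consecutive invalid draws")
        f = pd.DataFrame(draws, columns=list(PRIMARY_MEASURES))
        f.insert(0, "species_code", row.species_code)
        f.insert(1, "individual_id", np.arange(1, spec.n_per_species + 1))
        frames.append(f)
    cohort = pd.concat(frames, ignore_index=True)
    return augment_measurements(cohort)


def build_typical_reference(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Construct the synthetic typical individuals and their summary row.

    Requires equal per-species n.  Typical individual *i* is the across-species
    mean of each species' *i*-th individual, for all six analysis measures
    (F2AV is averaged, not recomputed, matching the published construction).
    Returns ``(typical_individuals, summary_row)`` where the summary row holds
    mean and sample SD (divisor n-1) per measure plus VR.
    """
    counts = cohort.groupby("species_code").size()
    if counts.nunique() != 1:
        raise ValueError("unequal per-species n; the typical construction "
                         "requires the same n for every species")
    n = int(counts.iloc[0])
    cols = list(MEASURES) + ["VR"]
    typical = (cohort.sort_values(["species_code", "individual_id"])
               .groupby("individual_id")[cols].mean().reset_index())
    typical.insert(0, "species_code", TYPICAL_CODE)
    summary = {"species_code": TYPICAL_CODE, "binomial": TYPICAL_CODE, "n": n}
    for m in cols:
        summary[f"{m}_mean"] = typical[m].mean()
        summary[f"{m}_sd"] = typical[m].std(ddof=1)
    return typical, pd.Series(summary)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean and sample SD (divisor n-1) of the six analysis
    measures and VR — the cohort analogue of the packaged reference table."""
    cols = list(MEASURES) + ["VR"]
    g = cohort.groupby("species_code", sort=False)
    out = {"species_code": list(g.groups)}
    out["n"] = g.size().to_numpy()
    for m in cols:
        out[f"{m}_mean"] = g[m].mean().to_numpy()
        out[f"{m}_sd"] = g[m].std(ddof=1).to_numpy()
    return pd.DataFrame(out)
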