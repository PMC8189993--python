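"""Packaged reference tables: species summaries, metadata and comparative records.

The central object is the reference summary table: per-species mean and
standard deviation (n = 20 adult females per species) for the idiosomal index
``IL``, cheliceral length ``CLI`` (reach), moveable-digit length ``L2M``
(gape), velocity ratio ``VR``, consensus crunch force ``F2AV``, cheliceral
height ``CHI`` and the chelal input lever ``L1U``.  It carries 47 species rows
plus one synthetic "Typical" pseudo-species whose measures are per-individual
averages across the 47 species; the Typical row anchors every divergence and
heuristic cut downstream.

All tables are plain CSV (UTF-8, "." decimal, header row); the readers accept
user files in the same dialect for novel species.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

#: The six analysis measures, in canonical order (µm except F2AV, µm²).
MEASURES = ("IL", "L1U", "L2M", "CHI", "CLI", "F2AV")
#: The five primary (directly measured) lengths, µm.
PRIMARY_MEASURES = ("IL", "L1U", "L2M", "CHI", "CLI")
#: All summarised quantities (adds the dimensionless velocity ratio).
SUMMARY_MEASURES = MEASURES + ("VR",)

TYPICAL_CODE = "Typical"


class ReferenceDataError(ValueError):
    """A packaged or user table failed structural validation."""


def _data_path(name: str):
    return resources.files("chelamorph").joinpath("data", name)


def _read_csv(path_or_packaged, packaged_name: str) -> pd.DataFrame:
    if path_or_packaged is None:
        with resources.as_file(_data_path(packaged_name)) as p:
            return pd.read_csv(p)
    return pd.read_csv(Path(path_or_packaged))


@functools.lru_cache(maxsize=1)
def constants() -> dict:
    """Versioned numeric constants (typical reference moments, nomogram
    weights, banding thresholds, condyle inflation factor)."""
    with resources.as_file(_data_path("constants.yaml")) as p:
        return yaml.safe_load(p.read_text())


def load_reference_summaries(path_or_packaged=None) -> pd.DataFrame:
    """Load the per-species summary table (47 species + Typical row).

    Raises :class:`ReferenceDataError` naming the offending row/column on a
    missing column, non-numeric cell, non-positive mean/sd, or duplicate
    species code.
    """
    df = _read_csv(path_or_packaged, "reference_summaries.csv")
    required = ["species_code", "binomial", "n"] + [
        f"{m}_{s}" for m in SUMMARY_MEASURES for s in ("mean", "sd")
    ]
    for col in required:
        if col not in df.columns:
            raise ReferenceDataError(f"missing column {col!r}")
    if df.species_code.duplicated().any():
        dup = df.species_code[df.species_code.duplicated()].iloc[0]
        raise ReferenceDataError(f"duplicate species_code {dup!r}")
    num_cols = [c for c in required if c not in ("species_code", "binomial")]
    for col in num_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.species_code[vals.isna()].iloc[0]
            raise ReferenceDataError(f"non-numeric {col!r} for species {row!r}")
        df[col] = vals
        if (vals <= 0).any():
            row = df.species_code[vals <= 0].iloc[0]
            raise ReferenceDataError(f"non-positive {col!r} for species {row!r}")
    if (df.n < 2).any():
        raise ReferenceDataError("n must be >= 2 for every species")
    return df


def species_rows(summaries: pd.DataFrame) -> pd.DataFrame:
    """The species rows (Typical excluded), original order preserved."""
    return summaries[summaries.species_code != TYPICAL_CODE].reset_index(drop=True)


def typical_row(summaries: pd.DataFrame) -> pd.Series:
    """The Typical pseudo-species row."""
    t = summaries[summaries.species_code == TYPICAL_CODE]
    if len(t) != 1:
        raise ReferenceDataError("table must contain exactly one Typical row")
    return t.iloc[0]


def validate_reference(summaries: pd.DataFrame, tol: float = 0.02) -> pd.DataFrame:
    """Consistency report for the typical-reference construction.

    For each linear measure (and VR) the Typical mean must equal the column
    mean over the species rows (the typical individuals are per-individual
    averages across species, so their mean is the grand mean) within ``tol``,
    which absorbs the 2-dp rounding of the stored values.  The crunch force
    is quadratic in the primaries, so its Typical mean is instead checked
    against the force recomputed from the Typical primary means (the grand
    mean of a product is not the product of grand means; relative tolerance
    0.05%).

    Returns a report frame with one row per check; report-only, never raises.
    """
    from chelamorph.forces import chelal_forces

    sp = species_rows(summaries)
    typ = typical_row(summaries)
    rows = []
    for m in ("IL", "L1U", "L2M", "CHI", "CLI", "VR"):
        col_mean = sp[f"{m}_mean"].mean()
        diff = abs(col_mean - typ[f"{m}_mean"])
        rows.append(dict(measure=m, check="column_mean", expected=col_mean,
                         typical=typ[f"{m}_mean"], abs_diff=diff,
                         tolerance=tol, passed=diff <= tol))
    f = chelal_forces(IL=typ.IL_mean, L1U=typ.L1U_mean, L2M=typ.L2M_mean,
                      CHI=typ.CHI_mean, CLI=typ.CLI_mean)
    rel = abs(f.F2AV - typ.F2AV_mean) / typ.F2AV_mean
    rows.append(dict(measure="F2AV", check="recomputed_from_typical_means",
                     expected=f.F2AV, typical=typ.F2AV_mean,
                     abs_diff=abs(f.F2AV - typ.F2AV_mean),
                     tolerance=0.0005 * typ.F2AV_mean, passed=rel <= 0.0005))
    return pd.DataFrame(rows)


def load_species_metadata(path_or_packaged=None) -> pd.DataFrame:
    """Taxonomy, pest status and published group assignments per species.

    ``published_group`` (omnivore/fragmentary) and ``published_habit``
    (surface/interstitial) are the published binary splits used by the
    hypothesis tests; they are shipped metadata, never recomputed (the split
    of the 17 specialists is not rule-derivable).  ``fig23_group`` is the
    published four-way functional-group assignment.
    """
    df = _read_csv(path_or_packaged, "species_metadata.csv")
    for col in ("species_code", "published_group", "published_habit",
                "fig23_group", "pest"):
        if col not in df.columns:
            raise ReferenceDataError(f"missing column {col!r}")
    return df


def load_comparative_table(path_or_packaged=None) -> pd.DataFrame:
    """Cross-suborder comparative records (oribatids plus two mesostigmatids):
    leverage/velocity ratio, squared cheliceral height, their product (the
    crunch-force surrogate), gape, reach and the source study's trophic
    designation.  Carried verbatim; some source rows have product ≠
    leverage × PHI² and are deliberately not reconciled."""
    df = _read_csv(path_or_packaged, "comparative_records.csv")
    if len(df) == 0:
        raise ReferenceDataError("comparative table is empty")
    num = ["leverage_or_VR", "PHI_squared", "product", "gape", "reach"]
    for col in num + ["taxon", "designation", "source"]:
        if col not in df.columns:
            raise ReferenceDataError(f"missing column {col!r}")
    for col in num:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise ReferenceDataError(f"malformed numeric column {col!r}")
        df[col] = vals
    return df


def load_published_verbal_codes(path_or_packaged=None) -> pd.DataFrame:
    """The transcribed 8-slot verbal trophic coding for the 47 species and
    the Typical row (display and verification data)."""
    return _read_csv(path_or_packaged, "published_verbal_codes.csv")


def load_published_summaries(path_or_packaged=None) -> pd.DataFrame:
    """The published per-species narrative summaries (display data)."""
    return _read_csv(path_or_packaged, "published_summaries.csv")
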