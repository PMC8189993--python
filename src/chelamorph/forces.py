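"""Static chelal lever mechanics: tendon forces, crunch force and shape ratios.

The chela is modelled as a frictionless rigid lever rotating in its condyle.
The velocity ratio ``VR = L1U/L2M`` (input over output moment arm) is the
mechanical advantage; low VR chelae are fast "tweezers", high VR chelae are
strong "pliers".  The adductive tendon force F1 is estimated under two muscle
topologies —

* pennate fibres filling the shaft:  ``F1P = (CHI/2) * (CLI - 1.1*L2M)``
* radial fibres on the base cross-section:  ``F1C = pi * (CHI/2)**2``

— and rectified by VR into output crunch forces F2P and F2C; their mean F2AV
is the topology-agnostic consensus estimate (units µm², a force surrogate).
The 1.1 condyle-inflation factor models the part of the moveable digit lying
inside the base, which shortens the usable muscle space; the halving of CHI
leaves room for the abductor below the adductor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class PennateSpaceError(ValueError):
    """Raised when CLI <= inflation*L2M: the pennate muscle space is
    non-positive and F1P undefined (never returned as a negative force)."""


@dataclass(frozen=True)
class ChelalForces:
    VR: float
    F1P: float
    F1C: float
    F2P: float
    F2C: float
    F2AV: float
    #: VR * CHI**2 — the cross-study comparative axis (uses the full squared
    #: height like the comparative records, not the halved radial area).
    toughness: float


@dataclass(frozen=True)
class DerivedRatios:
    reach_over_size: float      # CLI/IL
    gape_over_size: float       # L2M/IL
    gape_over_reach: float      # L2M/CLI
    aspect: float               # CHI/CLI, cheliceral aspect ratio
    rel_crunch: float           # F2AV/IL
    fd_over_md: float           # CLI/L2M, the classic reach/gape ratio
    rel_lever: float            # L1U/CHI


def chelal_forces(*, IL: float | None = None, L1U: float, L2M: float,
                  CHI: float, CLI: float,
                  condyle_inflation: float = 1.1,
                  shaft_fraction: float = 0.5) -> ChelalForces:
    """Forces for one individual from its primary measures (µm).

    ``condyle_inflation`` and ``shaft_fraction`` default to the reference
    analysis values (1.1; halve the shaft height before squaring) and exist
    as sensitivity knobs only.
    """
    for name, v in (("L1U", L1U), ("L2M", L2M), ("CHI", CHI), ("CLI", CLI)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    if IL is not None and not IL > 0:
        raise ValueError(f"IL must be strictly positive, got {IL}")
    space = CLI - condyle_inflation * L2M
    if space <= 0:
        raise PennateSpaceError(
            f"pennate muscle space non-positive: CLI={CLI} <= "
            f"{condyle_inflation}*L2M={condyle_inflation * L2M:.4g}")
    VR = L1U / L2M
    half = CHI * shaft_fraction
    F1P = half * space
    F1C = math.pi * half ** 2
    F2P = F1P * VR
    F2C = F1C * VR
    return ChelalForces(VR=VR, F1P=F1P, F1C=F1C, F2P=F2P, F2C=F2C,
                        F2AV=(F2P + F2C) / 2.0, toughness=VR * CHI ** 2)


def derived_ratios(*, IL: float, L1U: float, L2M: float, CHI: float,
                   CLI: float, F2AV: float | None = None) -> DerivedRatios:
    """Dimensionless shape/size ratios for one individual.

    ``F2AV`` is recomputed from the primaries when not supplied.
    """
    if F2AV is None:
        F2AV = chelal_forces(IL=IL, L1U=L1U, L2M=L2M, CHI=CHI, CLI=CLI).F2AV
    if not IL > 0:
        raise ValueError("IL must be strictly positive")
    return DerivedRatios(
        reach_over_size=CLI / IL,
        gape_over_size=L2M / IL,
        gape_over_reach=L2M / CLI,
        aspect=CHI / CLI,
        rel_crunch=F2AV / IL,
        fd_over_md=CLI / L2M,
        rel_lever=L1U / CHI,
    )


_FORCE_COLS = ["VR", "F1P", "F1C", "F2P", "F2C", "F2AV", "toughness"]
_RATIO_COLS = ["reach_over_size", "gape_over_size", "gape_over_reach",
               "aspect", "rel_crunch", "fd_over_md", "rel_lever"]


def augment_measurements(df: pd.DataFrame,
                         condyle_inflation: float = 1.1,
                         shaft_fraction: float = 0.5) -> pd.DataFrame:
    """Vectorised batch mode: append force and ratio columns to a
    per-individual table with columns IL, L1U, L2M, CHI, CLI.

    Raises :class:`PennateSpaceError` if any row violates
    ``CLI > condyle_inflation * L2M``.
    """
    out = df.copy()
    for col in ("IL", "L1U", "L2M", "CHI", "CLI"):
        if col not in df.columns:
            raise ValueError(f"missing measurement column {col!r}")
        if (df[col] <= 0).any():
            raise ValueError(f"non-positive values in column {col!r}")
    space = out.CLI - condyle_inflation * out.L2M
    if (space <= 0).any():
        bad = out.index[space <= 0][0]
        raise PennateSpaceError(
            f"pennate muscle space non-positive at row {bad}")
    half = out.CHI * shaft_fraction
    out["VR"] = out.L1U / out.L2M
    out["F1P"] = half * space
    out["F1C"] = np.pi * half ** 2
    out["F2P"] = out.F1P * out.VR
    out["F2C"] = out.F1C * out.VR
    out["F2AV"] = (out.F2P + out.F2C) / 2.0
    out["toughness"] = out.VR * out.CHI ** 2
    out["reach_over_size"] = out.CLI / out.IL
    out["gape_over_size"] = out.L2M / out.IL
    out["gape_over_reach"] = out.L2M / out.CLI
    out["aspect"] = out.CHI / out.CLI
    out["rel_crunch"] = out.F2AV / out.IL
    out["fd_over_md"] = out.CLI / out.L2M
    out["rel_lever"] = out.L1U / out.CHI
    return out
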