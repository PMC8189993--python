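"""Heuristic trophic classification: descriptor coding, four-box models,
functional groups, verbal summaries and cross-suborder banding.

Eight binary descriptors code each species against the typical reference
mite: four absolute (body size IL, reach CLI, food hardness F2AV, food size
L2M) and four relative (CLI/IL how far food is handled from the body,
F2AV/IL grip power, L2M/IL grab, L2M/CLI oral stuffing).  A species codes
+1 on a slot when its value lies strictly above the typical cut, -1 at or
below it (ties code low: the Typical row itself carries the all-low labels).
Ratio cuts are ratios of the Typical means, compared against each species'
ratio of means.

The four-way functional-group partition follows from the code: large
pan-saprophages are the chunk-crunching "demolition" omnivores (type 1),
small fragmentary feeders the selective picking/squashing design (type 2),
small long-reach pan-saprophages the small (interstitial/burrowing)
omnivores, everything else a specialist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from chelamorph.reference import constants

#: slot -> (value extractor keys, label if +1, label if -1)
DESCRIPTORS = {
    "size": ("IL", None, "Large", "Small"),
    "reach": ("CLI", None, "Long Range", "Short distance"),
    "rel_reach": ("CLI", "IL", "Well away", "Close to"),
    "hardness": ("F2AV", None, "Hard", "Soft"),
    "grip": ("F2AV", "IL", "Powerful grip", "Feeble effort"),
    "food_size": ("L2M", None, "Big food", "Small food"),
    "grab": ("L2M", "IL", "Major grab", "Little chunks"),
    "stuffing": ("L2M", "CLI", "Well stuffed", "Tiny mouthfulls"),
}

FOUR_BOX_PAIRINGS = [("IL", "CLI"), ("L2M", "F2AV"), ("L2M", "CLI"),
                     ("L2M", "IL"), ("F2AV", "CLI"), ("IL", "F2AV")]

_MEASURE_SLOT = {"IL": "size", "CLI": "reach", "F2AV": "hardness",
                 "L2M": "food_size"}


@dataclass(frozen=True)
class TrophicCode:
    species_code: str
    signs: dict      # slot -> +1 / -1
    labels: dict     # slot -> verbal label

    def as_row(self) -> dict:
        return dict(species_code=self.species_code, **self.labels)


@dataclass(frozen=True)
class FunctionalGroup:
    group: str            # omnivore_type1 | fragmentary_type2 | small_omnivore | specialist
    morsel_class: str     # pan_saprophage | macro_saprophage | micro_saprophage | fragmentary_feeder
    habit: str            # surface | interstitial
    specialist_sublabel: str = ""


def _value(summary, measure, denom):
    v = summary[f"{measure}_mean"]
    return v if denom is None else v / summary[f"{denom}_mean"]


def encode_trophic_descriptors(summary: pd.Series,
                               typical: pd.Series) -> TrophicCode:
    """Code one species summary against the typical reference (ties -> -1)."""
    signs, labels = {}, {}
    for slot, (m, denom, hi, lo) in DESCRIPTORS.items():
        cut = _value(typical, m, denom)
        val = _value(summary, m, denom)
        s = 1 if val > cut else -1
        signs[slot] = s
        labels[slot] = hi if s == 1 else lo
    return TrophicCode(species_code=summary["species_code"],
                       signs=signs, labels=labels)


_QUADRANT_TEXT = {
    ("IL", "CLI"): {
        (1, 1): "surface-living, potential crevice feeding/excavating",
        (1, -1): "surface-living, substratum browsing/gleaning",
        (-1, 1): "interstitial cavity-living, possible crevice feeding/excavating",
        (-1, -1): "interstitial cavity-living, substratum browsing/gleaning",
    },
    ("L2M", "F2AV"): {
        (1, 1): "large and hard food morsels (pan-saprophage)",
        (1, -1): "large but soft food morsels (macro-saprophage)",
        (-1, 1): "small but hard food morsels (micro-saprophage)",
        (-1, -1): "only small soft morsels (fragmentary feeder)",
    },
}


def four_box(summary: pd.Series, typical: pd.Series,
             model: tuple[str, str]) -> dict:
    """One of the six two-measure quadrant models.

    Returns the pair of above/below indicators, a quadrant name, and the
    quadrant semantics where the published model attaches one.
    """
    model = tuple(model)
    if model not in FOUR_BOX_PAIRINGS:
        raise ValueError(f"unknown pairing {model!r}; "
                         f"valid: {FOUR_BOX_PAIRINGS}")
    code = encode_trophic_descriptors(summary, typical)
    sx = code.signs[_MEASURE_SLOT[model[0]]]
    sy = code.signs[_MEASURE_SLOT[model[1]]]
    name = {(1, 1): "both-high", (1, -1): "x-high", (-1, 1): "y-high",
            (-1, -1): "both-low"}[(sx, sy)]
    semantics = _QUADRANT_TEXT.get(model, {}).get(
        (sx, sy), f"{model[0]} {'above' if sx > 0 else 'at/below'} and "
                  f"{model[1]} {'above' if sy > 0 else 'at/below'} typical")
    return dict(model=model, x_sign=sx, y_sign=sy, quadrant=name,
                semantics=semantics)


def assign_functional_group(code: TrophicCode) -> FunctionalGroup:
    """Functional group and morsel class from the descriptor signs."""
    s = code.signs
    morsel = {(1, 1): "pan_saprophage", (1, -1): "macro_saprophage",
              (-1, 1): "micro_saprophage", (-1, -1): "fragmentary_feeder"}[
        (s["food_size"], s["hardness"])]
    habit = "surface" if s["size"] == 1 else "interstitial"
    sub = ""
    if s["size"] == 1 and morsel == "pan_saprophage":
        group = "omnivore_type1"
    elif s["size"] == -1 and morsel == "fragmentary_feeder":
        group = "fragmentary_type2"
    elif s["size"] == -1 and s["reach"] == 1 and morsel == "pan_saprophage":
        group = "small_omnivore"
    else:
        group = "specialist"
        if s["size"] == -1 and morsel == "pan_saprophage":
            sub = "wide-mouthed durophage"
        elif s["size"] == 1 and morsel == "fragmentary_feeder":
            sub = "surface fragmentary variant"
        elif morsel == "macro_saprophage":
            sub = f"{habit} macro-saprophage soft-feeder"
        elif morsel == "micro_saprophage":
            sub = f"{habit} micro-saprophage durophage"
    return FunctionalGroup(group=group, morsel_class=morsel, habit=habit,
                           specialist_sublabel=sub)


_CLASS_TOKEN = {"pan_saprophage": "Pan-saprophages",
                "macro_saprophage": "Macro-saprophages",
                "micro_saprophage": "Micro-saprophages",
                "fragmentary_feeder": "Fragmentary feeders"}

_MORSEL_CLAUSE = {
    "pan_saprophage": "Potential specialist for large (and small) and hard (and soft) food morsels",
    "macro_saprophage": "Potential specialist for large but must be soft food morsels",
    "micro_saprophage": "Only small morsels but potential specialist for hard (and soft) food",
    "fragmentary_feeder": "Only small and soft food morsels",
}

_EPITHETS = {
    ("surface", "pan_saprophage"): "Chunk or Demolition feeder, Nutcracker or Cruncher",
    ("interstitial", "pan_saprophage"): "Burrowing Cruncher",
    ("surface", "macro_saprophage"): "Chunk or Demolition feeder, Squasher, Soft slicer or ‘Plankton’ feeder",
    ("interstitial", "macro_saprophage"): "Wide-mouthed burrower, Squasher, Soft slicer or ‘Plankton’ feeder",
    ("surface", "micro_saprophage"): "Picker or ‘Plankton’ feeder, Nutcracker or Cruncher",
    ("interstitial", "micro_saprophage"): "Burrowing picker, Nutcracker or Cruncher",
    ("surface", "fragmentary_feeder"): "Picker, Squasher, Soft slicer or ‘Plankton’ feeder",
    ("interstitial", "fragmentary_feeder"): "Burrowing picker, Selective burrower, Squasher, Soft slicer or ‘Plankton’ feeder",
}


def verbal_summary(code: TrophicCode, group: FunctionalGroup) -> dict:
    """Standardised narrative tokens and the assembled sentence."""
    habit_sentence = ("Surface-living" if group.habit == "surface"
                      else "Interstitial. Potential cavity-living")
    if code.signs["reach"] == 1:
        foraging = ("potential crevice feeding/excavating specialist"
                    if group.habit == "surface"
                    else "possible crevice feeding/excavating specialist")
    else:
        foraging = "substratum browsing/gleaning generalist"
    token = _CLASS_TOKEN[group.morsel_class]
    clause = _MORSEL_CLAUSE[group.morsel_class]
    epithets = _EPITHETS[(group.habit, group.morsel_class)]
    text = f"{habit_sentence}, {foraging}. {clause} ({token}). {epithets}"
    return dict(habit_sentence=habit_sentence, foraging_clause=foraging,
                class_token=token, morsel_clause=clause, epithets=epithets,
                text=text)


def cross_suborder_band(VR: float, CHI: float) -> dict:
    """Band a chelicera on the cross-suborder speed/toughness axes.

    Toughness is VR*CHI² (the comparative crunch-force surrogate); bands at
    the published thresholds, ties banding down.  The pest-range flag marks
    toughness at or above the lowest value seen among recognised pests.
    """
    if not VR > 0 or not CHI > 0:
        raise ValueError("VR and CHI must be strictly positive")
    c = constants()["bands"]
    tough = VR * CHI ** 2
    t_edges = c["toughness"]
    v_edges = c["velocity_ratio"]
    t_band = sum(tough > e for e in t_edges)
    v_band = sum(VR > e for e in v_edges)
    t_labels = ["hypocarnivore/fragmentary band", "secondary-decomposer band",
                "macrophytophage band", "extreme durophage band"]
    v_labels = ["cutting-carnivore band", "crushing/microphytophage band",
                "secondary-decomposer band", "primary-decomposer-like"]
    return dict(toughness=tough, toughness_band=t_labels[t_band],
                velocity_ratio_band=v_labels[v_band],
                pest_range=tough >= c["pest_toughness"])


def classify_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Run coder, grouping, banding and narrative for every species row
    against the table's Typical row."""
    from chelamorph.reference import species_rows, typical_row

    typ = typical_row(summaries)
    rows = []
    for _, r in species_rows(summaries).iterrows():
        code = encode_trophic_descriptors(r, typ)
        grp = assign_functional_group(code)
        verbal = verbal_summary(code, grp)
        band = cross_suborder_band(r["VR_mean"], r["CHI_mean"])
        rows.append(dict(species_code=r.species_code, **code.labels,
                         group=grp.group, morsel_class=grp.morsel_class,
                         habit=grp.habit,
                         specialist_sublabel=grp.specialist_sublabel,
                         **{k: v for k, v in band.items()},
                         narrative=verbal["text"]))
    return pd.DataFrame(rows)
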