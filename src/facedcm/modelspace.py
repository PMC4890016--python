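"""Enumeration of the 96-model space over the bilateral face network.

All models share the endogenous skeleton (reciprocal intrahemispheric
connections among EVC, OFA and FFA in each hemisphere; reciprocal
interhemispheric connections between homotopic OFA and between homotopic
FFA; no EVC-EVC and no heterotopic links) and the driving inputs (RVF to
left EVC, LVF to right EVC).

Models differ in where and how experimental inputs modulate connections:

* six *families* (A-F) defined by which intrahemispheric forward sites
  (EVC->OFA, OFA->FFA, EVC->FFA, applied bilaterally) are modulated, and
* sixteen *context combinations* per family: the intrahemispheric and the
  interhemispheric modulation each take one of four contexts -
  visual field (S), faces (F), both (F+S), or faces conditional on the
  visual field (FxS).

Family membership beyond the two text-anchored families (B and F) is
configurable; the defaults below grade from a single modulated site to all
three.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .forward import DCMSpec, N_REGIONS, REGIONS
from .paradigm import INPUT_LABELS

__all__ = [
    "CONTEXTS",
    "FORWARD_SITES",
    "DEFAULT_FAMILIES",
    "FamilyConfig",
    "build_endogenous_skeleton",
    "expand_context",
    "make_spec",
    "enumerate_model_space",
]

#: Modulation contexts: visual field, faces, both, faces-by-field interaction.
CONTEXTS = ("S", "F", "F+S", "FxS")

#: Intrahemispheric forward sites (applied bilaterally).
FORWARD_SITES = ("EVC->OFA", "OFA->FFA", "EVC->FFA")

_IDX = {r: i for i, r in enumerate(REGIONS)}
_UIDX = {lab: i for i, lab in enumerate(INPUT_LABELS)}

#: Interhemispheric links, (source, target), grouped by direction.
_INTER_L2R = (("OFA_L", "OFA_R"), ("FFA_L", "FFA_R"))
_INTER_R2L = (("OFA_R", "OFA_L"), ("FFA_R", "FFA_L"))


@dataclass(frozen=True)
class FamilyConfig:
    family_id: str
    modulated_forward_sites: tuple[str, ...]

    def __post_init__(self):
        bad = set(self.modulated_forward_sites) - set(FORWARD_SITES)
        if bad:
            raise ValueError(f"unknown forward sites: {sorted(bad)}")


#: Default family definitions.  B (EVC->OFA and OFA->FFA) and F (all three)
#: are fixed by the analysis; A, C, D, E grade the remaining subsets.
DEFAULT_FAMILIES = (
    FamilyConfig("A", ("EVC->OFA",)),
    FamilyConfig("B", ("EVC->OFA", "OFA->FFA")),
    FamilyConfig("C", ("OFA->FFA",)),
    FamilyConfig("D", ("EVC->FFA",)),
    FamilyConfig("E", ("EVC->OFA", "EVC->FFA")),
    FamilyConfig("F", ("EVC->OFA", "OFA->FFA", "EVC->FFA")),
)


def build_endogenous_skeleton() -> DCMSpec:
    """Endogenous (A) and driving (C) structure shared by all models."""
    a = np.eye(N_REGIONS, dtype=int)
    for hemi in ("L", "R"):
        for src, dst in (("EVC", "OFA"), ("OFA", "FFA"), ("EVC", "FFA")):
            i, j = _IDX[f"{dst}_{hemi}"], _IDX[f"{src}_{hemi}"]
            a[i, j] = 1
            a[j, i] = 1
    for src, dst in _INTER_L2R + _INTER_R2L:
        a[_IDX[dst], _IDX[src]] = 1

    c = np.zeros((N_REGIONS, len(INPUT_LABELS)), dtype=int)
    c[_IDX["EVC_L"], _UIDX["RVF"]] = 1
    c[_IDX["EVC_R"], _UIDX["LVF"]] = 1

    b = np.zeros((len(INPUT_LABELS), N_REGIONS, N_REGIONS), dtype=int)
    return DCMSpec(a_mask=a, b_masks=b, c_mask=c, input_labels=INPUT_LABELS)


def _site_links(site: str, hemi: str) -> tuple[int, int]:
    src, dst = site.split("->")
    return _IDX[f"{dst}_{hemi}"], _IDX[f"{src}_{hemi}"]


def expand_context(combo: tuple[str, str], family: FamilyConfig) -> np.ndarray:
    """Modulation masks (5, 6, 6) for one (inter, intra) context combo.

    Intrahemispheric placement: ``S`` puts RVF on the left-hemisphere
    members of the family's forward sites and LVF on the right-hemisphere
    ones (stimuli drive the contralateral hemisphere); ``F`` puts the faces
    input on all family sites bilaterally; ``F+S`` is the union; ``FxS``
    mirrors ``S`` with the conditional faces|RVF / faces|LVF inputs.
    Interhemispheric placement applies the same logic to the four homotopic
    links: lateralized inputs modulate the links leaving their driven
    hemisphere (RVF the left-to-right links, LVF the right-to-left links).
    """
    inter, intra = combo
    if inter not in CONTEXTS or intra not in CONTEXTS:
        raise ValueError(f"unknown context in combo {combo}")
    b = np.zeros((len(INPUT_LABELS), N_REGIONS, N_REGIONS), dtype=int)

    lateral_intra = {"S": ("RVF", "LVF"), "FxS": ("faces|RVF", "faces|LVF")}

    def place_intra(ctx):
        if ctx in lateral_intra:
            left_in, right_in = lateral_intra[ctx]
            for site in family.modulated_forward_sites:
                b[(_UIDX[left_in], *_site_links(site, "L"))] = 1
                b[(_UIDX[right_in], *_site_links(site, "R"))] = 1
        elif ctx == "F":
            for site in family.modulated_forward_sites:
                for hemi in ("L", "R"):
                    b[(_UIDX["faces"], *_site_links(site, hemi))] = 1
        else:  # F+S
            place_intra("F")
            place_intra("S")

    def place_inter(ctx):
        if ctx in lateral_intra:
            l2r_in, r2l_in = lateral_intra[ctx]
            for src, dst in _INTER_L2R:
                b[_UIDX[l2r_in], _IDX[dst], _IDX[src]] = 1
            for src, dst in _INTER_R2L:
                b[_UIDX[r2l_in], _IDX[dst], _IDX[src]] = 1
        elif ctx == "F":
            for src, dst in _INTER_L2R + _INTER_R2L:
                b[_UIDX["faces"], _IDX[dst], _IDX[src]] = 1
        else:
            place_inter("F")
            place_inter("S")

    place_intra(intra)
    place_inter(inter)
    return b


def make_spec(family: FamilyConfig, combo: tuple[str, str]) -> DCMSpec:
    """One fully specified model: skeleton plus the combo's modulations."""
    spec = build_endogenous_skeleton()
    spec.b_masks = expand_context(combo, family)
    spec.family_id = family.family_id
    spec.combo = combo
    spec.validate()
    return spec


def enumerate_model_space(
    families: tuple[FamilyConfig, ...] = DEFAULT_FAMILIES,
) -> list[DCMSpec]:
    """All models: every family crossed with the 16 context combos.

    Deterministic ordering: families in the given order, combos with the
    interhemispheric context varying slowest (model tag "inter/intra").
    """
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids")
    sites = [tuple(sorted(f.modulated_forward_sites)) for f in families]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate family definitions")
    return [
        make_spec(fam, (inter, intra))
        for fam in families
        for inter, intra in product(CONTEXTS, CONTEXTS)
    ]
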