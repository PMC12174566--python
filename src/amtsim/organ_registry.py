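"""Static domain knowledge: organs, Five-Elements cycles, exterior-interior
pairs, meridians and WHO acupoint codes.

Traditional Chinese medicine classifies the internal organs into five
*viscera* (zang: liver, heart, spleen, lung, kidney), each bearing one of the
Five Elements, and six *bowels* (fu: gallbladder, small intestine, stomach,
large intestine, bladder, triple energizer), paired exterior-interior with a
viscus (the pericardium is treated as a sixth viscus for pairing purposes but
carries no element).  The Five Elements are linked by a generation cycle
(wood -> fire -> earth -> metal -> water -> wood) and a restriction cycle
(wood -| earth, earth -| water, water -| fire, fire -| metal, metal -| wood).

Meridians and acupoints follow the WHO Standard Acupuncture Nomenclature:
12 organ meridians plus the conception vessel (CV) and governor vessel (GV)
carry 361 standard points; 48 extra points (EX) in five labeled sub-series
lie outside the meridians.  The registry is shipped as a packaged JSON file
and validated (per-meridian counts and totals) at load time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Optional


class RegistryError(ValueError):
    """Registry data failed validation at load."""


class AcupointError(ValueError):
    """An acupoint code is malformed or out of range."""


@dataclass(frozen=True)
class Organ:
    name: str
    klass: str      # "viscus" | "bowel"
    element: str    # wood/fire/earth/metal/water, or "none"


_ORGAN_ROWS = [
    ("liver", "viscus", "wood"),
    ("heart", "viscus", "fire"),
    ("spleen", "viscus", "earth"),
    ("lung", "viscus", "metal"),
    ("kidney", "viscus", "water"),
    ("pericardium", "viscus", "none"),
    ("gallbladder", "bowel", "none"),
    ("small_intestine", "bowel", "none"),
    ("stomach", "bowel", "none"),
    ("large_intestine", "bowel", "none"),
    ("bladder", "bowel", "none"),
    ("triple_energizer", "bowel", "none"),
]

ORGANS: dict[str, Organ] = {n: Organ(n, k, e) for n, k, e in _ORGAN_ROWS}

#: The five element-bearing viscera, in generation-cycle order starting at wood.
ELEMENT_VISCERA = ("liver", "heart", "spleen", "lung", "kidney")

#: All six viscera (incl. pericardium) and all six bowels.
VISCERA = tuple(n for n, k, _ in _ORGAN_ROWS if k == "viscus")
BOWELS = tuple(n for n, k, _ in _ORGAN_ROWS if k == "bowel")
ALL_ORGANS = VISCERA + BOWELS

_ELEMENT_OF = {v: ORGANS[v].element for v in ELEMENT_VISCERA}
_GENERATION = {"wood": "fire", "fire": "earth", "earth": "metal",
               "metal": "water", "water": "wood"}
_RESTRICTION = {"wood": "earth", "earth": "water", "water": "fire",
                "fire": "metal", "metal": "wood"}
_VISCUS_OF_ELEMENT = {e: v for v, e in _ELEMENT_OF.items()}

_PAIRS = {
    "liver": "gallbladder",
    "heart": "small_intestine",
    "spleen": "stomach",
    "lung": "large_intestine",
    "kidney": "bladder",
    "pericardium": "triple_energizer",
}
_PAIRS_INV = {b: v for v, b in _PAIRS.items()}


def _require_element_viscus(name: str) -> None:
    if name not in ELEMENT_VISCERA:
        raise RegistryError(f"{name!r} is not an element-bearing viscus")


def generation_partner(viscus: str) -> str:
    """The viscus whose element *generates* ``viscus``'s element
    (e.g. the heart, fire, is generated by the liver, wood)."""
    _require_element_viscus(viscus)
    gen_element = {v: k for k, v in _GENERATION.items()}[_ELEMENT_OF[viscus]]
    return _VISCUS_OF_ELEMENT[gen_element]


def restriction_partner(viscus: str) -> str:
    """The viscus whose element *restricts* ``viscus``'s element
    (e.g. the heart, fire, is restricted by the kidney, water)."""
    _require_element_viscus(viscus)
    res_element = {v: k for k, v in _RESTRICTION.items()}[_ELEMENT_OF[viscus]]
    return _VISCUS_OF_ELEMENT[res_element]


def paired_bowel(viscus: str) -> str:
    """The exterior-interior bowel of a viscus (incl. pericardium)."""
    try:
        return _PAIRS[viscus]
    except KeyError:
        raise RegistryError(f"{viscus!r} is not a viscus") from None


def paired_viscus(bowel: str) -> str:
    try:
        return _PAIRS_INV[bowel]
    except KeyError:
        raise RegistryError(f"{bowel!r} is not a bowel") from None


def exterior_interior_partner(organ: str) -> str:
    """The exterior-interior partner of any of the 12 organs (an involution)."""
    if organ in _PAIRS:
        return _PAIRS[organ]
    if organ in _PAIRS_INV:
        return _PAIRS_INV[organ]
    raise RegistryError(f"unknown organ {organ!r}")


VISCUS_BOWEL_PAIRS = tuple(_PAIRS.items())


# --------------------------------------------------------------------------
# meridians and acupoints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Meridian:
    code: str
    name: str
    organ: Optional[str]
    n_points: int
    ex_subranges: Optional[dict] = None   # EX only: sub-series label -> count


@dataclass(frozen=True, order=True)
class AcupointCode:
    meridian: str
    index: int
    subseries: Optional[str] = None   # EX only

    def __str__(self) -> str:
        if self.subseries:
            return f"{self.meridian}-{self.subseries}{self.index}"
        return f"{self.meridian}{self.index}"


def registry_payload() -> dict:
    """The registry as a JSON-compatible dict (single source of truth for the
    packaged data file; used by the fixtures command to rematerialize it)."""
    with resources.files("amtsim.data").joinpath("meridians.json").open() as fh:
        return json.load(fh)


def _load_meridians() -> dict[str, Meridian]:
    payload = registry_payload()
    meridians: dict[str, Meridian] = {}
    for row in payload["meridians"]:
        m = Meridian(row["code"], row["name"], row["organ"], row["n_points"],
                     row.get("subseries"))
        if m.organ is not None and m.organ not in ORGANS:
            raise RegistryError(f"meridian {m.code} references unknown organ {m.organ!r}")
        meridians[m.code] = m
    standard = sum(m.n_points for m in meridians.values() if m.code != "EX")
    if standard != 361:
        raise RegistryError(f"standard acupoint total is {standard}, expected 361")
    ex = meridians.get("EX")
    if ex is None or ex.ex_subranges is None:
        raise RegistryError("registry must define the EX extra-point sub-series")
    if sum(ex.ex_subranges.values()) != ex.n_points or ex.n_points != 48:
        raise RegistryError("EX sub-series counts must total 48")
    return meridians


MERIDIANS: dict[str, Meridian] = _load_meridians()

#: Meridian code affiliated with each of the 12 organs.
MERIDIAN_OF_ORGAN: dict[str, str] = {
    m.organ: m.code for m in MERIDIANS.values() if m.organ is not None
}

_ACUPOINT_RE = re.compile(
    r"^\s*([A-Za-z]{2})\s*-?\s*(?:([A-Za-z]{1,2})\s*-?\s*)?(\d+)\s*$")


def parse_acupoint(text: str) -> AcupointCode:
    """Parse a WHO acupoint code such as ``GB20``, ``GB-20`` or ``EX-HN4``.

    Case-insensitive; validates the index against the meridian's point count
    (per sub-series for EX).
    """
    m = _ACUPOINT_RE.match(str(text))
    if not m:
        raise AcupointError(f"malformed acupoint code {text!r}")
    code, sub, idx = m.group(1).upper(), m.group(2), int(m.group(3))
    meridian = MERIDIANS.get(code)
    if meridian is None:
        raise AcupointError(f"unknown meridian code {code!r} in {text!r}")
    if code == "EX":
        if sub is None:
            raise AcupointError(f"EX points need a sub-series label (e.g. EX-HN4): {text!r}")
        sub = sub.upper()
        ranges = meridian.ex_subranges or {}
        if sub not in ranges:
            raise AcupointError(f"unknown EX sub-series {sub!r} in {text!r}")
        if not 1 <= idx <= ranges[sub]:
            raise AcupointError(
                f"index {idx} out of range 1..{ranges[sub]} for EX-{sub} in {text!r}")
        return AcupointCode("EX", idx, sub)
    if sub is not None:
        raise AcupointError(f"meridian {code} has no sub-series: {text!r}")
    if not 1 <= idx <= meridian.n_points:
        raise AcupointError(
            f"index {idx} out of range 1..{meridian.n_points} for {code} in {text!r}")
    return AcupointCode(code, idx)


def format_acupoint(a: AcupointCode) -> str:
    """Canonical text form (inverse of :func:`parse_acupoint`)."""
    return str(a)


def organ_of_acupoint(a: AcupointCode | str) -> Optional[str]:
    """The organ affiliated with an acupoint's meridian; ``None`` for the
    conception/governor vessels and extra points."""
    if isinstance(a, str):
        a = parse_acupoint(a)
    return MERIDIANS[a.meridian].organ


def iter_acupoints() -> Iterator[AcupointCode]:
    """All 409 recognized acupoints (361 standard + 48 extra), in a stable
    order (meridian registry order, ascending index)."""
    for m in MERIDIANS.values():
        if m.code == "EX":
            for sub, count in (m.ex_subranges or {}).items():
                for i in range(1, count + 1):
                    yield AcupointCode("EX", i, sub)
        else:
            for i in range(1, m.n_points + 1):
                yield AcupointCode(m.code, i)


def total_points() -> tuple[int, int]:
    """(standard, extra) acupoint totals."""
    standard = sum(m.n_points for m in MERIDIANS.values() if m.code != "EX")
    return standard, MERIDIANS["EX"].n_points
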