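"""Controlled vocabularies and category assignment.

Marine fishes are binned into four trophic-level categories; crustaceans and
molluscs form a fifth "other seafoods" (OSE) category. Methylmercury
biomagnifies up the food web, so the trophic bin is the single most important
predictor of a fish's MeHg burden and the unit at which concentrations are
aggregated. Marine areas follow the FAO major-fishing-area vocabulary.
"""

from __future__ import annotations

from typing import Optional

#: The 19 FAO major marine fishing areas (controlled vocabulary).
FAO_AREAS: tuple[str, ...] = (
    "Arctic Sea",
    "Atlantic Antarctic",
    "Atlantic Eastern Central",
    "Atlantic Northeast",
    "Atlantic Northwest",
    "Atlantic Southeast",
    "Atlantic Southwest",
    "Atlantic Western Central",
    "Indian Ocean Antarctic",
    "Indian Ocean Eastern",
    "Indian Ocean Western",
    "Mediterranean and Black Sea",
    "Pacific Antarctic",
    "Pacific Eastern Central",
    "Pacific Northeast",
    "Pacific Northwest",
    "Pacific Southeast",
    "Pacific Southwest",
    "Pacific Western Central",
)

_AREA_LOOKUP = {name.casefold(): name for name in FAO_AREAS}

#: Trophic-level categories for marine fishes, in bioaccumulation order.
FISH_LEVELS: tuple[str, ...] = ("Level 1", "Level 2", "Level 3", "Level 4")

#: Label for other seafoods (crustaceans and molluscs), excluding marine fishes.
OSE: str = "OSE"

#: All five seafood categories handled by the pipeline.
CATEGORIES: tuple[str, ...] = FISH_LEVELS + (OSE,)

# Trophic bins: Level 1 = [1.5, 2.5), Level 2 = [2.5, 3.5), Level 3 = [3.5, 4.5),
# Level 4 = [4.5, 5.5]. Left-closed by convention; the top edge is included.
TROPHIC_MIN = 1.5
TROPHIC_MAX = 5.5

#: ISSCAAP capture-statistics groups recognised by the pipeline.
ISSCAAP_GROUPS = {
    "Marine Fishes": "FISH",
    "Crustaceans": "OSE",
    "Molluscs": "OSE",
}


def assign_trophic_category(trophic_level: float) -> str:
    """Bin a fish trophic level into one of the four Level categories.

    Bins are left-closed ([1.5, 2.5) -> Level 1, ...) except the top bin,
    which includes 5.5.

    Raises
    ------
    ValueError
        If the trophic level is outside [1.5, 5.5].
    """
    tl = float(trophic_level)
    if not (TROPHIC_MIN <= tl <= TROPHIC_MAX):
        raise ValueError(
            f"trophic level {tl} outside the supported range "
            f"[{TROPHIC_MIN}, {TROPHIC_MAX}]"
        )
    if tl < 2.5:
        return "Level 1"
    if tl < 3.5:
        return "Level 2"
    if tl < 4.5:
        return "Level 3"
    return "Level 4"


def assign_group(isscaap_category: str) -> str:
    """Map an ISSCAAP capture category to the pipeline's FISH / OSE split."""
    try:
        return ISSCAAP_GROUPS[isscaap_category]
    except KeyError:
        accepted = ", ".join(sorted(ISSCAAP_GROUPS))
        raise ValueError(
            f"unrecognised ISSCAAP category {isscaap_category!r}; "
            f"accepted values: {accepted}"
        ) from None


def validate_area(name: object) -> Optional[str]:
    """Return the canonical FAO area name, or None if not in the vocabulary.

    Matching is case-insensitive and whitespace-tolerant. A None return is a
    soft rejection signal consumed by the screening filters; it is not an
    error, because records with unidentifiable areas are an expected part of
    the raw literature corpus.
    """
    if name is None:
        return None
    text = str(name).strip()
    if not text or text.lower() == "nan":
        return None
    return _AREA_LOOKUP.get(text.casefold())
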