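"""Trait catalogue for twice-daily milk recording.

Nine traits are tracked per test day: milk itself, total fat, and seven
fatty-acid (FA) traits predicted from mid-infrared spectra — the saturated
(SFA), unsaturated (UFA) and mono-unsaturated (MUFA) groups, the short-,
medium- and long-chain groups (SCFA, MCFA, LCFA), and oleic acid
(C18:1 cis-9).  Contents are concentrations in g/dL of milk; yields are
masses secreted per milking or per day (g; milk itself is in kg).

Unit convention used throughout the package: 1 kg of milk occupies 10 dL,
so ``yield (g) = content (g/dL) x milk (kg) x 10``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: multiply content (g/dL) by milk (kg) and this factor to get grams
DL_PER_KG_MILK = 10.0

MILK = "milk"
FAT = "fat"

#: the seven FA traits, in conventional reporting order
FA_TRAITS = ("sfa", "mufa", "ufa", "scfa", "mcfa", "lcfa", "c18_1_cis9")

#: traits carrying a content (g/dL); everything except milk
CONTENT_TRAITS = (FAT,) + FA_TRAITS

#: all nine traits
ALL_TRAITS = (MILK,) + CONTENT_TRAITS

_LABELS = {
    MILK: "Milk",
    FAT: "Fat",
    "sfa": "SFA",
    "mufa": "MUFA",
    "ufa": "UFA",
    "scfa": "SCFA",
    "mcfa": "MCFA",
    "lcfa": "LCFA",
    "c18_1_cis9": "C18:1 cis-9",
}


@dataclass(frozen=True)
class Trait:
    """One recorded trait with its measurement units."""

    trait_id: str
    label: str
    content_unit: str  # "g/dL of milk" ("" for milk)
    yield_unit: str  # "g/day" ("kg/day" for milk)

    @property
    def has_content(self) -> bool:
        return self.trait_id != MILK


class TraitCatalog:
    """Fixed registry of the nine milk-recording traits."""

    def __init__(self) -> None:
        self._traits = {
            t: Trait(
                trait_id=t,
                label=_LABELS[t],
                content_unit="" if t == MILK else "g/dL of milk",
                yield_unit="kg/day" if t == MILK else "g/day",
            )
            for t in ALL_TRAITS
        }

    def __getitem__(self, trait_id: str) -> Trait:
        try:
            return self._traits[trait_id]
        except KeyError:
            raise KeyError(
                f"unknown trait {trait_id!r}; expected one of {ALL_TRAITS}"
            ) from None

    def __iter__(self):
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    @property
    def content_traits(self) -> tuple[str, ...]:
        return CONTENT_TRAITS

    @property
    def trait_ids(self) -> tuple[str, ...]:
        return ALL_TRAITS


CATALOG = TraitCatalog()


def content_column(trait: str, session: str) -> str:
    """Column name holding a session content, e.g. ``content_am_fat``."""
    if trait not in CONTENT_TRAITS:
        raise KeyError(f"trait {trait!r} has no content (content traits: {CONTENT_TRAITS})")
    if session not in ("am", "pm"):
        raise ValueError(f"session must be 'am' or 'pm', got {session!r}")
    return f"content_{session}_{trait}"


def yield_grams(content_g_per_dl, milk_kg):
    """Mass of a component (g) in ``milk_kg`` kg of milk at the given content."""
    return content_g_per_dl * milk_kg * DL_PER_KG_MILK
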