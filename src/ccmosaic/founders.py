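"""The eight Collaborative Cross founder strains and their letter codes.

The CC is derived from five classical laboratory strains and three
wild-derived strains; the single-letter codes A-H follow the community
convention and fix the canonical founder order used everywhere in this
package (state spaces, frequency tables, mosaic labels).
"""

FOUNDER_IDS = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HlLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

FOUNDER_CODES = "ABCDEFGH"

N_FOUNDERS = 8

#: wild-derived founders (CAST/EiJ and PWK/PhJ are additionally of
#: non-domesticus subspecific origin)
WILD_DERIVED = ("CAST/EiJ", "PWK/PhJ", "WSB/EiJ")
NON_DOMESTICUS = ("CAST/EiJ", "PWK/PhJ")

WILD_DERIVED_INDICES = tuple(FOUNDER_IDS.index(f) for f in WILD_DERIVED)
NON_DOMESTICUS_INDICES = tuple(FOUNDER_IDS.index(f) for f in NON_DOMESTICUS)


def founder_index(founder: str) -> int:
    """Map a founder strain name or letter code to its canonical index."""
    if founder in FOUNDER_IDS:
        return FOUNDER_IDS.index(founder)
    if len(founder) == 1 and founder in FOUNDER_CODES:
        return FOUNDER_CODES.index(founder)
    raise ValueError(f"unknown founder: {founder!r}")
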