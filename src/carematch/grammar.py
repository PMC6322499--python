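"""Versioned address grammar for the synthetic generator.

Deliberately small so generated examples stay stable across releases; bump
GRAMMAR_VERSION whenever any list changes.
"""

GRAMMAR_VERSION = 1

# stems used for care-home names
HOME_STEMS = [
    "ELM", "OAK", "BIRCH", "ROWAN", "WILLOW", "MAPLE", "CEDAR", "HOLLY",
    "HAWTHORN", "ASH", "BEECH", "LARCH", "HAZEL", "ALDER", "PINE", "JUNIPER",
    "ORCHARD", "MEADOW", "RIVERSIDE", "HILLSIDE",
]

HOME_SUFFIXES = ["HOUSE", "LODGE", "COURT", "GRANGE", "MANOR", "VILLA"]

SERVICE_TYPES = ["CARE HOME", "NURSING HOME"]

# stems used for private street names; a few overlap with HOME_STEMS on
# purpose so the phonetic matcher sees realistic near-misses
STREET_STEMS = [
    "STATION", "CHURCH", "MILL", "SCHOOL", "BRIDGE", "CASTLE", "HARBOUR",
    "MARKET", "QUEEN", "KING", "VICTORIA", "ALBERT", "GLEN", "STRATH",
    "BRAE", "KIRK", "ELM", "OAK", "MEADOW", "ORCHARD",
]

STREET_TYPES = [
    "STREET", "ROAD", "AVENUE", "LANE", "DRIVE", "TERRACE", "PLACE", "CRESCENT",
]

TOWNS = [
    "DUNBURGH", "KIRKFIELD", "GLENMOUTH", "STRATHAVEN", "BRAEMOOR",
    "EASTHAVEN", "WESTFORD", "NORTHWICK", "SOUTHBANK", "MIDLOTHAN",
]

# substitutions applied in either direction when perturbing addresses
ABBREVIATIONS = {
    "HOUSE": "HSE",
    "STREET": "ST",
    "ROAD": "RD",
    "AVENUE": "AVE",
    "DRIVE": "DR",
    "TERRACE": "TERR",
    "PLACE": "PL",
    "CRESCENT": "CRES",
    "LODGE": "LDG",
    "COURT": "CT",
}
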