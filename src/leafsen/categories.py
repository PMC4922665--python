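"""Shared color-category labels for senescence analysis.

The visible chlorophyll-breakdown sequence (deep green -> pale green ->
yellow -> brown) is discretized into four plant categories; everything
else — pot, soil, support frame, restoration artifacts — is background.
"""

from __future__ import annotations

BACKGROUND = 0
DARK_GREEN = 1
LIGHT_GREEN = 2
LIGHT_YELLOW = 3
BROWN = 4

PLANT_CATEGORIES = (DARK_GREEN, LIGHT_GREEN, LIGHT_YELLOW, BROWN)
SENESCENT_CATEGORIES = (LIGHT_YELLOW, BROWN)

CATEGORY_NAMES = {
    BACKGROUND: "background",
    DARK_GREEN: "dark_green",
    LIGHT_GREEN: "light_green",
    LIGHT_YELLOW: "light_yellow",
    BROWN: "brown",
}
CATEGORY_CODES = {name: code for code, name in CATEGORY_NAMES.items()}
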