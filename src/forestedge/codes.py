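"""Integer class codes shared by the simulator and the stratification stage.

The annual-change raster uses the semantics of a tropical-moist-forest
change product: a pixel is forest when it is undisturbed or (temporarily)
degraded; deforested means converted to another land use; regrowth means
secondary forest on previously deforested land.
"""

from __future__ import annotations

# Annual-change raster classes
UNDISTURBED = 1
DEGRADED = 2
DEFORESTED = 3
REGROWTH = 4
OTHER_NONFOREST = 5  # savannah / other natural non-forest
WATER = 6

CLASS_NAMES = {
    UNDISTURBED: "undisturbed",
    DEGRADED: "degraded",
    DEFORESTED: "deforested",
    REGROWTH: "regrowth",
    OTHER_NONFOREST: "nonforest_other",
    WATER: "water",
}

#: classes counted as moist-forest cover for edge/distance purposes
FOREST_CLASSES = (UNDISTURBED, DEGRADED)

#: natural non-forest classes whose adjacent edges are masked from analysis
NATURAL_NONFOREST_CLASSES = (OTHER_NONFOREST, WATER)

# Analysis strata
STRATUM_EXCLUDED = 0
STRATUM_INTACT = 1
STRATUM_DEGRADED_FIRE = 2
STRATUM_DEGRADED_LOGGING = 3
STRATUM_EDGE_UNDISTURBED = 4
STRATUM_EDGE_BURNED = 5
STRATUM_EDGE_LOGGED = 6
STRATUM_REGROWTH = 7

STRATUM_NAMES = {
    STRATUM_EXCLUDED: "excluded",
    STRATUM_INTACT: "intact",
    STRATUM_DEGRADED_FIRE: "degraded_fire",
    STRATUM_DEGRADED_LOGGING: "degraded_logging",
    STRATUM_EDGE_UNDISTURBED: "edge_undisturbed",
    STRATUM_EDGE_BURNED: "edge_burned",
    STRATUM_EDGE_LOGGED: "edge_logged",
    STRATUM_REGROWTH: "regrowth",
}
STRATUM_CODES = {v: k for k, v in STRATUM_NAMES.items()}

# Degradation drivers
DRIVER_NONE = 0
DRIVER_FIRE = 1
DRIVER_LOGGING = 2
DRIVER_NAMES = {DRIVER_NONE: "none", DRIVER_FIRE: "fire", DRIVER_LOGGING: "logging"}
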