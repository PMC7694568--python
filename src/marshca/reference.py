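"""Published landscape statistics for the Yancheng coastal wetland study frame.

These tables summarise the 1985-2017 Landsat-interpreted landscape of the
core Yancheng rare-bird reserve (Jiangsu, China): a ~23,830 ha strip of
silty intertidal flat bounded landward by the Sheyang seawall road, carrying
shore-parallel belts of Phragmites australis marsh, Suaeda salsa marsh and
open mudflat, with invasive Spartina alterniflora spreading between the
S. salsa belt and the flats since the 1980s.

They serve as worked-example inputs throughout this package: the annual
transition-probability matrix drives simulations, and the centroid/area
series feed the zonation-metric arithmetic.  The raw Landsat classifications
themselves are not needed (or shipped) anywhere.
"""

from __future__ import annotations

import numpy as np

from .markov import TransitionMatrix
from .raster_io import ClassScheme

# class codes used across the package for the study system
PHRAGMITES, SUAEDA, SPARTINA, MUDFLAT, WATER, POND, ROAD = 1, 2, 3, 4, 5, 6, 7

YANCHENG_SCHEME = ClassScheme(
    classes=(
        (PHRAGMITES, "P. australis", True),
        (SUAEDA, "S. salsa", True),
        (SPARTINA, "S. alterniflora", False),
        (MUDFLAT, "mudflat", True),
        (WATER, "water", False),
        (POND, "aquaculture pond", False),
        (ROAD, "road", False),
    ),
    nodata_code=0,
)

#: Annual landscape transition probabilities estimated from the 1985 and
#: 1990 scenes (rows: source class; columns: destination).  The mudflat row
#: sums to 0.9999 as printed; the constructor renormalizes it.
TRANSITION_1985_1990_ANNUAL = TransitionMatrix(
    probs=np.array(
        [
            # S. salsa  P. australis  mudflat
            [0.8789, 0.1128, 0.0083],   # S. salsa
            [0.0183, 0.9802, 0.0015],   # P. australis
            [0.0598, 0.0031, 0.9370],   # mudflat
        ]
    ),
    class_codes=[SUAEDA, PHRAGMITES, MUDFLAT],
    step_years=1.0,
)

#: Simulated no-invasion centroid distances from the seawall baseline (m).
CENTROID_DISTANCE_M = {
    PHRAGMITES: {1995: 5079.82, 2000: 5268.48, 2005: 5424.88,
                 2010: 5641.46, 2015: 5867.64, 2017: 5957.32},
    SUAEDA: {1995: 7949.92, 2000: 8328.99, 2005: 8665.32,
             2010: 8919.29, 2015: 9141.70, 2017: 9231.02},
    MUDFLAT: {1995: 13243.89, 2000: 13451.33, 2005: 13644.77,
              2010: 13819.33, 2015: 13977.54, 2017: 14041.36},
}

#: Observed class areas (hectares) per interpretation year.  Blank entries
#: (aquaculture ponds before 2000) are absent keys.
AREAS_HA = {
    SUAEDA: {1985: 3773.05, 1990: 4584.83, 1995: 4771.35, 2000: 5227.79,
             2005: 3385.65, 2010: 2656.16, 2015: 1498.06, 2017: 992.46},
    PHRAGMITES: {1985: 5038.48, 1990: 4887.95, 1995: 4765.92, 2000: 3221.19,
                 2005: 4904.90, 2010: 5602.39, 2015: 8242.41, 2017: 8751.37},
    SPARTINA: {1985: 214.53, 1990: 211.52, 1995: 680.60, 2000: 2173.89,
               2005: 3381.34, 2010: 4318.84, 2015: 3985.08, 2017: 3925.46},
    MUDFLAT: {1985: 14424.51, 1990: 13592.65, 1995: 13232.36, 2000: 10213.61,
              2005: 8640.78, 2010: 8140.35, 2015: 8417.34, 2017: 8295.04},
    WATER: {1985: 318.86, 1990: 492.74, 1995: 328.18, 2000: 545.36,
            2005: 813.28, 2010: 445.59, 2015: 504.19, 2017: 472.38},
    POND: {2000: 2018.31, 2005: 2209.76, 2010: 2261.26, 2015: 252.81,
           2017: 342.92},
    ROAD: {1985: 61.00, 1990: 60.82, 1995: 52.07, 2000: 430.31,
           2005: 494.83, 2010: 405.87, 2015: 930.70, 2017: 1050.98},
}

#: Total mapped area per year (ha); varies in the last digit with round-off.
TOTAL_AREA_HA = {1985: 23830.43, 1990: 23830.51, 1995: 23830.47,
                 2000: 23830.46, 2005: 23830.54, 2010: 23830.46,
                 2015: 23830.60, 2017: 23830.60}

#: The 1985 S. alterniflora area appears as 214.53 ha in the area table but
#: as 514.53 ha in the accompanying change narrative; only 514.53 is
#: arithmetically consistent with the published 662.92 % increase to 2017,
#: so percent-change examples use this value.  Both are kept on purpose.
SPARTINA_1985_NARRATIVE_HA = 514.53

#: Simulated (no-invasion) S. salsa area in 2017 vs the observed 992.46 ha;
#: basis of the published 82.47 % invasion-attributed reduction.
SUAEDA_2017_SIMULATED_HA = 5662.05

#: P. australis farthest-boundary displacement: 3,443 m seaward over the
#: 32-year 1985-2017 record (107.6 m/yr).
PHRAGMITES_FARTHEST_SHIFT_M = 3443.0
PHRAGMITES_FARTHEST_SPAN_YR = 32.0
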