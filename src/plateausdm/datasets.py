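"""Published range-area tables for the Qinghai-Tibet Plateau study system.

These are the reported potential-distribution areas (km^2) of the Tibetan
brown bear (*Ursus arctos pruinosus*), Himalayan marmot (*Marmota
himalayana*) and plateau pika (*Ochotona curzoniae*) by administrative
region under current climate and three emissions scenarios (RCP2.6/4.5/8.5,
2070s), and the areas of the three overlay classes (S1 ideal range, S2
stepping stone, S3 potential conflict zone) for the bear. They serve as
worked-example inputs for the change and proportion statistics.
"""

from __future__ import annotations

import pandas as pd

SCENARIOS = ("current", "RCP2.6", "RCP4.5", "RCP8.5")
REGIONS = ("Xizang", "Qinghai", "Sichuan", "Yunnan", "Xinjiang", "Gansu")

#: Reported area (km^2) by species, region and scenario.
RANGE_AREAS_KM2 = {
    "bear": {
        "Xizang":  {"current": 642343.61, "RCP2.6": 651577.48, "RCP4.5": 567331.63, "RCP8.5": 645814.36},
        "Qinghai": {"current": 421295.48, "RCP2.6": 395380.60, "RCP4.5": 346558.75, "RCP8.5": 346268.03},
        "Sichuan": {"current": 102907.05, "RCP2.6": 88633.88,  "RCP4.5": 58023.57,  "RCP8.5": 64609.53},
        "Yunnan":  {"current": 7533.52,   "RCP2.6": 7177.22,   "RCP4.5": 3160.95,   "RCP8.5": 4136.99},
        "Xinjiang": {"current": 6957.97,  "RCP2.6": 6767.15,   "RCP4.5": 8475.66,   "RCP8.5": 1288.42},
        "Gansu":   {"current": 5124.31,   "RCP2.6": 3682.63,   "RCP4.5": 3537.42,   "RCP8.5": 2965.59},
    },
    "marmot": {
        "Xizang":  {"current": 52413.97,  "RCP2.6": 49080.28,  "RCP4.5": 43156.33,  "RCP8.5": 51535.47},
        "Qinghai": {"current": 259639.59, "RCP2.6": 242533.23, "RCP4.5": 227969.42, "RCP8.5": 218038.43},
        "Sichuan": {"current": 78665.32,  "RCP2.6": 71804.75,  "RCP4.5": 56748.35,  "RCP8.5": 57033.27},
        "Yunnan":  {"current": 3823.42,   "RCP2.6": 3224.75,   "RCP4.5": 2903.24,   "RCP8.5": 2297.26},
        "Xinjiang": {"current": 3257.27,  "RCP2.6": 2005.21,   "RCP4.5": 2157.15,   "RCP8.5": 3950.64},
        "Gansu":   {"current": 43289.90,  "RCP2.6": 44047.56,  "RCP4.5": 45019.70,  "RCP8.5": 44906.17},
    },
    "pika": {
        "Xizang":  {"current": 144816.69, "RCP2.6": 134413.59, "RCP4.5": 129228.87, "RCP8.5": 125658.35},
        "Qinghai": {"current": 475453.75, "RCP2.6": 468369.41, "RCP4.5": 460831.66, "RCP8.5": 452042.43},
        "Sichuan": {"current": 45074.20,  "RCP2.6": 36371.21,  "RCP4.5": 29995.39,  "RCP8.5": 25029.01},
        "Yunnan":  {"current": 40.33,     "RCP2.6": 32.61,     "RCP4.5": 14.54,     "RCP8.5": 4.28},
        "Xinjiang": {"current": 3348.85,  "RCP2.6": 2664.37,   "RCP4.5": 3127.92,   "RCP8.5": 3695.65},
        "Gansu":   {"current": 38800.99,  "RCP2.6": 36285.71,  "RCP4.5": 36475.27,  "RCP8.5": 32512.86},
    },
}

#: Reported overlay-class areas (km^2) for the brown bear.
OVERLAY_AREAS_KM2 = {
    "S1": {"current": 672069.89, "RCP2.6": 607325.00, "RCP4.5": 622232.59, "RCP8.5": 524734.89},
    "S2": {"current": 476582.59, "RCP2.6": 483532.11, "RCP4.5": 415412.91, "RCP8.5": 491984.19},
    "S3": {"current": 673196.01, "RCP2.6": 686836.28, "RCP4.5": 787833.15, "RCP8.5": 653517.54},
}


def range_area_table(species: str, scenario: str) -> pd.DataFrame:
    """Zonal-area table (label/region/scenario_tag/area_km2/proportion_pct)
    for one species and scenario, built from the published areas."""
    from .overlay import areas_table
    areas = {r: RANGE_AREAS_KM2[species][r][scenario] for r in REGIONS}
    return areas_table(label=species, scenario_tag=scenario, areas_by_region=areas)


def total_range_area(species: str, scenario: str) -> float:
    """Published range area (km^2) summed over the six regions."""
    return sum(RANGE_AREAS_KM2[species][r][scenario] for r in REGIONS)
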