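"""Bundled default configuration: analyte panel, toxicity constants, exposure parameters.

The toxicity constants (reference doses and the arsenic slope factor) are the
standard USEPA/IRIS oral-ingestion values for the 15 non-carcinogenic PTEs
assessed here. Method detection limits (MDL), error fractions (EF) and most
drinking-water limits are *placeholders* in the style of Chinese monitoring
practice — every study should override them with its laboratory's values via
an analyte config file (see :func:`ptesr.data.load_analyte_config`).
"""

from __future__ import annotations

# The 17-analyte PTE panel, in the order used throughout (μg/L everywhere).
PTE_PANEL: tuple[str, ...] = (
    "Fe", "Mn", "Cu", "Zn", "Al", "Hg", "As", "Se", "Cd",
    "Pb", "Li", "B", "Ba", "Sb", "Ni", "Co", "Mo",
)

# Oral reference doses, mg/(kg·d).  Hg and Pb are in the panel but carry no
# RfD here and are excluded from the hazard index.
RFD_MG_PER_KG_DAY: dict[str, float] = {
    "Fe": 0.7,
    "Mn": 0.14,
    "Cu": 0.04,
    "Zn": 0.3,
    "Al": 1.0,
    "As": 0.0003,
    "Se": 0.005,
    "Cd": 0.0005,
    "Li": 0.002,
    "B": 0.2,
    "Ba": 0.2,
    "Sb": 0.0004,
    "Ni": 0.02,
    "Co": 0.0003,
    "Mo": 0.005,
}

# Cancer slope factors, kg·d/mg.  Only arsenic is treated as a carcinogen.
SF_KG_DAY_PER_MG: dict[str, float] = {
    "As": 1.5,
}

# Class-III drinking-water limits, μg/L.  Hg/Cd/As/Se are the values the
# assessment is anchored on; Fe/Al/Mn/Zn are GB 3838-2002-style placeholders.
DRINKING_LIMITS_UG_L: dict[str, float] = {
    "Fe": 300.0,
    "Mn": 100.0,
    "Zn": 1000.0,
    "Al": 200.0,
    "Hg": 1.0,
    "Cd": 5.0,
    "As": 10.0,
    "Se": 10.0,
}

# PLACEHOLDER method detection limits, μg/L, and error fractions
# (dimensionless).  Chosen at magnitudes typical for AAS analysis of each
# element; replace with the laboratory's reported values.
MDL_UG_L: dict[str, float] = {
    "Fe": 10.0, "Mn": 1.0, "Cu": 0.5, "Zn": 2.0, "Al": 10.0,
    "Hg": 0.04, "As": 0.3, "Se": 0.4, "Cd": 0.05, "Pb": 0.1,
    "Li": 0.3, "B": 2.0, "Ba": 1.0, "Sb": 0.05, "Ni": 0.5,
    "Co": 0.05, "Mo": 0.1,
}

ERROR_FRACTION: dict[str, float] = {name: 0.10 for name in PTE_PANEL}

# PLACEHOLDER ingestion exposure parameters per population group, in the
# style of Chinese technical-guideline values:
#   IR  ingestion rate, L/day;  EF  exposure frequency, days/year;
#   ED  exposure duration, years;  BW  body weight, kg;
#   LE  life expectancy, years.
EXPOSURE_DEFAULTS: dict[str, dict[str, float]] = {
    "children": {"IR": 1.0, "EF": 365.0, "ED": 6.0, "BW": 16.0, "LE": 70.0},
    "men": {"IR": 2.0, "EF": 365.0, "ED": 30.0, "BW": 65.0, "LE": 70.0},
    "women": {"IR": 1.7, "EF": 365.0, "ED": 30.0, "BW": 55.0, "LE": 70.0},
}
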