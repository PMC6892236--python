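"""Published characterization data for the XylE / XYL10C fragment-swap family.

These are measured bench values for the GH10 xylanase XylE (from
*Penicillium canescens*), its thermophilic homolog XYL10C (from *Bispora*
sp. MEY-1) and their fragment-replacement hybrids, kept here as worked
example inputs for the arithmetic layer (catalytic efficiency, fold
changes, Delta-T50, degree of synergy).  Nothing in this module is
computed; the toolkit recomputes the derivable columns from these inputs.

Columns: Km (mg/mL), Vmax (umol/min/mg), kcat (/s), kcat/Km (mL/s/mg),
specific activity (U/mg).  ``None`` marks a construct with no detectable
activity.
"""

from __future__ import annotations

#: per-enzyme kinetic characterization (beechwood xylan substrate)
KINETIC_TABLE: dict[str, dict[str, float | None]] = {
    "XYL10C":         {"km": 0.54, "vmax": 3600.0, "kcat": 2400.0, "kcat_over_km": 4400.0, "specific_activity": 3200.0},
    "XylE":           {"km": 0.75, "vmax": 680.0,  "kcat": 430.0,  "kcat_over_km": 570.0,  "specific_activity": 610.0},
    "XylE-M3":        {"km": 0.61, "vmax": 1390.0, "kcat": 860.0,  "kcat_over_km": 1340.0, "specific_activity": 1310.0},
    "XylE-M6":        {"km": 0.42, "vmax": 1160.0, "kcat": 740.0,  "kcat_over_km": 1760.0, "specific_activity": 1150.0},
    "XylE-M9":        {"km": 0.46, "vmax": 1390.0, "kcat": 900.0,  "kcat_over_km": 1960.0, "specific_activity": 1130.0},
    "XylE-M3/M6":     {"km": 0.62, "vmax": 2200.0, "kcat": 1410.0, "kcat_over_km": 2280.0, "specific_activity": 2010.0},
    "XylE-M3/M9":     {"km": 0.42, "vmax": 880.0,  "kcat": 570.0,  "kcat_over_km": 1370.0, "specific_activity": 730.0},
    "XylE-M6/M9":     {"km": 0.57, "vmax": 1280.0, "kcat": 820.0,  "kcat_over_km": 1440.0, "specific_activity": 1270.0},
    "XylE-M3/M6/M9":  {"km": 0.67, "vmax": 1760.0, "kcat": 1170.0, "kcat_over_km": 1750.0, "specific_activity": 1500.0},
    "XYL10C-M3":      {"km": None, "vmax": None,   "kcat": None,   "kcat_over_km": None,   "specific_activity": None},
    "XYL10C-M6":      {"km": 2.02, "vmax": 2530.0, "kcat": 1890.0, "kcat_over_km": 940.0,  "specific_activity": 1830.0},
    "XYL10C-M9":      {"km": None, "vmax": None,   "kcat": None,   "kcat_over_km": None,   "specific_activity": None},
}

#: the seven active XylE-recipient hybrids
XYLE_HYBRIDS: tuple[str, ...] = (
    "XylE-M3", "XylE-M6", "XylE-M9",
    "XylE-M3/M6", "XylE-M3/M9", "XylE-M6/M9", "XylE-M3/M6/M9",
)

#: T50 (degC): pre-incubation temperature retaining 50% activity after 30 min
T50_TABLE: dict[str, float] = {
    "XylE": 66.5,
    "XylE-M3": 71.2,
    "XylE-M3/M6": 70.4,
    "XylE-M3/M9": 70.0,
    "XylE-M3/M6/M9": 69.5,
}

#: half-lives (h) at 65 degC; wild type plus the stabilized hybrids' range
HALF_LIFE_TABLE: dict[str, float] = {"XylE": 1.2}
STABILIZED_HALF_LIFE_RANGE_H: tuple[float, float] = (1.8, 2.3)

#: calorimetric Tm (degC) — an external DSC measurement, stored only
TM_TABLE: dict[str, float] = {"XylE": 56.1}

#: reducing sugar (umol/mL) after 15 h of mulberry-bark hydrolysis:
#: cellulase alone, each xylanase alone, and the simultaneous arms
SYNERGY_15H: dict[str, dict[str, float]] = {
    "XylE":          {"cellulase_only": 3.2, "xylanase_only": 0.28, "both": 3.6},
    "XylE-M3/M6":    {"cellulase_only": 3.2, "xylanase_only": 0.45, "both": 3.9},
    "XylE-M3/M6/M9": {"cellulase_only": 3.2, "xylanase_only": 0.36, "both": 4.2},
}

#: theoretical mature-protein mass band (kDa) for the XylE constructs
THEORETICAL_MASS_KDA: float = 37.0
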