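"""Published study values for the pongamia-shell / *Rhodotorula pacifica* system.

These constants transcribe the printed tables of the source study — FAME
compositions of the oil grown on alkali-treated saccharified pongamia-shell
hydrolysate (AS-PSH), acid-treated detoxified hydrolysate (AD-PSH) and YNB
control medium; the hydrolysate nutrient composition before/after
cultivation; batch endpoints; and the pretreatment stream summaries.  They
parameterize the synthetic-data generators and serve as desk-scale inputs
for the worked examples.

All concentrations keep the units they were printed in (g/L unless noted
mg/L); compositions are weight percent.  ``None`` encodes "not detected".
"""

from __future__ import annotations

#: FAME composition (wt %) of AS-PSH-grown oil. Includes the 0.1 % C15:0
#: reported only in the running text; the column sums to 96.70, not 100.
AS_PSH_FAME: dict[str, float] = {
    "C14:0": 0.89,
    "C15:0": 0.10,
    "C16:0": 28.85,
    "C18:1": 52.58,
    "C18:2": 12.45,
    "C18:3": 1.37,
    "C22:0": 0.46,
}

#: FAME composition (wt %) of AD-PSH-grown oil (sums to 99.42).
AD_PSH_FAME: dict[str, float] = {
    "C16:0": 14.45,
    "C18:0": 6.13,
    "C18:1": 61.98,
    "C18:2": 16.86,
}

#: FAME composition (wt %) of YNB-grown oil (sums to 54.56 as printed).
YNB_FAME: dict[str, float] = {
    "C14:0": 0.55,
    "C16:0": 10.40,
    "C18:1": 43.61,
}

#: TLC densitometry lipid-class percentages of the selected isolate.
LIPID_CLASS_PERCENT = {"tag": 67.92, "dag": 10.29, "mag": 12.11, "ffa": 9.67}

#: Batch endpoints after 120 h: (DCW g/L, lipid titre g/L).
BATCH_ENDPOINTS: dict[str, tuple[float, float]] = {
    "as_psh": (12.56, 7.02),
    "ad_psh": (10.63, 4.48),
    # DCW and content as printed; the titre consistent with both is 6.65 g/L
    "ynb": (12.26, 6.65),
}

#: Batch duration (h) for all endpoint-based kinetics.
BATCH_DURATION_H = 120.0

#: Initial sugar concentrations (g/L) per medium.
INITIAL_SUGARS: dict[str, dict[str, float]] = {
    "as_psh": {"glucose": 28.05, "xylose": 18.13, "arabinose": 0.29},
    "ad_psh": {"glucose": 0.45, "xylose": 29.01, "arabinose": 2.45},
    # YNB with 3 % glucose
    "ynb": {"glucose": 30.0},
}

#: AS-PSH nutrient composition before/after cultivation:
#: analyte -> (unit, before_mean, before_sd, after_mean, after_sd).
#: ``None`` marks "not detected".
HYDROLYSATE_TABLE: dict[str, tuple[str, float | None, float | None, float | None, float | None]] = {
    "glucose": ("g/L", 28.05, 0.01, None, None),
    "xylose": ("g/L", 18.13, 0.04, 0.05, 0.08),
    "arabinose": ("g/L", 0.29, 0.01, None, None),
    "total_proteins": ("g/L", 0.33, 0.02, 0.23, 0.005),
    "total_nitrogen": ("g/L", 0.053, 0.01, 0.037, 0.02),
    "calcium": ("mg/L", 107.0, 0.87, 6.3, 2.28),
    "sodium": ("g/L", 1.08, 0.15, 0.84, 0.28),
    "magnesium": ("g/L", 1.53, 0.003, 0.22, 0.06),
    "phosphorus": ("g/L", 1.51, 0.001, 0.36, 0.12),
    "potassium": ("g/L", 1.53, 0.005, 0.38, 0.12),
    "manganese": ("mg/L", 0.37, 0.05, 0.24, 0.07),
    "iron": ("mg/L", 0.067, 0.009, 0.036, 0.021),
    "5_hmf": ("g/L", 0.013, 0.005, 0.01, 0.01),
    "acetic_acid": ("g/L", 0.046, 0.01, None, None),
}

#: Analytes in HYDROLYSATE_TABLE that are fermentable sugars.
SUGAR_ANALYTES = ("glucose", "xylose", "arabinose")

#: Pretreatment stream summaries: total fermentable sugars (g/L) and
#: inhibitor levels (g/L) per stream at 20 % w/v solids loading.
PRETREATMENT_STREAMS = {
    # acid-treatment liquid fraction, before activated-charcoal detox
    "acid-liquid": {
        "total_sugars": 37.38,
        "acetic_acid": 5.61,
        "acetic_acid_sd": 0.035,
    },
    # same stream after detox (= AD-PSH)
    "acid-liquid-detox": {
        "total_sugars": 31.91,
        "total_sugars_sd": 0.042,
        "acetic_acid": 0.11,
        "acetic_acid_sd": 0.005,
        "furfural": 0.0,
        "5_hmf": 0.0,
    },
    "alkali-liquid": {"total_sugars": 0.7},
    "acid-solid-sacch": {"total_sugars": 7.63, "acetic_acid": 0.3, "furfural": 0.19},
    # enzymatic saccharification of the alkali-treated solids (= AS-PSH)
    "alkali-solid-sacch": {
        "total_sugars": 46.47,
        "5_hmf": 0.013,
        "furfural": 0.0,
        "acetic_acid": 0.046,
    },
}

#: Solids loading (% w/v) of the pretreatment.
SOLIDS_LOADING_PCT = 20.0

#: Overall mass-balance row: shells loading % w/v, DCW g/L, lipid g/L,
#: biodiesel g/L.
MASS_BALANCE_ROW = {"ps_loading_pct": 20.0, "dcw": 12.8, "lipid": 6.8, "biodiesel": 6.24}

#: Nile-red screening campaign size and reported RFU–gravimetry correlation.
SCREENING_N_STRAINS = 57
SCREENING_TARGET_R = 0.94
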