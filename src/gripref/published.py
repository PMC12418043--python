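"""Published normative reference values bundled as package data.

These are the printed age- and sex-specific reference standards for absolute
handgrip strength (HGS, kg) of adolescents aged 12–16 from South Punjab,
Pakistan, together with the study's descriptive anthropometrics, its
back-generation (holdout cross-validation) table and its population zone
counts.  They serve three purposes:

* regression anchors — the LMS triples printed alongside the percentile
  cells they generate let every centile be recomputed and compared;
* defaults for the synthetic cohort generator (stratum sizes, HGS triples,
  height/weight medians and IQRs);
* inputs for rebuilding the Health Benefit Zone cut-off table.

All values are stored exactly as printed (2 decimals for kg, 3 for L and S).
"""

from __future__ import annotations

from .bccg import LMSTriple

__all__ = [
    "PERCENTILE_SET",
    "AGES",
    "SEXES",
    "LMS_TRIPLES",
    "REFERENCE_CELLS",
    "STRATUM_N",
    "HEIGHT_MEDIAN_IQR",
    "WEIGHT_MEDIAN_IQR",
    "HBZ_BANDS",
    "ZONE_COUNTS",
    "BACKGEN_ACTUAL",
    "BACKGEN_FITTED",
    "BACKGEN_ROW_MAPE",
    "BACKGEN_AVERAGE_MAPE",
]

#: Percentile ranks the reference tables tabulate.
PERCENTILE_SET: tuple[float, ...] = (3.0, 10.0, 35.0, 50.0, 65.0, 90.0)

AGES: tuple[int, ...] = (12, 13, 14, 15, 16)
SEXES: tuple[str, str] = ("boys", "girls")

#: Printed (L, M, S) triples per sex and age.
LMS_TRIPLES: dict[str, dict[int, LMSTriple]] = {
    "boys": {
        12: LMSTriple(lam=0.227, mu=22.53, sigma=0.483),
        13: LMSTriple(lam=-0.004, mu=25.77, sigma=0.432),
        14: LMSTriple(lam=-0.198, mu=29.00, sigma=0.393),
        15: LMSTriple(lam=-0.339, mu=32.24, sigma=0.364),
        16: LMSTriple(lam=-0.413, mu=35.47, sigma=0.345),
    },
    "girls": {
        12: LMSTriple(lam=0.268, mu=14.12, sigma=0.279),
        13: LMSTriple(lam=0.442, mu=15.01, sigma=0.317),
        14: LMSTriple(lam=0.615, mu=16.48, sigma=0.331),
        15: LMSTriple(lam=0.789, mu=18.16, sigma=0.293),
        16: LMSTriple(lam=0.963, mu=20.18, sigma=0.286),
    },
}

#: Printed percentile cells (kg), keyed sex -> age -> {rank: value}.
REFERENCE_CELLS: dict[str, dict[int, dict[float, float]]] = {
    "boys": {
        12: {3.0: 8.14, 10.0: 11.56, 35.0: 18.63, 50.0: 22.53, 65.0: 27.03, 90.0: 40.21},
        13: {3.0: 11.45, 10.0: 14.82, 35.0: 21.82, 50.0: 25.77, 65.0: 30.43, 90.0: 44.86},
        14: {3.0: 14.55, 10.0: 17.94, 35.0: 24.98, 50.0: 29.00, 65.0: 33.82, 90.0: 49.31},
        15: {3.0: 17.42, 10.0: 20.90, 35.0: 28.11, 50.0: 32.24, 65.0: 37.22, 90.0: 53.58},
        16: {3.0: 19.96, 10.0: 23.63, 35.0: 31.17, 50.0: 35.47, 65.0: 40.66, 90.0: 57.81},
    },
    "girls": {
        12: {3.0: 8.02, 10.0: 9.59, 35.0: 12.66, 50.0: 14.12, 65.0: 15.70, 90.0: 19.87},
        13: {3.0: 7.51, 10.0: 9.69, 35.0: 13.24, 50.0: 15.01, 65.0: 16.90, 90.0: 21.81},
        14: {3.0: 7.52, 10.0: 10.08, 35.0: 14.43, 50.0: 16.48, 65.0: 18.63, 90.0: 24.03},
        15: {3.0: 8.81, 10.0: 11.63, 35.0: 16.14, 50.0: 18.16, 65.0: 20.23, 90.0: 25.23},
        16: {3.0: 9.46, 10.0: 12.84, 35.0: 17.96, 50.0: 20.18, 65.0: 22.41, 90.0: 27.62},
    },
}

#: Realized stratum sizes (sex, age) -> n; totals 1477 boys + 1493 girls = 2970.
#: The printed per-age girls counts sum to 1,492, one short of the published
#: girls total; the age-14 stratum is incremented by one to reconcile.
STRATUM_N: dict[tuple[str, int], int] = {
    ("boys", 12): 291, ("boys", 13): 295, ("boys", 14): 298,
    ("boys", 15): 298, ("boys", 16): 295,
    ("girls", 12): 299, ("girls", 13): 298, ("girls", 14): 296,
    ("girls", 15): 300, ("girls", 16): 300,
}

#: Height (cm): (sex, age) -> (median, IQR).
HEIGHT_MEDIAN_IQR: dict[tuple[str, int], tuple[float, float]] = {
    ("boys", 12): (149.00, 14.00), ("boys", 13): (159.00, 15.00),
    ("boys", 14): (165.00, 11.00), ("boys", 15): (165.00, 9.00),
    ("boys", 16): (167.00, 12.00),
    ("girls", 12): (153.00, 14.00), ("girls", 13): (158.00, 14.00),
    ("girls", 14): (162.00, 8.00), ("girls", 15): (162.00, 10.00),
    ("girls", 16): (162.00, 8.00),
}

#: Weight (kg): (sex, age) -> (median, IQR).
WEIGHT_MEDIAN_IQR: dict[tuple[str, int], tuple[float, float]] = {
    ("boys", 12): (35.55, 13.00), ("boys", 13): (43.00, 12.80),
    ("boys", 14): (48.00, 9.63), ("boys", 15): (44.83, 7.25),
    ("boys", 16): (49.00, 10.00),
    ("girls", 12): (35.50, 11.00), ("girls", 13): (38.00, 9.00),
    ("girls", 14): (40.00, 8.75), ("girls", 15): (43.50, 9.00),
    ("girls", 16): (44.00, 8.00),
}

#: Printed Health Benefit Zone band strings, sex -> age -> zone -> string.
HBZ_BANDS: dict[str, dict[int, dict[str, str]]] = {
    "boys": {
        12: {"Very Poor": "8.14–11.56", "Poor": "11.57–18.63", "Medium": "18.64–27.03",
             "Good": "27.04–40.21", "Excellent": "≥40.22"},
        13: {"Very Poor": "11.45–14.82", "Poor": "14.83–21.82", "Medium": "21.83–30.43",
             "Good": "30.44–44.86", "Excellent": "≥44.87"},
        14: {"Very Poor": "14.55–17.94", "Poor": "17.95–24.98", "Medium": "24.99–33.82",
             "Good": "33.83–49.31", "Excellent": "≥49.32"},
        15: {"Very Poor": "17.42–20.90", "Poor": "20.91–28.11", "Medium": "28.12–37.22",
             "Good": "37.23–53.58", "Excellent": "≥53.59"},
        16: {"Very Poor": "19.96–23.63", "Poor": "23.64–31.17", "Medium": "31.18–40.66",
             "Good": "40.67–57.81", "Excellent": "≥57.82"},
    },
    "girls": {
        12: {"Very Poor": "8.02–9.59", "Poor": "9.60–12.66", "Medium": "12.67–15.70",
             "Good": "15.71–19.87", "Excellent": "≥19.88"},
        13: {"Very Poor": "7.51–9.69", "Poor": "9.70–13.24", "Medium": "13.25–16.90",
             "Good": "16.91–21.81", "Excellent": "≥21.82"},
        14: {"Very Poor": "7.52–10.08", "Poor": "10.09–14.43", "Medium": "14.44–18.63",
             "Good": "18.64–24.03", "Excellent": "≥24.04"},
        15: {"Very Poor": "8.81–11.63", "Poor": "11.64–16.14", "Medium": "16.15–20.23",
             "Good": "20.24–25.23", "Excellent": "≥25.24"},
        16: {"Very Poor": "9.46–12.84", "Poor": "12.85–17.96", "Medium": "17.97–22.41",
             "Good": "22.42–27.62", "Excellent": "≥27.63"},
    },
}

#: Published population zone counts: zone -> (total, boys, girls).
ZONE_COUNTS: dict[str, tuple[int, int, int]] = {
    "Very Poor": (329, 148, 181),
    "Poor": (669, 328, 341),
    "Medium": (970, 553, 417),
    "Good": (730, 302, 428),
    "Excellent": (272, 146, 126),
}

def reference_table(sex: str):
    """The bundled printed percentile table as a :class:`ReferenceTable`.

    Rows carry both the printed triples and the printed percentile cells
    (not recomputed ones), so reconstruction harnesses can diff them.
    """
    from .reference import ReferenceRow, ReferenceTable

    rows = [
        ReferenceRow(age=float(age), lms=LMS_TRIPLES[sex][age],
                     percentile_values=dict(REFERENCE_CELLS[sex][age]))
        for age in AGES
    ]
    return ReferenceTable(sex=sex, rows=rows, percentile_set=PERCENTILE_SET)


#: Back-generation test medians: sex -> {age: kg}.
BACKGEN_ACTUAL: dict[str, dict[int, float]] = {
    "boys": {12: 22.53, 13: 25.77, 14: 29.00, 15: 32.24, 16: 35.47},
    "girls": {12: 14.12, 13: 15.01, 14: 16.48, 15: 18.16, 16: 20.18},
}
BACKGEN_FITTED: dict[str, dict[int, float]] = {
    "boys": {12: 23.20, 13: 25.00, 14: 29.55, 15: 31.10, 16: 37.50},
    "girls": {12: 13.95, 13: 14.50, 14: 14.95, 15: 19.10, 16: 21.00},
}
#: Printed per-row signed MAPE (2 dp) and block averages (3 dp).
BACKGEN_ROW_MAPE: dict[str, dict[int, float]] = {
    "boys": {12: -0.03, 13: 0.03, 14: -0.02, 15: 0.04, 16: -0.05},
    "girls": {12: 0.01, 13: 0.04, 14: 0.10, 15: -0.05, 16: -0.04},
}
BACKGEN_AVERAGE_MAPE: dict[str, float] = {"boys": -0.007, "girls": 0.012}
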